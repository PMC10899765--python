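"""Screening-campaign reporting layer.

Turns the campaign's count pairs (numerators and denominators at each stage
of the funnel) into the percentages a screen report quotes: overall hit
rate, validation rate, secondary-screen fraction, interaction-database
coverage, cross-line confirmation, translation-inhibition fraction, and the
ribosomal-protein gene-group union. The defaults are the counts from the
MCF10A nucleolar-number campaign this pipeline models; any stage can be
overridden with recomputed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict


def ratio_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``decimals``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class ScreenCounts:
    """Count pairs across the screening funnel (defaults: the modeled
    campaign's printed counts)."""

    hits_one_nucleolus: int = 64
    hits_five_plus: int = 9
    library_size: int = 2603
    validated: int = 71
    validation_tested: int = 73
    secondary_pass: int = 51
    secondary_tested: int = 72
    db_covered_hits: int = 32
    db_hit_universe: int = 71
    db_covered_library: int = 1074
    cross_line_pass: int = 17
    cross_line_tested: int = 27
    translation_inhibited: int = 14
    translation_tested: int = 15
    rp_s_genes: int = 35
    rp_l_genes: int = 54

    @property
    def total_hits(self) -> int:
        return self.hits_one_nucleolus + self.hits_five_plus

    @property
    def rp_gene_union(self) -> int:
        return self.rp_s_genes + self.rp_l_genes

    def percentages(self) -> dict[str, float]:
        """Every funnel percentage, on the 0-100 scale."""
        return {
            "hit_rate_pct": ratio_percent(self.total_hits, self.library_size),
            "validation_rate_pct": ratio_percent(
                self.validated, self.validation_tested
            ),
            "secondary_inhibition_pct": ratio_percent(
                self.secondary_pass, self.secondary_tested
            ),
            "db_hit_coverage_pct": ratio_percent(
                self.db_covered_hits, self.db_hit_universe
            ),
            "db_library_coverage_pct": ratio_percent(
                self.db_covered_library, self.library_size
            ),
            "cross_line_confirmation_pct": ratio_percent(
                self.cross_line_pass, self.cross_line_tested
            ),
            "translation_inhibition_pct": ratio_percent(
                self.translation_inhibited, self.translation_tested
            ),
        }

    def summary(self) -> dict[str, float | int]:
        out: dict[str, float | int] = dict(asdict(self))
        out.update(self.percentages())
        out["total_hits"] = self.total_hits
        out["rp_gene_union"] = self.rp_gene_union
        return out
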