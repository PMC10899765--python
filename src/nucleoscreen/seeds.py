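"""Canonical microRNA seed-site scanning.

Finds exact ungapped antisense matches between mature miRNAs and target
transcripts. Two search modes are provided:

* :func:`scan_transcript` — all maximal ungapped antisense matches anchored at
  miRNA nucleotide 1 or 2, used to search long transcripts (e.g. a 45S
  pre-rRNA-like precursor) for potential binding sites.
* :func:`find_utr_sites` — canonical 3' UTR site detection (6mer, 7mer-m8,
  7mer-A1, 8mer), anchored at the seed (miRNA nt 2-7), with tandem-pair calls.

Only exact Watson-Crick pairing is considered; there is no G:U wobble and no
thermodynamic scoring. T and U are interchangeable on input; sequences are
normalized to RNA internally but coordinates always refer to the input
transcript, 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

_RNA = set("ACGU")
_TO_RNA = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: canonical site types, weakest to strongest
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U; reject non-ACGU characters."""
    s = seq.upper().translate(_TO_RNA)
    bad = set(s) - _RNA
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA/DNA sequence (returned as RNA)."""
    return normalize_rna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature microRNA, 5'->3', 18-26 nt over {A,C,G,U}."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if not 18 <= len(self.seq) <= 26:
            raise ValueError(
                f"{self.id}: mature miRNA length {len(self.seq)} outside 18-26"
            )

    @property
    def seed6(self) -> str:
        """Target-side match for the seed, miRNA nt 2-7 (revcomp)."""
        return revcomp(self.seq[1:7])

    @property
    def seed7m8(self) -> str:
        """Target-side match for miRNA nt 2-8 (revcomp)."""
        return revcomp(self.seq[1:8])


@dataclass(frozen=True)
class SeedSite:
    """An antisense seed match on a transcript.

    ``start``/``end`` are 0-based half-open transcript coordinates. The
    transcript subsequence equals the reverse complement of miRNA nucleotides
    ``mirna_start .. mirna_start+length-1`` (1-based miRNA positions).
    """

    transcript_id: str
    start: int
    end: int
    site_type: str
    mirna_id: str
    mirna_start: int
    length: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def scan_transcript(
    mirna: MatureMiRNA,
    transcript: str,
    transcript_id: str = "transcript",
    min_len: int = 7,
) -> list[SeedSite]:
    """All maximal ungapped antisense matches starting at miRNA nt 1 or 2.

    A match of length ``l`` anchored at miRNA nucleotide ``s`` (1 or 2) pairs
    miRNA positions ``s .. s+l-1`` with ``l`` consecutive transcript
    nucleotides in antisense orientation; only matches with ``l >= min_len``
    that cannot be extended on the miRNA 3' side are reported. Matches under
    the two start rules are reported separately even when they overlap.
    """
    tx = normalize_rna(transcript)
    n = len(tx)
    if n < min_len:
        return []
    t_enc = _encode(tx)
    comp = _encode(revcomp(mirna.seq)[::-1])  # comp[i] complements mirna[i]
    sites: list[SeedSite] = []
    for s0 in (0, 1):  # 0-based miRNA anchor
        kmax = len(mirna.seq) - s0
        # match[u, p]: transcript[p - u] pairs miRNA nt (s0 + u)
        run = np.zeros(n, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        for u in range(kmax):
            m = np.zeros(n, dtype=bool)
            if u < n:
                m[u:] = t_enc[: n - u] == comp[s0 + u]
            alive &= m
            if not alive.any():
                break
            run[alive] += 1
        for p in np.nonzero(run >= min_len)[0]:
            l = int(run[p])
            sites.append(
                SeedSite(
                    transcript_id=transcript_id,
                    start=int(p) - l + 1,
                    end=int(p) + 1,
                    site_type="antisense",
                    mirna_id=mirna.id,
                    mirna_start=s0 + 1,
                    length=l,
                )
            )
    sites.sort(key=lambda s: (s.start, s.mirna_start))
    return sites


def find_utr_sites(
    mirna: MatureMiRNA,
    utr: str,
    transcript_id: str = "utr",
    site_types: Sequence[str] = SITE_TYPES,
    tandem_window: int = 50,
) -> tuple[list[SeedSite], list[tuple[SeedSite, SeedSite]]]:
    """Canonical seed sites in a 3' UTR, plus tandem pairs.

    Site anatomy on the target, 5'->3': ``[m8][seed match nt7..2][A1]`` where
    the seed match is the exact reverse complement of miRNA nt 2-7, the m8
    position complements miRNA nt 8 (7mer-m8/8mer) and the A1 position is an
    adenosine opposite miRNA nt 1 (7mer-A1/8mer). Each seed occurrence is
    reported once with the strongest requested type it satisfies. A tandem
    pair is two sites whose starts differ by at most ``tandem_window``.
    """
    unknown = set(site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types {sorted(unknown)}")
    tx = normalize_rna(utr)
    seed = mirna.seed6
    m8_base = mirna.seed7m8[0]  # complements miRNA nt 8, 5' of the seed match
    sites: list[SeedSite] = []
    i = tx.find(seed)
    while i != -1:
        has_m8 = i >= 1 and tx[i - 1] == m8_base
        has_a1 = i + 6 < len(tx) and tx[i + 6] == "A"
        satisfied = ["6mer"]
        if has_a1:
            satisfied.append("7mer-A1")
        if has_m8:
            satisfied.append("7mer-m8")
        if has_m8 and has_a1:
            satisfied.append("8mer")
        chosen = [t for t in satisfied if t in site_types]
        if chosen:
            stype = max(chosen, key=SITE_TYPES.index)
            if stype == "8mer":
                start, end, m_start, length = i - 1, i + 7, 1, 8
            elif stype == "7mer-m8":
                start, end, m_start, length = i - 1, i + 6, 2, 7
            elif stype == "7mer-A1":
                start, end, m_start, length = i, i + 7, 1, 7
            else:
                start, end, m_start, length = i, i + 6, 2, 6
            sites.append(
                SeedSite(transcript_id, start, end, stype, mirna.id, m_start, length)
            )
        i = tx.find(seed, i + 1)
    pairs = [
        (a, b)
        for k, a in enumerate(sites)
        for b in sites[k + 1 :]
        if b.start - a.start <= tandem_window
    ]
    return sites, pairs


def scramble_site(
    utr: str,
    span: tuple[int, int],
    mirnas: Iterable[MatureMiRNA],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> str:
    """Permute the nucleotides of ``span`` so that no canonical site remains.

    Composition of the span is preserved exactly. The scramble is re-drawn
    until no 6mer seed match for any miRNA in ``mirnas`` remains anywhere in
    the modified region extended by one seed length on each side (every
    canonical site type contains the 6mer seed core, so absence of 6mer
    matches implies absence of all types).
    """
    a, b = span
    tx = normalize_rna(utr)
    if not (0 <= a < b <= len(tx)):
        raise ValueError(f"span {span} outside UTR of length {len(tx)}")
    seeds = [m.seed6 for m in mirnas]
    chars = np.array(list(tx[a:b]))
    flank = 8
    for _ in range(max_tries):
        perm = rng.permutation(chars)
        cand = tx[:a] + "".join(perm) + tx[b:]
        region = cand[max(0, a - flank) : min(len(cand), b + flank)]
        if not any(s in region for s in seeds):
            return cand
    raise ValueError(
        f"could not scramble span {span}: composition admits a seed match "
        f"after {max_tries} attempts"
    )


def sites_vs_inhibition(
    site_counts: Sequence[float], inhibition: Sequence[float]
) -> dict:
    """Correlation between per-miRNA site counts and percent inhibition.

    Returns Pearson and Spearman coefficients with two-sided p-values; a
    zero-variance input yields NaN coefficients with a warning, never an
    error.
    """
    x = np.asarray(site_counts, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    out = {"n": int(x.size)}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        out.update(pearson_r=np.nan, pearson_p=np.nan,
                   spearman_r=np.nan, spearman_p=np.nan)
        return out
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    out.update(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_r=float(sr.statistic), spearman_p=float(sr.pvalue),
    )
    return out
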