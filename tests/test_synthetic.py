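"""Synthetic generators: determinism, planted-effect calibration, null
behavior, and config validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucleoscreen import screen as sc
from nucleoscreen import seeds as sd
from nucleoscreen.synthetic import (
    SimConfig,
    SitePlan,
    gen_5eu_plate,
    gen_assay_tables,
    gen_interaction_db,
    gen_nucleolus_counts,
    gen_precursor_quants,
    gen_sequences,
    screen_truth,
)


class TestSimConfig:
    def test_magnitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(effect_sizes={"mimic-0001": ("one-nucleolus", 1.2)})

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(effect_sizes={"mimic-0001": ("two-nucleoli", 0.5)})

    def test_unknown_control_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(control_wells={"siFOO": ("A01",)})

    def test_overlapping_control_wells_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(control_wells={"siNT": ("A01",), "siKIF11": ("A01",)})

    def test_nonpositive_eu_sd_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(eu_sd=0.0)

    def test_truth_covers_every_mimic_once(self):
        cfg = SimConfig(n_mimics=25)
        truth = screen_truth(cfg)
        assert len(truth) == 25
        assert truth["mimic"].is_unique


class TestNucleolusCounts:
    def test_same_seed_identical_tables(self, small_config):
        a, ta = gen_nucleolus_counts(small_config)
        b, tb = gen_nucleolus_counts(small_config)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_differs(self, small_config):
        a, _ = gen_nucleolus_counts(small_config)
        cfg2 = SimConfig(**{**small_config.__dict__, "seed": 8})
        b, _ = gen_nucleolus_counts(cfg2)
        assert not a.equals(b)

    def test_baseline_mass_on_two_to_four(self):
        cfg = SimConfig(seed=3, n_mimics=10, cells_per_well_mean=2000,
                        plate_bias_sd=0.0, noise_sd=0.0)
        wells, _ = gen_nucleolus_counts(cfg)
        nt = wells[wells["treatment"] == "siNT"]
        mids = nt[["count_2", "count_3", "count_4"]].sum(axis=1).sum()
        assert mids / nt["n_cells"].sum() >= 0.8

    def test_full_magnitude_one_nucleolus(self):
        cfg = SimConfig(
            seed=3, n_mimics=5, cells_per_well_mean=10_000,
            plate_bias_sd=0.0, noise_sd=0.0, n_replicate_plates=1,
            effect_sizes={"mimic-0001": ("one-nucleolus", 1.0)},
        )
        wells, _ = gen_nucleolus_counts(cfg)
        row = wells[wells["treatment"] == "mimic-0001"].iloc[0]
        assert row["pct_one"] >= 90.0

    def test_full_magnitude_five_plus(self):
        cfg = SimConfig(
            seed=3, n_mimics=5, cells_per_well_mean=10_000,
            plate_bias_sd=0.0, noise_sd=0.0, n_replicate_plates=1,
            effect_sizes={"mimic-0001": ("five-plus", 1.0)},
        )
        wells, _ = gen_nucleolus_counts(cfg)
        row = wells[wells["treatment"] == "mimic-0001"].iloc[0]
        assert row["pct_fiveplus"] >= 90.0

    def test_null_mimics_distributed_like_sint(self):
        """Zero-magnitude mimic wells and siNT wells draw from the same law:
        their per-well one-nucleolus percentages are exchangeable."""
        cfg = SimConfig(seed=5, n_mimics=100, cells_per_well_mean=500)
        wells, _ = gen_nucleolus_counts(cfg)
        nt = wells.loc[wells["treatment"] == "siNT", "pct_one"]
        lib = wells[wells["treatment"].str.startswith("mimic")]
        # compare within single plates to avoid plate-bias confounding
        plate = wells["plate"].iloc[0]
        nt_p = nt[wells["plate"] == plate]
        lib_p = lib.loc[lib["plate"] == plate, "pct_one"]
        _, p = stats.mannwhitneyu(nt_p, lib_p)
        assert p > 0.01

    def test_per_cell_expansion_consistent(self, small_config):
        wells, _ = gen_nucleolus_counts(small_config)
        cells, _ = gen_nucleolus_counts(small_config, per_cell=True)
        per_well = cells.groupby(["plate", "well"])["nucleolus_count"]
        counts = per_well.apply(lambda s: (s == 1).sum()).sort_index()
        manual = wells.set_index(["plate", "well"])["count_1"].sort_index()
        pd.testing.assert_series_equal(
            counts, manual, check_names=False, check_dtype=False
        )

    def test_toxic_mimic_reduces_cell_count(self):
        cfg = SimConfig(
            seed=5, n_mimics=40, cells_per_well_mean=1000,
            toxic_mimics=frozenset({f"mimic-{i:04d}" for i in range(1, 21)}),
        )
        wells, _ = gen_nucleolus_counts(cfg)
        toxic = wells[wells["treatment"].isin(cfg.toxic_mimics)]
        healthy = wells[
            wells["treatment"].str.startswith("mimic")
            & ~wells["treatment"].isin(cfg.toxic_mimics)
        ]
        assert toxic["n_cells"].mean() < 0.9 * healthy["n_cells"].mean()
        assert (toxic["percent_viability"] <= 100.0).all()


class TestEuPlate:
    def test_anchor_means(self, small_config):
        truth = screen_truth(small_config)
        eu = gen_5eu_plate(small_config, truth)
        means = eu.groupby("treatment")["median_nucleolar_EU"].mean()
        assert means["siNT"] == pytest.approx(1000, abs=30)
        assert means["siPOLR1A"] == pytest.approx(200, abs=30)

    def test_linear_interpolation_of_inhibition(self):
        cfg = SimConfig(seed=2, n_mimics=3, eu_sd=1e-6, n_eu_replicates=1,
                        inhibition={"mimic-0001": 0.5})
        truth = screen_truth(cfg)
        eu = gen_5eu_plate(cfg, truth)
        val = eu.loc[eu["treatment"] == "mimic-0001",
                     "median_nucleolar_EU"].iloc[0]
        assert val == pytest.approx(600.0, abs=0.01)

    def test_deterministic(self, small_config):
        truth = screen_truth(small_config)
        a = gen_5eu_plate(small_config, truth)
        b = gen_5eu_plate(small_config, truth)
        pd.testing.assert_frame_equal(a, b)


class TestInteractionDb:
    def test_null_enrichment_equal_medians(self):
        cfg = SimConfig(seed=17, n_db_mirnas=400, enrichment_factor=1.0)
        inter, _, nucleolar, _ = gen_interaction_db(cfg)
        nuc = set(nucleolar)
        counts = (
            inter[inter["gene"].isin(nuc) & (inter["direction"] == "down")
                  & (inter["species"] == "Homo sapiens")]
            .groupby("mirna")["gene"].nunique()
        )
        hits = {f"hsa-miR-sim-{i}" for i in range(1, 41)}
        hit_med = counts[counts.index.isin(hits)].median()
        non_med = counts[~counts.index.isin(hits)].median()
        assert hit_med == pytest.approx(non_med, abs=2)

    def test_unexpressed_fraction(self):
        cfg = SimConfig(seed=17, frac_unexpressed=0.25)
        _, tpm, _, _ = gen_interaction_db(cfg)
        zero_rows = (tpm == 0).all(axis=1).mean()
        assert zero_rows == pytest.approx(0.25, abs=0.02)

    def test_all_expressed_when_fraction_zero(self):
        cfg = SimConfig(seed=17, frac_unexpressed=0.0)
        _, tpm, _, _ = gen_interaction_db(cfg)
        assert (tpm > 0).all(axis=None)

    def test_rp_groups_disjoint(self):
        cfg = SimConfig(seed=17)
        _, _, nucleolar, rp = gen_interaction_db(cfg)
        assert not (set(rp["S"]) & set(rp["L"]))
        assert not (set(rp["S"]) | set(rp["L"])) & set(nucleolar)


class TestPrecursorQuants:
    def test_zero_noise_nc_gives_zero_log_ratios(self):
        from nucleoscreen import ramp as rp

        cfg = SimConfig(seed=1, precursor_noise_sd=0.0)
        quants, truth = gen_precursor_quants(
            cfg, treatments={"t1": "n.c."}
        )
        sig = rp.ramp_ratios(quants)
        assert np.allclose(sig.loc["t1"].astype(float), 0.0, atol=1e-10)

    def test_negative_archetype_rejected(self):
        cfg = SimConfig(
            seed=1,
            archetype_means={"bad": {"30S": -1.0}},
        )
        with pytest.raises(ValueError):
            gen_precursor_quants(cfg, treatments={"t": "bad"})

    def test_reproducible(self):
        cfg = SimConfig(seed=30)
        a, _ = gen_precursor_quants(cfg)
        b, _ = gen_precursor_quants(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestSequences:
    def test_planted_site_round_trip(self):
        cfg = SimConfig(seed=2)
        out = gen_sequences(
            cfg, [SitePlan("hsa-miR-28-5p", "utr", 40, "6mer")]
        )
        m = out["mirnas"]["hsa-miR-28-5p"]
        sites, _ = sd.find_utr_sites(m, out["transcripts"]["utr"])
        assert [(s.start, s.site_type) for s in sites] == [(40, "6mer")]

    def test_tandem_spacing(self):
        cfg = SimConfig(seed=2)
        out = gen_sequences(
            cfg,
            [SitePlan("hsa-miR-28-5p", "utr", 40, "6mer",
                      n_sites=2, spacing=10)],
        )
        m = out["mirnas"]["hsa-miR-28-5p"]
        sites, pairs = sd.find_utr_sites(m, out["transcripts"]["utr"])
        assert [s.start for s in sites] == [40, 50]
        assert len(pairs) == 1

    def test_scrambled_variant_has_no_sites(self):
        cfg = SimConfig(seed=2)
        out = gen_sequences(
            cfg,
            [SitePlan("hsa-miR-28-5p", "utr", 40, "6mer", n_sites=2,
                      spacing=12)],
        )
        for m in out["mirnas"].values():
            sites, _ = sd.find_utr_sites(m, out["scrambled"]["utr"])
            assert sites == []

    def test_site_overlapping_end_rejected(self):
        cfg = SimConfig(seed=2)
        with pytest.raises(ValueError):
            gen_sequences(
                cfg,
                [SitePlan("hsa-miR-28-5p", "utr", 298, "6mer")],
            )

    def test_composition_preserved_by_scramble(self):
        cfg = SimConfig(seed=2)
        out = gen_sequences(
            cfg, [SitePlan("hsa-miR-28-5p", "utr", 40, "8mer")]
        )
        assert sorted(out["transcripts"]["utr"]) == sorted(out["scrambled"]["utr"])


class TestAssayTables:
    def test_zero_shared_variance_gives_null_r2(self):
        from nucleoscreen import compare as cp

        cfg = SimConfig(seed=3, sibling_shared_sd=0.0, sibling_noise_a=1.0,
                        sibling_r2=0.61, sibling_target_fraction=0.0)
        tables = gen_assay_tables(cfg)
        res = cp.lfc_regression(tables["sibling_lfc"])
        assert res.r_squared < 0.01

    def test_deterministic(self):
        cfg = SimConfig(seed=3)
        a = gen_assay_tables(cfg)
        b = gen_assay_tables(cfg)
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_calibrator_generated_at_null(self):
        from nucleoscreen import assays as aq

        cfg = SimConfig(seed=3)
        tables = gen_assay_tables(
            cfg, ct_effects={("m", "CDKN1A"): 1.0}, n_bio_replicates=10,
            ct_sd=0.02,
        )
        out = aq.ddct(tables["ct"])
        assert out.loc[out["sample"] == "siNT", "log2_fold"].mean() == \
            pytest.approx(0.0, abs=0.05)


class TestScreenPipelineRecovery:
    def test_planted_hits_recovered_small_screen(self, small_config):
        wells, truth = gen_nucleolus_counts(small_config)
        res = sc.primary_screen(wells, small_config.mimic_ids,
                                quantiles={"one-nucleolus": 0.05,
                                           "five-plus": 0.05})
        assert bool(res.loc["mimic-0001", "hit_one"])
        assert bool(res.loc["mimic-0002", "hit_five"])
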