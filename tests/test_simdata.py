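"""Generator tests: design counts, zero-noise exactness, variance structure,
mechanistic-curve properties and fixture determinism."""

import numpy as np
import pandas as pd
import pytest

from qpcrkit import simdata
from qpcrkit.simdata import (AmpCurve, CqTruth, CurveTruth, StudyDesign,
                             simulate_amp_curve, simulate_cq_dataset,
                             simulate_curve_set)


def _noise_free_truth(genes, **kw):
    return CqTruth(baseline={g: 20.0 + i for i, g in enumerate(genes)},
                   tech_sd={g: 0.0 for g in genes}, loading_sd=0.0, **kw)


class TestDesignCounts:
    def test_default_counts(self):
        d = StudyDesign()
        assert d.n_groups == 24
        assert d.n_samples == 240
        assert len(d.reference_genes) == 6
        assert len(d.target_genes) == 6

    def test_record_counts(self, default_dataset):
        design, _, records, meta, latent = default_dataset
        assert len(meta) == 240
        study = records[~records["is_calibrator"]]
        cal = records[records["is_calibrator"]]
        assert len(study) == 240 * 12 * 2
        # 3 calibrators x 12 genes x 3 plates x triplicate
        assert len(cal) == 3 * 12 * 3 * 3
        assert set(study["plate"]) == {1, 2, 3}
        assert latent["sample"].nunique() == 240 + 3

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            StudyDesign(ages=[])
        with pytest.raises(ValueError):
            StudyDesign(samples_per_cell=1)
        with pytest.raises(ValueError):
            CqTruth(baseline={"A": 20.0}, tech_sd={"A": -1.0})
        with pytest.raises(ValueError):
            CqTruth(baseline={"A": 20.0}, tech_sd={"A": 0.1}, failure_rate=1.5)


class TestCqGenerator:
    def test_zero_noise_exactness(self):
        design = StudyDesign(ages=[30], temperatures=["Low"], samples_per_cell=4,
                             reference_genes=["A", "B"], target_genes=[],
                             plates=1, calibrators=1, seed=3)
        truth = _noise_free_truth(["A", "B"])
        records, meta, latent = simulate_cq_dataset(design, truth)
        study = records[~records["is_calibrator"]]
        for g, base in [("A", 20.0), ("B", 21.0)]:
            assert np.allclose(study.loc[study["gene"] == g, "cq"], base)
        assert np.allclose(latent.loc[latent["gene"] == "A", "latent_cq"], 20.0)

    def test_group_offset_exact(self):
        design = StudyDesign(ages=[30, 60], temperatures=["Low"], samples_per_cell=3,
                             reference_genes=["A", "B", "C"], target_genes=[],
                             plates=1, calibrators=1, seed=3)
        truth = _noise_free_truth(["A", "B", "C"])
        truth.group_offsets["C"] = {(60, "Low"): 1.5}
        records, meta, latent = simulate_cq_dataset(design, truth)
        lat = latent.merge(meta, on="sample")
        c = lat[lat["gene"] == "C"]
        assert np.allclose(c.loc[c["age_dpf"] == 60, "latent_cq"], 23.5)
        assert np.allclose(c.loc[c["age_dpf"] == 30, "latent_cq"], 22.0)

    def test_plate_offsets_and_replicates(self):
        design = StudyDesign(ages=[30], temperatures=["Low"], samples_per_cell=4,
                             reference_genes=["A"], target_genes=[],
                             plates=2, calibrators=1, seed=0)
        truth = _noise_free_truth(["A"])
        truth.plate_offsets = {1: -0.4, 2: 0.4}
        records, _, _ = simulate_cq_dataset(design, truth)
        study = records[~records["is_calibrator"]]
        for plate, off in [(1, -0.4), (2, 0.4)]:
            sub = study[study["plate"] == plate]
            assert np.allclose(sub["cq"], 20.0 + off)

    def test_variance_composition(self):
        # empirical latent SD converges to sqrt(sum of variance components)
        design = StudyDesign(ages=[30], temperatures=["Low"], samples_per_cell=10000,
                             reference_genes=["A", "B", "C"], target_genes=[],
                             replicates_per_reaction=1, plates=1, calibrators=1,
                             seed=11)
        truth = CqTruth(baseline={"A": 20.0, "B": 21.0, "C": 22.0},
                        tech_sd={g: 0.0 for g in "ABC"}, loading_sd=0.5,
                        gene_sample_sd={"A": 1.2, "B": 0.6, "C": 0.0})
        _, _, latent = simulate_cq_dataset(design, truth)
        for g, expected in [("A", np.hypot(0.5, 1.2)), ("B", np.hypot(0.5, 0.6)),
                            ("C", 0.5)]:
            sd = latent.loc[latent["gene"] == g, "latent_cq"].std(ddof=1)
            assert abs(sd - expected) / expected < 0.05

    def test_coregulation_correlation(self):
        design = StudyDesign(ages=[30], temperatures=["Low"], samples_per_cell=8000,
                             reference_genes=["A", "B", "C"], target_genes=[],
                             replicates_per_reaction=1, plates=1, calibrators=1,
                             seed=12)
        share, rest = 0.8, 0.6
        truth = CqTruth(baseline={g: 20.0 for g in "ABC"},
                        tech_sd={g: 0.0 for g in "ABC"}, loading_sd=0.0,
                        gene_sample_sd={g: rest for g in "ABC"},
                        coreg=[("A", "B", share)])
        _, _, latent = simulate_cq_dataset(design, truth)
        wide = latent.pivot(index="sample", columns="gene", values="latent_cq")
        expected = share**2 / (share**2 + rest**2)
        assert abs(wide["A"].corr(wide["B"]) - expected) < 0.05
        assert abs(wide["A"].corr(wide["C"])) < 0.05

    def test_failures_produce_missing_or_wild(self):
        design = StudyDesign(ages=[30], temperatures=["Low"], samples_per_cell=500,
                             reference_genes=["A"], target_genes=[],
                             plates=1, calibrators=1, seed=5)
        truth = _noise_free_truth(["A"])
        truth.failure_rate = 0.2
        records, _, _ = simulate_cq_dataset(design, truth)
        study = records[~records["is_calibrator"]]
        n_missing = int(study["cq"].isna().sum())
        wild = study["cq"].dropna().sub(20.0).abs()
        n_wild = int((wild > 1.0).sum())
        assert n_missing > 0 and n_wild > 0
        assert wild[wild > 1.0].between(1.2, 3.0).all()

    def test_determinism(self):
        design = StudyDesign(seed=4, samples_per_cell=2)
        r1, m1, l1 = simulate_cq_dataset(design)
        r2, m2, l2 = simulate_cq_dataset(StudyDesign(seed=4, samples_per_cell=2))
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(l1, l2)


class TestCurveGenerator:
    def test_geometric_growth_early(self):
        truth = CurveTruth(e0=1.9, noise_sd=0.0, baseline=0.0, drift=0.0)
        c = simulate_amp_curve(truth)
        ratios = c.fluorescence[1:10] / c.fluorescence[:9]
        assert np.allclose(ratios, 1.9, atol=1e-3)

    def test_plateau_bounded_by_fmax(self):
        truth = CurveTruth(e0=2.0, noise_sd=0.0, baseline=0.0, drift=0.0,
                           cycles=60)
        c = simulate_amp_curve(truth)
        assert c.fluorescence.max() <= truth.fmax * (1.0 + 1e-9)
        # efficiency decays monotonically toward 1
        e_c = c.fluorescence[1:] / c.fluorescence[:-1]
        assert np.all(np.diff(e_c) <= 1e-12)

    def test_threshold_crossing_monotone_in_e0(self):
        def crossing(e0):
            truth = CurveTruth(e0=e0, noise_sd=0.0, baseline=0.0, drift=0.0)
            f = simulate_amp_curve(truth).fluorescence
            return int(np.argmax(f > 1000.0))

        assert crossing(2.0) < crossing(1.9) < crossing(1.8)

    def test_curve_set_counts_and_truth(self):
        curves = simulate_curve_set([1.8, 2.0], 5, seed=9)
        assert len(curves) == 10
        assert {c.true_e0 for c in curves} == {1.8, 2.0}

    def test_validation(self):
        with pytest.raises(ValueError):
            CurveTruth(e0=2.3)
        with pytest.raises(ValueError):
            CurveTruth(cycles=10)
        with pytest.raises(ValueError):
            AmpCurve(np.arange(30.0), np.arange(29.0))
        with pytest.raises(ValueError):
            AmpCurve(np.arange(1.0, 31.0), np.full(30, np.nan))


class TestFixtures:
    def test_fixture_suite_deterministic(self, tmp_path):
        p1 = simdata.make_fixture_suite(13, tmp_path / "a")
        p2 = simdata.make_fixture_suite(13, tmp_path / "b")
        assert set(p1) == set(p2)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_curve_table_roundtrip(self, tmp_path):
        paths = simdata.make_fixture_suite(13, tmp_path)
        df = pd.read_csv(paths["curves_e0_panel"])
        curves = simdata.curves_from_table(df)
        assert len(curves) == 300
        assert all(len(c.cycles) == 40 for c in curves)
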