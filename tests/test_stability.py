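"""Stability-method tests: hand-checked oracles, brute-force equivalence,
invariances and discrimination of a constructed unstable gene."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qpcrkit import simdata
from qpcrkit.preprocess import CqMatrix, average_replicates
from qpcrkit.stability import (BESTKEEPER_SD_CUTOFF, GENORM_M_CUTOFF,
                               bestkeeper, compare_normalization_factors,
                               delta_ct_stability, genorm,
                               genorm_set_stability, normfinder, run_method)


def brute_force_mean_pairwise_sd(values: pd.DataFrame) -> pd.Series:
    out = {}
    for g in values.columns:
        sds = [np.std(values[g] - values[h], ddof=1)
               for h in values.columns if h != g]
        out[g] = float(np.mean(sds))
    return pd.Series(out)


@pytest.fixture
def hand_matrix():
    # SD(g1-g2)=1, SD(g1-g3)=2, SD(g2-g3)=1 (exact, ddof=1)
    return pd.DataFrame({"g1": [0.0, 0.0, 0.0],
                         "g2": [-1.0, 0.0, 1.0],
                         "g3": [-2.0, 0.0, 2.0]},
                        index=["S1", "S2", "S3"])


class TestDeltaCt:
    def test_hand_example(self, hand_matrix):
        res = delta_ct_stability(hand_matrix)
        assert res.values["g1"] == pytest.approx(1.5)
        assert res.values["g2"] == pytest.approx(1.0)
        assert res.values["g3"] == pytest.approx(1.5)
        # g2 most stable; g1/g3 tie resolved by input order
        assert res.ranking == ["g2", "g1", "g3"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            values = pd.DataFrame(rng.normal(20, 2, size=(20, 5)),
                                  columns=list("ABCDE"))
            res = delta_ct_stability(values)
            expected = brute_force_mean_pairwise_sd(values)
            assert np.allclose(res.values[expected.index], expected, atol=1e-12)

    def test_shift_invariances(self, hand_matrix):
        base = delta_ct_stability(hand_matrix).values
        # per-gene constant shift
        shifted = hand_matrix.copy()
        shifted["g1"] += 5.0
        assert np.allclose(delta_ct_stability(shifted).values, base)
        # per-sample constant shift (loading) changes nothing either
        rowshift = hand_matrix.add(pd.Series([1.0, -2.0, 0.5],
                                             index=hand_matrix.index), axis=0)
        assert np.allclose(delta_ct_stability(rowshift).values, base)

    def test_input_validation(self, hand_matrix):
        with pytest.raises(ValueError):
            delta_ct_stability(hand_matrix[["g1", "g2"]])
        with pytest.raises(ValueError):
            delta_ct_stability(hand_matrix.iloc[:2])


class TestBestKeeper:
    def test_hand_example(self):
        values = pd.DataFrame({"g1": [20.0, 21.0, 22.0],
                               "g2": [10.0, 10.1, 10.2]})
        res = bestkeeper(values)
        assert res.values["g1"] == pytest.approx(1.0)
        assert res.extras["cv_percent"]["g1"] == pytest.approx(100.0 / 21.0)
        assert res.ranking == ["g2", "g1"]

    def test_sd_cutoff_flags(self):
        values = pd.DataFrame({"stable": [20.0, 20.2, 20.4, 20.1],
                               "wild": [20.0, 23.0, 18.0, 21.5]})
        res = bestkeeper(values)
        assert BESTKEEPER_SD_CUTOFF == 1.0
        assert res.extras["flagged_genes"] == ["wild"]

    def test_correlation_matrix(self):
        rng = np.random.default_rng(2)
        shared = rng.normal(0, 1, 30)
        values = pd.DataFrame({"a": 20 + shared,
                               "b": 21 + shared + rng.normal(0, 0.1, 30),
                               "c": 19 + rng.normal(0, 1, 30)})
        res = bestkeeper(values)
        r = res.extras["pearson_r"]
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert r.loc["a", "b"] > 0.9
        assert res.extras["pearson_p"].loc["a", "b"] < 1e-6


class TestGeNorm:
    def test_stepwise_toy(self):
        # A and B identical up to a constant; C and D increasingly divergent
        z = np.array([-1.0, 0.0, 1.0, 2.0])
        values = pd.DataFrame({"A": 20.0 + 0.0 * z, "B": 21.0 + 0.0 * z,
                               "C": 20.0 + 1.0 * z, "D": 20.0 + 2.0 * z})
        res = genorm(values)
        assert res.extras["exclusion_order"] == ["D", "C"]
        assert res.extras["final_pair"] == ("A", "B")
        assert res.extras["final_pair_m"] == pytest.approx(0.0)
        assert res.ranking == ["A", "B", "C", "D"]
        assert res.extras["final_pair_acceptable"]
        assert GENORM_M_CUTOFF == 1.5

    def test_round1_equals_delta_ct(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            values = pd.DataFrame(rng.normal(20, 2, size=(20, 5)),
                                  columns=list("ABCDE"))
            r1 = genorm(values).extras["round1_m"]
            dct = delta_ct_stability(values).values
            assert np.allclose(r1[dct.index], dct, atol=1e-12)

    def test_tie_breaking_logged(self):
        # C and D are mirror images: identical M values at round 1
        z = np.array([-1.0, 0.0, 1.0])
        values = pd.DataFrame({"A": [20.0] * 3, "B": [21.0] * 3,
                               "C": 20.0 + z, "D": 20.0 - z})
        res = genorm(values)
        assert res.extras["ties"]  # a tie was recorded
        assert res.extras["exclusion_order"][0] == "D"  # later in input order

    def test_set_stability(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(20, 1, size=(15, 4)),
                              columns=list("ABCD"))
        v = genorm_set_stability(values, ["A", "B", "C"])
        expected = brute_force_mean_pairwise_sd(values[["A", "B", "C"]]).mean()
        assert v == pytest.approx(expected, abs=1e-12)


class TestNormFinder:
    def _matrix(self, rng, n_per_group=8, shifted=None, offset=1.5):
        genes = list("ABCDEF")
        truth = simdata.stable_panel_truth(genes, shifted_gene=shifted,
                                           offset=offset, group=(30, "High"))
        design = simdata.StudyDesign(ages=[30, 60], temperatures=["Low", "High"],
                                     samples_per_cell=n_per_group,
                                     reference_genes=genes, target_genes=[],
                                     plates=1, calibrators=1,
                                     seed=int(rng.integers(1 << 31)))
        records, meta, _ = simdata.simulate_cq_dataset(design, truth)
        return average_replicates(records, meta)

    def test_degenerate_all_equal(self):
        values = pd.DataFrame({g: [20.0 + i for i in range(6)] for g in "ABCD"})
        groups = ["g1"] * 3 + ["g2"] * 3
        res = normfinder(values, groups=groups)
        # every gene identical: no deviation, no intra-group spread
        assert np.allclose(res.values, 0.0)

    def test_sample_shift_invariance(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(20, 1, size=(12, 4)),
                              columns=list("ABCD"))
        groups = ["g1"] * 6 + ["g2"] * 6
        base = normfinder(values, groups=groups).values
        rowshift = values.add(pd.Series(rng.normal(0, 3, 12)), axis=0)
        shifted = normfinder(rowshift, groups=groups).values
        assert np.allclose(shifted, base, atol=1e-10)

    def test_shifted_gene_ranks_last_mostly(self):
        rng = np.random.default_rng(6)
        last = 0
        for _ in range(10):
            m = self._matrix(rng, shifted="F")
            res = normfinder(m)
            if res.ranking[-1] == "F":
                last += 1
        assert last >= 9

    def test_group_variation_shape_and_best_pair(self):
        rng = np.random.default_rng(7)
        m = self._matrix(rng, shifted="F")
        res = normfinder(m)
        gv = res.extras["group_variation"]
        assert list(gv.columns) == ["intra_group", "inter_group"]
        assert set(gv.index) == set("ABCDEF")
        assert gv.loc["F", "inter_group"] > gv.drop("F")["inter_group"].max()
        pair = res.extras["best_pair"]
        assert "F" not in pair and len(pair) == 2
        assert res.extras["best_pair_value"] >= 0

    def test_requires_groups(self):
        values = pd.DataFrame(np.zeros((6, 3)), columns=list("ABC"))
        with pytest.raises(ValueError):
            normfinder(values)
        with pytest.raises(ValueError):
            normfinder(values, groups=["g1"] * 6)  # a single group


class TestNormalizationFactors:
    def test_perfect_reference_gives_zero_intra_sd(self, toy_matrix):
        # a target identical to a reference: delta-Cq is constant -> SD 0
        tgt = toy_matrix.values[["A"]].rename(columns={"A": "T1"})
        table = compare_normalization_factors(toy_matrix, tgt, [["A"]])
        assert table.loc["A", "avg_intragroup_sd"] == pytest.approx(0.0)
        assert table.loc["A", "avg_intergroup_sd"] == pytest.approx(0.0)

    def test_multi_gene_combo_is_mean(self, toy_matrix):
        tgt = toy_matrix.values[["F"]].rename(columns={"F": "T1"})
        t = compare_normalization_factors(toy_matrix, tgt, [["A", "B"], ["A"]])
        nf = toy_matrix.values[["A", "B"]].mean(axis=1)
        dcq = tgt["T1"] - nf
        expected = dcq.groupby(toy_matrix.groups.values).std(ddof=1).mean()
        assert t.loc["A + B", "avg_intragroup_sd"] == pytest.approx(expected)
        assert {"avg_F_group_sd", "avg_M_group_sd"} <= set(t.columns)

    def test_empty_combo_raises(self, toy_matrix):
        tgt = toy_matrix.values[["F"]]
        with pytest.raises(ValueError):
            compare_normalization_factors(toy_matrix, tgt, [[]])


class TestRegistry:
    def test_all_methods_run(self, toy_matrix):
        for name in ("deltact", "bestkeeper", "normfinder", "genorm"):
            res = run_method(name, toy_matrix)
            assert res.method == name
            assert set(res.ranking) == set("ABCDEF")

    def test_unknown_method(self, toy_matrix):
        with pytest.raises(ValueError, match="unknown"):
            run_method("qbase", toy_matrix)

    def test_toy_matrix_bestkeeper_order_by_construction(self, toy_matrix):
        # per-gene SDs are 0.4 * 2**i times a common factor
        res = run_method("bestkeeper", toy_matrix)
        assert res.ranking == list("ABCDEF")
        ratios = res.values[list("BCDEF")].to_numpy() / res.values[list("ABCDE")].to_numpy()
        assert np.allclose(ratios, 2.0)
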