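"""Transcriptomics-chain tests: Grubbs screening, probe QC, target collapse,
quantile normalisation, age correlation and hypergeometric ORA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plaquetime import geomx


class TestGrubbs:
    def test_constant_input_degenerate(self):
        g, crit, idx = geomx.grubbs_statistic(np.array([1.0, 1.0, 1.0]))
        assert g == 0.0 and idx is None

    def test_known_outlier_frozen_values(self):
        # hand-computed: G = 1.7875, critical = 1.7150 at alpha 0.05, n = 5
        g, crit, idx = geomx.grubbs_statistic(np.array([8, 9, 10, 9, 50.0]), 0.05)
        assert g == pytest.approx(1.78753, abs=1e-4)
        assert crit == pytest.approx(1.71504, abs=1e-4)
        assert idx == 4

    def test_no_extreme_point_passes(self):
        g, crit, idx = geomx.grubbs_statistic(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert g < crit and idx is None

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            geomx.grubbs_statistic(np.array([1.0, 2.0]))


def _probe_table(rng, n_rois=12):
    probes, targets, rows = [], {}, []
    for gene in ("Aa", "Bb", "Cc"):
        for j in range(4):
            pid = f"{gene}_p{j}"
            probes.append(pid)
            targets[pid] = gene
            rows.append(rng.poisson(200, n_rois))
    counts = pd.DataFrame(rows, index=probes,
                          columns=[f"roi{i}" for i in range(n_rois)])
    return counts, pd.Series(targets)


class TestProbeQC:
    def test_aberrant_probe_removed(self):
        rng = np.random.default_rng(0)
        counts, targets = _probe_table(rng)
        counts.loc["Aa_p0"] *= 10  # planted 10x aberrant probe
        kept, log = geomx.probe_qc(counts, targets)
        assert "Aa_p0" not in kept.index
        assert (log["probe"] == "Aa_p0").any()

    def test_single_probe_targets_never_grubbs_tested(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            {"roi0": [1000, 5], "roi1": [1000, 5]},
            index=["solo_p0", "solo2_p0"],
        )
        targets = pd.Series({"solo_p0": "Solo", "solo2_p0": "Solo2"})
        kept, log = geomx.probe_qc(
            counts, targets, geomx.QCConfig(low_count_floor=0.0)
        )
        assert set(kept.index) == {"solo_p0", "solo2_p0"}

    def test_zero_floor_disables_low_count_removal(self):
        rng = np.random.default_rng(2)
        counts, targets = _probe_table(rng)
        counts.loc["Bb_p1"] = 1
        _, log_default = geomx.probe_qc(counts, targets)
        _, log_zero = geomx.probe_qc(
            counts, targets, geomx.QCConfig(low_count_floor=0.0)
        )
        assert log_default["reason"].str.contains("floor").any()
        assert not log_zero["reason"].str.contains("floor").any()

    def test_roi_drop_list_applied(self):
        rng = np.random.default_rng(3)
        counts, targets = _probe_table(rng)
        kept, _ = geomx.probe_qc(
            counts, targets, geomx.QCConfig(roi_drop_list=("roi0", "roi3"))
        )
        assert "roi0" not in kept.columns and "roi3" not in kept.columns


class TestCollapseTargets:
    def test_single_probe_identity(self):
        counts = pd.DataFrame({"r1": [7.0], "r2": [9.0]}, index=["g_p0"])
        out = geomx.collapse_targets(counts, pd.Series({"g_p0": "g"}))
        np.testing.assert_allclose(out.loc["g"], [7.0, 9.0])

    def test_geometric_mean_of_two_probes(self):
        counts = pd.DataFrame({"r1": [4.0, 9.0]}, index=["g_p0", "g_p1"])
        out = geomx.collapse_targets(
            counts, pd.Series({"g_p0": "g", "g_p1": "g"}), pseudocount=0.0
        )
        assert out.loc["g", "r1"] == pytest.approx(6.0)

    def test_all_zero_probes_yield_zero(self):
        counts = pd.DataFrame({"r1": [0.0, 0.0]}, index=["g_p0", "g_p1"])
        out = geomx.collapse_targets(
            counts, pd.Series({"g_p0": "g", "g_p1": "g"}), pseudocount=1.0
        )
        # geometric mean of (0+1, 0+1) minus the pseudocount
        assert out.loc["g", "r1"] == pytest.approx(0.0)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        out = geomx.quantile_normalize(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy())

    def test_rank_means_by_hand(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = geomx.quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(3, 1, (50, 6)))
        once = geomx.quantile_normalize(m)
        twice = geomx.quantile_normalize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_column_multisets_identical(self, seed):
        """Tie-free columns share exactly the same value multiset afterwards
        (continuous draws are almost surely tie-free)."""
        rng = np.random.default_rng(seed)
        arr = rng.lognormal(2.0, 1.0, (17, 4))
        out = geomx.quantile_normalize(pd.DataFrame(arr)).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            geomx.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestCorrelateGenes:
    def test_gene_equal_to_age(self):
        age = np.arange(10, dtype=float)
        m = pd.DataFrame([age, age[::-1], np.ones(10)],
                         index=["up", "down", "flat"],
                         columns=[f"r{i}" for i in range(10)])
        out = geomx.correlate_genes(m, age)
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "r"] == pytest.approx(-1.0)
        assert out.loc["up", "p"] < 1e-10
        assert "flat" not in out.index  # constant gene excluded

    def test_bh_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(0)
        age = rng.normal(size=20)
        m = pd.DataFrame(rng.normal(size=(200, 20)),
                         columns=[f"r{i}" for i in range(20)])
        m.index = [f"g{i}" for i in range(200)]
        out = geomx.correlate_genes(m, age)
        assert (out["q"] >= out["p"] - 1e-12).all()
        s = out.sort_values("p")
        assert np.all(np.diff(s["q"].to_numpy()) >= -1e-12)

    def test_direction_labels(self):
        age = np.arange(8, dtype=float)
        m = pd.DataFrame([age + 0.01, -age], index=["pos", "neg"],
                         columns=[f"r{i}" for i in range(8)])
        out = geomx.correlate_genes(m, age)
        assert out.loc["pos", "direction"] == "positive"
        assert out.loc["neg", "direction"] == "negative"

    def test_too_few_rois_rejected(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError):
            geomx.correlate_genes(m, np.array([1.0, 2.0, 3.0]))


def _hypergeom_upper_tail(m, k, n, overlap):
    """Closed-form combinatorial oracle: P(X >= overlap) for drawing n genes
    from a universe of m containing k set members."""
    total = math.comb(m, n)
    return sum(
        math.comb(k, x) * math.comb(m - k, n - x)
        for x in range(overlap, min(k, n) + 1)
    ) / total


class TestORA:
    universe = {f"g{i}" for i in range(20)}

    def test_disjoint_set_has_p_one(self):
        selected = {f"g{i}" for i in range(10)}
        sets = {"disjoint": {f"g{i}" for i in range(10, 15)}}
        res = geomx.ora(set(), sets, self.universe)
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        res2 = geomx.ora(selected, {"far": {"g15", "g16"}}, self.universe)
        assert res2.table["p"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "set_size,sel_size", [(5, 10), (3, 7), (8, 4), (20, 10)]
    )
    def test_matches_combinatorial_oracle(self, set_size, sel_size):
        gene_set = {f"g{i}" for i in range(set_size)}
        selected = {f"g{i}" for i in range(0, 2)} | {
            f"g{i}" for i in range(10, 10 + sel_size - 2)
        }
        selected = set(list(selected)[:sel_size]) & self.universe
        overlap = len(gene_set & selected)
        res = geomx.ora(selected, {"s": gene_set}, self.universe)
        oracle = _hypergeom_upper_tail(20, len(gene_set), len(selected), overlap)
        assert res.table["p"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_selection_equals_universe(self):
        res = geomx.ora(self.universe, {"s": {f"g{i}" for i in range(5)}},
                        self.universe)
        assert res.table["overlap"].iloc[0] == 5
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_bh_within_slices(self):
        rng = np.random.default_rng(0)
        selected = {f"g{i}" for i in range(10)}
        sets = {f"s{i}": set(rng.choice(sorted(self.universe), 5, replace=False))
                for i in range(6)}
        slices = {name: ("BP" if i < 3 else "CC") for i, name in enumerate(sets)}
        res = geomx.ora(selected, sets, self.universe, slices=slices)
        for _, grp in res.table.groupby("slice"):
            assert (grp["q"] >= grp["p"] - 1e-12).all()

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            geomx.ora({"zz"}, {"s": {"g1"}}, self.universe)
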