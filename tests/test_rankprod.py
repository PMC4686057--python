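"""Rank-product statistic, permutation pfp and probeset collapsing."""

import numpy as np
import pandas as pd
import pytest

import fibrodiff as fd
from fibrodiff.rankprod import (
    call_significant,
    collapse_probesets,
    estimate_pfp,
    fold_change,
    pairwise_log_ratios,
    rank_product_statistic,
)
from tests.conftest import make_study


class TestPairwiseLogRatios:
    def test_two_vs_one_design(self):
        study = make_study(np.array([[5.0, 5.0, 3.0]]), ["A", "A", "B"])
        ratios = pairwise_log_ratios(study, fd.Contrast("A-B", "A", "B"))
        assert ratios.to_numpy().tolist() == [[2.0, 2.0]]

    def test_six_vs_six_has_36_columns(self):
        rng = np.random.default_rng(0)
        study = make_study(rng.normal(size=(3, 12)), ["A"] * 6 + ["B"] * 6)
        ratios = pairwise_log_ratios(study, fd.Contrast("A-B", "A", "B"))
        assert ratios.shape == (3, 36)

    def test_swapping_groups_negates_and_transposes(self):
        rng = np.random.default_rng(1)
        study = make_study(rng.normal(size=(4, 5)), ["A"] * 3 + ["B"] * 2)
        fwd = pairwise_log_ratios(study, fd.Contrast("A-B", "A", "B")).to_numpy()
        rev = pairwise_log_ratios(study, fd.Contrast("B-A", "B", "A")).to_numpy()
        fwd3 = fwd.reshape(4, 3, 2)
        rev3 = rev.reshape(4, 2, 3)
        assert np.allclose(rev3, -np.swapaxes(fwd3, 1, 2))

    def test_missing_group_errors(self):
        study = make_study(np.zeros((2, 4)), ["A"] * 2 + ["B"] * 2)
        with pytest.raises(fd.ConfigError):
            pairwise_log_ratios(study, fd.Contrast("A-X", "A", "X"))


class TestRankProductStatistic:
    def test_consistent_top_gene_has_rp_one(self):
        ratios = np.array([[9.0, 8.0], [1.0, 2.0], [0.0, 0.5]])
        rp = rank_product_statistic(ratios, "up")
        assert rp.iloc[0] == 1.0

    def test_hand_ranked_three_gene_example(self):
        # column 1 ranks (desc): g1=1,g2=2,g3=3; column 2: g1=1,g3=2,g2=3
        ratios = np.array([[3.0, 3.0], [2.0, 1.0], [1.0, 2.0]])
        rp = rank_product_statistic(ratios, "up")
        assert rp.iloc[0] == pytest.approx(1.0)
        assert rp.iloc[1] == pytest.approx(np.sqrt(6))
        assert rp.iloc[2] == pytest.approx(np.sqrt(6))

    def test_full_tie_column_gives_midpoint_rank(self):
        g = 5
        ratios = np.full((g, 1), 2.5)
        rp = rank_product_statistic(ratios, "up")
        assert np.allclose(rp, (g + 1) / 2)

    def test_invariant_under_monotone_column_transform(self):
        rng = np.random.default_rng(2)
        ratios = rng.normal(size=(8, 4))
        transformed = ratios.copy()
        transformed[:, 0] = np.exp(transformed[:, 0])        # strictly increasing
        transformed[:, 2] = 3.0 * transformed[:, 2] + 10.0   # affine increasing
        for d in ("up", "down"):
            assert np.allclose(
                rank_product_statistic(ratios, d),
                rank_product_statistic(transformed, d),
            )

    def test_empty_matrix_errors(self):
        with pytest.raises(fd.AnalysisError):
            rank_product_statistic(np.empty((0, 3)), "up")


class TestFoldChange:
    @pytest.mark.parametrize("m,expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0),
                                            (2.5, 2**2.5), (-0.5, -(2**0.5))])
    def test_sign_convention(self, m, expected):
        fc = fold_change(np.array([[m, m]]))
        assert fc.iloc[0] == pytest.approx(expected)

    def test_never_in_open_unit_interval(self):
        rng = np.random.default_rng(3)
        fc = fold_change(rng.normal(scale=0.2, size=(100, 6)))
        assert not ((fc > -1) & (fc < 1)).any()


class TestEstimatePfp:
    def _study(self, seed=0, g=60, npg=4):
        rng = np.random.default_rng(seed)
        values = rng.normal(8, 1, size=(g, 2 * npg))
        return make_study(values, ["P"] * npg + ["C"] * npg)

    def test_pfp_monotone_along_rp_order(self):
        study = self._study()
        t = estimate_pfp(study, fd.Contrast.parse("P-C"), n_permutations=40, seed=1)
        for col, rp_col in (("pfp_up", "rp_up"), ("pfp_down", "rp_down")):
            s = t.stats.sort_values(rp_col)
            assert (s[col].diff().dropna() >= -1e-12).all()

    @pytest.mark.parametrize("scheme", ["labels", "within-gene"])
    def test_swap_symmetry_exchanges_directions(self, scheme):
        study = self._study(seed=5)
        a = estimate_pfp(study, fd.Contrast.parse("P-C"), n_permutations=30,
                         seed=7, scheme=scheme)
        b = estimate_pfp(study, fd.Contrast.parse("C-P"), n_permutations=30,
                         seed=7, scheme=scheme)
        sa = a.stats.set_index("probe").sort_index()
        sb = b.stats.set_index("probe").sort_index()
        assert np.allclose(sa["rp_up"], sb["rp_down"])
        assert np.allclose(sa["pfp_up"], sb["pfp_down"])
        assert np.allclose(sa["pfp_down"], sb["pfp_up"])
        assert np.allclose(sa["fc_signed"], -sb["fc_signed"])

    def test_gene_below_all_nulls_gets_pfp_zero(self):
        # one gene with a huge consistent shift: observed RP 1, never matched by nulls
        rng = np.random.default_rng(8)
        values = rng.normal(8, 0.2, size=(40, 12))
        values[0, :6] += 50.0
        study = make_study(values, ["P"] * 6 + ["C"] * 6)
        t = estimate_pfp(study, fd.Contrast.parse("P-C"), n_permutations=50, seed=2)
        row = t.stats.set_index("probe").loc["g0"]
        assert row["rp_up"] == 1.0
        # the identity bipartition can recur by chance; pfp stays ~2/C(12,6)
        assert row["pfp_up"] < 0.01

    def test_missing_values_excluded_from_contrast(self):
        study = self._study(seed=9, g=10)
        study.values.iloc[3, 1] = np.nan
        t = estimate_pfp(study, fd.Contrast.parse("P-C"), n_permutations=5, seed=0)
        assert len(t.stats) == 9
        assert "g3" not in set(t.stats["probe"])

    def test_singleton_group_rejected(self):
        study = make_study(np.zeros((3, 3)), ["P", "P", "C"])
        with pytest.raises(fd.AnalysisError):
            estimate_pfp(study, fd.Contrast.parse("P-C"), n_permutations=5, seed=0)


class TestCallSignificant:
    def _table(self, pfp_up, pfp_down):
        stats = pd.DataFrame(
            {"probe": [f"p{i}" for i in range(len(pfp_up))],
             "rp_up": 1.0, "rp_down": 1.0,
             "pfp_up": pfp_up, "pfp_down": pfp_down,
             "fc_signed": [2.0] * len(pfp_up)}
        )
        return fd.DETable(fd.Contrast("P-C", "P", "C"), stats, 10, 0)

    def test_strict_threshold_boundary(self):
        t = self._table([0.04, 0.05], [0.9, 0.9])
        up, down = call_significant(t, 0.05)
        assert list(up["probe"]) == ["p0"]  # 0.05 exactly is excluded
        assert down.empty

    def test_both_directions_goes_to_smaller_pfp(self):
        t = self._table([0.01, 0.04], [0.03, 0.002])
        up, down = call_significant(t, 0.05)
        assert list(up["probe"]) == ["p0"]
        assert list(down["probe"]) == ["p1"]

    def test_empty_table_gives_empty_lists(self):
        t = self._table([], [])
        up, down = call_significant(t, 0.05)
        assert up.empty and down.empty

    def test_invalid_threshold(self):
        with pytest.raises(fd.ConfigError):
            call_significant(self._table([0.1], [0.1]), 0.0)


class TestCollapseProbesets:
    def test_best_probe_carries_gene(self):
        up = pd.DataFrame({"probe": ["a1", "a2"], "fc_signed": [2.0, 4.0],
                           "pfp": [0.01, 0.2]})
        down = pd.DataFrame(columns=["probe", "fc_signed", "pfp"])
        gup, gdown, total = collapse_probesets(up, down, {"a1": "GENE", "a2": "GENE"})
        assert total == 1
        assert gup.loc[0, "fc_signed"] == 2.0  # FC of the pfp=0.01 probe

    def test_conflicting_directions_resolved_by_best_pfp(self):
        up = pd.DataFrame({"probe": ["u"], "fc_signed": [2.0], "pfp": [0.001]})
        down = pd.DataFrame({"probe": ["d"], "fc_signed": [-2.0], "pfp": [0.04]})
        ann = {"u": "G1", "d": "G1"}
        gup, gdown, total = collapse_probesets(up, down, ann)
        assert total == 1 and len(gup) == 1 and gdown.empty

    def test_unannotated_probes_dropped_with_count(self):
        up = pd.DataFrame({"probe": ["x", "y"], "fc_signed": [2.0, 2.0],
                           "pfp": [0.01, 0.02]})
        down = pd.DataFrame(columns=["probe", "fc_signed", "pfp"])
        gup, _, total = collapse_probesets(up, down, {"x": "GX"})
        assert total == 1
        assert gup.attrs["n_unannotated"] == 1
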