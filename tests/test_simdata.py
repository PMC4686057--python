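"""The synthetic-data generator: planted effects, reproducibility, validity checks."""

import numpy as np
import pandas as pd
import pytest

import fibrodiff as fd
from fibrodiff.simdata import truth_table


def test_zero_noise_no_effect_gives_identical_group_means():
    cfg = fd.SimConfig(n_genes=30, noise_sd=0.0, de_fraction=0.0,
                       n_reversion_genes=0, seed=1)
    study, truth = fd.simulate_expression_study(cfg)
    means = pd.concat(
        {g: study.group_values(g).mean(axis=1) for g in study.group_names}, axis=1
    )
    assert np.allclose(means.sub(means["P"], axis=0), 0.0)
    assert not truth.de_up and not truth.de_down and not truth.reversion


def test_identical_seed_is_bit_identical():
    cfg = fd.SimConfig(n_genes=50, seed=42,
                       module_specs=[fd.ModuleSpec(5, 0.9, {"P": 1})])
    s1, t1 = fd.simulate_expression_study(cfg)
    s2, t2 = fd.simulate_expression_study(cfg)
    assert s1.values.equals(s2.values)
    assert t1.de_up == t2.de_up and t1.reversion == t2.reversion
    assert t1.module_edges == t2.module_edges


def test_planted_de_mean_shift_matches_generative_mean():
    """Over 200 replicate draws the P−C mean of a planted up gene is de_log2fc."""
    diffs = []
    for seed in range(200):
        cfg = fd.SimConfig(n_genes=40, de_fraction=0.1, de_log2fc=2.0,
                           n_reversion_genes=0, seed=seed)
        study, truth = fd.simulate_expression_study(cfg)
        gene = sorted(truth.de_up)[0]
        diffs.append(
            study.group_values("P").loc[gene].mean()
            - study.group_values("C").loc[gene].mean()
        )
    diffs = np.asarray(diffs)
    sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean() - 2.0) < 3 * sem


def test_module_correlation_present_only_in_active_group():
    cfg = fd.SimConfig(n_genes=60, n_per_group=20, de_fraction=0.0,
                       n_reversion_genes=0, noise_sd=0.5,
                       module_specs=[fd.ModuleSpec(10, 0.9, {"P": 1})], seed=7)
    study, truth = fd.simulate_expression_study(cfg)
    genes = sorted({g for pair in truth.module_edges["P"] for g in pair})

    def median_abs_r(group):
        sub = study.group_values(group).loc[genes].T.corr()
        vals = sub.to_numpy()[np.triu_indices(len(genes), k=1)]
        return np.median(np.abs(vals))

    assert median_abs_r("P") > 0.7
    assert median_abs_r("C") < 0.4


def test_discordant_module_flips_pair_signs_between_groups():
    cfg = fd.SimConfig(n_genes=30, de_fraction=0.0, n_reversion_genes=0,
                       module_specs=[fd.ModuleSpec(6, 0.9, {"P": 1, "C": -1})], seed=3)
    _, truth = fd.simulate_expression_study(cfg)
    p_edges, c_edges = truth.module_edges["P"], truth.module_edges["C"]
    assert set(p_edges) == set(c_edges)
    assert all(s == 1 for s in p_edges.values())
    flipped = [pair for pair, s in c_edges.items() if s == -1]
    assert flipped and len(flipped) < len(c_edges)


def test_truth_categories_are_disjoint_and_exhaustive():
    cfg = fd.SimConfig(n_genes=100, de_fraction=0.1, n_reversion_genes=10,
                       module_specs=[fd.ModuleSpec(8, 0.9, {"P": 1})], seed=5)
    _, truth = fd.simulate_expression_study(cfg)
    tt = truth_table(truth)
    assert not tt["gene"].duplicated().any()
    assert len(tt) == cfg.n_planted
    assert truth.de_up.isdisjoint(truth.de_down)
    assert (truth.de_up | truth.de_down).isdisjoint(truth.reversion)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_genes": 0},
        {"de_fraction": 1.5},
        {"de_log2fc": -1.0},
        {"noise_sd": -0.1},
        {"n_genes": 10, "de_fraction": 0.5, "n_reversion_genes": 20},
        {"module_specs": [fd.ModuleSpec(5, 1.5, {"P": 1})]},
        {"module_specs": [fd.ModuleSpec(5, 0.9, {"X": 1})]},
    ],
)
def test_invalid_config_raises_naming_constraint(kwargs):
    with pytest.raises(fd.ConfigError):
        fd.simulate_expression_study(fd.SimConfig(**kwargs))


def test_downstream_recovery_increases_with_group_size():
    """More lines per arm -> better rank-product recovery of planted genes."""

    def sensitivity(npg, seed):
        cfg = fd.SimConfig(n_genes=400, n_per_group=npg, de_fraction=0.05,
                           de_log2fc=1.5, noise_sd=0.6, n_reversion_genes=0, seed=seed)
        study, truth = fd.simulate_expression_study(cfg)
        table = fd.estimate_pfp(study, fd.Contrast.parse("P-C"),
                                n_permutations=100, seed=seed + 9)
        up, down = fd.call_significant(table, 0.05)
        tp = len(set(up["probe"]) & truth.de_up) + len(set(down["probe"]) & truth.de_down)
        return tp / (len(truth.de_up) + len(truth.de_down))

    small = np.mean([sensitivity(4, s) for s in range(3)])
    large = np.mean([sensitivity(8, s) for s in range(3)])
    assert large > small


class TestCtTable:
    def test_zero_noise_unit_fc_equalizes_dct(self):
        ct = fd.simulate_ct_table(1, 4, [1.0], 0.0, seed=0)
        dct = ct["ct_target"] - ct["ct_reference"]
        assert np.allclose(dct, dct.iloc[0])

    def test_zero_noise_fc2_gives_ddct_minus_one(self):
        ct = fd.simulate_ct_table(1, 4, [2.0], 0.0, seed=0)
        dct = (ct["ct_target"] - ct["ct_reference"]).groupby(ct["group"]).mean()
        assert dct["patient"] - dct["control"] == pytest.approx(-1.0)

    def test_geometric_mean_recovery_under_noise(self):
        recovered = []
        for seed in range(500):
            ct = fd.simulate_ct_table(1, 4, [2.0], 0.3, seed=seed)
            dct = ct["ct_target"] - ct["ct_reference"]
            ddct = dct[ct["group"] == "patient"] - dct[ct["group"] == "control"].mean()
            recovered.append(np.power(2.0, -ddct).to_numpy())
        gm = np.exp(np.mean(np.log(np.concatenate(recovered))))
        assert abs(gm - 2.0) / 2.0 < 0.05

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(fd.ConfigError):
            fd.simulate_ct_table(1, 4, [-2.0], 0.1, seed=0)


class TestPhenotypeTable:
    def test_unit_correlation_rejected(self):
        with pytest.raises(fd.ConfigError):
            fd.simulate_phenotype_table(10, 3, [(0, 1, 1.0)], seed=0)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(fd.ConfigError):
            fd.simulate_phenotype_table(10, 3, [(0, 1, 0.5), (1, 0, 0.4)], seed=0)

    def test_planted_pair_mean_empirical_r(self):
        rs = []
        for s in range(500):
            t = fd.simulate_phenotype_table(8, 2, [(0, 1, 0.9)], seed=s)
            rs.append(np.corrcoef(t["var01"], t["var02"])[0, 1])
        assert 0.8 <= np.mean(rs) <= 0.95

    def test_null_pairs_rarely_exceed_screen_threshold(self):
        tbl = fd.simulate_phenotype_table(30, 20, seed=4)
        corr = tbl.corr().to_numpy()
        vals = np.abs(corr[np.triu_indices(20, k=1)])
        assert (vals < 0.7).mean() >= 0.9
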