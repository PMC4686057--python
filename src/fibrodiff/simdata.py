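"""Synthetic expression studies, CT tables and phenotype tables with planted truth.

The generator emulates the four-arm fibroblast study design — patients (P) and
controls (C), each with and without ascorbic-acid treatment (P_AA, C_AA),
6 lines per arm — on a log2 scale resembling RMA-normalized microarray data:

* a per-gene baseline drawn once and shared across groups, so that any group
  difference is attributable to a planted effect;
* differentially expressed genes shifted by ±`de_log2fc` in both patient arms;
* ascorbic-acid *reversion* genes shifted in P only, so their fold change flips
  sign between the P−C and P_AA−P contrasts while C_AA stays at control level;
* correlation modules built from one latent factor per module with group-specific
  loadings ±√r, which plants pairwise Pearson correlations of exactly ±r in the
  groups where the module is active;
* i.i.d. Gaussian noise of SD `noise_sd` on every remaining value.

Every draw is reproducible from a single seed via a documented stream-splitting
order (baseline → category assignment → effects → module factors → noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .study import DEFAULT_GROUPS, ExpressionStudy


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    ``group_signs`` maps each group where the module is active to +1 or −1.
    All member genes load on one latent factor with magnitude √r; in a group
    with sign −1 the loading sign of odd-indexed member genes is flipped, so
    (even, odd) pairs correlate at −r there while they correlate at +r in a
    +1 group — this is how sign-flipped (discordant) edges are planted.
    """

    n_genes: int
    r: float
    group_signs: dict[str, int]

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("module n_genes must be >= 2")
        if not 0 < abs(self.r) < 1:
            raise ConfigError(f"module target correlation must be in (-1,1)\\{{0}}, got {self.r}")
        for g, s in self.group_signs.items():
            if s not in (-1, 1):
                raise ConfigError(f"module sign for group '{g}' must be +1 or -1, got {s}")


@dataclass
class SimConfig:
    """Configuration of one synthetic expression study."""

    n_genes: int = 20000
    n_per_group: int = 6
    group_names: tuple[str, ...] = DEFAULT_GROUPS
    de_fraction: float = 0.03
    de_log2fc: float = 2.0
    n_reversion_genes: int = 40
    module_specs: list[ModuleSpec] = field(default_factory=list)
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ConfigError("n_genes and n_per_group must be positive")
        if len(self.group_names) != 4 or len(set(self.group_names)) != 4:
            raise ConfigError("group_names must be four distinct labels (P, C, P_AA, C_AA order)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError(f"de_fraction must be in [0,1], got {self.de_fraction}")
        if self.de_log2fc <= 0:
            raise ConfigError("de_log2fc must be positive")
        if self.n_reversion_genes < 0:
            raise ConfigError("n_reversion_genes must be >= 0")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigError("noise_sd and baseline_sd must be >= 0")
        for m in self.module_specs:
            m.validate()
            unknown = set(m.group_signs) - set(self.group_names)
            if unknown:
                raise ConfigError(f"module references unknown groups: {sorted(unknown)}")
        if self.n_planted > self.n_genes:
            raise ConfigError(
                f"planted genes ({self.n_planted}) exceed n_genes ({self.n_genes})"
            )

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))

    @property
    def n_planted(self) -> int:
        return self.n_de + self.n_reversion_genes + sum(m.n_genes for m in self.module_specs)


@dataclass
class PlantedTruth:
    """Ground truth of one simulated study, for recovery tests.

    ``module_edges`` maps group label → {(gene_a, gene_b): expected correlation
    sign} with gene_a < gene_b; only groups where a module is active appear.
    """

    de_up: set[str]
    de_down: set[str]
    reversion: set[str]
    module_edges: dict[str, dict[tuple[str, str], int]]

    def category_of(self, gene: str) -> str:
        if gene in self.de_up:
            return "de_up"
        if gene in self.de_down:
            return "de_down"
        if gene in self.reversion:
            return "reversion"
        for edges in self.module_edges.values():
            for a, b in edges:
                if gene in (a, b):
                    return "module"
        return "background"


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(groups: tuple[str, ...], n_per_group: int) -> tuple[list[str], list[str]]:
    samples, labels = [], []
    for g in groups:
        for i in range(1, n_per_group + 1):
            samples.append(f"{g}_{i}")
            labels.append(g)
    return samples, labels


def simulate_expression_study(config: SimConfig) -> tuple[ExpressionStudy, PlantedTruth]:
    """Draw one study and its planted truth, deterministically from ``config.seed``."""
    config.validate()
    P, C, P_AA, C_AA = config.group_names
    n_genes, npg = config.n_genes, config.n_per_group
    genes = _gene_ids(n_genes)
    samples, labels = _sample_ids(config.group_names, npg)
    group_of_sample = np.array(labels)

    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_assign, rng_factor, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    baseline = rng_base.normal(config.baseline_mean, config.baseline_sd, size=n_genes)

    # assign disjoint gene indices to truth categories
    chosen = rng_assign.choice(n_genes, size=config.n_planted, replace=False)
    n_de = config.n_de
    de_idx = chosen[:n_de]
    rev_idx = chosen[n_de : n_de + config.n_reversion_genes]
    module_idx: list[np.ndarray] = []
    pos = n_de + config.n_reversion_genes
    for m in config.module_specs:
        module_idx.append(chosen[pos : pos + m.n_genes])
        pos += m.n_genes

    n_up = len(de_idx) // 2 + len(de_idx) % 2
    de_up_idx, de_down_idx = de_idx[:n_up], de_idx[n_up:]
    n_rev_up = len(rev_idx) // 2 + len(rev_idx) % 2
    rev_up_idx, rev_down_idx = rev_idx[:n_rev_up], rev_idx[n_rev_up:]

    # group effects (log2 shifts added to the shared baseline)
    effect = np.zeros((n_genes, 4))  # columns in group_names order
    gi = {g: k for k, g in enumerate(config.group_names)}
    fc = config.de_log2fc
    effect[de_up_idx[:, None], [gi[P], gi[P_AA]]] += fc
    effect[de_down_idx[:, None], [gi[P], gi[P_AA]]] -= fc
    # reversion: shifted in P only, back to baseline in P_AA, C_AA at control level
    effect[rev_up_idx, gi[P]] += fc
    effect[rev_down_idx, gi[P]] -= fc

    # module loadings per gene per group (0 where inactive)
    loadings = np.zeros((n_genes, 4))
    module_edges: dict[str, dict[tuple[str, str], int]] = {}
    for m, idx in zip(config.module_specs, module_idx):
        base = np.sqrt(abs(m.r)) * np.ones(len(idx))
        for g, s in m.group_signs.items():
            load = base.copy()
            if s == -1:
                load[1::2] *= -1
            loadings[idx, gi[g]] = load
            edges = module_edges.setdefault(g, {})
            ids = [genes[i] for i in idx]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    ga, gb = sorted((ids[a], ids[b]))
                    edges[(ga, gb)] = int(np.sign(load[a] * load[b]))

    n_samples = len(samples)
    X = baseline[:, None] + effect[:, [gi[g] for g in group_of_sample]]

    # noise: for module genes in active groups the per-value noise is factor-structured
    # (l*f + sqrt(1-l^2)*z) * noise_sd, which keeps the marginal SD at noise_sd while
    # planting pairwise correlation l_i * l_j = +/- r
    factors = rng_factor.normal(size=(len(config.module_specs), n_samples))
    z = rng_noise.normal(size=(n_genes, n_samples))
    noise = z.copy()
    for k, idx in enumerate(module_idx):
        lam = loadings[idx][:, [gi[g] for g in group_of_sample]]
        noise[idx] = lam * factors[k][None, :] + np.sqrt(1.0 - lam**2) * z[idx]
    X = X + config.noise_sd * noise

    values = pd.DataFrame(X, index=genes, columns=samples)
    groups = pd.Series(labels, index=samples, name="group")
    truth = PlantedTruth(
        de_up={genes[i] for i in de_up_idx},
        de_down={genes[i] for i in de_down_idx},
        reversion={genes[i] for i in rev_idx},
        module_edges=module_edges,
    )
    return ExpressionStudy(values, groups), truth


def truth_table(truth: PlantedTruth) -> pd.DataFrame:
    """Flatten a PlantedTruth into a (gene, category) sidecar table."""
    rows = [("%s" % g, "de_up") for g in sorted(truth.de_up)]
    rows += [(g, "de_down") for g in sorted(truth.de_down)]
    rows += [(g, "reversion") for g in sorted(truth.reversion)]
    module_genes = sorted(
        {g for edges in truth.module_edges.values() for pair in edges for g in pair}
    )
    rows += [(g, "module") for g in module_genes]
    return pd.DataFrame(rows, columns=["gene", "category"])


def simulate_ct_table(
    n_targets: int,
    n_samples_per_group: int,
    true_fold_changes,
    ct_noise_sd: float,
    seed: int,
    reference: str = "REF",
) -> pd.DataFrame:
    """Simulate a qPCR CT table whose expected 2^−ΔΔCT equals the given fold changes.

    Returns a long-format table with columns (sample, group, target, reference,
    ct_target, ct_reference); groups are 'patient' and 'control'. The reference
    gene CT is constant up to noise, and the patient-arm target CT is offset by
    −log2(FC) relative to controls, so the geometric mean of per-sample 2^−ΔΔCT
    recovers FC.
    """
    true_fold_changes = np.asarray(true_fold_changes, dtype=float)
    if len(true_fold_changes) != n_targets:
        raise ConfigError("true_fold_changes must have one entry per target")
    if np.any(true_fold_changes <= 0):
        raise ConfigError("fold changes must be positive (linear scale)")
    if ct_noise_sd < 0:
        raise ConfigError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    ref_ct0, dct0 = 20.0, 3.0
    for t in range(n_targets):
        target = f"tgt{t + 1:02d}"
        shift = -np.log2(true_fold_changes[t])
        for group, n, offset in (("control", n_samples_per_group, 0.0),
                                 ("patient", n_samples_per_group, shift)):
            for i in range(1, n + 1):
                rows.append(
                    {
                        "sample": f"{group[0].upper()}{i}",
                        "group": group,
                        "target": target,
                        "reference": reference,
                        "ct_target": ref_ct0 + dct0 + offset + rng.normal(0, ct_noise_sd),
                        "ct_reference": ref_ct0 + rng.normal(0, ct_noise_sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_phenotype_table(
    n_samples: int,
    n_variables: int,
    correlated_pairs=(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a sample-by-variable table with specified pairwise correlations.

    ``correlated_pairs`` is a list of (i, j, target_r) with 0-based variable
    indices and |target_r| < 1; the population correlation of each listed pair
    equals target_r and all other pairs are independent. Draws are from a
    multivariate normal with the implied correlation matrix.
    """
    if n_samples <= 0 or n_variables <= 0:
        raise ConfigError("n_samples and n_variables must be positive")
    cov = np.eye(n_variables)
    seen = set()
    for i, j, r in correlated_pairs:
        if i == j:
            raise ConfigError(f"pair ({i},{j}) is a self-pair")
        if not (0 <= i < n_variables and 0 <= j < n_variables):
            raise ConfigError(f"pair ({i},{j}) out of range for {n_variables} variables")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ConfigError(f"duplicate pair spec for variables {key}")
        seen.add(key)
        if not abs(r) < 1:
            raise ConfigError(f"|target R| must be < 1, got {r}")
        cov[i, j] = cov[j, i] = r
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("requested pair correlations are jointly infeasible "
                          "(correlation matrix not positive definite)") from exc
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_variables)) @ chol.T
    cols = [f"var{k + 1:02d}" for k in range(n_variables)]
    return pd.DataFrame(X, index=[f"S{i + 1}" for i in range(n_samples)], columns=cols)
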