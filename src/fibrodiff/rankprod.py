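"""Two-sample Rank Products differential expression with permutation pfp.

The rank product detects genes that are consistently extreme across replicate
comparisons. For a two-group contrast with n1 and n2 samples, every pairwise
between-group comparison (n1·n2 columns of log2 ratios) is ranked across genes
— descending for up-regulation, ascending for down-regulation, ties averaged —
and the per-gene statistic is the geometric mean of its ranks. A small RP means
the gene is consistently near the top.

Significance is expressed as the permutation-estimated proportion of false
positives (pfp, used interchangeably with "FDR" here): group labels are
randomly re-assigned, null rank products accumulated, and for each observed RP

    pfp = E[# null RP <= observed] / rank of the gene by observed RP,

made monotone non-decreasing along the RP-sorted list.

Two permutation schemes are offered:

* ``labels`` (default) — one random bipartition of the pooled samples per
  permutation, shared by all genes. This preserves both the gene-gene
  correlation structure and the within-gene coupling among the n1·n2 ratio
  columns (which reuse the same n1+n2 values), so the null RP distribution
  matches the observed one exactly under no group difference. It is the
  scheme that both controls the false discovery proportion and retains
  sensitivity on this all-pairs construction.
* ``within-gene`` — an independent uniform bipartition of each gene's pooled
  values, with a canonical (ascending-value) order within each side so that
  the sampled null converges to the exhaustive enumeration over the
  C(n1+n2, n1)^G per-gene splits. Kept for small-instance enumeration checks;
  note that for a strongly regulated gene this null reproduces the gene's own
  extreme split with probability 2/C(n1+n2, n1), which makes it very
  conservative as G grows.

In both schemes the drawn first side is attached to the study-order-first
group of the contrast, which makes swapping numerator and denominator exchange
the up and down results exactly under the same random stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError, ConfigError
from .study import Contrast, ExpressionStudy

log = logging.getLogger(__name__)


@dataclass
class DETable:
    """Per-probe rank-product results for one contrast.

    ``stats`` has columns probe, rp_up, rp_down, pfp_up, pfp_down, fc_signed
    and is sorted by min(pfp_up, pfp_down) ascending. pfp values are stored
    unclipped (they may exceed 1); writers clip at 1 for reporting.
    """

    contrast: Contrast
    stats: pd.DataFrame
    n_permutations: int
    seed: int


def pairwise_log_ratios(study: ExpressionStudy, contrast: Contrast) -> pd.DataFrame:
    """All-pairs log2 ratio matrix: column (i,j) = numerator_i − denominator_j.

    Columns are ordered lexicographically in (i, j) with samples in study order.
    Genes with any missing value in the contrast's samples are rejected, since
    ranking requires complete vectors; exclude them before calling (as
    :func:`estimate_pfp` does). A single-sample group is allowed here — the
    statistic degenerates gracefully — but the permutation analysis requires
    two per group.
    """
    num = study.group_values(contrast.numerator)
    den = study.group_values(contrast.denominator)
    sub = pd.concat([num, den], axis=1)
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise AnalysisError(
            f"genes with missing values in contrast '{contrast.name}': {bad[:10]}"
            + ("..." if len(bad) > 10 else "")
        )
    a, b = num.to_numpy(), den.to_numpy()
    ratios = (a[:, :, None] - b[:, None, :]).reshape(a.shape[0], -1)
    cols = [f"{i}/{j}" for i in num.columns for j in den.columns]
    return pd.DataFrame(ratios, index=study.genes, columns=cols)


def _rp_from_matrix(ratios: np.ndarray, direction: str) -> np.ndarray:
    if direction == "up":
        ranks = rankdata(-ratios, axis=0, method="average")
    elif direction == "down":
        ranks = rankdata(ratios, axis=0, method="average")
    else:
        raise ConfigError(f"direction must be 'up' or 'down', got {direction!r}")
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product_statistic(ratios, direction: str) -> pd.Series:
    """Geometric-mean rank of each gene across the ratio columns.

    Within each column genes are ranked by ratio — descending for 'up',
    ascending for 'down' — with ties given average ranks.
    """
    if isinstance(ratios, pd.DataFrame):
        index, arr = ratios.index, ratios.to_numpy()
    else:
        arr = np.asarray(ratios, dtype=float)
        index = pd.RangeIndex(arr.shape[0])
    if arr.size == 0:
        raise AnalysisError("empty ratio matrix")
    if not np.all(np.isfinite(arr)):
        raise AnalysisError("ratio matrix contains non-finite values")
    return pd.Series(_rp_from_matrix(arr, direction), index=index, name=f"rp_{direction}")


def fold_change(ratios) -> pd.Series:
    """Signed linear fold change from mean log2 ratios.

    The mean log2 ratio m maps to 2**m, reported as-is when >= 1 and as the
    negative reciprocal otherwise, so values never fall in (−1, 1) and m = 0
    maps to +1 — the sign convention of microarray result tables (ratio 0.5
    is printed as −2.0).
    """
    if isinstance(ratios, pd.DataFrame):
        m = ratios.mean(axis=1)
    else:
        m = pd.Series(np.asarray(ratios, dtype=float).mean(axis=1))
    linear = np.power(2.0, m)
    return pd.Series(np.where(linear >= 1.0, linear, -1.0 / linear),
                     index=m.index, name="fc_signed")


def _null_bipartitions(pooled: np.ndarray, n_first: int, rng: np.random.Generator):
    """Draw one uniform per-gene bipartition, canonical ascending order per side."""
    g, n = pooled.shape
    order = np.argsort(rng.random((g, n)), axis=1)
    permuted = np.take_along_axis(pooled, order, axis=1)
    side1 = np.sort(permuted[:, :n_first], axis=1)
    side2 = np.sort(permuted[:, n_first:], axis=1)
    return side1, side2


def _all_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] - b[:, None, :]).reshape(a.shape[0], -1)


def _pfp_from_counts(rp_obs: np.ndarray, mean_null_count: np.ndarray) -> np.ndarray:
    order = np.argsort(rp_obs, kind="stable")
    rank = np.searchsorted(rp_obs[order], rp_obs, side="right")  # ties -> max rank
    pfp = mean_null_count / rank
    # enforce monotone non-decreasing pfp along the RP-sorted list
    monotone = np.maximum.accumulate(pfp[order])
    out = np.empty_like(pfp)
    out[order] = monotone
    return out


def estimate_pfp(
    study: ExpressionStudy,
    contrast: Contrast,
    n_permutations: int = 1000,
    seed: int = 0,
    scheme: str = "labels",
) -> DETable:
    """Full rank-product analysis of one contrast: RP, pfp and signed FC per gene.

    ``scheme`` selects the permutation null: ``labels`` (shared bipartition,
    default) or ``within-gene`` (independent per-gene bipartitions); see the
    module docstring for the trade-off.
    """
    if n_permutations < 1:
        raise ConfigError(f"n_permutations must be >= 1, got {n_permutations}")
    if scheme not in ("labels", "within-gene"):
        raise ConfigError(f"scheme must be 'labels' or 'within-gene', got {scheme!r}")
    num_cols = study.samples_in_group(contrast.numerator)
    den_cols = study.samples_in_group(contrast.denominator)
    if len(num_cols) < 2 or len(den_cols) < 2:
        raise AnalysisError(
            f"contrast '{contrast.name}': permutation analysis needs >= 2 samples "
            f"per group (got {len(num_cols)} vs {len(den_cols)})"
        )
    # genes with missing values in the contrast's samples cannot be ranked
    complete = study.values[num_cols + den_cols].notna().all(axis=1)
    if not complete.all():
        log.info("excluding %d genes with missing values from contrast %s",
                 int((~complete).sum()), contrast.name)
        study = ExpressionStudy(study.values.loc[complete], study.groups.copy())
    ratios = pairwise_log_ratios(study, contrast)
    arr = ratios.to_numpy()
    rp_up = _rp_from_matrix(arr, "up")
    rp_down = _rp_from_matrix(arr, "down")
    fc = fold_change(ratios)

    num_samples = study.samples_in_group(contrast.numerator)
    den_samples = study.samples_in_group(contrast.denominator)
    # pooled values ordered with the study-order-first group first, so the drawn
    # side1 attaches to the same group whichever way the contrast is oriented
    order_of = {g: k for k, g in enumerate(study.group_names)}
    first_is_num = order_of[contrast.numerator] < order_of[contrast.denominator]
    first, second = (
        (num_samples, den_samples) if first_is_num else (den_samples, num_samples)
    )
    pooled = study.values[list(first) + list(second)].to_numpy()
    n_first = len(first)

    rng = np.random.default_rng(seed)
    count_up = np.zeros(len(rp_up))
    count_down = np.zeros(len(rp_down))
    for _ in range(n_permutations):
        if scheme == "labels":
            perm = rng.permutation(pooled.shape[1])
            side1, side2 = pooled[:, perm[:n_first]], pooled[:, perm[n_first:]]
        else:
            side1, side2 = _null_bipartitions(pooled, n_first, rng)
        null = _all_pairs(side1, side2) if first_is_num else _all_pairs(side2, side1)
        null_up = np.sort(_rp_from_matrix(null, "up"))
        null_down = np.sort(_rp_from_matrix(null, "down"))
        count_up += np.searchsorted(null_up, rp_up, side="right")
        count_down += np.searchsorted(null_down, rp_down, side="right")

    pfp_up = _pfp_from_counts(rp_up, count_up / n_permutations)
    pfp_down = _pfp_from_counts(rp_down, count_down / n_permutations)

    stats = pd.DataFrame(
        {
            "probe": study.genes,
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
            "fc_signed": fc.to_numpy(),
        }
    )
    min_pfp = np.minimum(stats["pfp_up"], stats["pfp_down"])
    stats = stats.loc[min_pfp.sort_values(kind="stable").index].reset_index(drop=True)
    return DETable(contrast, stats, n_permutations, seed)


def call_significant(
    table: DETable, fdr_threshold: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level significant lists: (up, down) with columns probe, fc_signed, pfp.

    A probe is up iff pfp_up < threshold (strict), down iff pfp_down < threshold;
    the pathological both-directions case goes to the smaller pfp.
    """
    if not 0 < fdr_threshold <= 1:
        raise ConfigError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    s = table.stats
    up_mask = s["pfp_up"] < fdr_threshold
    down_mask = s["pfp_down"] < fdr_threshold
    both = up_mask & down_mask
    up_mask = up_mask & (~both | (s["pfp_up"] <= s["pfp_down"]))
    down_mask = down_mask & (~both | (s["pfp_down"] < s["pfp_up"]))

    def _fmt(mask, pfp_col):
        d = s.loc[mask, ["probe", "fc_signed", pfp_col]].copy()
        d.columns = ["probe", "fc_signed", "pfp"]
        return d.sort_values("pfp", kind="stable").reset_index(drop=True)

    return _fmt(up_mask, "pfp_up"), _fmt(down_mask, "pfp_down")


def collapse_probesets(
    up: pd.DataFrame, down: pd.DataFrame, annotation: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Collapse probe-level calls to unique genes.

    Per gene the probe with the smallest pfp wins; a gene with probes in both
    direction lists takes the direction of its best probe. Unannotated probes
    are dropped (their count is reported via the returned frames' attrs).
    Returns (up_genes, down_genes, total) where total = len(up) + len(down).
    """
    frames = []
    n_unannotated = 0
    for direction, df in (("up", up), ("down", down)):
        d = df.copy()
        d["gene"] = d["probe"].map(annotation)
        n_unannotated += int(d["gene"].isna().sum())
        d = d.dropna(subset=["gene"])
        d["direction"] = direction
        frames.append(d)
    frames = [f for f in frames if not f.empty]
    if not frames:
        empty = pd.DataFrame(columns=["gene", "probe", "fc_signed", "pfp"])
        empty.attrs["n_unannotated"] = n_unannotated
        return empty, empty.copy(), 0
    merged = pd.concat(frames, ignore_index=True)
    best = (
        merged.sort_values("pfp", kind="stable")
        .drop_duplicates(subset="gene", keep="first")
        .reset_index(drop=True)
    )
    cols = ["gene", "probe", "fc_signed", "pfp"]
    up_genes = best.loc[best["direction"] == "up", cols].reset_index(drop=True)
    down_genes = best.loc[best["direction"] == "down", cols].reset_index(drop=True)
    up_genes.attrs["n_unannotated"] = down_genes.attrs["n_unannotated"] = n_unannotated
    return up_genes, down_genes, len(up_genes) + len(down_genes)
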