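"""Differential Pearson co-expression networks and the phenotype correlation screen.

For a chosen gene panel, pairwise Pearson correlations are computed separately
within patient and control samples. An edge is *significant in* a group when
|R| exceeds ``r_min`` and its two-sided p-value is below ``p_max`` there, and
each retained edge is classified by cross-group agreement:

* ``patient_only`` — significant in patient samples only (rewired in disease);
* ``control_only`` — significant in control samples only (lost in disease);
* ``shared_concordant`` — significant in both, same correlation sign;
* ``shared_discordant`` — significant in both, opposite signs.

Note that with six samples per group a p-value below 0.005 already forces
|R| above ~0.94, so an r_min of 0.8 is non-binding at that size; both
thresholds are applied conjunctively and are configurable, and patient/control
arms may pool treated and untreated samples.

The same machinery drives a screen over a sample-by-variable phenotype table
(miRNA levels vs histopathological and serum variables), retaining variable
pairs with |R| above a threshold and p below another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError
from .study import ExpressionStudy

EDGE_CLASSES = ("patient_only", "control_only", "shared_concordant", "shared_discordant")


@dataclass
class CorrelationEdge:
    """One classified gene pair; gene_a < gene_b canonically."""

    gene_a: str
    gene_b: str
    r_patient: float
    r_control: float
    p_patient: float
    p_control: float
    edge_class: str

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ConfigError(f"edge genes not in canonical order: {self.gene_a!r} >= {self.gene_b!r}")
        if self.edge_class not in EDGE_CLASSES:
            raise ConfigError(f"unknown edge class {self.edge_class!r}")


@dataclass
class DiffNetwork:
    panel: list[str]
    edges: list[CorrelationEdge]
    thresholds: tuple[float, float]  # (r_min, p_max)
    group_sizes: dict[str, int]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in EDGE_CLASSES}
        for e in self.edges:
            counts[e.edge_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "r_patient": e.r_patient,
                    "r_control": e.r_control,
                    "p_patient": e.p_patient,
                    "p_control": e.p_control,
                    "class": e.edge_class,
                }
                for e in self.edges
            ],
            columns=["gene_a", "gene_b", "r_patient", "r_control",
                     "p_patient", "p_control", "class"],
        )


def pearson_with_pvalue(x, y) -> tuple[float, float]:
    """Sample Pearson R with its two-sided p-value.

    Missing values are deleted pairwise. The p-value comes from the exact null
    distribution of R under bivariate normality (equivalent to the t transform
    R·sqrt((n−2)/(1−R²)) on n−2 df); |R| = 1 yields p = 0. Fewer than 3
    complete pairs or zero variance raise an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AnalysisError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise AnalysisError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-13:
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def _significant(r: float, p: float, r_min: float, p_max: float) -> bool:
    return abs(r) > r_min and p < p_max


def build_group_network(
    study: ExpressionStudy,
    panel,
    group_patient: str = "P",
    group_control: str = "C",
    r_min: float = 0.8,
    p_max: float = 0.005,
    pool_patient: tuple[str, ...] = (),
    pool_control: tuple[str, ...] = (),
) -> DiffNetwork:
    """Classify every unordered panel pair by patient/control correlation.

    ``pool_patient`` / ``pool_control`` name additional groups whose samples are
    pooled into the respective arm (e.g. treated + untreated, 12 per arm).
    Pairs significant in neither arm are not retained.
    """
    panel = list(panel)
    missing = [g for g in panel if g not in study.values.index]
    if missing:
        raise ConfigError(f"panel genes absent from the study: {missing}")
    pat_samples: list[str] = study.samples_in_group(group_patient)
    ctl_samples: list[str] = study.samples_in_group(group_control)
    for g in pool_patient:
        pat_samples += study.samples_in_group(g)
    for g in pool_control:
        ctl_samples += study.samples_in_group(g)
    if len(pat_samples) < 3 or len(ctl_samples) < 3:
        raise AnalysisError("each arm needs >= 3 samples for correlations")

    pat = study.values.loc[panel, pat_samples].to_numpy()
    ctl = study.values.loc[panel, ctl_samples].to_numpy()
    edges = []
    for ia, ib in combinations(range(len(panel)), 2):
        rp, pp = pearson_with_pvalue(pat[ia], pat[ib])
        rc, pc = pearson_with_pvalue(ctl[ia], ctl[ib])
        sig_p = _significant(rp, pp, r_min, p_max)
        sig_c = _significant(rc, pc, r_min, p_max)
        if sig_p and sig_c:
            cls = "shared_concordant" if np.sign(rp) == np.sign(rc) else "shared_discordant"
        elif sig_p:
            cls = "patient_only"
        elif sig_c:
            cls = "control_only"
        else:
            continue
        a, b = sorted((panel[ia], panel[ib]))  # R and p are symmetric in the pair
        edges.append(CorrelationEdge(a, b, rp, rc, pp, pc, cls))
    return DiffNetwork(
        panel=panel,
        edges=edges,
        thresholds=(r_min, p_max),
        group_sizes={group_patient: len(pat_samples), group_control: len(ctl_samples)},
    )


def phenotype_correlation_screen(
    table: pd.DataFrame, r_min: float = 0.7, p_max: float = 0.05
) -> pd.DataFrame:
    """Screen all unordered variable pairs of a sample-by-variable table.

    Pairs with |R| > r_min and p < p_max are retained, sorted by p ascending,
    with columns (variable_a, variable_b, p, R) matching the screen's table
    layout. Variables with fewer than 3 observations are excluded with a
    warning; perfect |R| = 1 pairs are retained but flagged as degenerate,
    since they usually indicate duplicated variables.
    """
    usable = []
    for col in table.columns:
        if table[col].notna().sum() < 3:
            warnings.warn(f"variable '{col}' has < 3 observations; excluded", stacklevel=2)
        else:
            usable.append(col)
    rows = []
    for a, b in combinations(usable, 2):
        try:
            r, p = pearson_with_pvalue(table[a], table[b])
        except AnalysisError:
            continue  # too few complete pairs or constant on the complete subset
        if abs(r) > r_min and p < p_max:
            rows.append(
                {"variable_a": a, "variable_b": b, "p": p, "R": r,
                 "degenerate": bool(abs(r) >= 1.0)}
            )
    out = pd.DataFrame(rows, columns=["variable_a", "variable_b", "p", "R", "degenerate"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)
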