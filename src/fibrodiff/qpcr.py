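"""ΔΔCT relative quantification for qPCR / miRNA assays.

Cycle-threshold (CT) values of a target are normalized against a housekeeping
reference (e.g. HPRT1 for mRNA, U6 snRNA for miRNA): ΔCT = CT_target − CT_ref
per sample, ΔΔCT = ΔCT − mean control ΔCT, relative expression = 2^−ΔΔCT.
Group fold changes are the arithmetic mean of per-sample 2^−ΔΔCT, reported
with the reciprocal sign convention (values below 1 become −1/FC) and the SEM
of the per-sample values. A |FC| strictly above 1.5 is called significant.

Technical replicates are averaged on the CT scale before ΔCT.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import AnalysisError, ConfigError

REQUIRED_COLUMNS = ("sample", "group", "target", "reference", "ct_target", "ct_reference")


def _validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigError(f"CT table missing columns: {missing}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    finite = np.isfinite(cts)
    if np.any(cts[finite] <= 0):
        raise AnalysisError("CT values must be positive")


def signed_fc(linear: float) -> float:
    """Reciprocal sign convention: linear ratio 0.5 -> −2.0; ratio ≥ 1 unchanged."""
    return float(linear) if linear >= 1.0 else float(-1.0 / linear)


def ddct_fold_changes(
    table: pd.DataFrame,
    target: str,
    control_group: str = "control",
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-group signed fold change of one target relative to the control group.

    Returns one row per group with columns (group, n, fold_change, sem, mean_fc
    on the linear scale). ``mean`` selects arithmetic (default) or geometric
    averaging of the per-sample 2^−ΔΔCT values.
    """
    _validate_ct_table(table)
    if mean not in ("arithmetic", "geometric"):
        raise ConfigError(f"mean must be 'arithmetic' or 'geometric', got {mean!r}")
    sub = table[table["target"] == target]
    if sub.empty:
        raise AnalysisError(f"no rows for target '{target}'")
    if sub["ct_reference"].isna().any():
        bad = sub.loc[sub["ct_reference"].isna(), "sample"].tolist()
        raise AnalysisError(f"missing reference CT for samples: {bad}")
    if sub["ct_target"].isna().any():
        bad = sub.loc[sub["ct_target"].isna(), "sample"].tolist()
        raise AnalysisError(f"missing target CT for samples: {bad}")
    # technical replicates averaged on the CT scale
    per_sample = (
        sub.groupby(["sample", "group"], sort=False)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    controls = per_sample[per_sample["group"] == control_group]
    if controls.empty:
        raise AnalysisError(f"no samples in control group '{control_group}'")
    ddct = per_sample["dct"] - controls["dct"].mean()
    per_sample["fc"] = np.power(2.0, -ddct)

    rows = []
    for group, d in per_sample.groupby("group", sort=False):
        linear = float(d["fc"].mean()) if mean == "arithmetic" else float(gmean(d["fc"]))
        sem = float(d["fc"].std(ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")
        rows.append(
            {"group": group, "n": len(d), "fold_change": signed_fc(linear),
             "linear_fc": linear, "sem": sem}
        )
    return pd.DataFrame(rows)


def call_fc_significant(fc: float, threshold: float = 1.5) -> bool:
    """True iff the signed fold change is strictly beyond ±threshold."""
    if abs(fc) < 1.0:
        raise ConfigError("signed fold changes never lie in (-1, 1); convert first")
    return abs(fc) > threshold
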