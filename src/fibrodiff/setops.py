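"""Contrast-level set algebra and the ascorbic-acid sign-reversion detector.

Works on gene-level (probeset-collapsed) results. The reversion detector finds
genes whose disease fold change (P−C) is undone by ascorbic-acid treatment
(P_AA−P): a gene qualifies when it is significant in both contrasts and its
two fold changes have opposite signs. No fold-change magnitude filter is
applied — reverted genes with |FC| below 1.5 are legitimate members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ContrastResult:
    """Gene-level significant lists of one contrast.

    ``up`` and ``down`` are DataFrames with at least columns gene, fc_signed,
    pfp; gene symbols are unique across the two lists.
    """

    name: str
    up: pd.DataFrame
    down: pd.DataFrame

    def __post_init__(self) -> None:
        overlap = set(map(_norm, self.up["gene"])) & set(map(_norm, self.down["gene"]))
        if overlap:
            raise AnalysisError(
                f"contrast '{self.name}': genes in both up and down lists: {sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> set[str]:
        return set(map(_norm, self.up["gene"])) | set(map(_norm, self.down["gene"]))

    def fc_of(self) -> dict[str, float]:
        out = {}
        for df in (self.up, self.down):
            for g, fc in zip(df["gene"], df["fc_signed"]):
                out[_norm(g)] = float(fc)
        return out


def contrast_overlap(a: ContrastResult, b: ContrastResult):
    """Symbol-level (common, unique_a, unique_b) over up ∪ down of each contrast."""
    ga, gb = a.genes, b.genes
    common = ga & gb
    return common, ga - common, gb - common


def reversion_genes(
    pc: ContrastResult, paap: ContrastResult
) -> pd.DataFrame:
    """Genes significant in both contrasts whose fold changes flip sign.

    ``pc`` is the disease contrast (P−C), ``paap`` the treatment-response
    contrast (P_AA−P). Output columns (gene, fc_paap, fc_pc) are sorted by
    FC(P−C) direction group — up-in-disease first — and |FC(P−C)| descending
    within each group, the layout of a reversion table.
    """
    fc_pc = pc.fc_of()
    fc_paap = paap.fc_of()
    if not set(fc_pc) | set(fc_paap):
        return pd.DataFrame(columns=["gene", "fc_paap", "fc_pc"])
    if set(fc_pc) and set(fc_paap) and not (set(fc_pc) & set(fc_paap)):
        raise AnalysisError("contrast gene universes are disjoint; check inputs")
    rows = []
    for g in fc_pc.keys() & fc_paap.keys():
        if np.sign(fc_pc[g]) != np.sign(fc_paap[g]):
            rows.append({"gene": g, "fc_paap": fc_paap[g], "fc_pc": fc_pc[g]})
    out = pd.DataFrame(rows, columns=["gene", "fc_paap", "fc_pc"])
    assert (np.sign(out["fc_pc"]) != np.sign(out["fc_paap"])).all()
    out["_dir"] = np.sign(out["fc_pc"])
    out = (
        out.sort_values(["_dir", "fc_pc"], ascending=[False, False], key=abs_key)
        .drop(columns="_dir")
        .reset_index(drop=True)
    )
    return out


def abs_key(s: pd.Series) -> pd.Series:
    return s.abs() if s.name == "fc_pc" else s


def summarize_counts(results: list[ContrastResult]) -> pd.DataFrame:
    """UP / DOWN / TOTAL counts, one column per contrast."""
    data = {r.name: [len(r.up), len(r.down), len(r.up) + len(r.down)] for r in results}
    return pd.DataFrame(data, index=["UP", "DOWN", "TOTAL"])


def cross_dataset_overlap(fibroblast: ContrastResult, external_list) -> set[str]:
    """Case-insensitive symbol intersection with an external gene list."""
    external = {_norm(g) for g in external_list if str(g).strip()}
    if not external:
        warnings.warn("external gene list is empty; overlap is empty", stacklevel=2)
        return set()
    return fibroblast.genes & external
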