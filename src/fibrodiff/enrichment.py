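"""Gene-set over-representation analysis (Fisher / EASE) against GMT collections.

A transparent hypergeometric ORA over a user-supplied universe. The universe
defaults to the annotated genes on the analyzed matrix, mirroring array-
background logic; this module makes no attempt to reproduce any specific
annotation-database tool's scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigError


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overrepresentation_test(
    query, sets: dict, universe, variant: str = "fisher"
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query list in each set.

    Parameters
    ----------
    query
        Gene symbols of interest; must be a subset of ``universe``.
    sets
        Mapping of set name -> iterable of member genes (a parsed GMT
        collection); each set is intersected with the universe before testing.
    universe
        Background gene symbols.
    variant
        ``fisher`` for the plain hypergeometric upper tail, ``ease`` for the
        conservative variant that removes one gene from the overlap.

    Returns rows (set, overlap, set_size, query_size, universe_size, p_raw,
    p_adjusted) sorted by p_raw, BH-adjusted across all tested sets.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise AnalysisError("empty universe")
    query = {str(g) for g in query}
    stray = query - universe
    if stray:
        raise AnalysisError(f"query genes outside the universe: {sorted(stray)[:10]}")
    if variant not in ("fisher", "ease"):
        raise ConfigError(f"variant must be 'fisher' or 'ease', got {variant!r}")

    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(members & query)
        k_eff = max(k - 1, 0) if variant == "ease" else k
        # P(X >= k_eff) for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail at k
        p = float(hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append(
            {"set": name, "overlap": k, "set_size": K, "query_size": n,
             "universe_size": N, "p_raw": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = bh_adjust(out["p_raw"])
        out = out.sort_values("p_raw", kind="stable").reset_index(drop=True)
    else:
        out["p_adjusted"] = []
    return out
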