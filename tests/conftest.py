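import numpy as np
import pandas as pd
import pytest

from fibrodiff import ExpressionStudy


def make_study(values: np.ndarray, groups: list[str], gene_prefix: str = "g") -> ExpressionStudy:
    """Wrap a raw matrix and per-sample group labels into an ExpressionStudy."""
    n_genes, n_samples = values.shape
    counts: dict[str, int] = {}
    samples = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        samples.append(f"{g}_{counts[g]}")
    df = pd.DataFrame(values, index=[f"{gene_prefix}{i}" for i in range(n_genes)],
                      columns=samples)
    return ExpressionStudy(df, pd.Series(groups, index=samples))


@pytest.fixture
def four_group_study():
    """Deterministic 4-gene study over the four-arm design, 3 samples per arm."""
    rng = np.random.default_rng(11)
    values = rng.normal(8, 1, size=(4, 12))
    groups = ["P"] * 3 + ["C"] * 3 + ["P_AA"] * 3 + ["C_AA"] * 3
    return make_study(values, groups)
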