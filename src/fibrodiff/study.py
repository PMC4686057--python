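"""In-memory container for a normalized expression study.

The central object is :class:`ExpressionStudy`: a log2-scale gene-by-sample
matrix (post-RMA style) together with a sample-to-group assignment. Groups
follow the four-arm fibroblast design: untreated patients (P), untreated
controls (C) and the same arms after ascorbic-acid treatment (P_AA, C_AA),
but arbitrary group labels are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_GROUPS = ("P", "C", "P_AA", "C_AA")


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus sample group labels.

    Parameters
    ----------
    values
        Gene-by-sample DataFrame of finite log2 expression values. The index
        holds probe/gene identifiers, the columns sample identifiers.
    groups
        Series mapping each sample identifier to exactly one group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ConfigError(f"duplicate sample ids: {dupes}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ConfigError(f"duplicate gene ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ConfigError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def group_names(self) -> list[str]:
        """Group labels in first-appearance (study) order."""
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        members = [s for s, g in self.groups.items() if g == group]
        if not members:
            raise ConfigError(f"group '{group}' has no samples in the study")
        return members

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]

    def subset_genes(self, genes) -> "ExpressionStudy":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ConfigError(f"genes absent from the study: {missing}")
        return ExpressionStudy(self.values.loc[list(genes)], self.groups.copy())


@dataclass
class Contrast:
    """A named two-group comparison, e.g. ``P-C`` (numerator minus denominator)."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigError(f"contrast '{self.name}': groups must be distinct")

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse ``"P-C"`` style contrast strings (first '-' splits the groups).

        Group labels containing '-' are not supported by this shorthand;
        construct the Contrast directly in that case.
        """
        num, sep, den = text.partition("-")
        if not sep or not num or not den:
            raise ConfigError(f"cannot parse contrast '{text}' (expected 'NUM-DEN')")
        return cls(text, num, den)
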