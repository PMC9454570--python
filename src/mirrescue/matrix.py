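"""Core expression-matrix container shared by every analysis stage.

An :class:`ExpressionMatrix` holds a probes-by-samples table of log2
intensities, a sample-to-group map over the four study conditions
(control ``C``, treated control ``C+P``, disease ``D``, treated disease
``D+P``) and, optionally, a same-shaped table of detection flags
(``P`` present / ``A`` absent) as produced by array feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The four experimental conditions, in canonical order.
GROUPS: tuple[str, ...] = ("C", "C+P", "D", "D+P")

PRESENT = "P"
ABSENT = "A"


class MatrixError(ValueError):
    """Raised for structurally invalid expression matrices."""


@dataclass
class ExpressionMatrix:
    """Probes (or miRNAs) x samples log2-intensity matrix.

    Parameters
    ----------
    values
        DataFrame indexed by probe/miRNA id with one column per sample.
        May contain NA.
    groups
        Series mapping sample id -> group label. Must cover every column
        of ``values``.
    flags
        Optional DataFrame of detection marks, same shape and labels as
        ``values``, entries in ``{"P", "A"}``.
    """

    values: pd.DataFrame
    groups: pd.Series
    flags: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise MatrixError("duplicate sample ids in matrix columns")
        if self.values.index.duplicated().any():
            raise MatrixError("duplicate probe ids in matrix index")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise MatrixError(f"samples without a group assignment: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise MatrixError("flags and values must share shape")
            self.flags = self.flags.loc[self.values.index, self.values.columns]
            bad = set(pd.unique(self.flags.values.ravel())) - {PRESENT, ABSENT}
            if bad:
                raise MatrixError(f"unknown detection flags: {sorted(bad)}")

    # -- convenience -------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise MatrixError(f"unknown group label: {group!r}")
        return [s for s in self.sample_ids if self.groups[s] == group]

    def group_means(self) -> pd.DataFrame:
        """Per-probe mean log2 intensity per group (NA-aware)."""
        cols = {}
        for g in pd.unique(self.groups):
            cols[g] = self.values[self.samples_in(g)].mean(axis=1)
        return pd.DataFrame(cols)

    def with_values(self, values: pd.DataFrame,
                    keep_flags: bool = True) -> "ExpressionMatrix":
        """Return a new matrix with replaced values (rows may be a subset)."""
        flags = None
        if keep_flags and self.flags is not None:
            flags = self.flags.loc[values.index, values.columns].copy()
        return ExpressionMatrix(values=values,
                                groups=self.groups.copy(),
                                flags=flags)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            groups=self.groups.copy(),
            flags=None if self.flags is None else self.flags.copy(),
        )
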