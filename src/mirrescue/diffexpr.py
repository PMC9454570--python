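"""Pairwise differential expression with family-wise error control.

Each comparison runs a per-probe two-sample t-test (Welch by default,
appropriate for n=3 groups) on log2 values, Bonferroni-adjusts the raw
p-values over the probes actually tested in that comparison, and flags
significance at ``alpha``. Probes without at least two observed values
per group are reported untested and excluded from the correction
denominator. Comparison-specific gene sets are obtained by an exclusive
Venn-region decomposition of the significant sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, MatrixError


@dataclass
class DEResult:
    """Per-probe statistics for one ordered group comparison (a vs b)."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # diff, t, df, p, p_bonf, tested, significant
    alpha: float
    m: int  # number of probes tested (Bonferroni denominator)

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _welch(a: np.ndarray, na: np.ndarray, b: np.ndarray, nb: np.ndarray):
    """Vectorized Welch t over rows; inputs are per-row means/vars/counts."""
    ma, va = a
    mb, vb = b
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # degenerate zero-variance rows: equal means -> t=0, else infinite t
    zero = se2 == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff != 0)] = np.inf * np.sign(diff[zero & (diff != 0)])
    df[zero] = na[zero] + nb[zero] - 2
    return diff, t, df


def _student(a, na, b, nb):
    ma, va = a
    mb, vb = b
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se2 = sp2 * (1 / na + 1 / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero = se2 == 0
    t[zero & (diff == 0)] = 0.0
    t[zero & (diff != 0)] = np.inf * np.sign(diff[zero & (diff != 0)])
    return diff, t, df.astype(float)


def pairwise_ttest(matrix: ExpressionMatrix, group_a: str, group_b: str,
                   alpha: float = 0.05, equal_var: bool = False,
                   correction: str = "bonferroni") -> DEResult:
    """Multiple t-tests for ``group_a`` vs ``group_b`` on log2 values.

    ``correction`` is ``"bonferroni"`` (default) or ``"holm"`` for the
    step-down variant; either way the adjusted p is reported in the
    ``p_bonf`` column and thresholded at ``alpha``.
    """
    known = set(matrix.groups)
    for g in (group_a, group_b):
        if g not in known:
            raise MatrixError(f"unknown group label: {g!r}")
    A = matrix.values[matrix.samples_in(group_a)].to_numpy(float)
    B = matrix.values[matrix.samples_in(group_b)].to_numpy(float)
    na = (~np.isnan(A)).sum(axis=1).astype(float)
    nb = (~np.isnan(B)).sum(axis=1).astype(float)
    tested = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore"):
        stats_a = (np.nanmean(A, axis=1), _nanvar(A))
        stats_b = (np.nanmean(B, axis=1), _nanvar(B))
    fn = _student if equal_var else _welch
    diff, t, df = fn(stats_a, na, stats_b, nb)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    diff[~tested] = np.nan
    t[~tested] = np.nan
    df[~tested] = np.nan
    p[~tested] = np.nan
    m = int(tested.sum())
    p_adj = np.full(p.shape, np.nan)
    if m:
        if correction == "bonferroni":
            p_adj[tested] = np.minimum(p[tested] * m, 1.0)
        elif correction == "holm":
            p_adj[tested] = multipletests(p[tested], method="holm")[1]
        else:
            raise ValueError(f"unknown correction: {correction!r}")
    significant = np.zeros(p.shape, dtype=bool)
    significant[tested] = p_adj[tested] <= alpha
    table = pd.DataFrame(
        {"diff": diff, "t": t, "df": df, "p": p, "p_bonf": p_adj,
         "tested": tested, "significant": significant},
        index=matrix.values.index)
    return DEResult(comparison=(group_a, group_b), table=table,
                    alpha=alpha, m=m)


def _nanvar(X: np.ndarray) -> np.ndarray:
    """Row-wise sample variance (ddof=1) ignoring NA; 0 for n<2."""
    mask = ~np.isnan(X)
    n = mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, np.nansum(X, axis=1) / np.maximum(n, 1), 0.0)
        sq = np.nansum((np.where(mask, X, 0.0)
                        - mean[:, None] * mask) ** 2, axis=1)
        v = np.where(n > 1, sq / np.maximum(n - 1, 1), 0.0)
    return v


def venn_partition(results) -> dict[frozenset, set[str]]:
    """Exclusive Venn-region decomposition of significant-gene sets.

    ``results`` is either a list of :class:`DEResult` (regions keyed by
    frozensets of "a_vs_b" comparison names) or a mapping name -> set.
    Regions are pairwise disjoint and union to all significant genes;
    empty regions are omitted.
    """
    if isinstance(results, dict):
        named = dict(results)
    else:
        named = {f"{r.comparison[0]}_vs_{r.comparison[1]}":
                 r.significant_genes for r in results}
    regions: dict[frozenset, set[str]] = {}
    universe = set().union(*named.values()) if named else set()
    for gene in universe:
        key = frozenset(n for n, s in named.items() if gene in s)
        regions.setdefault(key, set()).add(gene)
    return regions


def venn_table(regions: dict[frozenset, set[str]]) -> pd.DataFrame:
    rows = [{"region": "&".join(sorted(k)), "size": len(v),
             "genes": ",".join(sorted(v))} for k, v in regions.items()]
    return (pd.DataFrame(rows, columns=["region", "size", "genes"])
            .sort_values("region").reset_index(drop=True))
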