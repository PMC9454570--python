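"""Flag-based filtering and between-array normalization.

mRNA matrices go through: detection-flag masking (absent -> NA),
exclusion of probes with more than half NA within any condition, and
quantile normalization. miRNA matrices go through: exclusion of any
miRNA undetected in even a single sample (0% undetected allowed), then
cyclic loess normalization of the remaining complete rows. All steps
operate on log2 intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ABSENT, ExpressionMatrix, MatrixError


class PreprocessError(ValueError):
    pass


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) for matrices declared to hold raw linear intensities."""
    if (matrix.values < 0).any().any():
        raise PreprocessError("negative intensities cannot be log-transformed")
    return matrix.with_values(np.log2(matrix.values + 1.0))


def apply_flag_na(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Set values whose detection flag is absent to NA."""
    if matrix.flags is None:
        raise PreprocessError(
            "matrix has no detection flags; skip flag masking explicitly "
            "if your input carries none")
    values = matrix.values.mask(matrix.flags == ABSENT)
    return matrix.with_values(values)


def filter_mrna_probes(matrix: ExpressionMatrix,
                       max_na_frac: float = 0.5,
                       require_groups: tuple[str, ...] | None = None
                       ) -> ExpressionMatrix:
    """Drop probes with more than ``max_na_frac`` NA in any condition.

    The inequality is strict: a probe with exactly the threshold
    fraction of NA in every group is retained. ``require_groups`` names
    conditions that must each contribute at least one sample.
    """
    if require_groups is not None:
        for g in require_groups:
            if not (matrix.groups == g).any():
                raise PreprocessError(f"group {g!r} has no samples")
    drop = pd.Series(False, index=matrix.values.index)
    for g in pd.unique(matrix.groups):
        cols = matrix.samples_in(g)
        if not cols:
            raise PreprocessError(f"group {g!r} has no samples")
        na_frac = matrix.values[cols].isna().sum(axis=1) / len(cols)
        drop |= na_frac > max_na_frac
    return matrix.with_values(matrix.values.loc[~drop])


def filter_mirna(matrix: ExpressionMatrix,
                 max_undetected: int = 0) -> ExpressionMatrix:
    """Keep miRNAs detected above background in (all but
    ``max_undetected``) samples; the default allows none undetected."""
    if matrix.flags is not None:
        undetected = (matrix.flags == ABSENT).sum(axis=1)
    else:
        undetected = matrix.values.isna().sum(axis=1)
    keep = undetected <= max_undetected
    return matrix.with_values(matrix.values.loc[keep])


def _quantile_normalize_values(values: pd.DataFrame) -> pd.DataFrame:
    X = values.to_numpy(float)
    n, m = X.shape
    if m < 2:
        raise PreprocessError("quantile normalization needs >= 2 samples")
    grid = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    ref_curves = np.empty((m, n))
    for j in range(m):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        if obs.size == 0:
            raise PreprocessError(
                f"sample {values.columns[j]!r} is all-NA")
        pos = np.linspace(0.0, 1.0, obs.size) if obs.size > 1 else [0.0]
        ref_curves[j] = np.interp(grid, pos, obs)
    ref = ref_curves.mean(axis=0)
    out = np.full_like(X, np.nan)
    for j in range(m):
        mask = ~np.isnan(X[:, j])
        k = int(mask.sum())
        ranks = rankdata(X[mask, j], method="average")  # ties averaged
        pos = (ranks - 1.0) / (k - 1.0) if k > 1 else np.zeros(1)
        out[mask, j] = np.interp(pos, grid, ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common mean quantile distribution.

    Ranks are computed per sample on observed values only; the reference
    distribution is the mean of the per-sample empirical quantile
    curves, interpolated onto a common grid, which keeps the procedure
    NA-aware and idempotent. Ties share the average of their ranks.
    """
    return matrix.with_values(_quantile_normalize_values(matrix.values))


def cyclic_loess_normalize(matrix: ExpressionMatrix, span: float = 0.7,
                           max_iter: int = 3) -> ExpressionMatrix:
    """Remove intensity-dependent bias between every pair of samples.

    For each unordered sample pair a loess curve of the log-ratio
    M = x_i - x_j on the mean log-intensity A = (x_i + x_j) / 2 is
    fitted; half the fitted trend is subtracted from sample i and added
    to sample j, so the pair average A is preserved exactly. The sweep
    over all pairs is repeated ``max_iter`` times.
    """
    X = matrix.values.to_numpy(float).copy()
    if np.isnan(X).any():
        raise PreprocessError(
            "cyclic loess requires complete rows; run the detection filter "
            "first")
    n, m = X.shape
    if m < 2:
        raise PreprocessError("cyclic loess needs >= 2 samples")
    if n < 10:
        raise PreprocessError("too few probes for a stable loess fit")
    for _ in range(max_iter):
        for i in range(m - 1):
            for j in range(i + 1, m):
                A = 0.5 * (X[:, i] + X[:, j])
                M = X[:, i] - X[:, j]
                fit = lowess(M, A, frac=span, return_sorted=False)
                X[:, i] -= fit / 2.0
                X[:, j] += fit / 2.0
    values = pd.DataFrame(X, index=matrix.values.index,
                          columns=matrix.values.columns)
    return matrix.with_values(values)
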