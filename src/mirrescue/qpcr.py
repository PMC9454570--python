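"""qPCR quantification and cross-platform validation arithmetic.

Relative quantities follow the comparative ddCt method: per sample
dCt = Ct_target - Ct_reference; per group ddCt = mean dCt of the group
minus mean dCt of the calibrator group; RQ = 2^(-ddCt), so the
calibrator's RQ is exactly 1. The dCt method reports 2^(-dCt) per
sample without a calibrator. Candidate reference genes are ranked by
the standard deviation of their Ct across all samples (most stable
first). Platform agreement is summarized by the Pearson correlation of
qPCR and microarray values with the categories: strong r >= 0.7,
moderate 0.5 < r < 0.7, weak otherwise (r = 0.5 exactly is weak).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class QpcrError(ValueError):
    pass


@dataclass
class ValidationResult:
    name: str
    r: float
    category: str


def _collapse_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per (sample, group, gene)."""
    need = {"sample", "group", "gene", "ct"}
    if not need.issubset(ct.columns):
        raise QpcrError(f"Ct table needs columns {sorted(need)}")
    if (ct["ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")
    return (ct.groupby(["sample", "group", "gene"], as_index=False)["ct"]
              .mean())


def _delta_ct(ct: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    ct = _collapse_technical(ct)
    tgt = ct[ct["gene"] == target].set_index("sample")
    ref = ct[ct["gene"] == reference].set_index("sample")
    if tgt.empty:
        raise QpcrError(f"target gene {target!r} not in Ct table")
    if ref.empty:
        raise QpcrError(f"reference gene {reference!r} not in Ct table")
    missing = set(tgt.index) - set(ref.index)
    if missing:
        log.warning("excluding samples without reference Ct: %s",
                    sorted(missing))
    samples = [s for s in tgt.index if s in set(ref.index)]
    return pd.DataFrame({
        "sample": samples,
        "group": tgt.loc[samples, "group"].to_numpy(),
        "dct": (tgt.loc[samples, "ct"].to_numpy()
                - ref.loc[samples, "ct"].to_numpy()),
    })


def ddct(ct: pd.DataFrame, target: str, reference: str,
         calibrator_group: str = "C") -> pd.DataFrame:
    """Comparative ddCt relative quantity per group.

    Returns a per-group table with mean dCt, ddCt against the
    calibrator, RQ = 2^(-ddCt), and the SD of per-sample relative
    quantities over biological replicates.
    """
    d = _delta_ct(ct, target, reference)
    if calibrator_group not in set(d["group"]):
        raise QpcrError(f"calibrator group {calibrator_group!r} absent")
    cal_mean = d.loc[d["group"] == calibrator_group, "dct"].mean()
    rows = []
    for g, sub in d.groupby("group", sort=False):
        ddct_g = sub["dct"].mean() - cal_mean
        rq_samples = 2.0 ** (-(sub["dct"] - cal_mean))
        rows.append({"group": g, "mean_dct": sub["dct"].mean(),
                     "ddct": ddct_g, "rq": 2.0 ** (-ddct_g),
                     "rq_sd": rq_samples.std(ddof=1)
                     if len(rq_samples) > 1 else np.nan,
                     "n": len(sub)})
    return pd.DataFrame(rows).set_index("group")


def dct(ct: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample relative expression 2^(-dCt) without a calibrator."""
    d = _delta_ct(ct, target, reference)
    d["rel_expr"] = 2.0 ** (-d["dct"])
    return d


def reference_stability(ct: pd.DataFrame,
                        candidates: list[str],
                        max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Rank candidate reference genes by ascending Ct SD across samples.

    Candidates missing in more than ``max_missing_frac`` of samples are
    excluded with a warning; ties in SD break alphabetically.
    """
    if len(candidates) < 2:
        raise QpcrError("need at least 2 candidate reference genes")
    coll = _collapse_technical(ct)
    all_samples = set(coll["sample"])
    rows = []
    for gene in candidates:
        sub = coll[coll["gene"] == gene]
        missing = 1.0 - len(set(sub["sample"])) / len(all_samples)
        if missing > max_missing_frac:
            log.warning("excluding %r: missing in %.0f%% of samples",
                        gene, 100 * missing)
            continue
        rows.append({"gene": gene,
                     "ct_sd": float(sub["ct"].std(ddof=1)),
                     "n": len(sub)})
    if not rows:
        raise QpcrError("no candidate reference gene survived")
    df = pd.DataFrame(rows).sort_values(["ct_sd", "gene"],
                                        kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def categorize_correlation(r: float) -> str:
    if r >= 0.7:
        return "strong"
    if 0.5 < r < 0.7:
        return "moderate"
    return "weak"


def validate_platforms(qpcr_values, microarray_values,
                       name: str = "") -> ValidationResult:
    """Pearson correlation between paired platform values (typically the
    four group means) and its strength category."""
    x = np.asarray(qpcr_values, float)
    y = np.asarray(microarray_values, float)
    if x.size != y.size:
        raise QpcrError("platform value vectors differ in length")
    mask = ~np.isnan(x) & ~np.isnan(y)
    if mask.sum() < 3:
        raise QpcrError("need at least 3 paired values")
    r = float(np.corrcoef(x[mask], y[mask])[0, 1])
    return ValidationResult(name=name, r=r, category=categorize_correlation(r))
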