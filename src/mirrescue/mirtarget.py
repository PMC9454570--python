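"""miRNA-target consensus intake, seed matching and anti-correlation filter.

Predicted (miRNA, gene) pairs from any number of prediction tables are
unioned with per-pair source support. Because sequence-based predictors
over-call, each surviving pair must additionally show *expression
evidence of repression*: the Pearson correlation between the miRNA and
the candidate target across all shared samples must be negative, tested
one-sided via the t transform and controlled by Benjamini-Hochberg FDR
over all computed pairs. The retention rule is strict: r < r_max
(default -0.5) and BH q < q_max (default 0.05).

A seed-match scanner (6mer / 7mer-A1 / 7mer-m8 / 8mer sites of the
reverse complement of miRNA positions 2-8) is provided as a stand-in
generator of prediction tables when none are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}
SITE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass
class MiRTargetRecord:
    mirna: str
    gene: str
    sources: frozenset[str]
    r: float = np.nan
    p_neg: float = np.nan
    q: float = np.nan
    retained: bool = False


class PredictionError(ValueError):
    pass


def load_predictions(tables, min_support: int = 1) -> list[MiRTargetRecord]:
    """Union prediction tables into per-pair records with source sets.

    ``tables`` is an iterable of DataFrames with columns
    (mirna, gene, source). Malformed rows are skipped with a warning;
    pairs supported by fewer than ``min_support`` sources are dropped.
    """
    support: dict[tuple[str, str], set[str]] = {}
    n_rows = n_bad = 0
    for t, table in enumerate(tables):
        missing = {"mirna", "gene", "source"} - set(table.columns)
        if missing:
            raise PredictionError(
                f"table {t} lacks columns {sorted(missing)}")
        for row in table.itertuples(index=False):
            n_rows += 1
            m, g, s = row.mirna, row.gene, row.source
            if not (isinstance(m, str) and m and isinstance(g, str) and g
                    and isinstance(s, str) and s):
                n_bad += 1
                log.warning("skipping malformed prediction row: %r", row)
                continue
            support.setdefault((m, g), set()).add(s)
    if n_rows and n_bad == n_rows:
        raise PredictionError("every prediction row was malformed")
    return [MiRTargetRecord(m, g, frozenset(srcs))
            for (m, g), srcs in sorted(support.items())
            if len(srcs) >= min_support]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _normalize(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise PredictionError(
            f"{what} contains characters outside A/C/G/T/U/N: {sorted(bad)}")
    return seq


def seed_match(mirna_seq: str, utr_seq: str) -> list[dict]:
    """Scan a UTR for canonical seed sites of one miRNA.

    Site types, strongest first: 8mer (match to miRNA positions 2-8
    plus an A opposite position 1), 7mer-m8 (positions 2-8), 7mer-A1
    (positions 2-7 plus the A), 6mer (positions 2-7). Each match is
    reported once at its strongest type with 0-based half-open UTR
    coordinates of the matched stretch.
    """
    mirna = _normalize(mirna_seq, "miRNA sequence")
    utr = _normalize(utr_seq, "UTR sequence")
    if len(mirna) < 8:
        raise PredictionError("miRNA sequence shorter than 8 nt")
    core7 = _revcomp(mirna[1:8])   # matches positions 2-8, 7 nt
    sites = []
    # scan on the 6mer core; extend to stronger types where possible
    for i in range(len(utr) - 5):
        # the 6mer (positions 2-7) occupies utr[i:i+6]; the m8 match, if
        # present, sits immediately 5' of it; the A1 immediately 3'.
        if utr[i:i + 6] != core7[1:]:
            continue
        has_m8 = i >= 1 and utr[i - 1] == core7[0]
        has_a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append({"type": "8mer", "start": i - 1, "end": i + 7})
        elif has_m8:
            sites.append({"type": "7mer-m8", "start": i - 1, "end": i + 6})
        elif has_a1:
            sites.append({"type": "7mer-A1", "start": i, "end": i + 7})
        else:
            sites.append({"type": "6mer", "start": i, "end": i + 6})
    return sites


def predictions_from_seeds(mirna_seqs: dict[str, str],
                           utr_seqs: dict[str, str],
                           source: str = "seedmatch") -> pd.DataFrame:
    """Build a prediction table from seed-match hits (stand-in predictor)."""
    rows = []
    for mir, mseq in mirna_seqs.items():
        for gene, useq in utr_seqs.items():
            if seed_match(mseq, useq):
                rows.append((mir, gene, source))
    return pd.DataFrame(rows, columns=["mirna", "gene", "source"])


def anticorrelate(records: list[MiRTargetRecord],
                  mirna_matrix: ExpressionMatrix,
                  mrna_matrix: ExpressionMatrix) -> list[MiRTargetRecord]:
    """Pearson r and one-sided (negative) p per pair, BH over all pairs.

    Correlations use all samples shared by the two matrices (pairwise
    complete observations per pair); the one-sided p comes from
    t = r * sqrt((n - 2) / (1 - r^2)). Pairs whose members are missing
    from a matrix, or with a constant expression vector, get NA
    statistics and are excluded from the BH family.
    """
    shared = [s for s in mirna_matrix.sample_ids
              if s in set(mrna_matrix.sample_ids)]
    if len(shared) < 3:
        raise PredictionError("fewer than 3 shared samples")
    M = mirna_matrix.values[shared]
    G = mrna_matrix.values[shared]
    out = []
    pvals, idx = [], []
    for k, rec in enumerate(records):
        rec = MiRTargetRecord(rec.mirna, rec.gene, rec.sources)
        out.append(rec)
        if rec.mirna not in M.index or rec.gene not in G.index:
            log.warning("pair (%s, %s) missing from expression data",
                        rec.mirna, rec.gene)
            continue
        x = M.loc[rec.mirna].to_numpy(float)
        y = G.loc[rec.gene].to_numpy(float)
        mask = ~np.isnan(x) & ~np.isnan(y)
        n = int(mask.sum())
        if n < 3:
            continue
        x, y = x[mask], y[mask]
        if np.std(x) == 0 or np.std(y) == 0:
            continue  # flagged NA, excluded from the BH family
        r = float(np.corrcoef(x, y)[0, 1])
        r = min(1.0, max(-1.0, r))
        if abs(r) == 1.0:
            p = 0.0 if r < 0 else 1.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(stats.t.cdf(t, n - 2))
        rec.r = r
        rec.p_neg = p
        pvals.append(p)
        idx.append(k)
    if pvals:
        q = multipletests(pvals, method="fdr_bh")[1]
        for k, qv in zip(idx, q):
            out[k].q = float(qv)
    return out


def filter_pairs(records: list[MiRTargetRecord], r_max: float = -0.5,
                 q_max: float = 0.05) -> list[MiRTargetRecord]:
    """Retain pairs with r strictly below ``r_max`` and q strictly below
    ``q_max``; sets the ``retained`` flag on every record."""
    retained = []
    for rec in records:
        rec.retained = bool(np.isfinite(rec.r) and np.isfinite(rec.q)
                            and rec.r < r_max and rec.q < q_max)
        if rec.retained:
            retained.append(rec)
    return retained


def records_table(records: list[MiRTargetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna": r.mirna, "gene": r.gene, "n_sources": len(r.sources),
          "r": r.r, "p_neg": r.p_neg, "q": r.q, "retained": r.retained}
         for r in records])


def targets_by_mirna(retained: list[MiRTargetRecord]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for rec in retained:
        out.setdefault(rec.mirna, []).append(rec.gene)
    return {m: sorted(gs) for m, gs in sorted(out.items())}
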