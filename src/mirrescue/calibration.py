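"""Statistical calibration scenarios run on the synthetic generator.

These functions measure, by repeated seeded simulation, the operating
characteristics that the analysis pipeline is supposed to guarantee:

* the family-wise error rate of the Bonferroni-controlled multiple
  t-test under a global null;
* the false-discovery proportion of the miRNA-target anti-correlation
  filter when no coupling exists;
* the sensitivity and FDR of the same filter on planted couplings;
* the agreement of a one-split SOTA run with the exhaustive minimum
  within-cluster-distance 2-partition on small, well-separated inputs;
* the recovery of planted rescue-pattern genes by SOTA clustering plus
  the pattern classifier.

Null-calibration scenarios use complete matrices (``dropout_p = 0``)
and, for the filter null, a fully flat design (``effect = 0``) so that
every retained pair is unambiguously a false discovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import SotaParams, assign_patterns, relative_profiles, \
    sota_cluster
from .diffexpr import pairwise_ttest
from .mirtarget import anticorrelate, filter_pairs, load_predictions
from .simulate import (SimulationConfig, simulate_mirna, simulate_mrna,
                       simulate_predictions)


def empirical_fwer(n_datasets: int = 200, base_seed: int = 1,
                   n_genes: int = 2000, alpha: float = 0.05) -> dict:
    """Fraction of global-null datasets with any Bonferroni-significant
    probe in the D vs C comparison (4 groups, 3 replicates, sigma 0.3)."""
    hits = 0
    for i in range(n_datasets):
        cfg = SimulationConfig(n_genes=n_genes, effect=0.0, sigma=0.3,
                               n_reps=3, dropout_p=0.0, n_true_pairs=0,
                               seed=base_seed + i)
        matrix, _ = simulate_mrna(cfg)
        res = pairwise_ttest(matrix, "D", "C", alpha=alpha)
        hits += bool(res.significant_genes)
    fwer = hits / n_datasets
    se = np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {"fwer": fwer, "n_datasets": n_datasets,
            "bound": alpha + 2 * se}


def anticorrelation_null_fdr(n_datasets: int = 100, base_seed: int = 1,
                             n_pairs: int = 500) -> dict:
    """Mean false-retained fraction of the anti-correlation filter over
    fully null datasets (beta=0, effect=0, 12 samples, ``n_pairs``
    candidate predictions each; 0 when nothing is retained)."""
    fdps = []
    for i in range(n_datasets):
        cfg = SimulationConfig(n_genes=1000, n_mirnas=300,
                               n_true_pairs=n_pairs // 2, effect=0.0,
                               beta=0.0, sigma=0.3, dropout_p=0.0,
                               decoy_rate=1.0, seed=base_seed + i)
        mrna, truth = simulate_mrna(cfg)
        mirna, truth = simulate_mirna(cfg, truth, mrna)
        tables = simulate_predictions(truth, cfg.decoy_rate, n_sources=1,
                                      seed=base_seed + i)
        records = anticorrelate(load_predictions(tables), mirna, mrna)
        retained = filter_pairs(records)
        # beta=0: no coupling exists, so every retained pair is false
        fdps.append(1.0 if retained else 0.0)
    fdps = np.asarray(fdps)
    return {"mean_fdp": float(fdps.mean()),
            "se": float(fdps.std(ddof=1) / np.sqrt(len(fdps)))
            if len(fdps) > 1 else 0.0,
            "n_datasets": n_datasets}


def pair_recovery(n_datasets: int = 100, base_seed: int = 1) -> dict:
    """Sensitivity and FDR for planted couplings (beta=1, sigma=0.3,
    12 samples, decoys at rate 1.0)."""
    sens, fdps = [], []
    for i in range(n_datasets):
        cfg = SimulationConfig(n_genes=400, n_mirnas=120, n_true_pairs=40,
                               beta=1.0, sigma=0.3, dropout_p=0.0,
                               decoy_rate=1.0, seed=base_seed + i)
        mrna, truth = simulate_mrna(cfg)
        mirna, truth = simulate_mirna(cfg, truth, mrna)
        tables = simulate_predictions(truth, cfg.decoy_rate, n_sources=1,
                                      seed=base_seed + i)
        records = anticorrelate(load_predictions(tables), mirna, mrna)
        kept = {(r.mirna, r.gene) for r in filter_pairs(records)}
        sens.append(len(kept & truth.pair_set) / len(truth.pair_set))
        fdps.append(len(kept - truth.pair_set) / max(len(kept), 1))
    return {"sensitivity": float(np.mean(sens)),
            "fdr": float(np.mean(fdps)), "n_datasets": n_datasets}


def _best_two_partition(X: np.ndarray) -> frozenset:
    """Exhaustive minimum total within-cluster-distance 2-partition."""
    n = X.shape[0]
    best, best_cost = None, np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> k) & 1 for k in range(n)], bool)
        if mask.all() or (~mask).all():
            continue
        cost = 0.0
        for m in (mask, ~mask):
            c = X[m].mean(axis=0)
            cost += np.sqrt(((X[m] - c) ** 2).sum(axis=1)).sum()
        if cost < best_cost:
            best_cost, best = cost, mask
    return frozenset(np.flatnonzero(best))


def sota_partition_agreement(n_instances: int = 100, base_seed: int = 1,
                             n_profiles: int = 10, sigma: float = 0.5,
                             separation: float = 2.0) -> dict:
    """Fraction of seeded two-cluster instances (group separation
    ``separation`` = 4 sigma per dimension) where a one-split SOTA run
    reproduces the exhaustive optimum 2-partition."""
    rng = np.random.default_rng(base_seed)
    agree = 0
    params = SotaParams(max_cycles=1, distance="euclidean",
                        epochs_per_cycle=300)
    for _ in range(n_instances):
        half = n_profiles // 2
        X = np.vstack([
            rng.normal(-separation / 2, sigma, (half, 6)),
            rng.normal(separation / 2, sigma, (n_profiles - half, 6))])
        X = X[rng.permutation(n_profiles)]
        prof = pd.DataFrame(X, index=[f"x{k}" for k in range(n_profiles)])
        _, assignment = sota_cluster(prof, params)
        got = frozenset(np.flatnonzero(
            assignment.labels.to_numpy() == assignment.labels.iloc[0]))
        want = _best_two_partition(X)
        if got in (want, frozenset(range(n_profiles)) - want):
            agree += 1
    return {"agreement": agree / n_instances, "n_instances": n_instances}


def rescue_recovery(base_seed: int = 1, n_genes: int = 300,
                    effect: float = 2.0, sigma: float = 0.3) -> dict:
    """Fraction of planted rescue-pattern genes assigned to clusters
    labeled with the matching pattern (delta = effect / 2)."""
    cfg = SimulationConfig(n_genes=n_genes, effect=effect, sigma=sigma,
                           frac_up_rescued=0.1, frac_down_rescued=0.1,
                           dropout_p=0.0, n_true_pairs=0, seed=base_seed)
    matrix, truth = simulate_mrna(cfg)
    profiles = relative_profiles(matrix.values)
    params = SotaParams(max_cycles=8, epochs_per_cycle=100)
    _, assignment = sota_cluster(profiles, params)
    assignment = assign_patterns(assignment, matrix.groups,
                                 delta=effect / 2)
    hits = total = 0
    for pattern in ("up_rescued", "down_rescued"):
        for g in truth.genes_with(pattern):
            total += 1
            hits += assignment.pattern_of(g) == pattern
    return {"recovery": hits / total, "n_planted": total}
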