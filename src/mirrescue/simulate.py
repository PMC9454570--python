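"""Synthetic paired mRNA/miRNA data with the structure the pipeline assumes.

The generator emulates a four-condition two-color-array experiment —
control (C), treated control (C+P), disease (D), treated disease (D+P),
each with ``n_reps`` biological replicates — with three kinds of planted
structure:

* **rescue patterns**: genes (and miRNAs) shifted by ``effect`` log2
  units in D but restored to control level in D+P, leaving C+P
  untouched (``up_rescued``) or the mirrored down-shift
  (``down_rescued``);
* **miRNA->target repression**: for each planted pair the target gene is
  re-drawn as ``baseline - beta * (miRNA deviation) + noise`` so its
  expression anti-correlates with the miRNA, with a closed-form expected
  Pearson correlation usable as a test oracle;
* **detection dropout**: independent Bernoulli "absent" flags at rate
  ``dropout_p`` per cell, exercising the flag/NA filter rules.

Intensities are log2-normal: per-row baselines drawn from a normal in
log2 space, additive group shifts, Gaussian residual noise of SD
``sigma``. Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import ABSENT, GROUPS, PRESENT, ExpressionMatrix

UP, DOWN, NULL = "up_rescued", "down_rescued", "null"


class ConfigurationError(ValueError):
    """Invalid simulation settings."""


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    n_mirnas: int = 300
    n_reps: int = 3
    effect: float = 2.0
    frac_up_rescued: float = 0.05
    frac_down_rescued: float = 0.05
    n_true_pairs: int = 50
    beta: float = 1.0
    sigma: float = 0.3
    dropout_p: float = 0.05
    decoy_rate: float = 1.0
    seed: int = 0
    # baseline log2-intensity distribution (typical array brightness)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    mirna_baseline_mean: float = 6.0

    def __post_init__(self) -> None:
        for name in ("frac_up_rescued", "frac_down_rescued", "dropout_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up_rescued + self.frac_down_rescued > 1.0:
            raise ConfigurationError(
                "frac_up_rescued + frac_down_rescued must be <= 1")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.decoy_rate < 0:
            raise ConfigurationError("decoy_rate must be >= 0")
        if self.n_true_pairs > self.n_genes * self.n_mirnas:
            raise ConfigurationError(
                "n_true_pairs exceeds the number of possible (miRNA, gene) pairs")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted: per-row pattern labels, couplings, group means."""

    gene_patterns: dict[str, str]
    gene_group_means: pd.DataFrame
    mirna_patterns: dict[str, str] = field(default_factory=dict)
    mirna_group_means: pd.DataFrame | None = None
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.pairs}

    def genes_with(self, pattern: str) -> list[str]:
        return [g for g, p in self.gene_patterns.items() if p == pattern]


def _sample_ids(n_reps: int) -> list[str]:
    return [f"{g}_{r + 1}" for g in GROUPS for r in range(n_reps)]


def _patterns(n_rows: int, cfg: SimulationConfig) -> list[str]:
    n_up = int(round(cfg.frac_up_rescued * n_rows))
    n_down = int(round(cfg.frac_down_rescued * n_rows))
    return [UP] * n_up + [DOWN] * n_down + [NULL] * (n_rows - n_up - n_down)


def _build_matrix(ids: list[str], patterns: list[str], cfg: SimulationConfig,
                  rng: np.random.Generator,
                  baseline_mean: float) -> tuple[pd.DataFrame, pd.DataFrame,
                                                 pd.DataFrame]:
    """Values, flags and true group means for one matrix."""
    n = len(ids)
    samples = _sample_ids(cfg.n_reps)
    base = rng.normal(baseline_mean, cfg.baseline_sd, size=n)
    shift = np.zeros((n, len(GROUPS)))
    d_col = GROUPS.index("D")
    pat = np.asarray(patterns)
    shift[pat == UP, d_col] = cfg.effect
    shift[pat == DOWN, d_col] = -cfg.effect
    group_means = base[:, None] + shift
    per_sample_mean = np.repeat(group_means, cfg.n_reps, axis=1)
    values = per_sample_mean + rng.normal(0.0, cfg.sigma,
                                          size=(n, len(samples)))
    flags = np.where(rng.random(values.shape) < cfg.dropout_p,
                     ABSENT, PRESENT)
    vdf = pd.DataFrame(values, index=ids, columns=samples)
    fdf = pd.DataFrame(flags, index=ids, columns=samples)
    gm = pd.DataFrame(group_means, index=ids, columns=list(GROUPS))
    return vdf, fdf, gm


def simulate_mrna(config: SimulationConfig) -> tuple[ExpressionMatrix,
                                                     GroundTruth]:
    """Generate the mRNA matrix with planted rescue-pattern genes."""
    rng = np.random.default_rng([config.seed, 0])
    ids = [f"G{i:05d}" for i in range(config.n_genes)]
    patterns = _patterns(config.n_genes, config)
    values, flags, gm = _build_matrix(ids, patterns, config, rng,
                                      config.baseline_mean)
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in values.columns})
    matrix = ExpressionMatrix(values=values, groups=groups, flags=flags)
    truth = GroundTruth(gene_patterns=dict(zip(ids, patterns)),
                        gene_group_means=gm)
    return matrix, truth


def simulate_mirna(config: SimulationConfig, truth: GroundTruth,
                   mrna: ExpressionMatrix) -> tuple[ExpressionMatrix,
                                                    GroundTruth]:
    """Generate the miRNA matrix and plant miRNA->target repression.

    For every planted pair the target gene's rows in ``mrna`` are
    **re-drawn in place** as ``mu_g - beta * (m - mu_m) + eps`` where
    ``m`` is the miRNA's realized per-sample level and ``mu`` are the
    baselines; with a rescue-patterned miRNA this yields a strongly
    negative expected Pearson correlation. The passed truth is updated
    with miRNA patterns, planted pairs and the coupled genes' new group
    means, and returned.
    """
    rng = np.random.default_rng([config.seed, 1])
    ids = [f"miR-{i:04d}" for i in range(config.n_mirnas)]
    patterns = _patterns(config.n_mirnas, config)
    values, flags, gm = _build_matrix(ids, patterns, config, rng,
                                      config.mirna_baseline_mean)
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in values.columns})
    mirna = ExpressionMatrix(values=values, groups=groups, flags=flags)

    truth.mirna_patterns = dict(zip(ids, patterns))
    truth.mirna_group_means = gm

    if config.n_true_pairs:
        patterned = [m for m, p in truth.mirna_patterns.items() if p != NULL]
        pool = patterned if patterned else ids
        null_genes = truth.genes_with(NULL)
        if config.n_true_pairs > len(null_genes):
            raise ConfigurationError(
                "n_true_pairs exceeds the number of unpatterned genes "
                "available as targets")
        target_genes = list(rng.choice(null_genes, size=config.n_true_pairs,
                                       replace=False))
        for k, gene in enumerate(target_genes):
            mir = pool[k % len(pool)]
            m = mirna.values.loc[mir].to_numpy(float)
            mu_m = gm.loc[mir].to_numpy(float).mean()  # expected overall level
            mu_g = float(truth.gene_group_means.loc[gene].iloc[0])
            new = (mu_g - config.beta * (m - mu_m)
                   + rng.normal(0.0, config.sigma, size=m.size))
            mrna.values.loc[gene] = new
            truth.gene_group_means.loc[gene] = (
                mu_g - config.beta * (gm.loc[mir].to_numpy(float) - mu_m))
            truth.pairs.append((mir, gene, config.beta))
    return mirna, truth


def simulate_predictions(truth: GroundTruth, decoy_rate: float,
                         n_sources: int,
                         seed: int = 0) -> list[pd.DataFrame]:
    """Per-source prediction tables: all true pairs plus uniform decoys.

    Each of the ``n_sources`` tables contains every planted pair plus
    ``round(decoy_rate * n_true)`` decoys drawn uniformly (without
    replacement, independently per source) from the non-planted
    (miRNA, gene) combinations.
    """
    rng = np.random.default_rng([seed, 2])
    mirnas = list(truth.mirna_patterns)
    genes = list(truth.gene_patterns)
    if not mirnas or not genes:
        raise ValueError("truth lacks miRNA or gene identifiers")
    true_pairs = sorted(truth.pair_set)
    n_decoys = int(round(decoy_rate * len(true_pairs)))
    tables = []
    for s in range(n_sources):
        decoys: set[tuple[str, str]] = set()
        forbidden = truth.pair_set
        while len(decoys) < n_decoys:
            m = mirnas[rng.integers(len(mirnas))]
            g = genes[rng.integers(len(genes))]
            if (m, g) not in forbidden and (m, g) not in decoys:
                decoys.add((m, g))
        rows = true_pairs + sorted(decoys)
        tables.append(pd.DataFrame(
            {"mirna": [m for m, _ in rows],
             "gene": [g for _, g in rows],
             "source": f"alg{s + 1}"}))
    return tables


def simulate_ct(config: SimulationConfig,
                fold_changes: dict[str, dict[str, float]] | None = None,
                reference_sds: dict[str, float] | None = None,
                ct_noise: float = 0.1) -> pd.DataFrame:
    """Long-format qPCR Ct table with embedded fold changes.

    Target genes carry group fold changes (relative to C) embedded as
    ``-log2(FC)`` cycle shifts around a base Ct of 26; candidate
    reference genes sit at base Ct 20 with per-gene noise SDs, the first
    (smallest SD) being the intended stable reference.
    """
    if fold_changes is None:
        fold_changes = {"Tgt1": {"D": 4.0}, "Tgt2": {"D": 0.25}}
    if reference_sds is None:
        reference_sds = {"Tbp": 0.05, "Actb": 0.4, "Gapdh": 0.7, "Rpl4": 1.0}
    rng = np.random.default_rng([config.seed, 3])
    samples = _sample_ids(config.n_reps)
    records = []
    for gene, fcs in fold_changes.items():
        for s in samples:
            g = s.rsplit("_", 1)[0]
            fc = fcs.get(g, 1.0)
            ct = 26.0 - np.log2(fc) + rng.normal(0.0, ct_noise)
            records.append((s, g, gene, ct))
    for gene, sd in reference_sds.items():
        for s in samples:
            g = s.rsplit("_", 1)[0]
            ct = 20.0 + rng.normal(0.0, sd)
            records.append((s, g, gene, ct))
    return pd.DataFrame(records, columns=["sample", "group", "gene", "ct"])


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: (mrna, mirna, truth, prediction tables)."""
    mrna, truth = simulate_mrna(config)
    mirna, truth = simulate_mirna(config, truth, mrna)
    tables = simulate_predictions(truth, config.decoy_rate, n_sources=5,
                                  seed=config.seed)
    return mrna, mirna, truth, tables
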