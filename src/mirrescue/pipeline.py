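"""End-to-end orchestration from a single config, with a hashed manifest.

Stage order follows the analysis narrative: preprocess (mRNA flags ->
NA -> probe filter -> quantile normalization; miRNA detection filter ->
cyclic loess) -> differential expression with Venn partitioning ->
SOTA clustering with rescue-pattern labels and sample dendrograms ->
miRNA-target anti-correlation filtering -> network assembly ->
enrichment (when gene sets / annotations are supplied) -> qPCR (when a
Ct table is supplied). Inputs come either from files or from the
bundled synthetic generator. Every artifact is written as text with 6
significant digits and listed in a manifest JSON with SHA-256 content
hashes, so identical configs give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, diffexpr, enrichment, io, mirtarget, network
from . import preprocess, qpcr, simulate
from .matrix import GROUPS, ExpressionMatrix

log = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "outdir", "synthetic", "inputs", "preprocess",
               "diffexpr", "sota", "mirtarget", "network", "enrichment",
               "qpcr"}

DEFAULT_COMPARISONS = [("D", "C"), ("C+P", "C"), ("D+P", "D"),
                       ("D+P", "C+P")]


class PipelineError(RuntimeError):
    pass


class RunConfig(dict):
    """Validated run configuration (a thin dict wrapper)."""

    def __init__(self, data: dict):
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        super().__init__(data)
        inputs = self.get("inputs") or {}
        for key, path in inputs.items():
            paths = path if isinstance(path, list) else [path]
            for p in paths:
                if not Path(p).exists():
                    raise PipelineError(f"input {key!r}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_all(config: RunConfig | dict, outdir: str | Path | None = None
            ) -> dict:
    """Execute every configured stage; return the manifest dict."""
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    outdir = Path(outdir or config.get("outdir", "mirrescue_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    artifacts: dict[str, Path] = {}
    params_used: dict[str, dict] = {}

    # ---- inputs ---------------------------------------------------
    mrna, mirna, ct_table, pred_tables = _load_inputs(config, seed,
                                                      outdir, artifacts)

    # ---- preprocess ----------------------------------------------
    pp = dict(config.get("preprocess") or {})
    params_used["preprocess"] = pp
    mrna_n = _preprocess_mrna(mrna, pp)
    artifacts["mrna_normalized"] = outdir / "mrna_normalized.tsv"
    io.write_matrix_tsv(mrna_n.values, artifacts["mrna_normalized"])
    mirna_n = None
    if mirna is not None:
        mirna_n = _preprocess_mirna(mirna, pp)
        artifacts["mirna_normalized"] = outdir / "mirna_normalized.tsv"
        io.write_matrix_tsv(mirna_n.values, artifacts["mirna_normalized"])

    # ---- differential expression ---------------------------------
    de_cfg = dict(config.get("diffexpr") or {})
    params_used["diffexpr"] = de_cfg
    comparisons = [tuple(c) for c in de_cfg.get("comparisons",
                                                DEFAULT_COMPARISONS)]
    alpha = float(de_cfg.get("alpha", 0.05))
    results = _run_diffexpr(mrna_n, comparisons, alpha, outdir, artifacts)
    regions = diffexpr.venn_partition(results)
    artifacts["venn"] = outdir / "venn_regions.tsv"
    diffexpr.venn_table(regions).to_csv(artifacts["venn"], sep="\t",
                                        index=False)

    # ---- clustering ----------------------------------------------
    sota_cfg = dict(config.get("sota") or {})
    params_used["sota"] = sota_cfg
    de_genes = sorted(set().union(*(r.significant_genes for r in results))
                      if results else set())
    _run_clustering(mrna_n, results, de_genes, sota_cfg, outdir, artifacts)

    # ---- miRNA targets and network -------------------------------
    retained = []
    if mirna_n is not None and pred_tables:
        mt_cfg = dict(config.get("mirtarget") or {})
        params_used["mirtarget"] = mt_cfg
        records = mirtarget.load_predictions(
            pred_tables, min_support=int(mt_cfg.get("min_support", 1)))
        records = mirtarget.anticorrelate(records, mirna_n, mrna_n)
        retained = mirtarget.filter_pairs(
            records, r_max=float(mt_cfg.get("r_max", -0.5)),
            q_max=float(mt_cfg.get("q_max", 0.05)))
        artifacts["mirtarget"] = outdir / "mirtarget_records.tsv"
        mirtarget.records_table(records).to_csv(
            artifacts["mirtarget"], sep="\t", index=False,
            float_format=io.FLOAT_FORMAT)
        net_cfg = dict(config.get("network") or {})
        params_used["network"] = net_cfg
        ppi = (network.load_ppi((config.get("inputs") or {})["ppi"])
               if "ppi" in (config.get("inputs") or {}) else [])
        gm = pd.concat([mrna_n.group_means(), mirna_n.group_means()])
        net = network.build_network(retained, ppi, gm,
                                    ppi_hops=int(net_cfg.get("ppi_hops", 1)))
        artifacts["network"] = outdir / "network.graphml"
        network.export_network(net, artifacts["network"], "graphml")
        artifacts["network_nodes"] = outdir / "network_nodes.tsv"
        network.node_attribute_table(net).to_csv(
            artifacts["network_nodes"], sep="\t", index=False,
            float_format=io.FLOAT_FORMAT)

    # ---- enrichment ----------------------------------------------
    inputs = config.get("inputs") or {}
    if "gene_sets" in inputs and de_genes:
        en_cfg = dict(config.get("enrichment") or {})
        params_used["enrichment"] = en_cfg
        sets = io.read_gmt(inputs["gene_sets"])
        coll = enrichment.GeneSetCollection(
            sets, universe=set(mrna_n.probe_ids) | set().union(*sets.values()))
        res = enrichment.ora(set(de_genes), coll,
                             ease=bool(en_cfg.get("ease", False)))
        artifacts["ora"] = outdir / "ora.tsv"
        res.to_csv(artifacts["ora"], sep="\t", index=False,
                   float_format=io.FLOAT_FORMAT)

    # ---- qPCR -----------------------------------------------------
    if ct_table is not None:
        q_cfg = dict(config.get("qpcr") or {})
        params_used["qpcr"] = q_cfg
        candidates = q_cfg.get("reference_candidates")
        reference = q_cfg.get("reference")
        if candidates:
            ranking = qpcr.reference_stability(ct_table, list(candidates))
            artifacts["reference_stability"] = outdir / "reference_stability.tsv"
            ranking.to_csv(artifacts["reference_stability"], sep="\t",
                           index=False, float_format=io.FLOAT_FORMAT)
            reference = reference or ranking["gene"].iloc[0]
        if reference:
            targets = q_cfg.get("targets") or sorted(
                set(ct_table["gene"]) - set(candidates or []) - {reference})
            rq = {t: qpcr.ddct(ct_table, t, reference,
                               q_cfg.get("calibrator", "C"))
                  for t in targets}
            artifacts["qpcr_rq"] = outdir / "qpcr_rq.tsv"
            pd.concat(rq, names=["gene"]).to_csv(
                artifacts["qpcr_rq"], sep="\t",
                float_format=io.FLOAT_FORMAT)

    # ---- manifest -------------------------------------------------
    manifest = {
        "seed": seed,
        "params": params_used,
        "artifacts": {k: {"path": str(p.relative_to(outdir)),
                          "sha256": _sha256(p)}
                      for k, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest


# ---------------------------------------------------------------------------


@_stage("inputs")
def _load_inputs(config, seed, outdir, artifacts):
    inputs = config.get("inputs") or {}
    synth = config.get("synthetic")
    pred_tables = []
    ct_table = None
    if synth is not None:
        cfg = simulate.SimulationConfig(**{**synth, "seed": seed})
        mrna, mirna, truth, pred_tables = simulate.simulate_dataset(cfg)
        ct_table = simulate.simulate_ct(cfg)
        for prefix, mat in (("mrna", mrna), ("mirna", mirna)):
            for kind, p in io.write_expression(mat, outdir,
                                               f"input_{prefix}").items():
                artifacts[f"input_{prefix}_{kind}"] = p
    else:
        if "mrna_matrix" not in inputs:
            raise PipelineError("config needs 'synthetic' or inputs.mrna_matrix")
        mrna = io.read_expression(inputs["mrna_matrix"], inputs["samples"],
                                  inputs.get("mrna_flags"))
        mirna = None
        if "mirna_matrix" in inputs:
            mirna = io.read_expression(inputs["mirna_matrix"],
                                       inputs["samples"],
                                       inputs.get("mirna_flags"))
        for p in inputs.get("predictions", []):
            pred_tables.append(io.read_predictions(p))
        if "ct" in inputs:
            ct_table = io.read_ct_table(inputs["ct"])
    return mrna, mirna, ct_table, pred_tables


@_stage("preprocess")
def _preprocess_mrna(mrna: ExpressionMatrix, pp: dict) -> ExpressionMatrix:
    if mrna.flags is not None:
        mrna = preprocess.apply_flag_na(mrna)
    mrna = preprocess.filter_mrna_probes(
        mrna, max_na_frac=float(pp.get("max_na_frac", 0.5)))
    return preprocess.quantile_normalize(mrna)


@_stage("preprocess")
def _preprocess_mirna(mirna: ExpressionMatrix, pp: dict) -> ExpressionMatrix:
    mirna = preprocess.filter_mirna(mirna)
    return preprocess.cyclic_loess_normalize(
        mirna, span=float(pp.get("loess_span", 0.7)),
        max_iter=int(pp.get("loess_iters", 3)))


@_stage("diffexpr")
def _run_diffexpr(mrna_n, comparisons, alpha, outdir, artifacts):
    results = []
    for a, b in comparisons:
        res = diffexpr.pairwise_ttest(mrna_n, a, b, alpha=alpha)
        results.append(res)
        name = f"de_{a}_vs_{b}".replace("+", "p")
        artifacts[name] = outdir / f"{name}.tsv"
        res.table.to_csv(artifacts[name], sep="\t",
                         float_format=io.FLOAT_FORMAT)
    return results


@_stage("clustering")
def _run_clustering(mrna_n, results, de_genes, sota_cfg, outdir, artifacts):
    if len(de_genes) >= 2:
        profiles = clustering.relative_profiles(
            mrna_n.values.loc[de_genes].dropna(axis=0))
        params = clustering.SotaParams(**{
            k: v for k, v in sota_cfg.items() if k != "delta"})
        tree, assignment = clustering.sota_cluster(profiles, params)
        dc_diffs = [r.table.loc[list(r.significant_genes), "diff"]
                    for r in results if r.comparison == ("D", "C")]
        if "delta" in sota_cfg:
            delta = float(sota_cfg["delta"])
        elif dc_diffs and len(dc_diffs[0]):
            delta = clustering.default_delta(dc_diffs[0])
        else:
            delta = 0.5
        assignment = clustering.assign_patterns(assignment, mrna_n.groups,
                                                delta)
        out = pd.DataFrame({
            "cluster": assignment.labels,
            "pattern": [assignment.patterns[c]
                        for c in assignment.labels]})
        out.index.name = "probe"
        artifacts["sota_clusters"] = outdir / "sota_clusters.tsv"
        out.to_csv(artifacts["sota_clusters"], sep="\t")
        artifacts["sota_tree"] = outdir / "sota_tree.nwk"
        artifacts["sota_tree"].write_text(tree.to_newick() + "\n")
    Z, labels = clustering.hcluster_samples(mrna_n)
    artifacts["sample_dendrogram"] = outdir / "sample_dendrogram.nwk"
    artifacts["sample_dendrogram"].write_text(
        clustering.linkage_to_newick(Z, labels) + "\n")
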