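"""End-to-end orchestration of the analysis stages on synthetic or user data.

The stage order mirrors the experimental workflow: simulate (or load) →
qPCR processing → co-expression clustering → network reconstruction →
FAIRE enrichment → summit annotation and association tests → motif
scanning.  Every run writes its resolved configuration next to the outputs
and a machine-readable JSON summary, and is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, faire, iota, motifs, peaks, qpcr, synthetic

log = logging.getLogger("ccmgrn")

STAGES = ["simulate", "qpcr", "cluster", "grn", "faire", "annotate", "motif"]


@dataclass
class RunConfig:
    """All stage parameters; defaults are the protocol's values."""

    outdir: str = "ccmgrn_run"
    seed: int = 0
    simulate: bool = True
    ct_table: str | None = None  # input Ct table when simulate=False
    # simulation
    n_genes: int = 20
    edge_density: float = 0.08
    coupling: float = 3.0
    noise_sd: float = 0.05
    n_timepoints: int = 12
    n_replicates: int = 5
    ct_offset: float = 25.0
    tech_sd: float = 0.05
    genome_n_genes: int = 300
    genome_chrom_length: int = 400_000
    de_gene_fraction: float = 0.3
    p_peak_given_de: float = 0.9
    p_peak_given_not_de: float = 0.1
    summit_offset_sd: int = 100
    # qPCR processing
    ct_threshold: float = 0.2
    baseline_lo: int = 3
    baseline_hi: int = 15
    min_efficiency: float = 95.0
    max_fail_frac: float = 0.25
    gdna_cutoff: float = 36.0
    # clustering
    qt_diameter: float = 0.5
    qt_min_size: int = 4
    # network inference
    n_perm: int = 10000
    alpha: float = 0.01
    # annotation / association
    fc_cutoff: float = 2.0
    max_distance: float = 1000
    histogram_bin: int = 500
    # motif
    motif: str = motifs.EE_CONSENSUS
    upstream_bp: int = 500

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat key=value text file; CLI overrides beat the file."""
        values = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in fields:
                    raise KeyError(f"unknown config key {key!r}")
                values[key] = _coerce(raw.strip(), fields[key].type)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _coerce(raw: str, ftype) -> object:
    t = str(ftype)
    if raw.lower() in ("none", ""):
        return None
    if "bool" in t:
        return raw.lower() in ("1", "true", "yes")
    if "int" in t and "str" not in t:
        return int(raw)
    if "float" in t:
        return float(raw)
    return raw


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the configured stages; returns the summary dict.

    Artifacts (delimited-text tables, FASTA, network exports) and a
    ``summary.json`` land in ``config.outdir``; the resolved configuration
    is written there too, so every run is self-describing.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.txt").write_text(config.to_json() + "\n")
    stages = stages or STAGES
    summary: dict = {"seed": config.seed}
    state: dict = {}
    for stage in stages:
        fn = _STAGE_FUNCS[stage]
        log.info("stage %s starting", stage)
        try:
            fn(config, state, summary, out)
        except Exception as err:  # noqa: BLE001 - re-raised with stage tag
            raise StageError(stage, err) from err
        log.info("stage %s done", stage)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_simulate(cfg: RunConfig, state, summary, out: Path) -> None:
    if not cfg.simulate:
        if not cfg.ct_table:
            raise FileNotFoundError("no Ct table given and simulate=False")
        state["ct"] = qpcr.read_ct_table(cfg.ct_table)
        summary["n_genes_input"] = state["ct"]["gene_id"].nunique()
        return
    exp = synthetic.simulate_grn_timeseries(
        n_genes=cfg.n_genes, edge_density=cfg.edge_density,
        coupling=cfg.coupling, noise_sd=cfg.noise_sd,
        n_timepoints=cfg.n_timepoints, n_replicates=cfg.n_replicates,
        seed=cfg.seed,
    )
    state["experiment"] = exp
    ct = synthetic.expression_to_ct(
        exp.expression, ct_offset=cfg.ct_offset, tech_sd=cfg.tech_sd,
        seed=cfg.seed + 1, timepoints_min=exp.timepoints_min,
        gene_ids=exp.gene_ids,
    )
    state["ct"] = ct
    qpcr.write_ct_table(ct, out / "ct_table.tsv")
    pd.DataFrame(exp.truth.edges, columns=["regulator", "target"]).to_csv(
        out / "truth_edges.tsv", sep="\t", index=False)

    genes, summits, truth = synthetic.simulate_genome_with_peaks(
        n_genes=cfg.genome_n_genes, chrom_length=cfg.genome_chrom_length,
        de_gene_fraction=cfg.de_gene_fraction,
        p_peak_given_de=cfg.p_peak_given_de,
        p_peak_given_not_de=cfg.p_peak_given_not_de,
        summit_offset_sd=cfg.summit_offset_sd, seed=cfg.seed + 2,
    )
    state["genome"] = (genes, summits, truth)
    peaks.write_gff3_genes(genes, out / "genes.gff3")
    peaks.write_summit_bed(summits, out / "summits.bed")
    truth.to_csv(out / "genome_truth.tsv", sep="\t", index=False)
    summary["n_genes_simulated"] = cfg.n_genes
    summary["n_true_edges"] = len(exp.truth.edges)
    summary["n_summits"] = len(summits)


def _stage_qpcr(cfg: RunConfig, state, summary, out: Path) -> None:
    ct = state["ct"]
    normalized = qpcr.quantile_normalize(ct)
    fc = qpcr.relative_expression(normalized)
    state["fold_changes"] = fc
    fc.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    profiles = fc.pivot(index="gene_id", columns="timepoint_min",
                        values="fold_change")
    scaled, excluded = qpcr.scale_profiles(profiles)
    state["scaled_profiles"] = scaled
    scaled.to_csv(out / "scaled_profiles.tsv", sep="\t")
    # profiles for network inference: log2 relative expression, i.e. the
    # negated replicate-median normalized Ct (the ordering-based inference
    # is invariant under this monotone rescaling)
    dct = normalized.groupby(["gene_id", "timepoint_min"])["ct"].median()
    expr = (-dct).unstack("timepoint_min")
    state["expression_profiles"] = expr
    expr.to_csv(out / "expression_profiles.tsv", sep="\t")
    summary["n_genes_detected"] = int(ct["gene_id"].nunique())
    summary["n_genes_changed_2fold"] = int(
        ((fc["fold_change"] >= cfg.fc_cutoff)
         | (fc["fold_change"] <= 1 / cfg.fc_cutoff))
        .groupby(fc["gene_id"]).any().sum()
    )
    summary["n_constant_profiles_excluded"] = len(excluded)


def _stage_cluster(cfg: RunConfig, state, summary, out: Path) -> None:
    assignment = clustering.qt_cluster(
        state["scaled_profiles"], diameter=cfg.qt_diameter,
        min_size=cfg.qt_min_size,
    )
    state["clusters"] = assignment
    assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
    summary["n_clusters"] = assignment.n_clusters
    summary["n_genes_clustered"] = sum(len(c) for c in assignment.clusters)
    summary["n_genes_unassigned"] = len(assignment.unassigned)


def _stage_grn(cfg: RunConfig, state, summary, out: Path) -> None:
    net = iota.reconstruct_network(
        state["expression_profiles"], alpha=cfg.alpha, n_perm=cfg.n_perm,
        seed=cfg.seed + 3,
    )
    state["network"] = net
    net.write_edge_list(out / "network_edges.tsv")
    net.write_sif(out / "network.sif")
    net.write_graphml(out / "network.graphml")
    net.iota_matrix.to_csv(out / "iota_matrix.tsv", sep="\t")
    net.p_matrix.to_csv(out / "p_matrix.tsv", sep="\t")
    stats = iota.degree_stats(net)
    summary["n_network_nodes"] = stats["n_nodes"]
    summary["n_network_edges"] = stats["n_edges"]
    summary["mean_out_degree"] = stats["mean_out_degree"]
    if "experiment" in state:
        truth = state["experiment"].truth
        ids = state["experiment"].gene_ids
        true_edges = {(ids[r], ids[t]) for r, t in truth.edges}
        found = {(r, t) for r, t in
                 zip(net.edges["regulator"], net.edges["target"])}
        tp = len(found & true_edges)
        summary["edge_recall"] = tp / len(true_edges) if true_edges else np.nan
        summary["edge_precision"] = tp / len(found) if found else np.nan


def _stage_faire(cfg: RunConfig, state, summary, out: Path) -> None:
    panel, _window = faire.load_cah1_panel()
    amplicons = panel["amplicon"]
    rng = np.random.default_rng(cfg.seed + 4)
    # planted ground truth: promoter (B, C) and 3'-UTR (I, J) amplicons open
    # under LC, promoter alone mildly open under HC
    open_lc = {"B": 8.0, "C": 6.0, "I": 4.0, "J": 4.0}
    open_hc = {"B": 2.0, "C": 2.0}
    control = pd.Series(1.0, index=amplicons)
    profiles = {}
    for cond, planted in (("HC", open_hc), ("LC", open_lc)):
        ab = pd.Series([planted.get(a, 1.0) for a in amplicons],
                       index=amplicons, dtype=float)
        ct_f, ct_c = synthetic.simulate_faire_ct(
            ab, control, tech_sd=cfg.tech_sd,
            seed=int(rng.integers(2 ** 31)),
        )
        # least-enriched reference: with planted truth the promoter/3'UTR
        # openness then reads out directly as enrichment > 1
        profiles[cond] = faire.enrichment_profile(ct_f, ct_c,
                                                  rule="least-enriched")
        profiles[cond].table.to_csv(out / f"faire_enrichment_{cond}.tsv",
                                    sep="\t")
    comparison = faire.compare_conditions(profiles["HC"], profiles["LC"])
    comparison.to_csv(out / "faire_hc_vs_lc.tsv", sep="\t")
    state["faire"] = (profiles, comparison)
    summary["faire_reference_amplicon"] = profiles["LC"].reference
    summary["n_amplicons_lc_open"] = int(comparison["lc_gt_hc"].sum())


def _stage_annotate(cfg: RunConfig, state, summary, out: Path) -> None:
    genes, summits, truth = state["genome"]
    assignments = peaks.assign_summits(summits, genes,
                                       max_distance=np.inf)
    assignments.to_csv(out / "summit_assignments.tsv", sep="\t", index=False)
    hist = peaks.distance_histogram(assignments, bin_bp=cfg.histogram_bin)
    hist.to_csv(out / "distance_histogram.tsv", sep="\t", index=False)

    near = peaks.assign_summits(summits, genes, max_distance=cfg.max_distance)
    peak_near = pd.Series(False, index=truth["gene_id"])
    peak_near[near["gene_id"].dropna().unique()] = True
    de = truth.set_index("gene_id")["de"]
    up = truth.set_index("gene_id")["up"]
    assoc = peaks.association_test(peak_near, de)
    direction = peaks.direction_test(peak_near, up[de])
    state["association"] = (assoc, direction)
    summary["n_summits_assigned"] = int(assignments["gene_id"].notna().sum())
    summary["pct_within_500bp"] = float(hist["cumulative_pct"].iloc[0])
    summary["association_chi2"] = assoc["chi2"]
    summary["association_p"] = assoc["p"]
    summary["direction_chi2"] = direction["chi2"]
    summary["direction_p"] = direction["p"]


def _stage_motif(cfg: RunConfig, state, summary, out: Path) -> None:
    ee_hits = {
        "EE-1": motifs.scan_iupac(motifs.EE1, cfg.motif, seq_id="EE-1"),
        "EE-2": motifs.scan_iupac(motifs.EE2, cfg.motif, seq_id="EE-2"),
    }
    with open(out / "motif_hits.tsv", "w") as fh:
        fh.write("seq_id\toffset\tstrand\tmatch\n")
        for hits in ee_hits.values():
            for h in hits:
                fh.write(f"{h.seq_id}\t{h.offset}\t{h.strand}\t{h.match}\n")
    summary["ee_sequences_with_consensus"] = sum(
        bool(h) for h in ee_hits.values())
    if "genome" in state:
        genes, _, truth = state["genome"]
        fasta = out / "toy_genome.fa"
        de_ids = set(truth.loc[truth["de"], "gene_id"])
        synthetic.write_toy_genome_fasta(
            genes, cfg.genome_chrom_length, fasta, seed=cfg.seed + 5,
            planted_motif="GACTTTC",  # a concrete instance of the consensus
            planted_genes=de_ids,
        )
        promoters = motifs.extract_promoters(genes, fasta, cfg.upstream_bp)
        motifs.write_fasta(promoters, out / "promoters.fa")
        hit = {
            r.id.removesuffix("_promoter")
            for r in promoters
            if motifs.scan_iupac(str(r.seq), cfg.motif, seq_id=r.id)
        }
        summary["n_promoters"] = len(promoters)
        summary["n_de_promoters_with_motif"] = len(hit & de_ids)
        summary["n_other_promoters_with_motif"] = len(hit - de_ids)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qpcr": _stage_qpcr,
    "cluster": _stage_cluster,
    "grn": _stage_grn,
    "faire": _stage_faire,
    "annotate": _stage_annotate,
    "motif": _stage_motif,
}


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
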