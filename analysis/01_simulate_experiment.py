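#!/usr/bin/env python
"""Generate the synthetic study: expression time series, Ct tables, genome.

A 20-gene ground-truth regulatory network drives a 12-point expression time
course (5 biological replicates, HC sample at t = 0, LC afterwards); the
expression is converted to qPCR Ct tables with technical noise.  A 300-gene
toy genome gets open-chromatin summits planted preferentially near the
differentially expressed genes (P(peak|DE) = 0.9 vs 0.1), with a wide summit
jitter so the distance histogram has a realistic tail.

Writes: scratch/ct_table.tsv (bulky intermediate), results/truth_edges.tsv,
results/genes.gff3, results/summits.bed, results/genome_truth.tsv
"""

from pathlib import Path

import pandas as pd

from ccmgrn import peaks, qpcr, synthetic

SEED = 20131101 % 2**31
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)

exp = synthetic.simulate_grn_timeseries(
    n_genes=60, edge_density=0.02, coupling=3.0, noise_sd=0.05,
    n_timepoints=12, n_replicates=5, seed=SEED)
ct = synthetic.expression_to_ct(
    exp.expression, ct_offset=25.0, tech_sd=0.05, seed=SEED + 1,
    timepoints_min=exp.timepoints_min, gene_ids=exp.gene_ids)
qpcr.write_ct_table(ct.round({"ct": 4}), SCRATCH / "ct_table.tsv")
ids = exp.gene_ids
pd.DataFrame([(ids[r], ids[t]) for r, t in exp.truth.edges],
             columns=["regulator", "target"]).to_csv(
    RESULTS / "truth_edges.tsv", sep="\t", index=False)

genes, summits, truth = synthetic.simulate_genome_with_peaks(
    n_genes=300, chrom_length=600_000, de_gene_fraction=0.3,
    p_peak_given_de=0.9, p_peak_given_not_de=0.1, summit_offset_sd=600,
    seed=SEED + 2)
peaks.write_gff3_genes(genes, RESULTS / "genes.gff3")
peaks.write_summit_bed(summits, RESULTS / "summits.bed")
truth.to_csv(RESULTS / "genome_truth.tsv", sep="\t", index=False)

print(f"simulated {len(ids)} genes x {len(exp.timepoints_min)} timepoints "
      f"x 5 replicates ({len(ct)} Ct values), "
      f"{len(exp.truth.edges)} true regulatory edges")
print(f"toy genome: {len(genes)} genes, {len(summits)} planted summits, "
      f"{int(truth.de.sum())} DE genes")
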