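"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design of a high-to-low CO2 shift
experiment: a known directed regulatory network drives gene expression time
series, expression is converted to qPCR cycle-threshold (Ct) tables via the
relative-quantification identity Ct = offset − log2(expression), raw
amplification curves follow a saturated exponential with a known efficiency,
and a toy genome carries genes with open-chromatin summits planted
preferentially near differentially expressed genes.  Everything is a pure
function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthNetwork",
    "SimulatedExperiment",
    "random_network",
    "simulate_grn_timeseries",
    "simulate_amplification_curve",
    "expression_to_ct",
    "simulate_genome_with_peaks",
    "simulate_faire_ct",
    "write_toy_genome_fasta",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A known directed network: edges are ordered (regulator, target) pairs.

    ``coupling_strength`` > 0 scales the regulatory effect of each edge and
    ``sign`` (+1 activation, −1 repression) its direction; repression is
    first-class because the downstream monotonicity measure detects monotone
    couplings of either sign.
    """

    n_genes: int
    edges: tuple[tuple[int, int], ...]
    coupling_strength: dict = field(default_factory=dict)
    sign: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for r, t in self.edges:
            if r == t:
                raise ValueError(f"self-edge {r}->{t} not allowed")
            if not (0 <= r < self.n_genes and 0 <= t < self.n_genes):
                raise ValueError(f"gene index out of range in edge {r}->{t}")
            if self.coupling_strength.get((r, t), 1.0) <= 0:
                raise ValueError("coupling_strength must be > 0")

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges)

    def regulators_of(self, target: int) -> list[int]:
        return [r for r, t in self.edges if t == target]


@dataclass(frozen=True)
class SimulatedExperiment:
    """Expression array (gene × timepoint × replicate), its truth and seed."""

    expression: np.ndarray
    timepoints_min: np.ndarray
    truth: GroundTruthNetwork
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.expression <= 0):
            raise ValueError("expression must be strictly positive")
        if np.any(np.diff(self.timepoints_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.truth.n_genes)]

    def replicate_mean_profiles(self) -> pd.DataFrame:
        """Gene × timepoint matrix of replicate-averaged expression."""
        return pd.DataFrame(
            self.expression.mean(axis=2),
            index=self.gene_ids,
            columns=self.timepoints_min,
        )


def random_network(
    n_genes: int,
    edge_density: float,
    coupling: float,
    seed: int = 0,
    edges=None,
    repression_fraction: float = 0.3,
) -> GroundTruthNetwork:
    """Sample a directed network; each ordered pair is an edge w.p. density.

    An explicit ``edges`` iterable overrides the random sampling (used to
    plant specific motifs such as a single forced edge or a regulator with a
    known target set).
    """
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if edges is None:
        edges = [
            (i, j)
            for i in range(n_genes)
            for j in range(n_genes)
            if i != j and rng.random() < edge_density
        ]
    edges = tuple(tuple(e) for e in edges)
    strength = {e: float(coupling * rng.uniform(0.8, 1.2)) for e in edges}
    sign = {
        e: (-1 if rng.random() < repression_fraction else 1) for e in edges
    }
    # zero coupling is allowed at the experiment level (null model) but the
    # network type requires positive strengths; encode it with epsilon there
    if coupling == 0:
        strength = {e: 1e-12 for e in edges}
    return GroundTruthNetwork(n_genes, edges, strength, sign)


def _source_response(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Deterministic transient response of an unregulated gene (log2 units).

    A smooth random curve — a low-order Fourier series over the observation
    window — standing in for the gene-specific transcriptional response to
    the CO2 downshift.  Transient (non-monotone) shapes are the norm, which
    is what gives unrelated genes generically non-monotone mutual relations.
    """
    m = t.size
    phase = t / t[-1] if t[-1] > 0 else t
    amp = rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])
    coeff = rng.normal(size=3) * [1.0, 0.7, 0.4]
    z = np.zeros(m)
    for k, c in enumerate(coeff, start=1):
        z += c * np.sin(np.pi * k * phase + rng.uniform(0, 2 * np.pi))
    z *= amp / max(np.abs(z).max(), 1e-9)
    return z


def simulate_grn_timeseries(
    n_genes: int,
    edge_density: float = 0.1,
    coupling: float = 3.0,
    noise_sd: float = 0.1,
    n_timepoints: int = 12,
    n_replicates: int = 5,
    seed: int = 0,
    edges=None,
    timestep_min: float = 60.0,
) -> SimulatedExperiment:
    """Simulate coupled expression time series from a known directed network.

    Unregulated genes follow deterministic gene-specific transient response
    curves; a regulated gene's log2-expression is a saturating monotone
    (tanh) function of its regulators' log2-expression, with sign −1 edges
    modelling repression.  Regulatory equilibration is treated as fast
    relative to the sampling interval, so a target tracks its regulators
    within the same sample (edges that would close a cycle fall back to the
    regulator's previous timepoint).  Measurement noise is additive Gaussian
    on log2-expression, independent per replicate, and expression is obtained
    by exponentiation so it stays strictly positive.
    """
    if n_timepoints < 3:
        raise ValueError("n_timepoints must be >= 3 (downstream ι undefined)")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0 or coupling < 0:
        raise ValueError("noise_sd and coupling must be >= 0")

    rng = np.random.default_rng(seed)
    truth = random_network(n_genes, edge_density, coupling, seed=seed + 1,
                           edges=edges)
    t = np.arange(n_timepoints) * timestep_min

    z = np.zeros((n_genes, n_timepoints))
    regulators = {g: truth.regulators_of(g) for g in range(n_genes)}
    for g in range(n_genes):
        if not regulators[g]:
            z[g] = _source_response(rng, t)

    # genes updated in index order each timepoint: an edge r->g reads the
    # regulator's current value when r was already updated this step
    # (r < g), else its previous value — this breaks cycles deterministically
    for step in range(n_timepoints):
        for g in range(n_genes):
            if not regulators[g]:
                continue
            total = 0.0
            for r in regulators[g]:
                use_step = step if (r < g or not regulators[r]) else max(step - 1, 0)
                s = truth.coupling_strength[(r, g)]
                total += truth.sign[(r, g)] * s * np.tanh(z[r, use_step] / 2.0)
            # averaging the parental drives keeps the log2 amplitude within
            # the per-edge strength, matching realistic fold-change ranges
            z[g, step] = total / len(regulators[g])

    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_timepoints, n_replicates)) \
        if noise_sd > 0 else np.zeros((n_genes, n_timepoints, n_replicates))
    expression = np.exp2(z[:, :, None] + noise)
    return SimulatedExperiment(expression=expression, timepoints_min=t,
                               truth=truth, seed=seed)


def simulate_amplification_curve(
    efficiency_pct: float,
    f0: float,
    plateau: float,
    n_cycles: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Saturated exponential qPCR amplification curve, one value per cycle.

    Below the plateau the clean signal is exactly f0·(1 + E/100)^c for cycle
    c = 1..n_cycles, then capped at the plateau; Gaussian noise is added on
    top.  f0 = 0 yields a flat (undetectable) curve, which is valid input
    downstream.
    """
    if not (0 < efficiency_pct <= 100):
        raise ValueError("efficiency_pct must be in (0, 100]")
    if f0 < 0 or plateau <= 0 or noise_sd < 0:
        raise ValueError("f0 >= 0, plateau > 0, noise_sd >= 0 required")
    if n_cycles < 20:
        raise ValueError("n_cycles must be >= 20")
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    base = 1.0 + efficiency_pct / 100.0
    with np.errstate(over="ignore"):
        clean = np.minimum(f0 * base ** cycles, plateau)
    if noise_sd > 0:
        clean = clean + np.random.default_rng(seed).normal(0, noise_sd, n_cycles)
    return clean


def expression_to_ct(
    expression,
    ct_offset: float = 25.0,
    tech_sd: float = 0.0,
    seed: int = 0,
    timepoints_min=None,
    gene_ids=None,
    hc_timepoint: float = 0.0,
) -> pd.DataFrame:
    """Convert an expression array to a long-format Ct table.

    Inverts the relative-quantification relation: Ct = offset − log2(x) plus
    technical noise.  ``expression`` is gene × timepoint × replicate (a 2-D
    gene × timepoint array is treated as a single replicate).  Samples taken
    at ``hc_timepoint`` are labelled condition HC (before the CO2 shift),
    all later samples LC.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if np.any(x <= 0):
        raise ValueError("expression must be strictly positive")
    if tech_sd < 0:
        raise ValueError("tech_sd must be >= 0")
    n_genes, n_tp, n_rep = x.shape
    if timepoints_min is None:
        timepoints_min = np.arange(n_tp) * 60.0
    timepoints_min = np.asarray(timepoints_min, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i:03d}" for i in range(n_genes)]

    rng = np.random.default_rng(seed)
    ct = ct_offset - np.log2(x)
    if tech_sd > 0:
        ct = ct + rng.normal(0, tech_sd, size=ct.shape)

    records = []
    for gi, gene in enumerate(gene_ids):
        for ti, tp in enumerate(timepoints_min):
            cond = "HC" if tp == hc_timepoint else "LC"
            for rep in range(n_rep):
                records.append((gene, cond, float(tp), rep + 1, ct[gi, ti, rep]))
    return pd.DataFrame(
        records, columns=["gene_id", "condition", "timepoint_min", "replicate", "ct"]
    )


def simulate_faire_ct(
    abundance_faire: pd.Series,
    abundance_control: pd.Series,
    ct_offset: float = 22.0,
    n_replicates: int = 3,
    tech_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-amplicon FAIRE and de-crosslinked-control Ct replicate tables.

    Plumbing for the enrichment stage: relative template abundances per
    amplicon map to Ct via offset − log2(abundance) + noise.  Returns two
    amplicon × replicate DataFrames (FAIRE, control).
    """
    if not abundance_faire.index.equals(abundance_control.index):
        raise ValueError("FAIRE and control panels must match")
    rng = np.random.default_rng(seed)
    out = []
    for ab in (abundance_faire, abundance_control):
        if np.any(ab.values <= 0):
            raise ValueError("abundances must be strictly positive")
        ct = ct_offset - np.log2(ab.values[:, None])
        ct = ct + rng.normal(0, tech_sd, size=(len(ab), n_replicates)) \
            if tech_sd > 0 else np.repeat(ct, n_replicates, axis=1)
        out.append(pd.DataFrame(
            ct, index=ab.index,
            columns=[f"rep{r+1}" for r in range(n_replicates)],
        ))
    return out[0], out[1]


def simulate_genome_with_peaks(
    n_genes: int,
    chrom_length: int,
    de_gene_fraction: float = 0.3,
    p_peak_given_de: float = 0.9,
    p_peak_given_not_de: float = 0.1,
    summit_offset_sd: int = 100,
    seed: int = 0,
    gene_length: int = 200,
    chrom: str = "chr1",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Toy genome: non-overlapping genes, planted summits, truth labels.

    Genes are placed without overlap on a single chromosome; a summit is
    planted near the coding start or stop codon of a gene with probability
    ``p_peak_given_de`` if the gene is differentially expressed (DE), else
    ``p_peak_given_not_de``, offset by Gaussian jitter of ``summit_offset_sd``
    bp.  Returns (genes, summits, truth) where genes use 1-based inclusive
    coding coordinates (GFF3 convention), summits are single-base features
    with a surrounding peak span, and truth records DE status, direction and
    peak presence per gene.
    """
    for p in (de_gene_fraction, p_peak_given_de, p_peak_given_not_de):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    slot = chrom_length // n_genes
    margin = 2 * max(summit_offset_sd, 50)
    if slot < gene_length + margin:
        raise ValueError(
            f"chrom_length {chrom_length} too small to place {n_genes} "
            f"non-overlapping {gene_length}-bp genes with flanks"
        )
    rng = np.random.default_rng(seed)

    genes, truths, summits = [], [], []
    for i in range(n_genes):
        gene_id = f"gene{i:04d}"
        lo = i * slot + margin // 2
        start = int(lo + rng.integers(0, max(slot - gene_length - margin, 1)))
        end = start + gene_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        de = bool(rng.random() < de_gene_fraction)
        up = bool(rng.random() < 0.5)
        p_peak = p_peak_given_de if de else p_peak_given_not_de
        has_peak = bool(rng.random() < p_peak)
        genes.append((gene_id, chrom, start, end, strand))
        truths.append((gene_id, de, de and up, has_peak))
        if has_peak:
            anchor = start if rng.random() < 0.5 else end
            offset = int(round(rng.normal(0, summit_offset_sd))) \
                if summit_offset_sd > 0 else 0
            pos = int(np.clip(anchor + offset, 1, chrom_length))
            summits.append((chrom, pos, max(pos - 100, 1),
                            min(pos + 100, chrom_length),
                            float(rng.uniform(10, 100)), gene_id))

    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    summits_df = pd.DataFrame(
        summits,
        columns=["chrom", "summit", "peak_start", "peak_end", "score",
                 "planted_near"],
    )
    truth_df = pd.DataFrame(truths, columns=["gene_id", "de", "up", "has_peak"])
    return genes_df, summits_df, truth_df


def write_toy_genome_fasta(
    genes: pd.DataFrame,
    chrom_length: int,
    path,
    seed: int = 0,
    planted_motif: str | None = None,
    planted_offset: int = 50,
    planted_genes=None,
    line_width: int = 70,
) -> None:
    """Random nucleotide sequence for the toy genome, written as FASTA.

    If ``planted_motif`` is given (plain ACGT), one copy is written
    ``planted_offset`` bp upstream of each gene's coding start on the plus
    strand (downstream of the coding end for minus-strand genes), so promoter
    extraction and motif scanning have a known positive set;
    ``planted_genes`` restricts planting to a subset of gene ids.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=chrom_length)
    if planted_motif:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for row in genes.itertuples(index=False):
            if planted_genes is not None and row.gene_id not in planted_genes:
                continue
            if row.strand == "+":
                pos = row.start - planted_offset - len(planted_motif)
                insert = planted_motif
            else:
                pos = row.end + planted_offset
                insert = "".join(comp[b] for b in reversed(planted_motif))
            if 0 <= pos and pos + len(insert) <= chrom_length:
                seq[pos:pos + len(insert)] = list(insert)
    chrom = genes["chrom"].iloc[0] if len(genes) else "chr1"
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for i in range(0, len(s), line_width):
            fh.write(s[i:i + line_width] + "\n")
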