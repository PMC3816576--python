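"""Summit-to-gene assignment, distance histogram and association tests.

Open-chromatin summits (single-base positions of maximal FAIRE read
enrichment) are assigned to the nearest gene *coding-sequence boundary* —
the translation start (ATG) or stop codon — on the same chromosome.
Distances therefore measure proximity to coding spans, not to transcript
TSS/TTS; strand is recorded but does not change the unsigned distance.

Coordinate conventions: GFF3 gene annotations are 1-based inclusive, BED
summit records 0-based half-open; everything is converted to 1-based
positions internally, and the summit of an even-width peak takes the
lower-middle base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_gff3_genes",
    "write_gff3_genes",
    "read_summit_bed",
    "write_summit_bed",
    "assign_summits",
    "distance_histogram",
    "association_test",
    "direction_test",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gff3_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene coding spans from GFF3 (1-based inclusive, kept as such)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or parts[8]
            rows.append((gene_id, parts[0], int(parts[3]), int(parts[4]),
                         parts[6]))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if (df["start"] > df["end"]).any():
        raise ValueError("GFF3 records with start > end")
    return df


def write_gff3_genes(genes: pd.DataFrame, path, source: str = "ccmgrn") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_summit_bed(path) -> pd.DataFrame:
    """Summits from 4+ column BED (0-based half-open, single-base intervals).

    The internal ``summit`` column is the 1-based position (= BED end for a
    single-base interval).  Wider intervals are allowed and reduced to their
    lower-middle base, the convention for even-width peaks.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "bed_start", 2: "bed_end",
                            3: "name", 4: "score"})
    if (df["bed_end"] <= df["bed_start"]).any():
        raise ValueError("BED records with end <= start")
    width = df["bed_end"] - df["bed_start"]
    # 1-based position of the lower-middle base of the interval
    df["summit"] = df["bed_start"] + (width - 1) // 2 + 1
    if "score" not in df.columns:
        df["score"] = 0.0
    return df[["chrom", "summit", "bed_start", "bed_end", "score"]]


def write_summit_bed(summits: pd.DataFrame, path) -> None:
    """Write single-base BED intervals (0-based half-open) for summits."""
    with open(path, "w") as fh:
        for i, row in enumerate(summits.itertuples(index=False)):
            name = getattr(row, "planted_near", f"summit{i}")
            score = getattr(row, "score", 0.0)
            fh.write(f"{row.chrom}\t{row.summit - 1}\t{row.summit}\t"
                     f"{name}\t{score:g}\n")


def assign_summits(
    summits: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: float = 1000,
) -> pd.DataFrame:
    """Assign each summit to the gene with the nearest coding boundary.

    The distance of a summit to a gene is min(|summit − start|,
    |summit − end|); the nearest gene on the same chromosome wins, with ties
    broken by gene id order.  Summits farther than ``max_distance`` from
    every boundary (pass ``np.inf`` for unbounded histograms) or on a
    chromosome without annotation are unassigned.

    Returns one row per summit: gene_id (or None), distance (signed,
    summit − boundary), abs_distance, boundary ('start' or 'stop').
    """
    rows = []
    by_chrom = {c: g.sort_values("gene_id") for c, g in genes.groupby("chrom")}
    for row in summits.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            rows.append((row.chrom, row.summit, None, np.nan, np.nan, None))
            continue
        d_start = row.summit - g["start"].to_numpy()
        d_end = row.summit - g["end"].to_numpy()
        use_start = np.abs(d_start) <= np.abs(d_end)
        dist = np.where(use_start, d_start, d_end)
        k = int(np.argmin(np.abs(dist)))  # first minimum = gene id order
        if np.abs(dist[k]) > max_distance:
            rows.append((row.chrom, row.summit, None, np.nan, np.nan, None))
            continue
        rows.append((
            row.chrom, row.summit, g["gene_id"].iloc[k], float(dist[k]),
            float(abs(dist[k])), "start" if use_start[k] else "stop",
        ))
    return pd.DataFrame(rows, columns=[
        "chrom", "summit", "gene_id", "distance", "abs_distance", "boundary",
    ])


def distance_histogram(
    assignments: pd.DataFrame,
    bin_bp: int = 500,
    max_bp: int = 5000,
) -> pd.DataFrame:
    """Binned counts of |distance| with the cumulative percentage of summits.

    Bins are [k·bin_bp, (k+1)·bin_bp) up to ``max_bp`` plus an overflow bin;
    the cumulative percentage is taken over all *assigned* summits, so it
    reads "x% of summits lie within this distance of a coding boundary".
    Compute assignments with ``max_distance=np.inf`` first — truncated
    assignments would clip the histogram's tail.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    d = assignments["abs_distance"].dropna().to_numpy()
    edges = list(np.arange(0, max_bp + bin_bp, bin_bp))
    counts, _ = np.histogram(d, bins=edges + [np.inf])
    total = counts.sum()
    labels = [f"[{int(a)},{int(b)})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f">={max_bp}")
    out = pd.DataFrame({
        "bin": labels,
        "bin_start": edges[:-1] + [max_bp],
        "count": counts,
    })
    out["cumulative_pct"] = (
        100.0 * out["count"].cumsum() / total if total else 0.0
    )
    return out


def _chi2_2x2(table: np.ndarray, yates: bool) -> tuple[float, float]:
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=yates)
    assert dof == 1
    return float(chi2), float(p)


def association_test(
    peak_near_gene: pd.Series,
    fc_class: pd.Series,
    yates: bool = False,
) -> dict:
    """Association between peak presence and a >2-fold expression change.

    Both inputs are boolean Series over the same genes; the test is the
    Pearson chi-square on the 2×2 contingency table (no continuity
    correction by default), 1 degree of freedom.
    """
    peak_near_gene, fc_class = peak_near_gene.align(fc_class, join="inner")
    if peak_near_gene.empty:
        raise ValueError("no shared genes between the two label sets")
    table = np.array([
        [int((peak_near_gene & fc_class).sum()),
         int((peak_near_gene & ~fc_class).sum())],
        [int((~peak_near_gene & fc_class).sum()),
         int((~peak_near_gene & ~fc_class).sum())],
    ])
    chi2, p = _chi2_2x2(table, yates)
    return {"chi2": chi2, "p": p, "table": table}


def direction_test(
    peak_near_gene: pd.Series,
    up: pd.Series,
    yates: bool = False,
) -> dict:
    """Peak presence vs direction of change, restricted to the DE genes.

    ``up`` is boolean (True = up-regulated) indexed by the differentially
    expressed genes only; peak labels are subset to that index.
    """
    peak_sub = peak_near_gene.loc[peak_near_gene.index.intersection(up.index)]
    return association_test(peak_sub, up.loc[peak_sub.index], yates=yates)
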