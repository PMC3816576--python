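"""Degenerate IUPAC consensus scanning and promoter FASTA export.

The Cah1 promoter carries two experimentally mapped enhancer elements
(EE-1 and EE-2) that share the degenerate consensus 5'-GANTTNC-3' (IUPAC:
N = any base), similar to the plant box III light-responsive element.  This
module scans sequences for such consensus patterns — every position of the
pattern is an IUPAC character whose base set must contain the sequence base
— and extracts strand-aware promoter windows as FASTA for downstream motif
discovery tools.

Overlapping matches are all reported; scanning is single-strand by default
(enhancer elements are defined on the promoter strand) with an optional
reverse-complement scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EE1", "EE2", "EE_CONSENSUS",
    "MotifHit",
    "scan_iupac",
    "count_matching_sequences",
    "extract_promoters",
    "write_fasta",
]

# Published Cah1 enhancer-element sequences and their shared consensus
# (EE-1: −293..−269 bp, EE-2: −241..−231 bp upstream of the Cah1 ATG).
EE1 = "AGATTTTCACCGGTTGGAAGGAGGT"
EE2 = "CGACTTACGAA"
EE_CONSENSUS = "GANTTNC"

# Biopython's table adds the non-IUPAC placeholder X; restrict to the
# fifteen IUPAC nucleotide codes.
_IUPAC = {k.upper(): frozenset(v.upper())
          for k, v in ambiguous_dna_values.items() if k.upper() != "X"}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based position on the forward sequence
    strand: str  # '+' or '-'
    match: str   # the matched substring, as written on the forward strand


def _validate_pattern(pattern: str) -> list[frozenset]:
    if not pattern:
        raise ValueError("empty motif pattern")
    sets = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC letter {ch!r} in pattern")
        sets.append(_IUPAC[ch])
    return sets


def scan_iupac(
    seq: str,
    pattern: str,
    both_strands: bool = False,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All offsets where the IUPAC pattern matches the sequence.

    A position matches when the pattern letter's IUPAC base set contains the
    sequence base (an N in the *sequence* only matches pattern N).  With
    ``both_strands=True`` the reverse complement of the pattern is also
    scanned and minus-strand hits are reported at their forward-strand
    offsets.
    """
    sets = _validate_pattern(pattern)
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-nucleotide letters: {bad}")
    k = len(sets)
    hits = [
        MotifHit(seq_id, i, "+", s[i:i + k])
        for i in range(len(s) - k + 1)
        if all(s[i + j] in sets[j] for j in range(k))
    ]
    if both_strands:
        rc_sets = _validate_pattern(str(Seq(pattern).reverse_complement()))
        hits += [
            MotifHit(seq_id, i, "-", s[i:i + k])
            for i in range(len(s) - k + 1)
            if all(s[i + j] in rc_sets[j] for j in range(k))
        ]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def count_matching_sequences(seqs: dict, pattern: str,
                             both_strands: bool = False) -> int:
    """Number of sequences containing at least one pattern match."""
    return sum(
        bool(scan_iupac(s, pattern, both_strands=both_strands, seq_id=name))
        for name, s in seqs.items()
    )


def extract_promoters(
    genes,
    genome,
    upstream_bp: int,
) -> list[SeqRecord]:
    """Strand-aware upstream windows ending just before each coding start.

    ``genes`` is a DataFrame with 1-based inclusive coding coordinates and
    strand; ``genome`` a FASTA path or a dict of chromosome → sequence.  For
    a plus-strand gene the window covers [start − upstream_bp, start − 1];
    for a minus-strand gene the reverse complement of
    [end + 1, end + upstream_bp].  Windows truncated at a chromosome edge are
    flagged in the record description.
    """
    if upstream_bp < 1:
        raise ValueError("upstream_bp must be >= 1")
    if not isinstance(genome, dict):
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}
    records = []
    for row in genes.itertuples(index=False):
        if row.chrom not in genome:
            raise KeyError(f"chromosome {row.chrom!r} missing from genome")
        chrom_seq = genome[row.chrom]
        if row.strand == "-":
            lo = row.end + 1
            hi = min(row.end + upstream_bp, len(chrom_seq))
            window = str(Seq(chrom_seq[lo - 1:hi]).reverse_complement())
        else:
            lo = max(row.start - upstream_bp, 1)
            hi = row.start - 1
            window = chrom_seq[lo - 1:hi]
        truncated = len(window) < upstream_bp
        desc = f"upstream={upstream_bp} strand={row.strand}" + (
            " truncated" if truncated else "")
        records.append(SeqRecord(Seq(window), id=f"{row.gene_id}_promoter",
                                 description=desc))
    return records


def write_fasta(records: list[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fasta")
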