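"""FAIRE qPCR enrichment across a locus, with reference-region normalization.

FAIRE (formaldehyde-assisted isolation of regulatory elements) enriches
nucleosome-depleted DNA; qPCR over a tiling panel of amplicons then reads
out *where* along a locus the open chromatin sits.  De-crosslinked chromatin
serves as the abundance control.  For each amplicon x and a chosen reference
amplicon ref,

    ΔCt_FAIRE(x) = Ct_FAIRE(x) − Ct_FAIRE(ref)
    ΔCt_ctrl(x)  = Ct_ctrl(x)  − Ct_ctrl(ref)
    ΔΔCt(x)      = ΔCt_FAIRE(x) − ΔCt_ctrl(x)
    enrichment   = 2^−ΔΔCt(x)

so the reference amplicon has enrichment exactly 1 and a 2-fold excess of a
fragment in the FAIRE sample doubles its enrichment.  The default reference
rule picks the amplicon with the lowest Ct(FAIRE)/Ct(control) *ratio* (the
rule used for the Cah1 locus reference region); the alternative
``rule='least-enriched'`` picks the amplicon whose un-normalized ΔΔCt is
largest, i.e. the least-enriched region.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentProfile",
    "read_amplicon_panel",
    "load_cah1_panel",
    "validate_panel",
    "select_reference",
    "enrichment_profile",
    "compare_conditions",
]

PANEL_COLUMNS = ["amplicon", "start", "end", "forward", "reverse"]


@dataclass
class EnrichmentProfile:
    """Per-amplicon enrichment table plus the chosen reference amplicon."""

    table: pd.DataFrame  # ct_faire, ct_control, delta_delta_ct, enrichment, sd
    reference: str

    @property
    def enrichment(self) -> pd.Series:
        return self.table["enrichment"]


def read_amplicon_panel(path, sep: str = "\t") -> tuple[pd.DataFrame, tuple[int, int]]:
    """Read an amplicon panel (id, start/end, primer pair) with its window.

    The file may carry a ``# locus_window: lo-hi`` comment giving the
    1-based surveyed window the coordinates are relative to; without it the
    window defaults to (1, max end).
    """
    window = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "locus_window:" in line:
                lo, hi = line.split("locus_window:")[1].strip().split("-")
                window = (int(lo), int(hi))
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if window is None:
        window = (1, int(df["end"].max()))
    return df, window


def load_cah1_panel() -> tuple[pd.DataFrame, tuple[int, int]]:
    """The ten-amplicon qPCR tiling panel of the Cah1 locus (A–J)."""
    ref = resources.files("ccmgrn.data").joinpath("cah1_amplicons.tsv")
    with resources.as_file(ref) as path:
        return read_amplicon_panel(path)


def validate_panel(panel: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Check structural validity: start < end, inside window, non-nested.

    Returns the panel (unchanged) or raises with the first violation.
    Amplicons may appear in any order but must not be nested inside one
    another.
    """
    lo, hi = window
    for row in panel.itertuples(index=False):
        if not row.start < row.end:
            raise ValueError(f"amplicon {row.amplicon}: start >= end")
        if row.start < lo or row.end > hi:
            raise ValueError(
                f"amplicon {row.amplicon}: outside locus window {window}")
        for seq, name in ((row.forward, "forward"), (row.reverse, "reverse")):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(
                    f"amplicon {row.amplicon}: invalid {name} primer")
    spans = list(zip(panel["amplicon"], panel["start"], panel["end"]))
    for a, s1, e1 in spans:
        for b, s2, e2 in spans:
            if a != b and s1 <= s2 and e2 <= e1 and (s1, e1) != (s2, e2):
                raise ValueError(f"amplicon {b} nested inside {a}")
    return panel


def _means(ct) -> pd.Series:
    """Per-amplicon mean Ct from a Series or amplicon × replicate frame."""
    if isinstance(ct, pd.DataFrame):
        return ct.mean(axis=1)
    return pd.Series(ct, dtype=float)


def _sds(ct) -> pd.Series:
    if isinstance(ct, pd.DataFrame):
        return ct.std(axis=1, ddof=1).fillna(0.0)
    return pd.Series(0.0, index=pd.Series(ct, dtype=float).index)


def select_reference(ct_faire, ct_control, rule: str = "ct-ratio") -> str:
    """Choose the normalization reference amplicon.

    ``rule='ct-ratio'``: the amplicon minimizing mean Ct(FAIRE)/Ct(control)
    — ties broken by panel order.  ``rule='least-enriched'``: the amplicon
    with the largest Ct(FAIRE) − Ct(control) difference, i.e. the region
    least enriched in the FAIRE sample.
    """
    f, c = _means(ct_faire), _means(ct_control)
    if len(f) == 0:
        raise ValueError("empty amplicon panel")
    if not f.index.equals(c.index):
        raise ValueError("FAIRE and control tables must cover the same panel")
    if (f <= 0).any() or (c <= 0).any():
        raise ValueError("Ct values must be positive")
    if rule == "ct-ratio":
        score = f / c
    elif rule == "least-enriched":
        score = -(f - c)
    else:
        raise ValueError("rule must be 'ct-ratio' or 'least-enriched'")
    # first index attaining the minimum, in panel order
    return score.index[int(np.argmin(score.to_numpy()))]


def enrichment_profile(
    ct_faire,
    ct_control,
    reference: str = "auto",
    rule: str = "ct-ratio",
) -> EnrichmentProfile:
    """Per-amplicon FAIRE enrichment 2^−ΔΔCt against a reference amplicon.

    ``ct_faire`` / ``ct_control`` are per-amplicon mean Ct Series or
    amplicon × replicate DataFrames (replicate SD is then propagated by
    quadrature onto the ΔΔCt).  ``reference='auto'`` applies
    :func:`select_reference`.
    """
    f, c = _means(ct_faire), _means(ct_control)
    if not f.index.equals(c.index):
        raise ValueError("FAIRE and control tables must cover the same panel")
    if reference == "auto":
        reference = select_reference(ct_faire, ct_control, rule=rule)
    if reference not in f.index:
        raise ValueError(f"reference amplicon {reference!r} missing")
    ddct = (f - f.loc[reference]) - (c - c.loc[reference])
    sd_f, sd_c = _sds(ct_faire), _sds(ct_control)
    sd = np.sqrt(sd_f ** 2 + sd_c ** 2
                 + sd_f.loc[reference] ** 2 + sd_c.loc[reference] ** 2)
    sd.loc[reference] = 0.0
    table = pd.DataFrame({
        "ct_faire": f,
        "ct_control": c,
        "delta_delta_ct": ddct,
        "enrichment": np.exp2(-ddct),
        "sd_ddct": sd,
    })
    return EnrichmentProfile(table=table, reference=reference)


def compare_conditions(
    profile_hc: EnrichmentProfile,
    profile_lc: EnrichmentProfile,
) -> pd.DataFrame:
    """Aligned HC/LC enrichment with the LC/HC ratio per amplicon.

    Flags the amplicons where the low-CO2 chromatin is more open than the
    high-CO2 chromatin (``lc_gt_hc``).
    """
    a, b = profile_hc.table, profile_lc.table
    if not a.index.equals(b.index):
        raise ValueError("profiles cover different amplicon panels")
    out = pd.DataFrame({
        "enrichment_hc": a["enrichment"],
        "enrichment_lc": b["enrichment"],
    })
    out["ratio_lc_hc"] = out["enrichment_lc"] / out["enrichment_hc"]
    out["lc_gt_hc"] = out["enrichment_lc"] > out["enrichment_hc"]
    return out
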