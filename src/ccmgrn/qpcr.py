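"""From raw amplification curves to QC-filtered relative expression.

The processing chain mirrors standard SYBR-green RT-qPCR practice for a
two-condition (high CO2 / low CO2) time course with biological replicates:

1. Ct calling on baseline-corrected fluorescence at a fixed threshold.
2. Per-reaction amplification-efficiency estimation by log-linear regression
   over a window of linearity, with gene-level quality filtering.
3. Genomic-DNA contamination check on an intergenic amplicon.
4. Quantile normalization of Ct values across samples.
5. ΔΔCt relative quantification: ΔCt is the biological-replicate median of
   normalized Ct, ΔΔCt = ΔCt(LC, t) − ΔCt(reference), and the fold change is
   FC = 2^−ΔΔCt.
6. Min–max scaling of log2 profiles (mean-centred) for clustering.

Ct values are plain floats; a reaction with no threshold crossing is
"not detected" and represented as NaN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "call_ct",
    "estimate_efficiency",
    "qc_filter_genes",
    "gdna_check",
    "quantile_normalize",
    "relative_expression",
    "reference_gene_expression",
    "scale_profiles",
    "read_ct_table",
    "write_ct_table",
]

CT_COLUMNS = ["gene_id", "condition", "timepoint_min", "replicate", "ct"]


def _baseline_correct(f: np.ndarray, baseline_cycles: tuple[int, int]) -> np.ndarray:
    lo, hi = baseline_cycles
    if lo < 1 or hi > f.size or hi <= lo:
        raise ValueError("baseline window must lie within the curve")
    c = np.arange(lo, hi + 1, dtype=float)
    slope, intercept = np.polyfit(c, f[lo - 1:hi], 1)
    cycles = np.arange(1, f.size + 1, dtype=float)
    return f - (intercept + slope * cycles)


def call_ct(
    curve,
    threshold: float = 0.2,
    baseline_cycles: tuple[int, int] | None = (3, 15),
) -> float:
    """Cycle threshold of an amplification curve; NaN if never crossed.

    A linear baseline fitted over ``baseline_cycles`` (1-based, inclusive)
    is subtracted first; the Ct is the linearly interpolated fractional
    cycle at which the corrected fluorescence first rises through
    ``threshold``.  The baseline window must precede the amplification
    phase — fitting through rising signal drags the baseline up and biases
    the Ct (pass ``baseline_cycles=None`` for curves that are already
    baseline-free).
    """
    f = np.asarray(curve, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if f.ndim != 1 or not np.all(np.isfinite(f)):
        raise ValueError("curve must be a finite 1-D vector")
    if baseline_cycles is not None:
        f = _baseline_correct(f, baseline_cycles)

    above = f >= threshold
    if not above.any():
        return float("nan")
    k = int(np.argmax(above))  # first cycle index (0-based) at/over threshold
    cycle = k + 1.0
    if k == 0 or f[k] == threshold:
        return cycle
    prev, cur = f[k - 1], f[k]
    return float(cycle - 1 + (threshold - prev) / (cur - prev))


def estimate_efficiency(
    curve,
    window_len: int = 5,
    criterion: str = "r2",
    weighted: bool = True,
) -> float:
    """Amplification efficiency (%) by log-linear regression.

    log10(fluorescence) is regressed against cycle number over every
    contiguous window of ``window_len`` cycles in which the fluorescence is
    positive and strictly rising (the candidate exponential stretches); the
    window of linearity is the candidate with the best log-linear fit
    (``criterion='r2'``, ties broken by steeper slope then earlier position)
    or, alternatively, the steepest one (``criterion='slope'``).  By default
    the fit weights each point by its squared fluorescence — the
    inverse-variance weighting for additive fluorescence noise, which keeps
    the noisy low-signal cycles from dominating the log-scale fit
    (``weighted=False`` gives plain OLS; identical on noiseless curves).
    Efficiency is (10^slope − 1)·100, i.e. 100% for perfect per-cycle
    doubling.
    """
    f = np.asarray(curve, dtype=float)
    if window_len < 3:
        raise ValueError("window_len must be >= 3")
    if criterion not in ("r2", "slope"):
        raise ValueError("criterion must be 'r2' or 'slope'")
    n = f.size
    candidates = []
    for start in range(0, n - window_len + 1):
        w = f[start:start + window_len]
        if not (np.all(w > 0) and np.all(np.diff(w) > 0)):
            continue
        c = np.arange(start + 1, start + window_len + 1, dtype=float)
        logf = np.log10(w)
        wt = w ** 2 if weighted else np.ones_like(w)
        wt = wt / wt.sum()
        cbar = float((wt * c).sum())
        lbar = float((wt * logf).sum())
        slope = float((wt * (c - cbar) * (logf - lbar)).sum()
                      / (wt * (c - cbar) ** 2).sum())
        resid = logf - (lbar + slope * (c - cbar))
        ss_tot = float((wt * (logf - lbar) ** 2).sum())
        r2 = 1.0 - float((wt * resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
        candidates.append((start, slope, r2))
    if not candidates:
        raise ValueError(
            "efficiency indeterminate: no positive strictly-rising window"
        )
    if criterion == "slope":
        best = max(candidates, key=lambda c: (c[1], -c[0]))
    else:
        best = max(candidates, key=lambda c: (round(c[2], 12), c[1], -c[0]))
    return float((10.0 ** best[1] - 1.0) * 100.0)


def qc_filter_genes(
    efficiencies: pd.DataFrame,
    min_eff: float = 95.0,
    max_fail_frac: float = 0.25,
) -> tuple[list, pd.DataFrame]:
    """Exclude genes whose reactions fail the efficiency criterion too often.

    ``efficiencies`` is a long table with columns ``gene_id`` and
    ``efficiency_pct`` (one row per reaction).  A gene is excluded iff the
    fraction of its reactions with efficiency < ``min_eff`` is strictly
    greater than ``max_fail_frac``; a fail fraction exactly at the limit is
    retained.  Returns (retained gene list, per-gene report).
    """
    if efficiencies.empty:
        raise ValueError("empty efficiency table")
    df = efficiencies.copy()
    df["fail"] = df["efficiency_pct"] < min_eff
    report = df.groupby("gene_id", sort=False).agg(
        n_reactions=("fail", "size"), n_fail=("fail", "sum")
    )
    report["fail_frac"] = report["n_fail"] / report["n_reactions"]
    report["retained"] = report["fail_frac"] <= max_fail_frac
    retained = list(report.index[report["retained"]])
    return retained, report.reset_index()


def gdna_check(ct_intergenic: float, cutoff: float = 36.0) -> bool:
    """Genomic-DNA contamination check on an intergenic amplicon.

    Passes iff the intergenic Ct exceeds the cutoff or no amplification was
    detected at all (NaN): no amplification means no contamination.
    """
    if ct_intergenic is None or np.isnan(ct_intergenic):
        return True
    return bool(ct_intergenic > cutoff)


def quantile_normalize(ct: pd.DataFrame, by_condition: bool = False) -> pd.DataFrame:
    """Quantile-normalize Ct values across samples.

    Within each sample (condition × timepoint × replicate), values are
    replaced so every sample's sorted Ct vector equals the across-sample
    mean of sorted vectors, preserving within-sample rank order.  Genes with
    a missing value in any sample are dropped from the rank computation and
    restored as missing.  With ``by_condition=True`` the normalization is
    applied within each condition separately instead of jointly.
    """
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if by_condition:
        parts = [
            quantile_normalize(sub, by_condition=False)
            for _, sub in ct.groupby("condition", sort=False)
        ]
        return pd.concat(parts, ignore_index=True)

    wide = ct.pivot(
        index="gene_id",
        columns=["condition", "timepoint_min", "replicate"],
        values="ct",
    )
    if wide.shape[1] >= 1 and wide.isna().all(axis=0).any():
        raise ValueError("a sample has all-missing Ct values")
    complete = wide.dropna(axis=0)
    if wide.shape[1] > 1 and not complete.empty:
        arr = complete.to_numpy(dtype=float)
        order = np.argsort(arr, axis=0, kind="stable")
        mean_sorted = np.sort(arr, axis=0).mean(axis=1)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            out[order[:, j], j] = mean_sorted
        normalized = pd.DataFrame(out, index=complete.index, columns=complete.columns)
    else:
        normalized = complete  # single sample: identity
    long = normalized.stack(list(range(normalized.columns.nlevels)),
                            future_stack=True).rename("ct").reset_index()
    return long[CT_COLUMNS]


def _delta_ct(ct: pd.DataFrame, stat: str = "median") -> pd.DataFrame:
    agg = ct.groupby(["gene_id", "condition", "timepoint_min"])["ct"]
    out = agg.median() if stat == "median" else agg.mean()
    spread = agg.std(ddof=1).fillna(0.0)
    return pd.DataFrame({"delta_ct": out, "spread": spread}).reset_index()


def relative_expression(
    ct: pd.DataFrame,
    reference_condition: tuple[str, float] = ("HC", 0.0),
    test_condition: str = "LC",
) -> pd.DataFrame:
    """ΔΔCt fold changes per gene and timepoint against a reference sample.

    ΔCt is the median of normalized Ct across biological replicates; for each
    gene and LC timepoint, ΔΔCt = ΔCt(LC, t) − ΔCt(reference) and the fold
    change is FC = 2^−ΔΔCt.  ``replicate_spread`` is the replicate standard
    deviation of the test-condition Ct values.
    """
    dct = _delta_ct(ct, stat="median")
    ref_cond, ref_tp = reference_condition
    ref = dct[(dct["condition"] == ref_cond) & (dct["timepoint_min"] == ref_tp)]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition} absent")
    ref = ref.set_index("gene_id")["delta_ct"]

    test = dct[dct["condition"] == test_condition].copy()
    test = test[test["gene_id"].isin(ref.index)]
    test["delta_delta_ct"] = test["delta_ct"] - ref.loc[test["gene_id"]].values
    test["fold_change"] = np.exp2(-test["delta_delta_ct"])
    test = test.rename(columns={"spread": "replicate_spread"})
    return test[["gene_id", "timepoint_min", "delta_delta_ct", "fold_change",
                 "replicate_spread"]].reset_index(drop=True)


def reference_gene_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    reference_condition: tuple[str, float] = ("HC", 0.0),
) -> pd.DataFrame:
    """ΔΔCt of a target gene normalized to a reference gene (e.g. actin).

    ΔCt = Ct(target) − Ct(reference) within each sample, averaged over
    replicates per condition × timepoint (SD reported); ΔΔCt subtracts the
    reference-condition ΔCt and FC = 2^−ΔΔCt.  Used for marker genes such as
    Cah1/Mca where a single stable housekeeping gene is the normalizer.
    """
    sub = ct[ct["gene_id"].isin([target, reference])]
    wide = sub.pivot_table(
        index=["condition", "timepoint_min", "replicate"],
        columns="gene_id", values="ct",
    )
    for g in (target, reference):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} not present in all samples")
    if wide[reference].isna().any():
        raise ValueError("reference gene not detected in at least one sample")
    wide = wide.dropna()
    delta = (wide[target] - wide[reference]).rename("delta_ct").reset_index()
    agg = delta.groupby(["condition", "timepoint_min"])["delta_ct"].agg(
        delta_ct="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0
    ).reset_index()
    ref_cond, ref_tp = reference_condition
    ref_rows = agg[(agg["condition"] == ref_cond) & (agg["timepoint_min"] == ref_tp)]
    if ref_rows.empty:
        raise ValueError(f"reference condition {reference_condition} absent")
    ref_val = float(ref_rows["delta_ct"].iloc[0])
    agg["delta_delta_ct"] = agg["delta_ct"] - ref_val
    agg["fold_change"] = np.exp2(-agg["delta_delta_ct"])
    return agg


def scale_profiles(profiles: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-gene scaled log2 profiles for clustering; constant genes dropped.

    Each gene's profile (fold changes or relative expression, strictly
    positive) is log2-transformed, linearly mapped so its minimum is 0 and
    maximum 1, then mean-centred (so every scaled profile sums to zero).
    Genes with a constant profile have no defined scaling and are excluded;
    their ids are returned alongside the scaled matrix.
    """
    if (profiles <= 0).to_numpy().any():
        raise ValueError("profiles must be strictly positive before log2")
    logp = np.log2(profiles.astype(float))
    rng_span = logp.max(axis=1) - logp.min(axis=1)
    excluded = list(profiles.index[rng_span == 0])
    kept = logp.loc[rng_span > 0]
    scaled = kept.sub(kept.min(axis=1), axis=0).div(
        rng_span.loc[kept.index], axis=0)
    scaled = scaled.sub(scaled.mean(axis=1), axis=0)
    return scaled, excluded


def read_ct_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def write_ct_table(ct: pd.DataFrame, path, sep: str = "\t") -> None:
    ct[CT_COLUMNS].to_csv(path, sep=sep, index=False)
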