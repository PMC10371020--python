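"""Feature-level aggregation of enrichment z-scores and the associated
statistical battery: head-on vs codirectional contrasts, cross-genotype
paired comparisons (Wilcoxon + Benjamini-Hochberg FDR, bootstrap CIs), and
the Bayesian orientation x expression regression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bayes import GLMFit, sample_glm
from .genome import first_n_bp
from .signal import robust_z
from .trackio import GenomicTrack


def expression_z(log_expr: np.ndarray) -> np.ndarray:
    """Robust z of log-scale expression (computed once per genotype)."""
    return robust_z(np.asarray(log_expr, dtype=float))


def aggregate_features(
    z_tracks: dict,
    features: list,
    mask_flags: np.ndarray | None = None,
    first_bp: int | None = None,
) -> pd.DataFrame:
    """Median same-strand z-score per feature.

    ``z_tracks`` maps strand ('+'/'-') to a :class:`GenomicTrack` of robust
    z-scores.  A bin contributes to a feature when its midpoint lies inside
    the (optionally truncated to the first ``first_bp``) feature interval;
    masked bins (``mask_flags`` True, aligned to the track bins) are
    excluded.  Features left with no usable bin get NaN.
    """
    any_track = next(iter(z_tracks.values()))
    mids = 0.5 * (any_track.starts + any_track.ends)
    if mask_flags is None:
        mask_flags = np.zeros(any_track.n_bins, dtype=bool)
    rows = []
    for f in features:
        sub = first_n_bp(f, first_bp) if first_bp is not None else f
        track = z_tracks[f.strand]
        inside = (mids >= sub.start) & (mids < sub.end) & ~mask_flags
        vals = track.values[inside]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "id": f.id,
                "type": f.type.value,
                "orientation": f.orientation.value,
                "strand": f.strand,
                "length": f.length,
                "score": float(np.median(vals)) if vals.size else np.nan,
                "n_bins": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def top_expression_ids(table: pd.DataFrame, frac: float = 0.2) -> set:
    """IDs of the top ``frac`` of features by expression z (ties kept)."""
    expr = table.dropna(subset=["expr_z"])
    cut = expr["expr_z"].quantile(1.0 - frac)
    return set(expr.loc[expr["expr_z"] >= cut, "id"])


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    label: str
    estimate: float  # median difference (Hodges-Lehmann for unpaired)
    ci_low: float
    ci_high: float
    p_value: float
    n1: int
    n2: int
    paired: bool
    fdr: float = np.nan
    stars: str = ""


def stars_from_fdr(fdr: float) -> str:
    if fdr < 0.001:
        return "***"
    if fdr < 0.01:
        return "**"
    if fdr < 0.05:
        return "*"
    return ""


def _bootstrap_ci(stat_fn, args, n_boot, seed, level=0.95):
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        resampled = [a[rng.integers(0, len(a), len(a))] for a in args]
        reps[i] = stat_fn(*resampled)
    alpha = (1.0 - level) / 2.0
    return tuple(np.quantile(reps, [alpha, 1.0 - alpha]))


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    label: str = "",
    n_boot: int = 10_000,
    seed: int = 0,
    exact_max_n: int = 25,
) -> GroupComparison:
    """Compare two score groups.

    Unpaired: Wilcoxon rank-sum p (exact for groups <= ``exact_max_n``
    without ties, normal approximation with continuity correction
    otherwise), Hodges-Lehmann median difference a-b, percentile-bootstrap
    95% CI.  Paired: per-element differences a-b, their median, bootstrap
    CI, and the Wilcoxon signed-rank p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length groups")
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if len(a) < 3:
            raise ValueError(f"comparison {label!r}: fewer than 3 paired features")
        d = a - b
        est = float(np.median(d))
        if np.all(d == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
        lo, hi = _bootstrap_ci(lambda x: np.median(x), [d], n_boot, seed)
        return GroupComparison(label, est, lo, hi, p, len(a), len(b), True)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"comparison {label!r}: fewer than 3 features in a group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= exact_max_n and not ties) else "asymptotic"
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    est = float(np.median(np.subtract.outer(a, b)))  # Hodges-Lehmann
    lo, hi = _bootstrap_ci(
        lambda x, y: np.median(np.subtract.outer(x, y)), [a, b], n_boot, seed
    )
    return GroupComparison(label, est, lo, hi, min(p, 1.0), len(a), len(b), False)


def adjust_battery(comparisons: list) -> pd.DataFrame:
    """Benjamini-Hochberg FDR across a battery of comparisons + star map."""
    ps = [c.p_value for c in comparisons]
    if ps:
        _, fdr, _, _ = multipletests(ps, method="fdr_bh")
        for c, q in zip(comparisons, fdr):
            c.fdr = float(q)
            c.stars = stars_from_fdr(c.fdr)
    return pd.DataFrame(
        {
            "comparison": [c.label for c in comparisons],
            "estimate": [c.estimate for c in comparisons],
            "ci_low": [c.ci_low for c in comparisons],
            "ci_high": [c.ci_high for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "fdr": [c.fdr for c in comparisons],
            "stars": [c.stars for c in comparisons],
            "n1": [c.n1 for c in comparisons],
            "n2": [c.n2 for c in comparisons],
            "paired": [c.paired for c in comparisons],
        }
    )


def run_battery(
    tables: dict,
    battery: list,
    n_boot: int = 10_000,
    seed: int = 0,
    on_error: str = "raise",
) -> pd.DataFrame:
    """Run a configured list of comparisons and BH-adjust across them.

    ``tables`` maps genotype -> feature score table (columns id, type,
    orientation, score, optionally score_first100 and expr_z).  Each battery
    entry is a dict: feature_type, comparison ('orientation' for HO vs CD
    within a genotype, or 'genotype' paired across two genotypes), genotype
    / genotypes, and optional filters first100 (bool), top_expression
    (fraction).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    comps = []
    for i, spec in enumerate(battery):
        ftype = spec["feature_type"]
        col = "score_first100" if spec.get("first100") else "score"
        try:
            if spec["comparison"] == "orientation":
                t = tables[spec["genotype"]]
                sel = t[t["type"] == ftype]
                if spec.get("top_expression"):
                    keep = top_expression_ids(t, spec["top_expression"])
                    sel = sel[sel["id"].isin(keep)]
                ho = sel.loc[sel["orientation"] == "head_on", col].to_numpy()
                cd = sel.loc[sel["orientation"] == "codirectional", col].to_numpy()
                if min(len(ho), len(cd)) == 0:
                    raise ValueError(f"battery entry {i}: empty group after filter {spec}")
                label = spec.get("label", f"{ftype}:HO-CD:{spec['genotype']}")
                comp = compare_groups(ho, cd, paired=False, label=label,
                                      n_boot=n_boot, seed=seed + i)
            elif spec["comparison"] == "genotype":
                g1, g2 = spec["genotypes"]
                t1, t2 = tables[g1], tables[g2]
                merged = t1.merge(t2, on="id", suffixes=("_1", "_2"))
                merged = merged[merged["type_1"] == ftype]
                if spec.get("top_expression"):
                    keep = top_expression_ids(t1, spec["top_expression"])
                    merged = merged[merged["id"].isin(keep)]
                if merged.empty:
                    raise ValueError(f"battery entry {i}: empty group after filter {spec}")
                label = spec.get("label", f"{ftype}:{g1}-{g2}")
                comp = compare_groups(
                    merged[f"{col}_1"].to_numpy(),
                    merged[f"{col}_2"].to_numpy(),
                    paired=True, label=label, n_boot=n_boot, seed=seed + i,
                )
            else:
                raise ValueError(f"unknown comparison kind {spec['comparison']!r}")
        except ValueError:
            if on_error == "skip":
                warnings.warn(f"battery entry {i} skipped: group too small ({spec})")
                continue
            raise
        comps.append(comp)
    return adjust_battery(comps)


# ---------------------------------------------------------------------------
# Orientation x expression regression
# ---------------------------------------------------------------------------

ORIENTATION_COEFS = ["intercept", "head_on", "expr_z", "head_on:expr_z"]


def fit_orientation_regression(
    table: pd.DataFrame,
    draws: int = 4000,
    seed: int = 0,
    prior_sd: float = 2.0,
) -> GLMFit:
    """Gaussian Bayesian regression of per-CDS hybrid z on orientation,
    expression z, and their interaction.

    ``table`` needs columns score, expr_z, orientation; rows with missing
    values are dropped.  Requires >= 20 complete CDSs.
    """
    t = table.dropna(subset=["score", "expr_z"])
    t = t[t["orientation"].isin(["head_on", "codirectional"])]
    if len(t) < 20:
        raise ValueError(f"need >= 20 CDSs with both scores, have {len(t)}")
    ho = (t["orientation"] == "head_on").to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(t)), ho, t["expr_z"].to_numpy(), ho * t["expr_z"].to_numpy()]
    )
    return sample_glm(
        X,
        t["score"].to_numpy(),
        ORIENTATION_COEFS,
        family="gaussian",
        prior_sd=prior_sd,
        draws=draws,
        seed=seed,
    )
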