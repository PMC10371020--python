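"""Mutation-accumulation (MA) line data model, filtering rules, frequentist
rate statistics, and the Bayesian mutation-rate regression.

MA lines are repeatedly bottlenecked lineages in which mutations accrue
nearly neutrally; rates are events per generation (or per bp*generation).
Event tables use 1-based inclusive genomic coordinates, the convention of
variant tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import EffectPosterior, GLMFit, bayes_factors, sample_glm

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
MUTATION_CLASSES = ("transition", "transversion", "insertion", "deletion")
#: classes modelled in the rate regression (indel pools both indel kinds)
MODEL_CLASSES = ("transition", "transversion", "indel")


def classify_substitution(ref: str, alt: str) -> str:
    """transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion.

    Indels (ref/alt of different length) are classified insertion/deletion.
    Strand-symmetric by construction: complementing both alleles preserves
    the class.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != len(alt):
        return "insertion" if len(alt) > len(ref) else "deletion"
    if len(ref) != 1:
        raise ValueError(f"multi-base substitution {ref}>{alt} not supported")
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref})")
    same_class = (ref in PURINES) == (alt in PURINES)
    return "transition" if same_class else "transversion"


@dataclass
class MALineDataset:
    lines: pd.DataFrame  # id, genotype, generations
    events: pd.DataFrame  # line, position, ref, alt, class
    svs: pd.DataFrame  # line, start, end, type
    intended_alterations: pd.DataFrame  # line, start, end (engineered loci)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.lines["generations"] < 0).any():
            bad = self.lines.loc[self.lines["generations"] < 0, "id"].tolist()
            raise ValueError(f"negative generation counts for lines {bad}")
        ev = self.events
        if len(ev):
            if "class" not in ev.columns or ev["class"].isna().any():
                ev = ev.copy()
                ev["class"] = [
                    classify_substitution(r, a) for r, a in zip(ev["ref"], ev["alt"])
                ]
                self.events = ev
            recomputed = [
                classify_substitution(r, a) for r, a in zip(ev["ref"], ev["alt"])
            ]
            mismatch = ev["class"].to_numpy() != np.array(recomputed)
            if mismatch.any():
                raise ValueError(
                    f"{mismatch.sum()} events have a class inconsistent with ref/alt"
                )

    @property
    def total_generations(self) -> float:
        return float(self.lines["generations"].sum())

    def generations_by_genotype(self) -> pd.Series:
        return self.lines.groupby("genotype")["generations"].sum()

    def subset_lines(self, line_ids) -> "MALineDataset":
        ids = set(line_ids)
        return MALineDataset(
            lines=self.lines[self.lines["id"].isin(ids)].reset_index(drop=True),
            events=self.events[self.events["line"].isin(ids)].reset_index(drop=True),
            svs=self.svs[self.svs["line"].isin(ids)].reset_index(drop=True),
            intended_alterations=self.intended_alterations[
                self.intended_alterations["line"].isin(ids)
            ].reset_index(drop=True),
            flags=dict(self.flags),
        )

    # -- I/O ----------------------------------------------------------------

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.lines.to_csv(os.path.join(outdir, "lines.tsv"), sep="\t", index=False)
        self.events.to_csv(os.path.join(outdir, "events.tsv"), sep="\t", index=False)
        self.svs.to_csv(os.path.join(outdir, "svs.tsv"), sep="\t", index=False)
        self.intended_alterations.to_csv(
            os.path.join(outdir, "intended_alterations.tsv"), sep="\t", index=False
        )

    @classmethod
    def read(cls, outdir) -> "MALineDataset":
        return cls(
            lines=pd.read_csv(os.path.join(outdir, "lines.tsv"), sep="\t"),
            events=pd.read_csv(os.path.join(outdir, "events.tsv"), sep="\t"),
            svs=pd.read_csv(os.path.join(outdir, "svs.tsv"), sep="\t"),
            intended_alterations=pd.read_csv(
                os.path.join(outdir, "intended_alterations.tsv"), sep="\t"
            ),
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_sv_near_alterations(
    dataset: MALineDataset, window: int = 100
) -> tuple[MALineDataset, pd.DataFrame]:
    """Drop SVs within ``window`` bp of a line's engineered alteration.

    An SV is removed iff its interval intersects
    [alteration_start - window, alteration_end + window] with *inclusive*
    endpoints (an SV exactly touching the window boundary is removed).
    Returns the filtered dataset and a report of removals.
    """
    if dataset.intended_alterations.empty:
        raise ValueError("dataset has no intended_alterations table")
    svs = dataset.svs
    removed = np.zeros(len(svs), dtype=bool)
    win_rows = []
    for _, alt in dataset.intended_alterations.iterrows():
        lo, hi = alt["start"] - window, alt["end"] + window
        win_rows.append({"line": alt["line"], "window_start": lo, "window_end": hi})
        hits = (
            (svs["line"] == alt["line"])
            & (svs["end"] >= lo)
            & (svs["start"] <= hi)
        )
        removed |= hits.to_numpy()
    report = svs[removed].copy()
    report["reason"] = "within_window_of_intended_alteration"
    filtered = replace(
        dataset,
        svs=svs[~removed].reset_index(drop=True),
        flags={**dataset.flags, "sv_filter_window_bp": window,
               "sv_filter_windows": pd.DataFrame(win_rows)},
    )
    return filtered, report


def alteration_window(start: int, end: int, window: int = 100) -> tuple[int, int]:
    """Exclusion window (inclusive endpoints) around an engineered locus."""
    return start - window, end + window


def flag_repair_deficient_lines(
    dataset: MALineDataset, guarded_genes: list, exclude: bool = True
) -> tuple[MALineDataset, pd.DataFrame]:
    """Flag (and by default exclude) lines whose SVs hit a guarded gene.

    ``guarded_genes`` is a list of (start, end) intervals, 1-based
    inclusive — e.g. the mismatch-repair gene whose loss would corrupt the
    line's mutation spectrum.
    """
    flagged = set()
    for s, e in guarded_genes:
        hits = dataset.svs[(dataset.svs["end"] >= s) & (dataset.svs["start"] <= e)]
        flagged |= set(hits["line"])
    report = dataset.lines[dataset.lines["id"].isin(flagged)].copy()
    report["reason"] = "sv_overlaps_guarded_gene"
    if exclude and flagged:
        kept = [i for i in dataset.lines["id"] if i not in flagged]
        return dataset.subset_lines(kept), report
    out = replace(dataset, flags={**dataset.flags, "repair_deficient_lines": sorted(flagged)})
    return out, report


# ---------------------------------------------------------------------------
# Frequentist rate statistics
# ---------------------------------------------------------------------------


@dataclass
class RateEstimate:
    events: int
    exposure: float
    rate: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def rate_with_ci(events: int, exposure: float, level: float = 0.95) -> RateEstimate:
    """Poisson rate with exact (Garwood) confidence bounds.

    lower = Gamma(events).ppf(alpha/2) / exposure (0 when events = 0);
    upper = Gamma(events + 1).ppf(1 - alpha/2) / exposure.
    """
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if events < 0 or events != int(events):
        raise ValueError("events must be a non-negative integer")
    events = int(events)
    alpha = 1.0 - level
    lo = 0.0 if events == 0 else stats.gamma.ppf(alpha / 2, events) / exposure
    hi = stats.gamma.ppf(1 - alpha / 2, events + 1) / exposure
    return RateEstimate(events, float(exposure), events / exposure, float(lo), float(hi), level)


def rate_ratio_test(
    x1: int, t1: float, x2: int, t2: float, alternative: str = "greater"
) -> float:
    """Exact conditional test of rate equality between two Poisson processes.

    Conditional on n = x1 + x2, X1 ~ Binomial(n, t1/(t1+t2)) under the
    null.  One-tailed p is P(X1 >= x1) ('greater') or P(X1 <= x1) ('less');
    two-sided sums the probabilities of outcomes no more likely than the
    observed one.
    """
    if min(x1, x2) < 0 or min(t1, t2) <= 0:
        raise ValueError("counts must be >= 0 and exposures > 0")
    if x1 + x2 == 0:
        raise ValueError("both counts are zero; the conditional test is undefined")
    n = x1 + x2
    p = t1 / (t1 + t2)
    return float(stats.binomtest(x1, n, p, alternative=alternative).pvalue)


def genotype_rate_table(
    dataset: MALineDataset, per: str = "generation"
) -> pd.DataFrame:
    """Per-genotype event rates with exact Poisson CIs (events + SVs rows)."""
    gens = dataset.generations_by_genotype()
    line_geno = dataset.lines.set_index("id")["genotype"]
    rows = []
    ev = dataset.events.copy()
    ev["genotype"] = ev["line"].map(line_geno)
    sv = dataset.svs.copy()
    sv["genotype"] = sv["line"].map(line_geno)
    for g, exposure in gens.items():
        for cls in MUTATION_CLASSES:
            k = int(((ev["genotype"] == g) & (ev["class"] == cls)).sum())
            est = rate_with_ci(k, exposure)
            rows.append({"genotype": g, "class": cls, "events": k,
                         "exposure": exposure, "rate": est.rate,
                         "ci_low": est.ci_low, "ci_high": est.ci_high})
        k = int((sv["genotype"] == g).sum())
        est = rate_with_ci(k, exposure)
        rows.append({"genotype": g, "class": "structural_variant", "events": k,
                     "exposure": exposure, "rate": est.rate,
                     "ci_low": est.ci_low, "ci_high": est.ci_high})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian mutation-rate regression
# ---------------------------------------------------------------------------

DEFAULT_TERMS = ("z_rdh", "z_expr", "head_on", "head_on:z_rdh", "head_on:z_expr")


@dataclass
class MutationRegressionFit:
    mclass: str
    fit: GLMFit
    effects: dict  # coef name -> EffectPosterior

    def summary(self) -> pd.DataFrame:
        df = self.fit.summary()
        df["class"] = self.mclass
        df["K"] = [self.effects[c].K if c in self.effects else np.nan for c in df["coef"]]
        df["K0"] = [self.effects[c].K0 if c in self.effects else np.nan for c in df["coef"]]
        df["K_category"] = [
            self.effects[c].K_category if c in self.effects else "" for c in df["coef"]
        ]
        df["K0_category"] = [
            self.effects[c].K0_category if c in self.effects else "" for c in df["coef"]
        ]
        return df


def build_design(
    table: pd.DataFrame, terms=DEFAULT_TERMS, genotypes: list | None = None
) -> tuple[np.ndarray, list]:
    """Design matrix for the per-CDS rate model.

    ``table`` needs one row per (CDS, genotype) with columns genotype,
    z_rdh, z_expr, head_on (0/1) and any extra term columns.  Continuous
    covariates are assumed already standardised.  Genotype dummies are
    relative to the first genotype (reference).
    """
    genotypes = genotypes or list(dict.fromkeys(table["genotype"]))
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for g in genotypes[1:]:
        cols.append((table["genotype"] == g).to_numpy(dtype=float))
        names.append(f"genotype:{g}")
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
        else:
            cols.append(table[term].to_numpy(dtype=float))
        names.append(term)
    return np.column_stack(cols), names


def fit_mutation_regression(
    table: pd.DataFrame,
    mclass: str,
    terms=DEFAULT_TERMS,
    rope_halfwidth: float = 0.05,
    prior_sd: float = 2.0,
    draws: int = 4000,
    seed: int = 0,
) -> MutationRegressionFit:
    """Exposure-offset Poisson regression of per-CDS mutation counts.

    count ~ Poisson(exposure * exp(X beta)) with exposure = CDS length (bp)
    x summed generations, Normal(0, prior_sd^2) coefficient priors, and per
    coefficient an :class:`EffectPosterior` carrying Bayes factors K / K0
    against the ROPE (half-width ``rope_halfwidth`` on the log-rate scale).
    """
    col = f"count_{mclass}"
    if col not in table.columns:
        raise ValueError(f"table lacks column {col}")
    X, names = build_design(table, terms)
    y = table[col].to_numpy(dtype=float)
    offset = np.log(table["exposure"].to_numpy(dtype=float))
    fit = sample_glm(
        X, y, names, family="poisson", offset=offset,
        prior_sd=prior_sd, draws=draws, seed=seed,
    )
    effects = {
        name: bayes_factors(fit.coef_draws(name), prior_sd, rope_halfwidth, name=name)
        for name in names
        if name != "intercept"
    }
    return MutationRegressionFit(mclass, fit, effects)


def counts_by_cds(
    dataset: MALineDataset, cds_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-(CDS, genotype) mutation counts by model class, with exposures.

    ``cds_table`` has one row per CDS: id, start, end (1-based inclusive),
    plus per-genotype covariates merged in by the caller.  Events are
    assigned to a CDS when their position falls inside it.
    """
    line_geno = dataset.lines.set_index("id")["genotype"]
    gens = dataset.generations_by_genotype()
    ev = dataset.events.copy()
    ev["genotype"] = ev["line"].map(line_geno)
    ev["mclass"] = ev["class"].replace({"insertion": "indel", "deletion": "indel"})
    rows = []
    for _, cds in cds_table.iterrows():
        inside = ev[(ev["position"] >= cds["start"]) & (ev["position"] <= cds["end"])]
        for g, total_gen in gens.items():
            sub = inside[inside["genotype"] == g]
            row = {
                "id": cds["id"],
                "genotype": g,
                "length": cds["end"] - cds["start"] + 1,
                "exposure": (cds["end"] - cds["start"] + 1) * total_gen,
            }
            for m in MODEL_CLASSES:
                row[f"count_{m}"] = int((sub["mclass"] == m).sum())
            rows.append(row)
    return pd.DataFrame(rows)
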