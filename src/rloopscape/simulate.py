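"""Synthetic-data generator with planted ground truth for every pipeline
stage: genome annotation with replichore geometry, negative-binomial
pull-down/input counts with planted log2 enrichments, replication coverage
profiles with planted slow-replication intervals, per-gene expression, and
mutation-accumulation lines with planted rate-regression coefficients.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator`` per operation, so a fixed seed reproduces every
output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import StrandedCountMatrix
from .genome import (
    FeatureType,
    GenomeFeature,
    MaskSet,
    Orientation,
    ReplichoreMap,
    classify_all,
    write_annotation,
)
from .trackio import GenomicTrack, make_bins

SPIKE_CONTIG = "spike"


@dataclass
class EnrichmentEffects:
    """Planted log2 enrichment structure.

    Every bin inside a feature gets the feature-type effect; CDS bins
    additionally respond to expression (per-genotype slope), head-on
    orientation, and their interaction — echoing the biology the pipeline
    is meant to resolve (hybrids track transcription, most strongly in the
    R-loop-nuclease deletion).
    """

    feature_effect: dict = field(
        default_factory=lambda: {
            "CDS": 0.5, "UTR5": 1.5, "UTR3": 0.5,
            "ncRNA": 1.0, "rRNA": 2.5, "tRNA": 1.0,
        }
    )
    expression_slope: dict = field(
        default_factory=lambda: {"WT": 0.3, "dRnhB": 0.3, "dRnhC": 0.8}
    )
    orientation_effect: float = 0.2
    interaction_effect: float = -0.3


def default_mutation_coeffs() -> dict:
    """Planted log-linear rate coefficients per mutation class.

    Baseline 3.5e-10 events/bp/generation; genotype, hybrid-z, expression-z
    and orientation terms echo the qualitative pattern under study
    (hybrids raise indel rates; the RER-deficient genotype raises
    transitions; the R-loop-nuclease deletion raises transversions).
    """
    base = float(np.log(3.5e-10))
    return {
        "transition": {
            "intercept": base, "genotype:dRnhB": 1.0, "genotype:dRnhC": 0.4,
            "z_rdh": 0.0, "z_expr": 0.05, "head_on": 0.0,
            "head_on:z_rdh": 0.0, "head_on:z_expr": -0.2,
        },
        "transversion": {
            "intercept": base, "genotype:dRnhB": 0.0, "genotype:dRnhC": 0.7,
            "z_rdh": 0.0, "z_expr": -0.3, "head_on": 0.0,
            "head_on:z_rdh": 0.0, "head_on:z_expr": 0.0,
        },
        "indel": {
            "intercept": base, "genotype:dRnhB": 0.0, "genotype:dRnhC": 0.3,
            "z_rdh": 0.5, "z_expr": -0.25, "head_on": 0.0,
            "head_on:z_rdh": 0.0, "head_on:z_expr": 0.0,
        },
    }


@dataclass
class SimConfig:
    genome_length: int = 200_000
    bin_width: int = 100
    contig: str = "chr"
    oriC_pos: int = 0
    ter_pos: int | None = None  # default genome_length // 2

    n_features: dict = field(
        default_factory=lambda: {"CDS": 120, "ncRNA": 12, "rRNA": 3, "tRNA": 12}
    )
    cds_len_mean: float = 900.0
    cds_len_sd: float = 300.0
    utr5_len: int = 40
    utr3_len: int = 30
    utr3_fraction: float = 0.5
    p_head_on: float = 0.25
    n_rrna_decoys: int = 2  # masked duplicate rRNA copies

    genotypes: tuple = ("WT", "dRnhB", "dRnhC")
    replicates: int = 2
    nb_dispersion: float | None = 1000.0  # None -> Poisson limit
    mean_input_depth: float = 100.0
    extracted_depth: float | None = None  # default: same as input
    library_depth_spread: float = 0.15  # lognormal sd of true size factors
    coverage_log2_amplitude: float = 0.0  # oriC->ter gradient in pull-down input

    spike_length: int = 20_000
    #: constant true enrichment of the spike-in reference.  The default 0
    #: makes the spike contribute identically to input and pull-down
    #: fractions, so genome enrichment scores are absolute; any other value
    #: simply shifts all scores to be relative to the spike reference.
    spike_log2_enrichment: float = 0.0

    expression_mean: float = 5.0  # log2 CPM scale
    expression_sd: float = 2.0
    enrichment_effects: EnrichmentEffects = field(default_factory=EnrichmentEffects)
    #: (genotype, start, end, delta_log2) regions added on both strands
    differential_regions: tuple = (("dRnhC", 150_000, 160_000, 1.5),)

    mutation_coeffs: dict = field(default_factory=default_mutation_coeffs)
    generations_per_line: int = 3700
    n_lines: int = 72  # per genotype
    sv_rate: dict = field(
        default_factory=lambda: {"WT": 2.2e-5, "dRnhB": 2.2e-5, "dRnhC": 6.4e-5}
    )
    sv_len_mean: float = 2000.0
    sv_near_alteration_rate: float = 0.3  # per-line chance of a filterable SV

    wgs_bin_width: int = 1000
    wgs_mean_depth: float = 200.0
    replication_log2_drop: float = 1.0  # oriC -> ter in log2 CPM
    slow_factor: float = 4.0
    #: (genotype, start, end) intervals where the coverage slope steepens
    slow_intervals: tuple = (("dRnhC", 88_000, 98_000),)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.ter_pos is None:
            self.ter_pos = self.genome_length // 2
        if self.genome_length % self.bin_width != 0:
            raise ValueError("genome_length must be divisible by bin_width")
        if self.spike_length % self.bin_width != 0:
            raise ValueError("spike_length must be divisible by bin_width")
        for name in ("oriC_pos", "ter_pos"):
            v = getattr(self, name)
            if not 0 <= v < self.genome_length:
                raise ValueError(f"{name}={v} outside [0, {self.genome_length})")
        if self.oriC_pos == self.ter_pos:
            raise ValueError("oriC_pos and ter_pos must differ")
        if self.mean_input_depth <= 0:
            raise ValueError("mean_input_depth must be positive")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive (or None for Poisson)")

    @property
    def replichore_map(self) -> ReplichoreMap:
        return ReplichoreMap(self.contig, self.genome_length, self.oriC_pos, self.ter_pos)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth aligned 1:1 with the emitted bins and features."""

    bins: pd.DataFrame  # genome bins: contig, start, end
    beta: dict  # (genotype, strand) -> per-bin true log2 enrichment
    features: pd.DataFrame  # id, type, start, end, strand, orientation
    expression: pd.DataFrame  # id, log2_expr, expr_z (CDS-level)
    cds_covariates: pd.DataFrame  # per (CDS, genotype): z_rdh, z_expr, head_on, eta per class
    size_factors: pd.DataFrame | None = None  # library, true_size_factor
    slow_intervals: pd.DataFrame | None = None
    engineered_loci: dict = field(default_factory=dict)  # genotype -> (start, end)
    guarded_interval: tuple | None = None  # mismatch-repair-like locus

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        wide = self.bins.copy()
        for (g, s), v in sorted(self.beta.items()):
            wide[f"beta__{g}__{s}"] = v
        wide.to_csv(os.path.join(outdir, "truth_beta.tsv"), sep="\t", index=False)
        self.features.to_csv(os.path.join(outdir, "truth_features.tsv"), sep="\t", index=False)
        self.expression.to_csv(os.path.join(outdir, "truth_expression.tsv"), sep="\t", index=False)
        self.cds_covariates.to_csv(
            os.path.join(outdir, "truth_cds_covariates.tsv"), sep="\t", index=False
        )
        if self.size_factors is not None:
            self.size_factors.to_csv(
                os.path.join(outdir, "truth_size_factors.tsv"), sep="\t", index=False
            )
        if self.slow_intervals is not None:
            self.slow_intervals.to_csv(
                os.path.join(outdir, "truth_slow_intervals.tsv"), sep="\t", index=False
            )
        extra = {
            "engineered_loci": {
                g: [int(x) for x in v] for g, v in self.engineered_loci.items()
            },
            "guarded_interval": [int(x) for x in self.guarded_interval]
            if self.guarded_interval else None,
        }
        with open(os.path.join(outdir, "truth_extra.json"), "w") as fh:
            json.dump(extra, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, outdir) -> "GroundTruth":
        wide = pd.read_csv(os.path.join(outdir, "truth_beta.tsv"), sep="\t")
        beta_cols = [c for c in wide.columns if c.startswith("beta__")]
        beta = {}
        for c in beta_cols:
            _, g, s = c.split("__")
            beta[(g, s)] = wide[c].to_numpy()
        sf_path = os.path.join(outdir, "truth_size_factors.tsv")
        slow_path = os.path.join(outdir, "truth_slow_intervals.tsv")
        with open(os.path.join(outdir, "truth_extra.json")) as fh:
            extra = json.load(fh)
        return cls(
            bins=wide[["contig", "start", "end"]],
            beta=beta,
            features=pd.read_csv(os.path.join(outdir, "truth_features.tsv"), sep="\t"),
            expression=pd.read_csv(os.path.join(outdir, "truth_expression.tsv"), sep="\t"),
            cds_covariates=pd.read_csv(
                os.path.join(outdir, "truth_cds_covariates.tsv"), sep="\t"
            ),
            size_factors=pd.read_csv(sf_path, sep="\t") if os.path.exists(sf_path) else None,
            slow_intervals=pd.read_csv(slow_path, sep="\t") if os.path.exists(slow_path) else None,
            engineered_loci={g: tuple(v) for g, v in extra["engineered_loci"].items()},
            guarded_interval=tuple(extra["guarded_interval"])
            if extra["guarded_interval"] else None,
        )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

_OTHER_LEN = {"ncRNA": 200, "rRNA": 1200, "tRNA": 80}


def simulate_genome_annotation(cfg: SimConfig):
    """Place non-overlapping features of each type on both strands.

    Each CDS gets an adjacent 5'-UTR (and a 3'-UTR for a configurable
    fraction); strand is drawn so a feature is head-on with probability
    ``p_head_on`` given the replichore arc of its midpoint.  ``n_rrna_decoys``
    extra rRNA copies are emitted and masked, emulating analysis against a
    single consensus with duplicate chromosomal copies excluded.

    Returns (features, replichore_map, mask_set).  Raises when the requested
    features cannot be placed without overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    rep = cfg.replichore_map

    units = []  # list of (kind, parts) with parts = [(type, length), ...]
    for i in range(cfg.n_features.get("CDS", 0)):
        cds_len = int(np.clip(rng.normal(cfg.cds_len_mean, cfg.cds_len_sd), 150, None))
        parts = [(FeatureType.UTR5, cfg.utr5_len), (FeatureType.CDS, cds_len)]
        if rng.random() < cfg.utr3_fraction:
            parts.append((FeatureType.UTR3, cfg.utr3_len))
        units.append((f"cds_{i:04d}", parts))
    for ftype in ("ncRNA", "rRNA", "tRNA"):
        for i in range(cfg.n_features.get(ftype, 0)):
            length = int(_OTHER_LEN[ftype] * np.exp(rng.normal(0, 0.1)))
            units.append((f"{ftype.lower()}_{i:04d}", [(FeatureType(ftype), length)]))
    for i in range(cfg.n_rrna_decoys):
        length = int(_OTHER_LEN["rRNA"] * np.exp(rng.normal(0, 0.1)))
        units.append((f"rrna_copy_{i:04d}", [(FeatureType.rRNA, length)]))

    total = sum(length for _, parts in units for _, length in parts)
    if total > 0.95 * cfg.genome_length:
        raise ValueError(
            f"cannot place features without overlap: requested {total} bp of "
            f"features on a {cfg.genome_length} bp genome (need <= 95% occupancy)"
        )

    order = rng.permutation(len(units))
    gaps = rng.multinomial(
        cfg.genome_length - total, np.full(len(units) + 1, 1.0 / (len(units) + 1))
    )
    features = []
    cursor = 0
    for slot, u in enumerate(order):
        cursor += gaps[slot]
        uid, parts = units[u]
        unit_len = sum(length for _, length in parts)
        mid = cursor + unit_len / 2.0
        fork = int(rep.fork_direction(mid))
        head_on = rng.random() < cfg.p_head_on
        gene_dir = -fork if head_on else fork
        strand = "+" if gene_dir == 1 else "-"
        laid = parts if strand == "+" else [
            (t, L) for t, L in reversed(parts)
        ]
        sub_cursor = cursor
        for ftype, length in laid:
            suffix = "" if len(parts) == 1 else f"_{ftype.value.lower()}"
            fid = uid if len(parts) == 1 else (
                uid if ftype == FeatureType.CDS else f"{uid}{suffix}"
            )
            features.append(
                GenomeFeature(fid, ftype, cfg.contig, sub_cursor, sub_cursor + length, strand)
            )
            sub_cursor += length
        cursor += unit_len
    features = classify_all(features, rep)
    mask = MaskSet(
        [(cfg.contig, f.start, f.end) for f in features if f.id.startswith("rrna_copy_")]
    )
    return features, rep, mask


# ---------------------------------------------------------------------------
# Expression and planted enrichment truth
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimConfig, features) -> pd.DataFrame:
    """Per-gene log2 expression with its robust z (one value per gene)."""
    from .signal import robust_z

    rng = np.random.default_rng(cfg.seed + 1)
    genes = [f for f in features if f.type not in (FeatureType.UTR5, FeatureType.UTR3)]
    log2_expr = rng.normal(cfg.expression_mean, cfg.expression_sd, len(genes))
    df = pd.DataFrame(
        {
            "id": [g.id for g in genes],
            "type": [g.type.value for g in genes],
            "log2_expr": log2_expr,
        }
    )
    df["expr_z"] = (
        robust_z(df["log2_expr"].to_numpy()) if len(df) >= 2 else 0.0
    )
    return df


def _bin_indices(starts, ends, f_start, f_end):
    mids = 0.5 * (starts + ends)
    return np.flatnonzero((mids >= f_start) & (mids < f_end))


def build_ground_truth(cfg: SimConfig, features, expression: pd.DataFrame) -> GroundTruth:
    """Planted per-bin log2 enrichment and per-CDS regression covariates."""
    starts, ends = make_bins(cfg.contig, cfg.genome_length, cfg.bin_width)
    bins = pd.DataFrame({"contig": cfg.contig, "start": starts, "end": ends})
    eff = cfg.enrichment_effects
    expr_z = expression.set_index("id")["expr_z"]

    beta = {}
    for g in cfg.genotypes:
        for strand in ("+", "-"):
            beta[(g, strand)] = np.zeros(len(starts))
    for f in features:
        base = eff.feature_effect.get(f.type.value, 0.0)
        parent = f.id.split("_utr")[0] if f.type in (FeatureType.UTR5, FeatureType.UTR3) else f.id
        z = float(expr_z.get(parent, 0.0))
        ho = 1.0 if f.orientation == Orientation.head_on else 0.0
        idx = _bin_indices(starts, ends, f.start, f.end)
        for g in cfg.genotypes:
            if f.type == FeatureType.CDS:
                val = (
                    base
                    + eff.expression_slope.get(g, 0.0) * z
                    + eff.orientation_effect * ho
                    + eff.interaction_effect * ho * z
                )
            else:
                val = base
            beta[(g, f.strand)][idx] += val
    for g, lo, hi, delta in cfg.differential_regions:
        if g not in cfg.genotypes:
            continue
        idx = _bin_indices(starts, ends, lo, hi)
        for strand in ("+", "-"):
            beta[(g, strand)][idx] += delta

    # per-CDS covariates and planted regression linear predictors
    cds = [f for f in features if f.type == FeatureType.CDS]
    rows = []
    for f in cds:
        z_e = float(expr_z.get(f.id, 0.0))
        ho = 1.0 if f.orientation == Orientation.head_on else 0.0
        # hybrid z truth: genotype-averaged planted enrichment within the CDS,
        # standardised downstream; here keep the raw planted mean per genotype
        for g in cfg.genotypes:
            idx = _bin_indices(starts, ends, f.start, f.end)
            z_r = float(np.mean(beta[(g, f.strand)][idx])) if idx.size else 0.0
            row = {
                "id": f.id, "genotype": g, "start": f.start + 1, "end": f.end,
                "length": f.length, "z_expr": z_e, "head_on": ho, "raw_rdh": z_r,
            }
            rows.append(row)
    cov = pd.DataFrame(
        rows,
        columns=["id", "genotype", "start", "end", "length",
                 "z_expr", "head_on", "raw_rdh"],
    ).astype({"z_expr": float, "head_on": float, "raw_rdh": float})
    # standardise the hybrid covariate per genotype (as the pipeline does)
    from .signal import robust_z

    cov["z_rdh"] = 0.0
    for g in cfg.genotypes:
        sel = cov["genotype"] == g
        if sel.sum() >= 2:
            from .signal import ScaleError

            try:
                cov.loc[sel, "z_rdh"] = robust_z(cov.loc[sel, "raw_rdh"].to_numpy())
            except ScaleError:  # all-zero planted enrichment
                cov.loc[sel, "z_rdh"] = 0.0
    for mclass, coeffs in cfg.mutation_coeffs.items():
        eta = np.full(len(cov), coeffs["intercept"])
        for g in cfg.genotypes:
            key = f"genotype:{g}"
            if key in coeffs:
                eta += np.where(cov["genotype"] == g, coeffs[key], 0.0)
        for term in ("z_rdh", "z_expr", "head_on"):
            eta += coeffs.get(term, 0.0) * cov[term].to_numpy()
        eta += coeffs.get("head_on:z_rdh", 0.0) * (cov["head_on"] * cov["z_rdh"]).to_numpy()
        eta += coeffs.get("head_on:z_expr", 0.0) * (cov["head_on"] * cov["z_expr"]).to_numpy()
        cov[f"eta_{mclass}"] = eta

    # engineered loci: one designated CDS per deletion genotype; one guarded
    # (mismatch-repair-like) CDS whose SV hits disqualify a line
    engineered = {}
    cds_sorted = sorted(cds, key=lambda f: f.start)
    for k, g in enumerate(g for g in cfg.genotypes if g != "WT"):
        f = cds_sorted[(k * 7 + 3) % len(cds_sorted)]
        engineered[g] = (f.start + 1, f.end)  # 1-based inclusive
    guarded = None
    if len(cds_sorted) > 10:
        f = cds_sorted[len(cds_sorted) // 2]
        guarded = (f.start + 1, f.end)

    slow = pd.DataFrame(
        [{"genotype": g, "start": lo, "end": hi} for g, lo, hi in cfg.slow_intervals],
        columns=["genotype", "start", "end"],
    )
    from .genome import features_frame

    return GroundTruth(
        bins=bins,
        beta=beta,
        features=features_frame(features),
        expression=expression,
        cds_covariates=cov,
        slow_intervals=slow,
        engineered_loci=engineered,
        guarded_interval=guarded,
    )


# ---------------------------------------------------------------------------
# Sequencing counts
# ---------------------------------------------------------------------------


def _nb_draw(rng, mu, phi):
    mu = np.asarray(mu, dtype=float)
    if phi is None or np.isinf(phi):
        return rng.poisson(mu)
    return rng.negative_binomial(phi, phi / (phi + mu))


def simulate_counts(cfg: SimConfig, truth: GroundTruth) -> StrandedCountMatrix:
    """Input and extracted libraries per genotype/replicate/strand.

    input ~ NB(depth * profile * sf, phi); extracted ~ NB(input mean *
    2^beta * sf, phi).  Spike-in bins live on a separate contig with
    constant true enrichment; rRNA-decoy bins carry the analysis mask.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    rep = cfg.replichore_map
    starts = truth.bins["start"].to_numpy()
    ends = truth.bins["end"].to_numpy()
    n_genome = len(starts)
    mids = 0.5 * (starts + ends)

    if cfg.coverage_log2_amplitude > 0:
        dist = rep.fork_distance(mids)
        prof = 2.0 ** (-cfg.coverage_log2_amplitude * dist / dist.max())
        profile = prof / prof.mean()
    else:
        profile = np.ones(n_genome)

    s_starts, s_ends = make_bins(SPIKE_CONTIG, cfg.spike_length, cfg.bin_width)
    bins = pd.concat(
        [
            truth.bins,
            pd.DataFrame({"contig": SPIKE_CONTIG, "start": s_starts, "end": s_ends}),
        ],
        ignore_index=True,
    )
    spike_mask = np.zeros(len(bins), dtype=bool)
    spike_mask[n_genome:] = True

    libraries = []
    for g in cfg.genotypes:
        for r in range(1, cfg.replicates + 1):
            libraries.append((f"{g}_input_rep{r}", g, r, "input", "."))
            for strand in ("+", "-"):
                tag = "fwd" if strand == "+" else "rev"
                libraries.append((f"{g}_extracted_rep{r}_{tag}", g, r, "extracted", strand))
    lib_df = pd.DataFrame(
        libraries, columns=["library", "genotype", "replicate", "sample_type", "strand"]
    )
    true_sf = np.exp(rng.normal(0.0, cfg.library_depth_spread, len(lib_df)))

    ext_depth = cfg.extracted_depth or cfg.mean_input_depth
    counts = np.zeros((len(bins), len(lib_df)), dtype=np.int64)
    for j, row in lib_df.iterrows():
        sf = true_sf[j]
        if row["sample_type"] == "input":
            mu_genome = cfg.mean_input_depth * profile * sf
            mu_spike = np.full(len(s_starts), cfg.mean_input_depth * sf)
        else:
            b = truth.beta[(row["genotype"], row["strand"])]
            mu_genome = ext_depth * profile * 2.0**b * sf
            mu_spike = np.full(
                len(s_starts), ext_depth * 2.0**cfg.spike_log2_enrichment * sf
            )
        counts[:n_genome, j] = _nb_draw(rng, mu_genome, cfg.nb_dispersion)
        counts[n_genome:, j] = _nb_draw(rng, mu_spike, cfg.nb_dispersion)

    mask = np.zeros(len(bins), dtype=bool)
    decoys = truth.features[truth.features["id"].astype(str).str.startswith("rrna_copy_")]
    ms = MaskSet([(cfg.contig, r["start"], r["end"]) for _, r in decoys.iterrows()])
    mask[:n_genome] = ms.mask_bins(cfg.contig, starts, ends)

    truth.size_factors = pd.DataFrame(
        {"library": lib_df["library"], "true_size_factor": true_sf}
    )
    return StrandedCountMatrix(
        bins=bins, libraries=lib_df, counts=counts,
        size_factors=None, spike_mask=spike_mask, mask=mask,
    )


def simulate_replication_coverage(
    cfg: SimConfig, genotype: str, seed_offset: int = 3
) -> tuple[GenomicTrack, pd.DataFrame]:
    """Binned WGS coverage with a piecewise-linear log2 profile.

    Coverage declines linearly in log2 space from oriC to ter along each
    replichore (total drop ``replication_log2_drop``); inside a planted
    slow interval for ``genotype`` the local slope steepens by
    ``slow_factor``.  Returns the counts track and the planted intervals.
    """
    import zlib

    rng = np.random.default_rng(
        cfg.seed + seed_offset + zlib.crc32(genotype.encode()) % 1000
    )
    rep = cfg.replichore_map
    starts, ends = make_bins(cfg.contig, cfg.genome_length, cfg.wgs_bin_width)
    mids = 0.5 * (starts + ends)
    dist = rep.fork_distance(mids)
    max_dist = dist.max()
    base_slope = cfg.replication_log2_drop / max_dist  # log2 units per bp

    slow = [iv for iv in cfg.slow_intervals if iv[0] == genotype]
    log2rel = -base_slope * dist
    for _, lo, hi in slow:
        inside = (mids >= lo) & (mids < hi)
        if not inside.any():
            continue
        # extra drop accrues through the interval, then persists downstream
        # on the same replichore
        extra_per_bp = base_slope * (cfg.slow_factor - 1.0)
        dirn = int(rep.fork_direction(0.5 * (lo + hi)))
        depth_into = np.clip(mids - lo if dirn == 1 else hi - mids, 0, hi - lo)
        same_arc = rep.fork_direction(mids) == dirn
        downstream = same_arc & (dist > dist[inside].max()) & ~inside
        log2rel = log2rel - extra_per_bp * np.where(inside, depth_into, 0.0)
        log2rel = log2rel - extra_per_bp * (hi - lo) * np.where(downstream, 1.0, 0.0)
    relative = 2.0**log2rel
    mu = cfg.wgs_mean_depth * relative / relative.mean()
    values = _nb_draw(rng, mu, cfg.nb_dispersion).astype(float)
    track = GenomicTrack(cfg.contig, starts, ends, values, {"genotype": genotype})
    planted = pd.DataFrame([{"genotype": g, "start": lo, "end": hi} for g, lo, hi in slow])
    return track, planted


# ---------------------------------------------------------------------------
# MA lines
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = np.array(list("ACGT"))


def simulate_ma_lines(cfg: SimConfig, truth: GroundTruth) -> "MALineDataset":
    """Mutation-accumulation lines with planted Poisson rate structure.

    Per CDS, genotype, and class: count ~ Poisson(length * total
    generations * exp(planted linear predictor)); events land uniformly in
    the CDS and are split across lines in proportion to their generations.
    SVs arrive at the planted per-genotype rate, plus filterable SVs near
    each line's engineered locus at ``sv_near_alteration_rate``.
    """
    from .mutation import MALineDataset

    rng = np.random.default_rng(cfg.seed + 4)
    line_rows = []
    for g in cfg.genotypes:
        for i in range(cfg.n_lines):
            line_rows.append(
                {"id": f"{g}_L{i:03d}", "genotype": g, "generations": cfg.generations_per_line}
            )
    lines = pd.DataFrame(line_rows)

    ev_rows = []
    cov = truth.cds_covariates
    for g in cfg.genotypes:
        sub = cov[cov["genotype"] == g]
        g_lines = lines[lines["genotype"] == g]
        total_gens = g_lines["generations"].sum()
        if total_gens == 0:
            continue
        probs = (g_lines["generations"] / total_gens).to_numpy()
        ids = g_lines["id"].to_numpy()
        for mclass in ("transition", "transversion", "indel"):
            lam = sub["length"].to_numpy() * total_gens * np.exp(
                sub[f"eta_{mclass}"].to_numpy()
            )
            ks = rng.poisson(lam)
            for (_, cds), k in zip(sub.iterrows(), ks):
                if k == 0:
                    continue
                pos = rng.integers(cds["start"], cds["end"] + 1, k)
                line_of = ids[rng.choice(len(ids), size=k, p=probs)]
                for p, ln in zip(pos, line_of):
                    ref = str(rng.choice(_BASES))
                    if mclass == "transition":
                        alt = _TRANSITION[ref]
                        cls = "transition"
                    elif mclass == "transversion":
                        alt = str(rng.choice(list(_TRANSVERSIONS[ref])))
                        cls = "transversion"
                    else:
                        ins = str(rng.choice(_BASES))
                        if rng.random() < 0.5:
                            ref, alt, cls = ref, ref + ins, "insertion"
                        else:
                            ref, alt, cls = ref + ins, ref, "deletion"
                    ev_rows.append(
                        {"line": ln, "position": int(p), "ref": ref, "alt": alt, "class": cls}
                    )
    events = pd.DataFrame(ev_rows, columns=["line", "position", "ref", "alt", "class"])

    sv_rows, alt_rows = [], []
    for _, line in lines.iterrows():
        g = line["genotype"]
        k = rng.poisson(cfg.sv_rate.get(g, 0.0) * line["generations"])
        for _ in range(k):
            length = max(50, int(rng.exponential(cfg.sv_len_mean)))
            start = int(rng.integers(1, cfg.genome_length - length))
            sv_rows.append(
                {
                    "line": line["id"], "start": start, "end": start + length,
                    "type": str(rng.choice(["deletion", "inversion"])),
                }
            )
        if g in truth.engineered_loci:
            lo, hi = truth.engineered_loci[g]
            alt_rows.append({"line": line["id"], "start": lo, "end": hi})
            if rng.random() < cfg.sv_near_alteration_rate:
                # breakpoint artefact adjacent to the engineered deletion
                start = int(lo - rng.integers(0, 90))
                sv_rows.append(
                    {"line": line["id"], "start": start, "end": int(lo + 10),
                     "type": "deletion"}
                )
    svs = pd.DataFrame(sv_rows, columns=["line", "start", "end", "type"])
    alterations = pd.DataFrame(alt_rows, columns=["line", "start", "end"])
    return MALineDataset(
        lines=lines, events=events, svs=svs, intended_alterations=alterations
    )


# ---------------------------------------------------------------------------
# Regression-recovery tables (bypassing the genome for calibration studies)
# ---------------------------------------------------------------------------


def simulate_regression_table(
    n_cds: int,
    coeffs: dict,
    genotypes: tuple = ("WT",),
    mean_count: float = 2.0,
    covariate_corr: float = 0.0,
    p_head_on: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct per-CDS count table from planted regression coefficients.

    Builds standard-normal z_rdh / z_expr covariates (correlated at
    ``covariate_corr``), Bernoulli head_on labels, a common exposure chosen
    so the *baseline* expected count per CDS is ``mean_count``, and Poisson
    counts for each class with a coefficient dict (same structure as
    ``SimConfig.mutation_coeffs`` but the intercept is ignored and set from
    ``mean_count``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        z = rng.multivariate_normal(
            [0, 0], [[1.0, covariate_corr], [covariate_corr, 1.0]], size=n_cds
        )
        ho = (rng.random(n_cds) < p_head_on).astype(float)
        exposure = np.full(n_cds, 1.0)
        df = pd.DataFrame(
            {
                "id": [f"cds_{g}_{i:05d}" for i in range(n_cds)],
                "genotype": g,
                "z_rdh": z[:, 0],
                "z_expr": z[:, 1],
                "head_on": ho,
                "exposure": exposure * mean_count,
            }
        )
        for mclass, cf in coeffs.items():
            eta = np.zeros(n_cds)
            eta += cf.get(f"genotype:{g}", 0.0)
            for term in ("z_rdh", "z_expr", "head_on"):
                eta += cf.get(term, 0.0) * df[term].to_numpy()
            eta += cf.get("head_on:z_rdh", 0.0) * (df["head_on"] * df["z_rdh"]).to_numpy()
            eta += cf.get("head_on:z_expr", 0.0) * (df["head_on"] * df["z_expr"]).to_numpy()
            df[f"count_{mclass}"] = rng.poisson(df["exposure"].to_numpy() * np.exp(eta))
            df[f"eta_{mclass}"] = eta
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Full-output writer
# ---------------------------------------------------------------------------


def write_simulation(cfg: SimConfig, outdir: str) -> dict:
    """Run every generator and write all pipeline inputs under ``outdir``.

    Writes FASTA (synthetic genome sequence), GFF3 annotation, mask BED,
    per-library bedGraphs, expression TSV, MA-line TSVs, WGS coverage
    bedGraphs, ground-truth TSVs, and a JSON config echo.  Returns the
    in-memory objects keyed by stage.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    os.makedirs(outdir, exist_ok=True)
    features, rep, mask = simulate_genome_annotation(cfg)
    expression = simulate_expression(cfg, features)
    truth = build_ground_truth(cfg, features, expression)
    counts = simulate_counts(cfg, truth)
    ma = simulate_ma_lines(cfg, truth)

    rng = np.random.default_rng(cfg.seed + 5)
    seq = "".join(rng.choice(_BASES, cfg.genome_length))
    spike_seq = "".join(rng.choice(_BASES, cfg.spike_length))
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=cfg.contig, description="synthetic genome"),
            SeqRecord(Seq(spike_seq), id=SPIKE_CONTIG, description="synthetic spike-in"),
        ],
        os.path.join(outdir, "genome.fasta"),
        "fasta",
    )
    write_annotation(features, os.path.join(outdir, "annotation.gff3"), "GFF3")
    mask.write_bed(os.path.join(outdir, "mask.bed"))
    counts.write(os.path.join(outdir, "counts"))
    expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
    ma.write(os.path.join(outdir, "ma_lines"))
    coverage = {}
    for g in cfg.genotypes:
        track, _ = simulate_replication_coverage(cfg, g)
        coverage[g] = track
        df = track.to_frame()
        df.to_csv(
            os.path.join(outdir, f"wgs_coverage_{g}.bedgraph"),
            sep="\t", header=False, index=False,
        )
    truth.write(os.path.join(outdir, "truth"))
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        fh.write(cfg.to_json())
    with open(os.path.join(outdir, "replichore.json"), "w") as fh:
        json.dump(
            {"contig": rep.contig, "length": rep.length,
             "oriC_pos": rep.oriC_pos, "ter_pos": rep.ter_pos,
             "circular": rep.circular},
            fh, indent=2,
        )
    return {
        "features": features, "replichore": rep, "mask": mask, "truth": truth,
        "counts": counts, "expression": expression, "ma": ma, "coverage": coverage,
    }
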