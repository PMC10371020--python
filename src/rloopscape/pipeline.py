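"""End-to-end orchestration: simulate -> normalise -> fit enrichment ->
tracks -> feature statistics -> MA rates -> mutation model -> manifest.

Every stochastic stage takes an explicit seed derived from the run seed;
re-running with an identical config reproduces identical file digests for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .counts import size_factors_from_spike
from .enrich import EnrichmentOptions, contrast, fit_all_enrichment
from .featstats import aggregate_features, fit_orientation_regression, run_battery
from .genome import FeatureType
from .signal import log2_cpm, replication_slope_z
from .mutation import (
    fit_mutation_regression,
    filter_sv_near_alterations,
    flag_repair_deficient_lines,
    genotype_rate_table,
    rate_ratio_test,
)
from .simulate import SimConfig, write_simulation
from .trackio import write_bedgraph

log = logging.getLogger("rloopscape")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULT_PIPELINE = {
    "reference_genotype": "WT",
    "engine": "vi",
    "draws": 500,
    "rolling_median_bp": 10_000,
    "contrast_median_bp": 500,
    "slope_smooth_bp": 10_000,
    "slope_window_bp": 10_000,
    "first_bp": 100,
    "mutation_draws": 1000,
    "rope_halfwidth": 0.05,
    "n_boot": 2000,
}

_ALLOWED_KEYS = set(DEFAULT_PIPELINE) | {"sim", "seed"}


def validate_config(config: dict) -> dict:
    bad = sorted(set(config) - _ALLOWED_KEYS)
    if bad:
        raise ValueError(f"unknown pipeline config keys: {bad}")
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    bad_sim = sorted(set(config.get("sim", {})) - sim_fields)
    if bad_sim:
        raise ValueError(f"unknown sim config keys: {bad_sim}")
    merged = dict(DEFAULT_PIPELINE)
    merged.update({k: v for k, v in config.items() if k != "sim"})
    merged["sim"] = dict(config.get("sim", {}))
    return merged


def run_pipeline(config: dict, out_dir: str, seed: int | None = None) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    cfgd = validate_config(config)
    seed = int(seed if seed is not None else cfgd.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in cfgd.items()}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "log2_enrichment_base": 2,
        "stages": {},
        "files": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {"started": time.time()}
        return time.time()

    def done(name, t0):
        manifest["stages"][name]["seconds"] = round(time.time() - t0, 3)

    # -- simulate ----------------------------------------------------------
    t0 = stage("simulate")
    sim_cfg = SimConfig(**{**cfgd["sim"], "seed": seed})
    sim_dir = os.path.join(out_dir, "sim")
    sim = write_simulation(sim_cfg, sim_dir)
    done("simulate", t0)

    counts, truth = sim["counts"], sim["truth"]
    features = sim["features"]

    # -- normalisation -----------------------------------------------------
    t0 = stage("size_factors")
    counts.size_factors = size_factors_from_spike(counts)
    sf = counts.libraries.copy()
    sf["size_factor"] = counts.size_factors
    sf_path = os.path.join(out_dir, "size_factors.tsv")
    sf.to_csv(sf_path, sep="\t", index=False)
    done("size_factors", t0)

    # -- enrichment --------------------------------------------------------
    t0 = stage("fit_enrichment")
    opts = EnrichmentOptions(engine=cfgd["engine"], draws=cfgd["draws"], seed=seed + 10)
    posteriors = fit_all_enrichment(counts, opts)
    track_dir = os.path.join(out_dir, "tracks")
    os.makedirs(track_dir, exist_ok=True)
    z_tracks = {}
    summaries = []
    for (g, s), post in posteriors.items():
        tag = f"{g}_{'fwd' if s == '+' else 'rev'}"
        write_bedgraph(post.mean_track(), os.path.join(track_dir, f"enrichment_{tag}_mean.bedgraph"))
        zt = post.z_track()
        z_tracks[(g, s)] = zt
        write_bedgraph(zt, os.path.join(track_dir, f"enrichment_{tag}_z.bedgraph"))
        from .signal import rolling_median_track

        smooth = rolling_median_track(zt, cfgd["rolling_median_bp"])
        write_bedgraph(
            smooth, os.path.join(track_dir, f"enrichment_{tag}_z_smoothed.bedgraph")
        )
        summaries.append(post.summary_frame())
    pd.concat(summaries).to_csv(
        os.path.join(out_dir, "enrichment_summary.tsv"), sep="\t", index=False
    )
    done("fit_enrichment", t0)

    # -- contrasts ---------------------------------------------------------
    t0 = stage("contrasts")
    ref = cfgd["reference_genotype"]
    from .signal import rolling_median_track

    for (g, s), post in posteriors.items():
        if g == ref:
            continue
        ct = contrast(post, posteriors[(ref, s)])
        zt = ct.z_track()
        sm = rolling_median_track(zt, cfgd["contrast_median_bp"])
        tag = f"{g}_vs_{ref}_{'fwd' if s == '+' else 'rev'}"
        write_bedgraph(sm, os.path.join(track_dir, f"contrast_{tag}_z.bedgraph"))
    done("contrasts", t0)

    # -- replication profiling --------------------------------------------
    t0 = stage("replication")
    rep = sim["replichore"]
    for g, cov_track in sim["coverage"].items():
        cov = log2_cpm(cov_track)
        write_bedgraph(cov.track, os.path.join(track_dir, f"coverage_log2cpm_{g}.bedgraph"))
        slope_z = replication_slope_z(
            cov, rep, smooth_bp=cfgd["slope_smooth_bp"], slope_bp=cfgd["slope_window_bp"]
        )
        write_bedgraph(slope_z, os.path.join(track_dir, f"replication_slope_z_{g}.bedgraph"))
    done("replication", t0)

    # -- feature statistics ------------------------------------------------
    t0 = stage("feature_stats")
    expr = sim["expression"].set_index("id")
    mask_flags = counts.mask[counts.genome_bins()]
    tables = {}
    for g in counts.genotypes:
        tr = {s: z_tracks[(g, s)] for s in ("+", "-")}
        table = aggregate_features(tr, features, mask_flags)
        t100 = aggregate_features(tr, features, mask_flags, first_bp=cfgd["first_bp"])
        table["score_first100"] = t100["score"]
        table["expr_z"] = table["id"].map(expr["expr_z"])
        tables[g] = table
        table.to_csv(os.path.join(out_dir, f"feature_scores_{g}.tsv"), sep="\t", index=False)
    battery = []
    genos = counts.genotypes
    for g in genos:
        battery.append({"feature_type": "CDS", "comparison": "orientation", "genotype": g})
        battery.append({"feature_type": "CDS", "comparison": "orientation", "genotype": g,
                        "first100": True})
        battery.append({"feature_type": "ncRNA", "comparison": "orientation", "genotype": g})
        if g != ref:
            for ftype in ("CDS", "UTR5"):
                battery.append({"feature_type": ftype, "comparison": "genotype",
                                "genotypes": (g, ref)})
            battery.append({"feature_type": "CDS", "comparison": "genotype",
                            "genotypes": (g, ref), "top_expression": 0.2})
    bat = run_battery(tables, battery, n_boot=cfgd["n_boot"], seed=seed + 20,
                      on_error="skip")
    bat.to_csv(os.path.join(out_dir, "comparisons.tsv"), sep="\t", index=False)
    reg_rows = []
    for g in genos:
        cds = tables[g][tables[g]["type"] == FeatureType.CDS.value]
        fit = fit_orientation_regression(cds, draws=cfgd["mutation_draws"], seed=seed + 30)
        s = fit.summary()
        s["genotype"] = g
        reg_rows.append(s)
    pd.concat(reg_rows).to_csv(
        os.path.join(out_dir, "orientation_regression.tsv"), sep="\t", index=False
    )
    done("feature_stats", t0)

    # -- MA rates ----------------------------------------------------------
    t0 = stage("ma_rates")
    ma = sim["ma"]
    ma, sv_report = filter_sv_near_alterations(ma)
    sv_report.to_csv(os.path.join(out_dir, "sv_removals.tsv"), sep="\t", index=False)
    guarded = [truth.guarded_interval] if truth.guarded_interval else []
    ma, line_report = flag_repair_deficient_lines(ma, guarded)
    line_report.to_csv(os.path.join(out_dir, "excluded_lines.tsv"), sep="\t", index=False)
    rates = genotype_rate_table(ma)
    # one-tailed rate-ratio tests vs the reference genotype
    gens = ma.generations_by_genotype()
    pvals = []
    for _, row in rates.iterrows():
        if row["genotype"] == ref:
            pvals.append(np.nan)
            continue
        ref_row = rates[(rates["genotype"] == ref) & (rates["class"] == row["class"])]
        if ref_row.empty or row["events"] + int(ref_row["events"].iloc[0]) == 0:
            pvals.append(np.nan)
            continue
        pvals.append(
            rate_ratio_test(
                int(row["events"]), gens[row["genotype"]],
                int(ref_row["events"].iloc[0]), gens[ref],
                alternative="greater",
            )
        )
    rates["p_vs_reference"] = pvals
    rates.to_csv(os.path.join(out_dir, "ma_rates.tsv"), sep="\t", index=False)
    done("ma_rates", t0)

    # -- mutation model ----------------------------------------------------
    t0 = stage("mutation_model")
    cov = truth.cds_covariates.copy()
    # measured per-CDS counts from the surviving lines
    from .mutation import counts_by_cds

    cds_tab = cov[cov["genotype"] == genos[0]][["id", "start", "end"]]
    counted = counts_by_cds(ma, cds_tab)
    table = counted.merge(
        cov[["id", "genotype", "z_rdh", "z_expr", "head_on"]], on=["id", "genotype"]
    )
    model_rows = []
    for mclass in ("transition", "transversion", "indel"):
        fit = fit_mutation_regression(
            table, mclass,
            rope_halfwidth=cfgd["rope_halfwidth"],
            draws=cfgd["mutation_draws"], seed=seed + 40,
        )
        model_rows.append(fit.summary())
    pd.concat(model_rows).to_csv(
        os.path.join(out_dir, "mutation_model.tsv"), sep="\t", index=False
    )
    done("mutation_model", t0)

    # -- manifest ----------------------------------------------------------
    for root, _, files in os.walk(out_dir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            p = os.path.join(root, f)
            manifest["files"][os.path.relpath(p, out_dir)] = _sha256(p)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
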