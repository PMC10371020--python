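"""Bayesian inference of strand-specific hybrid enrichment from pull-down
versus input sequencing counts.

Per genotype and strand, each bin ``i`` gets an abundance intercept ``a_i``
and a log2 enrichment ``b_i``; library ``l`` with size factor ``s_l``
contributes counts

    y_il ~ NegBin(mu_il, phi),   log mu_il = log s_l + a_i + ln2 * b_i * e_l

where ``e_l`` indicates an extracted (pull-down) library.  Input libraries
are unstranded and shared by both strand models; extracted libraries are
strand-resolved.  The NB dispersion ``phi`` is shared per genotype
(variance = mu + mu^2/phi) and profiled from the data.

Two engines produce 500 posterior draws of ``b`` per bin:

``vi``
    A Gaussian approximate posterior per bin (Laplace: MAP by Fisher
    scoring, covariance from the expected information plus the prior
    precision).  Bins are independent given ``phi``, so this is a
    mean-field approximation across the genome.
``mcmc``
    Vectorised random-walk Metropolis on ``(a_i, b_i)`` for every bin
    simultaneously, proposals preconditioned by the Laplace covariance.

Priors: ``a ~ Normal(log mean depth, 3^2)``, ``b ~ Normal(0, 2^2)`` (log2
scale), dispersion ``~ half-Normal(0, 5^2)`` on 1/phi acting only as a
weak regulariser of the profile fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .counts import StrandedCountMatrix
from .signal import robust_z
from .trackio import GenomicTrack

LN2 = np.log(2.0)


@dataclass
class EnrichmentOptions:
    engine: str = "vi"  # "vi" (Gaussian approximation) or "mcmc"
    draws: int = 500
    seed: int = 0
    prior_alpha_sd: float = 3.0
    prior_beta_sd: float = 2.0  # log2 units
    dispersion: float | None = None  # fix phi instead of profiling it
    mcmc_steps: int = 2500
    mcmc_burn: int = 500


@dataclass
class EnrichmentPosterior:
    """Per-bin posterior draws of log2 enrichment for one genotype/strand."""

    genotype: str
    strand: str
    bins: pd.DataFrame  # contig, start, end (genome bins only)
    draws: np.ndarray  # (n_bins, n_draws) log2 enrichment; NaN on masked bins
    masked: np.ndarray  # flag: bin excluded from the fit
    dispersion: float
    engine: str
    log_base: int = 2  # enrichment scale recorded for the manifest
    metadata: dict = field(default_factory=dict)

    def _nanstat(self, fn) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fn(self.draws)

    @property
    def mean(self) -> np.ndarray:
        return self._nanstat(lambda d: np.nanmean(d, axis=1))

    @property
    def q05(self) -> np.ndarray:
        return self._nanstat(lambda d: np.nanquantile(d, 0.05, axis=1))

    @property
    def q95(self) -> np.ndarray:
        return self._nanstat(lambda d: np.nanquantile(d, 0.95, axis=1))

    def summary_frame(self) -> pd.DataFrame:
        df = self.bins.copy()
        df["genotype"] = self.genotype
        df["strand"] = self.strand
        df["mean"] = self.mean
        df["q05"] = self.q05
        df["q95"] = self.q95
        df["masked"] = self.masked
        return df

    def mean_track(self) -> GenomicTrack:
        vals = self.mean.copy()
        vals[self.masked] = np.nan
        return GenomicTrack(
            self.bins["contig"].iloc[0],
            self.bins["start"].to_numpy(),
            self.bins["end"].to_numpy(),
            vals,
            {"genotype": self.genotype, "strand": self.strand, "log_base": 2},
        )

    def z_track(self) -> GenomicTrack:
        t = self.mean_track()
        return t.with_values(robust_z(t.values), transform="robust_z")

    def save_draws(self, path) -> None:
        """NPZ draw archive: arrays 'draws', 'start', 'end', scalars in meta."""
        np.savez_compressed(
            path,
            draws=self.draws.astype(np.float32),
            start=self.bins["start"].to_numpy(),
            end=self.bins["end"].to_numpy(),
            masked=self.masked,
            meta=np.array(
                [self.genotype, self.strand, str(self.dispersion), self.engine]
            ),
        )


# ---------------------------------------------------------------------------
# Negative-binomial machinery (vectorised over bins)
# ---------------------------------------------------------------------------


def _nb_loglik(y, mu, phi):
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1)
        + phi * np.log(phi / (phi + mu))
        + y * np.log(mu / (phi + mu))
    )


def _map_fit(y, log_sf, is_ext, phi, prior_mean_a, sd_a, sd_b, n_iter=40):
    """Fisher-scoring MAP for (a, b) per bin; returns MAP and 2x2 covariance.

    y: (n_bins, n_libs); log_sf, is_ext: (n_libs,).
    """
    e = is_ext.astype(float)[None, :]
    norm = np.exp(-log_sf)[None, :]
    inp = ~is_ext
    mean_in = (y[:, inp] * norm[:, inp]).mean(axis=1)
    mean_ex = (y[:, ~inp] * norm[:, ~inp]).mean(axis=1)
    a = np.log(mean_in + 0.5)
    b = np.log2((mean_ex + 0.5) / (mean_in + 0.5))
    pa, pb = 1.0 / sd_a**2, 1.0 / sd_b**2
    for _ in range(n_iter):
        eta = log_sf[None, :] + a[:, None] + LN2 * b[:, None] * e
        mu = np.exp(np.clip(eta, -30, 30))
        g = y - mu * (y + phi) / (mu + phi)
        w = mu * phi / (mu + phi)
        ga = g.sum(axis=1) - (a - prior_mean_a) * pa
        gb = LN2 * (g * e).sum(axis=1) - b * pb
        haa = w.sum(axis=1) + pa
        hab = LN2 * (w * e).sum(axis=1)
        hbb = LN2**2 * (w * e).sum(axis=1) + pb
        det = haa * hbb - hab**2
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        step = np.maximum(1.0, np.maximum(np.abs(da), np.abs(db)) / 2.0)
        a = a + da / step
        b = b + db / step
        if max(np.abs(da).max(), np.abs(db).max()) < 1e-10:
            break
    # covariance from the (expected) information at the MAP
    eta = log_sf[None, :] + a[:, None] + LN2 * b[:, None] * e
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu * phi / (mu + phi)
    haa = w.sum(axis=1) + pa
    hab = LN2 * (w * e).sum(axis=1)
    hbb = LN2**2 * (w * e).sum(axis=1) + pb
    det = haa * hbb - hab**2
    cov = np.empty((len(a), 2, 2))
    cov[:, 0, 0] = hbb / det
    cov[:, 1, 1] = haa / det
    cov[:, 0, 1] = cov[:, 1, 0] = -hab / det
    return a, b, cov


def _moment_dispersion(y, log_sf, is_ext, a, b):
    """Pearson moment estimate of phi given per-bin MAP means.

    Solves sum (y - mu)^2 / (mu + mu^2/phi) = residual degrees of freedom
    (n_libs - 2 per bin, since each bin fits an intercept and an
    enrichment).  Sub-Poisson residuals return +inf (Poisson limit).
    """
    e = is_ext.astype(float)[None, :]
    eta = log_sf[None, :] + a[:, None] + LN2 * b[:, None] * e
    mu = np.exp(np.clip(eta, -30, 30))
    resid2 = (y - mu) ** 2
    df = y.shape[0] * max(y.shape[1] - 2, 1)

    def excess(log_phi):
        phi = np.exp(log_phi)
        return (resid2 / (mu + mu**2 / phi)).sum() - df

    # Pearson sum grows with phi (variance shrinks towards Poisson)
    lo, hi = np.log(0.05), np.log(1e9)
    if excess(hi) <= 0:  # sub-Poisson residuals: effectively Poisson
        return float(np.exp(hi))
    if excess(lo) >= 0:
        return float(np.exp(lo))
    from scipy.optimize import brentq

    return float(np.exp(brentq(excess, lo, hi, xtol=1e-6)))


def _logpost(theta_a, theta_b, y, log_sf, is_ext, phi, prior_mean_a, sd_a, sd_b):
    e = is_ext.astype(float)[None, :]
    eta = log_sf[None, :] + theta_a[:, None] + LN2 * theta_b[:, None] * e
    mu = np.exp(np.clip(eta, -30, 30))
    ll = _nb_loglik(y, mu, phi).sum(axis=1)
    ll -= (theta_a - prior_mean_a) ** 2 / (2 * sd_a**2)
    ll -= theta_b**2 / (2 * sd_b**2)
    return ll


def fit_enrichment(
    counts: StrandedCountMatrix,
    genotype: str,
    strand: str,
    opts: EnrichmentOptions | None = None,
) -> EnrichmentPosterior:
    """Fit the per-bin enrichment model for one genotype and strand."""
    opts = opts or EnrichmentOptions()
    idx_in = counts.library_indices(genotype, "input")
    idx_ex = counts.library_indices(genotype, "extracted", strand)
    if idx_in.size == 0 or idx_ex.size == 0:
        raise ValueError(
            f"genotype {genotype!r} lacks "
            f"{'input' if idx_in.size == 0 else f'extracted ({strand})'} libraries"
        )
    lib_idx = np.concatenate([idx_in, idx_ex])
    totals = counts.counts[:, lib_idx].sum(axis=0)
    if np.any(totals == 0):
        bad = counts.libraries["library"].iloc[lib_idx[totals == 0]].tolist()
        raise ValueError(f"all-zero library: {bad}")

    genome = counts.genome_bins()
    fit_bins = genome[~counts.mask[genome]]
    y = counts.counts[np.ix_(fit_bins, lib_idx)].astype(float)
    log_sf = np.log(counts.size_factors[lib_idx])
    is_ext = np.zeros(len(lib_idx), dtype=bool)
    is_ext[len(idx_in):] = True

    depth = (y * np.exp(-log_sf)[None, :]).mean()
    prior_mean_a = np.log(depth + 0.5)

    phi = opts.dispersion
    a, b, cov = _map_fit(
        y, log_sf, is_ext, phi if phi else 100.0, prior_mean_a,
        opts.prior_alpha_sd, opts.prior_beta_sd,
    )
    if phi is None:
        for _ in range(2):
            phi = _moment_dispersion(y, log_sf, is_ext, a, b)
            a, b, cov = _map_fit(
                y, log_sf, is_ext, phi, prior_mean_a,
                opts.prior_alpha_sd, opts.prior_beta_sd,
            )

    rng = np.random.default_rng(opts.seed)
    if opts.engine == "vi":
        sd_b = np.sqrt(cov[:, 1, 1])
        draws = b[:, None] + sd_b[:, None] * rng.standard_normal((len(b), opts.draws))
    elif opts.engine == "mcmc":
        draws = _metropolis_draws(
            y, log_sf, is_ext, phi, prior_mean_a, opts, a, b, cov, rng
        )
    else:
        raise ValueError(f"unknown engine {opts.engine!r}")

    # re-insert masked bins as flagged null records
    n_genome = len(genome)
    full = np.full((n_genome, opts.draws), np.nan)
    keep = ~counts.mask[genome]
    full[keep] = draws
    bins = counts.bins.iloc[genome].reset_index(drop=True)
    return EnrichmentPosterior(
        genotype=genotype,
        strand=strand,
        bins=bins,
        draws=full,
        masked=counts.mask[genome].copy(),
        dispersion=float(phi),
        engine=opts.engine,
        metadata={"seed": opts.seed, "n_libraries": len(lib_idx), "log_base": 2},
    )


def _metropolis_draws(y, log_sf, is_ext, phi, prior_mean_a, opts, a, b, cov, rng):
    """Random-walk Metropolis on (a, b), all bins in parallel."""
    n = len(a)
    chol = np.linalg.cholesky(cov * (2.4**2 / 2.0))
    cur_a, cur_b = a.copy(), b.copy()
    cur_lp = _logpost(cur_a, cur_b, y, log_sf, is_ext, phi, prior_mean_a,
                      opts.prior_alpha_sd, opts.prior_beta_sd)
    kept = []
    n_keep = opts.draws
    keep_every = max(1, (opts.mcmc_steps - opts.mcmc_burn) // n_keep)
    for step in range(opts.mcmc_steps):
        eps = rng.standard_normal((n, 2))
        prop = np.einsum("nij,nj->ni", chol, eps)
        pa, pb = cur_a + prop[:, 0], cur_b + prop[:, 1]
        lp = _logpost(pa, pb, y, log_sf, is_ext, phi, prior_mean_a,
                      opts.prior_alpha_sd, opts.prior_beta_sd)
        accept = np.log(rng.random(n)) < lp - cur_lp
        cur_a = np.where(accept, pa, cur_a)
        cur_b = np.where(accept, pb, cur_b)
        cur_lp = np.where(accept, lp, cur_lp)
        if step >= opts.mcmc_burn and (step - opts.mcmc_burn) % keep_every == 0:
            kept.append(cur_b.copy())
    draws = np.stack(kept, axis=1)
    if draws.shape[1] < n_keep:  # top up from the end of the chain
        reps = n_keep - draws.shape[1]
        draws = np.concatenate([draws, np.tile(draws[:, -1:], (1, reps))], axis=1)
    return draws[:, :n_keep]


def fit_all_enrichment(
    counts: StrandedCountMatrix, opts: EnrichmentOptions | None = None
) -> dict:
    """Fit every (genotype, strand) model present in the library table."""
    out = {}
    for g in counts.genotypes:
        strands = sorted(
            set(counts.libraries.loc[
                (counts.libraries["genotype"] == g)
                & (counts.libraries["sample_type"] == "extracted"), "strand"
            ])
        )
        for s in strands:
            out[(g, s)] = fit_enrichment(counts, g, s, opts)
    return out


# ---------------------------------------------------------------------------
# Genotype contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastTrack:
    """Paired-draw difference of two enrichment posteriors (a - b)."""

    label: str
    bins: pd.DataFrame
    draws: np.ndarray
    masked: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.draws, axis=1)

    def mean_track(self) -> GenomicTrack:
        vals = self.mean.copy()
        vals[self.masked] = np.nan
        return GenomicTrack(
            self.bins["contig"].iloc[0],
            self.bins["start"].to_numpy(),
            self.bins["end"].to_numpy(),
            vals,
            {"contrast": self.label},
        )

    def z_track(self) -> GenomicTrack:
        t = self.mean_track()
        return t.with_values(robust_z(t.values), transform="robust_z")


def contrast(a: EnrichmentPosterior, b: EnrichmentPosterior) -> ContrastTrack:
    """Per-bin draws of ``beta_a - beta_b`` paired by draw index."""
    for col in ("contig", "start", "end"):
        av, bv = a.bins[col].to_numpy(), b.bins[col].to_numpy()
        if len(av) != len(bv) or np.any(av != bv):
            first = int(np.flatnonzero(av != bv)[0]) if len(av) == len(bv) else 0
            raise ValueError(
                f"bin mismatch between posteriors at row {first} (column {col})"
            )
    if a.draws.shape != b.draws.shape:
        raise ValueError("posteriors carry different draw counts")
    return ContrastTrack(
        label=f"{a.genotype}-{b.genotype}",
        bins=a.bins,
        draws=a.draws - b.draws,
        masked=a.masked | b.masked,
    )


# ---------------------------------------------------------------------------
# Spike-referenced qPCR quantitation
# ---------------------------------------------------------------------------


@dataclass
class DdcqResult:
    locus: str
    genotype: str
    reference: str
    ddcq: float
    se: float
    n_replicates: int


def ddcq(table: pd.DataFrame, locus: str, genotype: str, reference: str) -> DdcqResult:
    """Spike-referenced qPCR double difference of quantification cycles.

    ddCq = (Cq_pulldown - Cq_input) at ``locus`` minus the same difference at
    the spike-in ``reference`` locus, using replicate means; the standard
    error propagates the replicate spread of all four cell means.
    """
    req = {"locus", "genotype", "fraction", "replicate", "cq"}
    if not req <= set(table.columns):
        raise ValueError(f"qPCR table needs columns {sorted(req)}")
    if (table["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    sub = table[table["genotype"] == genotype]
    cells = {}
    ns = []
    for loc in (locus, reference):
        for frac in ("pulldown", "input"):
            vals = sub.loc[(sub["locus"] == loc) & (sub["fraction"] == frac), "cq"]
            if vals.empty:
                raise ValueError(
                    f"missing fraction {frac!r} for locus {loc!r}, genotype {genotype!r}"
                )
            cells[(loc, frac)] = (vals.mean(), vals.var(ddof=1) if len(vals) > 1 else 0.0,
                                  len(vals))
            ns.append(len(vals))
    val = (
        cells[(locus, "pulldown")][0] - cells[(locus, "input")][0]
        - (cells[(reference, "pulldown")][0] - cells[(reference, "input")][0])
    )
    se = float(np.sqrt(sum(v / n for (_, v, n) in cells.values())))
    return DdcqResult(locus, genotype, reference, float(val), se, min(ns))
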