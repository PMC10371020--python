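"""Track-level transforms: robust z-scores, rolling medians, coverage CPM,
replication slope z-scores, and kernel density of event positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .genome import ReplichoreMap
from .trackio import GenomicTrack

#: Consistency factor making MAD an unbiased scale estimate for a Gaussian.
MAD_CONSTANT = 1.4826
#: Same role for the interquartile range.
IQR_CONSTANT = 1.349


class ScaleError(ValueError):
    """Raised when the robust scale of a track is zero.

    Pass ``fallback="iqr"`` to :func:`robust_z` to switch to an IQR-based
    scale when the MAD degenerates.
    """


def robust_scale(x: np.ndarray, method: str = "mad") -> float:
    x = np.asarray(x, dtype=float)
    if method == "mad":
        med = np.nanmedian(x)
        return MAD_CONSTANT * float(np.nanmedian(np.abs(x - med)))
    if method == "iqr":
        q75, q25 = np.nanpercentile(x, [75, 25])
        return float(q75 - q25) / IQR_CONSTANT
    raise ValueError(f"unknown scale method {method!r}")


def robust_z(x, fallback: str | None = None) -> np.ndarray:
    """(x - median) / (1.4826 * MAD); NaN entries stay NaN.

    Shift- and scale-invariant: ``robust_z(a*x + b) == robust_z(x)`` for
    ``a > 0``.  A zero MAD raises :class:`ScaleError` unless
    ``fallback="iqr"`` switches the scale estimate to IQR/1.349.
    """
    x = np.asarray(x, dtype=float)
    if np.sum(~np.isnan(x)) < 2:
        raise ScaleError("robust_z needs at least 2 non-missing values")
    scale = robust_scale(x, "mad")
    if scale == 0.0:
        if fallback == "iqr":
            scale = robust_scale(x, "iqr")
        if scale == 0.0:
            raise ScaleError(
                "robust scale is zero (MAD=0); pass fallback='iqr' or inspect the track"
            )
    return (x - np.nanmedian(x)) / scale


def robust_z_track(track: GenomicTrack, fallback: str | None = None) -> GenomicTrack:
    return track.with_values(robust_z(track.values, fallback=fallback), transform="robust_z")


def rolling_median(values, window_bins: int) -> np.ndarray:
    """Centered rolling median; edge windows truncate; NaNs are excluded."""
    if window_bins < 1:
        raise ValueError("window must span at least one bin")
    if window_bins % 2 == 0:
        window_bins += 1  # force odd so the window is centered
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window_bins, center=True, min_periods=1).median().to_numpy()


def rolling_median_track(track: GenomicTrack, window_bp: int) -> GenomicTrack:
    if window_bp < track.bin_width:
        raise ValueError(
            f"window {window_bp} bp is narrower than the {track.bin_width} bp bins"
        )
    k = int(np.ceil(window_bp / track.bin_width))
    return track.with_values(rolling_median(track.values, k), smoothed_bp=window_bp)


# ---------------------------------------------------------------------------
# Coverage and replication slope
# ---------------------------------------------------------------------------


@dataclass
class CoverageTrack:
    """log2 counts-per-million coverage with its pseudocount recorded."""

    track: GenomicTrack
    total_reads: float
    pseudocount: float


def log2_cpm(counts_track: GenomicTrack, pseudocount: float = 0.5) -> CoverageTrack:
    counts = counts_track.values
    total = float(np.nansum(counts))
    if total <= 0:
        raise ValueError("coverage track has no reads")
    cpm = (counts + pseudocount) * 1e6 / total
    values = np.log2(cpm)
    return CoverageTrack(
        counts_track.with_values(values, transform="log2_cpm", pseudocount=pseudocount),
        total_reads=total,
        pseudocount=pseudocount,
    )


def replication_slope_z(
    cov: CoverageTrack,
    rep: ReplichoreMap,
    smooth_bp: int = 10_000,
    slope_bp: int = 10_000,
) -> GenomicTrack:
    """Robust z-score of the coverage slope along the direction of fork travel.

    The log2 CPM track is smoothed with a rolling median, a least-squares
    slope is computed over a centered window at every bin, and the slope is
    signed along the direction of replication-fork travel on each replichore
    (so fork slow-down is strongly negative).  The slope track is converted
    to robust z; if the slope is exactly constant (zero MAD and IQR), the z
    track is all zeros and flagged ``degenerate_scale``.
    """
    track = cov.track
    smoothed = rolling_median_track(track, smooth_bp)
    k = int(np.ceil(slope_bp / track.bin_width))
    if k % 2 == 0:
        k += 1
    if k < 3:
        raise ValueError("slope window must span at least 3 bins")
    flags = {}
    if k > track.n_bins:
        k = track.n_bins if track.n_bins % 2 == 1 else track.n_bins - 1
        flags["slope_window_truncated"] = True
    slope = savgol_filter(
        smoothed.values, window_length=k, polyorder=1, deriv=1,
        delta=track.bin_width, mode="interp",
    )
    mids = 0.5 * (track.starts + track.ends)
    slope = slope * rep.fork_direction(mids)
    # a slope constant up to float jitter has no meaningful z-scale
    med = np.nanmedian(slope)
    degenerate = robust_scale(slope, "mad") <= 1e-9 * max(abs(med), 1e-12)
    if degenerate:
        z = np.zeros_like(slope)
        flags["degenerate_scale"] = True
    else:
        try:
            z = robust_z(slope, fallback="iqr")
        except ScaleError:
            z = np.zeros_like(slope)
            flags["degenerate_scale"] = True
    return track.with_values(z, transform="replication_slope_z", **flags)


# ---------------------------------------------------------------------------
# Event-position density
# ---------------------------------------------------------------------------


def density_bandwidth(positions, adjust: float = 1.0) -> float:
    """adjust x 0.9 x min(sd, IQR/1.34) x n^(-1/5) (the classical
    rule-of-thumb bandwidth used by the usual density-plot default)."""
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 positions")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr_scale = (q75 - q25) / 1.34
    spread = min(s for s in (sd, iqr_scale) if s > 0) if (sd > 0 or iqr_scale > 0) else 0.0
    bw = adjust * 0.9 * spread * n ** (-1 / 5)
    if bw <= 0:
        raise ValueError("bandwidth is zero: all positions identical")
    return bw


def event_density(
    positions,
    genome_length: float | None = None,
    adjust: float = 1.0,
    n_grid: int = 512,
) -> pd.DataFrame:
    """Gaussian kernel density of event positions on a regular grid.

    The grid spans [min - 3*bw, max + 3*bw], clipped to [0, genome_length]
    when a genome length is given.  The returned density integrates to 1
    (within ~1%, boundary truncation aside).
    """
    x = np.asarray(positions, dtype=float)
    bw = density_bandwidth(x, adjust=adjust)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    if genome_length is not None:
        lo, hi = max(lo, 0.0), min(hi, float(genome_length))
    grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))
    return pd.DataFrame({"position": grid, "density": dens, "bandwidth": bw})
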