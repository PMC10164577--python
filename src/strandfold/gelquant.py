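"""1-D gel densitometry.

Quantifications performed on lane intensity profiles: minimum-profile
background subtraction, molecular-size calibration against a ladder via the
retardation factor (Rf), detection of the high-molecular-weight front of a
product smear, maximum replication rates from pulse-chase time courses,
rate normalization across conditions, EMSA percent-bound from depletion of
the unbound band, and full-length-product fractions from primer extensions.

Size calibration follows the standard log-linear model
``log10(size_bp) = slope * Rf + intercept`` with ``Rf = position /
lane_length``; the slope is negative because large fragments migrate less.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from strandfold.core import LadderCalibration, LaneProfile, RateEstimate

DEFAULT_FRONT_FRACTION = 0.05


def subtract_background_minprofile(
    profile: LaneProfile, window_fraction: float = 0.1
) -> LaneProfile:
    """Subtract the running-minimum lower envelope from a lane.

    The envelope at each position is the minimum intensity within a window of
    ``window_fraction`` of the lane length; subtracting it removes a slowly
    varying baseline while leaving peaks intact. Output is clipped at zero and
    is pointwise <= the input.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    n = profile.intensity.size
    window = max(int(round(window_fraction * n)), 1)
    envelope = ndimage.minimum_filter1d(profile.intensity, size=window, mode="nearest")
    corrected = np.clip(profile.intensity - envelope, 0.0, None)
    return LaneProfile(
        position=profile.position,
        intensity=corrected,
        lane_length=profile.lane_length,
        ladder_positions=profile.ladder_positions,
        ladder_sizes=profile.ladder_sizes,
    )


def fit_ladder(
    band_positions: np.ndarray, band_sizes: np.ndarray, lane_length: float
) -> LadderCalibration:
    """Least-squares log-linear size calibration from ladder bands.

    Fits log10(size_bp) on Rf = position / lane_length; at least three bands
    are required. Order of the bands does not matter.
    """
    pos = np.asarray(band_positions, dtype=float)
    sizes = np.asarray(band_sizes, dtype=float)
    if pos.shape != sizes.shape:
        raise ValueError("band positions and sizes must match in length")
    if pos.size < 3:
        raise ValueError("ladder calibration needs at least 3 bands")
    if np.any(sizes <= 0):
        raise ValueError("band sizes must be positive")
    if np.unique(pos).size < 2:
        raise ValueError("degenerate band positions")
    rf = pos / lane_length
    res = stats.linregress(rf, np.log10(sizes))
    return LadderCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        lane_length=float(lane_length),
        r_squared=float(res.rvalue**2),
    )


def position_to_bp(calib: LadderCalibration, position: float | np.ndarray) -> float | np.ndarray:
    """Convert a migration position to fragment size: 10^(slope*Rf + intercept)."""
    rf = np.asarray(position, dtype=float) / calib.lane_length
    bp = 10.0 ** (calib.slope * rf + calib.intercept)
    return float(bp) if bp.ndim == 0 else bp


def detect_front(profile: LaneProfile, fraction_of_max: float = DEFAULT_FRONT_FRACTION) -> float:
    """Migration position of the high-molecular-weight front of the main peak.

    Returns the smallest position at which the intensity first reaches
    ``fraction_of_max`` of the lane maximum, linearly interpolated between
    samples. The threshold is relative, so the detected front is invariant to
    exposure scaling. ``fraction_of_max=1`` returns the peak position itself.
    """
    if not 0 < fraction_of_max <= 1:
        raise ValueError("fraction_of_max must lie in (0, 1]")
    intensity = profile.intensity
    peak = intensity.max()
    if peak <= 0:
        raise ValueError("profile has no signal")
    threshold = fraction_of_max * peak
    above = np.nonzero(intensity >= threshold)[0]
    i = above[0]
    if i == 0 or intensity[i] == threshold:
        return float(profile.position[i])
    # linear interpolation between the last sub-threshold sample and this one
    x0, x1 = profile.position[i - 1], profile.position[i]
    y0, y1 = intensity[i - 1], intensity[i]
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


def max_replication_rate(
    front_bp_by_time: dict[float, float], use_first: int = 3
) -> RateEstimate:
    """Maximum replication rate from product-front sizes over a chase.

    Ordinary least squares of front size (bp) on time (min) over the earliest
    ``use_first`` timepoints; the slope, in kb/min, is the maximum rate of
    leading-strand synthesis. Later timepoints are ignored by design (the
    front saturates as forks terminate).
    """
    if len(front_bp_by_time) < use_first:
        raise ValueError(f"need at least {use_first} timepoints")
    times = np.array(sorted(front_bp_by_time))[:use_first]
    if times.size < 2:
        raise ValueError("need at least 2 usable timepoints")
    sizes = np.array([front_bp_by_time[t] for t in times], dtype=float)
    res = stats.linregress(times, sizes)
    predicted = res.intercept + res.slope * times
    rms = float(np.sqrt(np.mean((sizes - predicted) ** 2)))
    return RateEstimate(
        rate_kb_per_min=float(res.slope) / 1000.0,
        intercept_kb=float(res.intercept) / 1000.0,
        n_points=int(times.size),
        residual_kb_rms=rms / 1000.0,
    )


def normalize_rate(rate_kb_per_min: float, reference_rate_kb_per_min: float) -> float:
    """Rate relative to a reference condition (reference maps to 1)."""
    if reference_rate_kb_per_min <= 0:
        raise ValueError("reference rate must be positive")
    return rate_kb_per_min / reference_rate_kb_per_min


def emsa_percent_bound(unbound_intensity: float, unbound_reference: float) -> float:
    """Percent bound from depletion of the unbound-DNA band.

    100 minus the percentage of unbound DNA relative to the no-protein
    reference lane, clamped to [0, 100].
    """
    if unbound_reference <= 0:
        raise ValueError("reference (no-protein) unbound intensity must be positive")
    if unbound_intensity < 0:
        raise ValueError("unbound intensity must be nonnegative")
    return float(np.clip(100.0 - 100.0 * unbound_intensity / unbound_reference, 0.0, 100.0))


def fulllength_fraction(profile: LaneProfile, band_window: tuple[float, float]) -> float:
    """Percent of lane intensity inside a band window (full-length product
    relative to the whole lane)."""
    lo, hi = band_window
    if lo > hi:
        raise ValueError("band window must be ordered (lo, hi)")
    total = profile.intensity.sum()
    if total <= 0:
        raise ValueError("lane has no intensity")
    inside = profile.intensity[(profile.position >= lo) & (profile.position <= hi)].sum()
    return float(100.0 * inside / total)
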