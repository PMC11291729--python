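"""Amplitude histograms, Gaussian-mixture fitting and trace idealization.

The single-channel workflow is: build an all-points amplitude histogram of
a sweep, fit a sum-of-Gaussians

    f(x) = sum_i A_i exp(-(x - mu_i)^2 / 2 sigma_i^2) / (sigma_i sqrt(2 pi)) + C

to the density-normalised histogram, take mu2 - mu1 as the unitary current,
and idealize the sweep by half-amplitude threshold crossing between
adjacent level means, merging events shorter than the dead time.
"""

from __future__ import annotations

import warnings

import numpy as np
import lmfit

from .models import (
    AmplitudeHistogram,
    GaussianComponent,
    GaussianMixtureFit,
    IdealizedTrace,
    Trace,
)

__all__ = [
    "amplitude_histogram",
    "fit_gaussian_mixture",
    "fit_mixture_to_points",
    "unitary_amplitude",
    "NoOpeningDetected",
    "idealize_trace",
    "default_dead_time",
    "subtract_baseline",
]


class NoOpeningDetected(ValueError):
    """Raised when a fit has a single component, so no unitary amplitude exists."""


def subtract_baseline(trace: Trace, segment_s: float = 1.0) -> Trace:
    """Piecewise-linear baseline correction for slowly drifting sweeps.

    The baseline (closed level) of each ``segment_s`` stretch is estimated
    as the mode of a coarse segment histogram — the closed state dominates
    occupancy in typical records — and a line through the segment-centre
    estimates is subtracted.  Off by default everywhere; apply it before
    histogramming when a sweep drifts.
    """
    if segment_s <= 0:
        raise ValueError("segment length must be positive")
    fs = trace.sampling_rate_hz
    n_seg = max(int(round(trace.duration_s / segment_s)), 1)
    bounds = np.linspace(0, trace.n_samples, n_seg + 1).astype(int)
    centers, base = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = trace.samples[a:b]
        if seg.size == 0:
            continue
        counts, edges = np.histogram(seg, bins=max(seg.size // 200, 10))
        k = int(np.argmax(counts))
        centers.append((a + b) / 2.0 / fs)
        base.append(0.5 * (edges[k] + edges[k + 1]))
    baseline = np.interp(trace.time_s(), centers, base)
    return Trace(
        samples=trace.samples - baseline,
        sampling_rate_hz=fs,
        command_voltage_mv=trace.command_voltage_mv,
        capacitance_pf=trace.capacitance_pf,
        meta=dict(trace.meta, baseline_corrected=True),
    )


def freedman_diaconis_width(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return max(np.ptp(x) / 50.0, 1e-6)
    return 2.0 * iqr / x.size ** (1.0 / 3.0)


def amplitude_histogram(
    trace: Trace,
    bin_width_pa: float | None = None,
) -> AmplitudeHistogram:
    """All-points histogram of a sweep's current samples.

    ``bin_width_pa`` defaults to the Freedman-Diaconis rule, capped so a
    multimodal all-points histogram gets at least ~60 bins (FD assumes a
    unimodal spread and over-widens on well-separated open/closed peaks).
    Counts are conserved: they always sum to the number of samples.
    """
    x = trace.samples
    if x.size == 0:
        raise ValueError("trace is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if bin_width_pa is None:
        bin_width_pa = freedman_diaconis_width(x)
        span = np.ptp(x)
        if span > 0:
            bin_width_pa = min(bin_width_pa, span / 60.0)
    if bin_width_pa <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = x.min(), x.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_width_pa)), 1)
    edges = lo + bin_width_pa * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi + bin_width_pa * 1e-9)  # include max sample
    counts, edges = np.histogram(x, bins=edges)
    v = trace.command_voltage_mv
    return AmplitudeHistogram(
        bin_edges=edges,
        counts=counts,
        voltage_mv=float(v) if np.isscalar(v) else None,
        n_samples=x.size,
    )


def _mixture(x, params, n):
    y = np.full_like(x, params["c"].value if hasattr(params["c"], "value") else params["c"])
    for i in range(n):
        a, mu, sd = (params[f"{k}{i}"] for k in ("a", "mu", "sigma"))
        if hasattr(a, "value"):
            a, mu, sd = a.value, mu.value, sd.value
        y = y + a * np.exp(-((x - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))
    return y


def _initial_means(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Greedy density-peak starting means: repeatedly take the highest
    remaining point subject to a minimum separation; duplicates of the
    tallest peak seed any leftover components."""
    span = max(x.max() - x.min(), 1e-12)
    min_sep = span / (3.0 * n)
    order = np.argsort(y)[::-1]
    picked: list[float] = []
    for j in order:
        xj = float(x[j])
        if all(abs(xj - p) >= min_sep for p in picked):
            picked.append(xj)
        if len(picked) == n:
            break
    k = 1
    while len(picked) < n:  # degenerate histograms: stack near the tallest peak
        picked.append(picked[0] + k * min_sep / 2.0)
        k += 1
    return np.sort(picked)


def fit_mixture_to_points(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    sigma_floor: float = 1e-6,
    init_means: np.ndarray | None = None,
) -> GaussianMixtureFit:
    """Least-squares Gaussian mixture fit to (x, y) density points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components < 1:
        raise ValueError("need at least one component")
    n_free = 3 * n_components + 1
    if x.size <= n_free:
        raise ValueError(f"too few points ({x.size}) for {n_free} free parameters")

    mus = np.sort(np.asarray(init_means, dtype=float)) if init_means is not None \
        else _initial_means(x, y, n_components)
    span = x.max() - x.min()
    dx = np.median(np.diff(np.sort(x))) if x.size > 1 else 1.0
    total_area = max(float(np.trapezoid(y, x)), 1e-12)

    params = lmfit.Parameters()
    params.add("c", value=0.0, min=0.0)
    for i in range(n_components):
        # assign initial areas by nearest-mean partition of the observed mass
        d = np.abs(x[:, None] - mus[None, :])
        share = (d.argmin(axis=1) == i)
        a0 = float(np.trapezoid(np.where(share, y, 0.0), x)) or total_area / n_components
        # start narrow: the optimiser widens a component far more reliably
        # than it splits an overly wide one
        sd0 = max(2 * dx, span / 100.0)
        params.add(f"a{i}", value=max(a0, total_area * 1e-3), min=0.0)
        params.add(f"mu{i}", value=float(mus[i]), min=x.min() - span, max=x.max() + span)
        params.add(f"sigma{i}", value=sd0, min=sigma_floor, max=span if span > 0 else 1.0)

    def resid(p):
        return _mixture(x, p, n_components) - y

    # trust-region reflective handles the area>=0 / sigma floor bounds without
    # the MINPACK bound-transform stalling on redundant components
    result = lmfit.minimize(resid, params, method="least_squares")
    comps = [
        GaussianComponent(
            area=float(result.params[f"a{i}"].value),
            mu=float(result.params[f"mu{i}"].value),
            sigma=float(result.params[f"sigma{i}"].value),
        )
        for i in range(n_components)
    ]
    fit = GaussianMixtureFit(
        components=comps,
        offset=float(result.params["c"].value),
        converged=bool(result.success),
        redchi=float(result.redchi) if result.redchi is not None else np.nan,
        message=str(result.message),
    )
    if not result.success:
        fit.warnings.append(f"mixture fit did not converge: {result.message}")
    return fit


def fit_gaussian_mixture(
    hist: AmplitudeHistogram,
    n_components: int,
    init_means: np.ndarray | None = None,
) -> GaussianMixtureFit:
    """Fit the Gaussian mixture to a density-normalised amplitude histogram.

    The sigma of every component is bounded below by half the bin width so
    a component can never collapse onto a single bin.  Non-convergence is
    reported on the returned object (``converged`` flag plus warning),
    never silently.
    """
    occupied = int(np.count_nonzero(hist.counts))
    n_free = 3 * n_components + 1
    if occupied <= n_free:
        raise ValueError(
            f"histogram has {occupied} occupied bins; need more than {n_free} "
            f"for {n_components} components"
        )
    fit = fit_mixture_to_points(
        hist.centers,
        hist.density(),
        n_components,
        sigma_floor=hist.bin_width / 2.0,
        init_means=init_means,
    )
    if not fit.converged:
        warnings.warn(fit.message, RuntimeWarning, stacklevel=2)
    return fit


def unitary_amplitude(fit: GaussianMixtureFit) -> float:
    """Unitary current from a mixture fit: difference of adjacent level means.

    Means are ordered by distance from baseline (the component nearest
    0 pA), so the sign of the returned amplitude follows the sign of the
    current at that voltage: mu2 - mu1 is positive for outward openings
    and negative for inward ones.
    """
    if fit.n_components < 2:
        raise NoOpeningDetected(
            "fit has a single component: no opening detected, unitary amplitude undefined"
        )
    mus = fit.means
    base = mus[np.argmin(np.abs(mus))]
    ordered = mus[np.argsort(np.abs(mus - base))]
    return float(ordered[1] - ordered[0])


def default_dead_time(filter_cutoff_hz: float) -> float:
    """Dead time of a Gaussian-response filter: T_d = 0.179 / f_c (seconds)."""
    return 0.179 / filter_cutoff_hz


def _level_order(means: np.ndarray) -> np.ndarray:
    """Component means ordered as levels 0..n-1: baseline (nearest 0 pA)
    first, then increasing distance from baseline."""
    base = means[np.argmin(np.abs(means))]
    return means[np.argsort(np.abs(means - base))]


def idealize_trace(
    trace: Trace,
    fit: GaussianMixtureFit,
    dead_time_s: float = 0.0,
) -> IdealizedTrace:
    """Half-amplitude threshold idealization against fitted level means.

    Every sample is assigned the level whose fitted mean is on its side of
    the half-amplitude thresholds between adjacent means; runs shorter
    than ``dead_time_s`` are merged into the neighbouring level (longer
    neighbour wins).  The dwell durations sum exactly to the sweep
    duration.  Overlapping level means (closer than 3x the widest sigma)
    set an ``overlap_warning`` flag in the metadata.
    """
    if dead_time_s < 0:
        raise ValueError("dead time must be >= 0")
    means = _level_order(fit.means)
    n_levels = means.size
    fs = trace.sampling_rate_hz
    dt = 1.0 / fs

    overlap = bool(np.min(np.abs(np.diff(np.sort(means)))) < 3 * fit.sigmas.max()) \
        if n_levels > 1 else False

    if n_levels == 1:
        level_idx = np.zeros(trace.n_samples, dtype=int)
    else:
        # project onto the baseline->open axis; thresholds midway between means
        sign = np.sign(means[-1] - means[0]) or 1.0
        proj = (trace.samples - means[0]) * sign
        mproj = (means - means[0]) * sign
        order = np.argsort(mproj)
        thresholds = 0.5 * (mproj[order][:-1] + mproj[order][1:])
        level_idx = order[np.searchsorted(thresholds, proj)]

    # compress into runs
    change = np.flatnonzero(np.diff(level_idx)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [trace.n_samples]))
    levels = level_idx[starts].astype(int)
    durations = (ends - starts) * dt

    if dead_time_s > 0:
        levels, durations = _apply_dead_time(levels, durations, dead_time_s)

    return IdealizedTrace(
        levels=levels,
        durations=durations,
        meta={
            "overlap_warning": overlap,
            "dead_time_s": dead_time_s,
            "voltage_mv": trace.command_voltage_mv
            if np.isscalar(trace.command_voltage_mv) else None,
        },
    )


def _apply_dead_time(
    levels: np.ndarray, durations: np.ndarray, dead_time_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge events shorter than the dead time into a neighbouring level.

    Shortest events are removed first; the first and last dwell are kept
    regardless (no neighbour on one side to absorb them reliably).
    Repeated until every interior dwell is >= dead time.
    """
    lv = list(levels)
    du = list(durations)
    while len(lv) > 2:
        interior = range(1, len(lv) - 1)
        short = [i for i in interior if du[i] < dead_time_s]
        if not short:
            break
        i = min(short, key=lambda j: du[j])
        # absorb into the longer neighbour
        left, right = i - 1, i + 1
        target = left if du[left] >= du[right] else right
        du[target] += du[i]
        del lv[i], du[i]
        # merge equal neighbours created by the deletion
        j = 1
        while j < len(lv):
            if lv[j] == lv[j - 1]:
                du[j - 1] += du[j]
                del lv[j], du[j]
            else:
                j += 1
    return np.asarray(lv), np.asarray(du)
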