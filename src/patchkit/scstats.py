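"""Single-channel open-probability statistics and conductance.

Implements the standard dwell-time statistics of excised-patch analysis:

* Popen = To / T for a single channel, where To is the time spent at any
  conducting level within the analysis window and T the window length;
* the multi-channel form Popen = To / (N T) with the level-weighted open
  time To = sum_L L * (time at level L), which counts a double opening
  twice;
* NPo = To / (To + Tc) with Tc the fully-closed time.  With the
  level-weighted To this is the formula as conventionally printed; note
  that when multi-level openings occur To + Tc exceeds the window length,
  so NPo is not a per-channel time fraction.  ``strict_time_fraction``
  switches to the fraction of time any channel is open.
* slope conductance from an ordinary least-squares line through the
  unitary i-V points, G (pS) = slope(pA/mV) x 10^3.
"""

from __future__ import annotations

import numpy as np

from .models import IdealizedTrace, IVCurve, OpenProbabilityResult

__all__ = [
    "level_weighted_open_time",
    "popen",
    "popen_multi",
    "npo",
    "normalize_popen",
    "fit_iv",
    "conductance",
]


def level_weighted_open_time(ideal: IdealizedTrace) -> float:
    """Level-weighted open time To = sum over dwells of level x duration (s)."""
    return float((ideal.levels * ideal.durations).sum())


def _windowed(ideal: IdealizedTrace, window_s: float, start_s: float) -> IdealizedTrace:
    if window_s <= 0:
        raise ValueError("window length must be positive")
    if start_s + window_s > ideal.duration_s + 1e-9:
        raise ValueError(
            f"window of {window_s} s starting at {start_s} s does not fit in a "
            f"{ideal.duration_s} s trace"
        )
    return ideal.window(start_s, window_s)


def popen_multi(
    ideal: IdealizedTrace,
    n_channels: int,
    window_s: float = 10.0,
    start_s: float = 0.0,
) -> OpenProbabilityResult:
    """Open probability Popen = To / (N T) over an analysis window.

    To is the level-weighted open time, so with N = 1 and only level-1
    openings this reduces to the single-channel To / T.  ``n_channels``
    must cover the largest level actually observed.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    w = _windowed(ideal, window_s, start_s)
    if n_channels < w.max_level:
        raise ValueError(
            f"n_channels={n_channels} is smaller than the maximum observed "
            f"level {w.max_level}"
        )
    to = level_weighted_open_time(w)
    tc = w.time_at_level(0)
    t = w.duration_s
    return OpenProbabilityResult(
        popen=to / (n_channels * t),
        npo=to / (to + tc) if (to + tc) > 0 else 0.0,
        open_time_s=to,
        closed_time_s=tc,
        total_time_s=t,
        n_channels=n_channels,
        voltage_mv=ideal.meta.get("voltage_mv"),
        window=(start_s, window_s),
    )


def popen(
    ideal: IdealizedTrace,
    window_s: float = 10.0,
    start_s: float = 0.0,
) -> OpenProbabilityResult:
    """Single-channel open probability Popen = To / T.

    To is the total time at any conducting level (level >= 1) within the
    window; T is the window length.  For a true single-channel patch this
    equals the N = 1 multi-channel form.
    """
    w = _windowed(ideal, window_s, start_s)
    t = w.duration_s
    tc = w.time_at_level(0)
    to_weighted = level_weighted_open_time(w)
    # for a genuine single-channel record (levels 0/1) the open time equals
    # the level-weighted To bit-for-bit, keeping the N=1 identity exact
    to_any = to_weighted if w.max_level <= 1 else t - tc
    return OpenProbabilityResult(
        popen=to_any / t,
        npo=to_weighted / (to_weighted + tc) if (to_weighted + tc) > 0 else 0.0,
        open_time_s=to_any,
        closed_time_s=tc,
        total_time_s=t,
        n_channels=1,
        voltage_mv=ideal.meta.get("voltage_mv"),
        window=(start_s, window_s),
    )


def npo(
    ideal: IdealizedTrace,
    window_s: float = 10.0,
    start_s: float = 0.0,
    strict_time_fraction: bool = False,
) -> float:
    """Absolute open probability NPo = To / (To + Tc).

    To is level-weighted (the literal printed form); Tc is the fully-closed
    time.  With ``strict_time_fraction=True`` the per-sample alternative
    (fraction of the window during which any channel is open) is returned
    instead.
    """
    w = _windowed(ideal, window_s, start_s)
    tc = w.time_at_level(0)
    if strict_time_fraction:
        return (w.duration_s - tc) / w.duration_s
    to = level_weighted_open_time(w)
    if to + tc == 0:
        raise ValueError("empty window")
    return to / (to + tc)


def normalize_popen(values: np.ndarray | list[float]) -> tuple[np.ndarray, bool]:
    """Normalise a voltage series of open probabilities to its maximum.

    Returns (normalised array, all_zero flag).  An all-zero series is
    returned unchanged with the flag set rather than dividing 0/0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    if np.any(v < 0):
        raise ValueError("open probabilities cannot be negative")
    m = v.max()
    if m == 0:
        return v.copy(), True
    return v / m, False


def fit_iv(
    voltages_mv: np.ndarray,
    currents_pa: np.ndarray,
    fit_range_mv: tuple[float, float] | None = None,
) -> IVCurve:
    """Ordinary least-squares line through unitary i-V points.

    The slope in pA/mV converted by 10^3 gives the chord conductance in
    pS.  ``fit_range_mv`` restricts the fit to one limb, e.g. (0, 100)
    for the outward limb of a rectifying channel.
    """
    v = np.asarray(voltages_mv, dtype=float)
    i = np.asarray(currents_pa, dtype=float)
    if v.shape != i.shape:
        raise ValueError("voltage and current arrays must match")
    mask = np.isfinite(v) & np.isfinite(i)
    if fit_range_mv is not None:
        lo, hi = fit_range_mv
        mask &= (v >= lo) & (v <= hi)
    vf, cf = v[mask], i[mask]
    if np.unique(vf).size < 2:
        raise ValueError("need at least two distinct voltages inside the fit range")
    design = np.column_stack([vf, np.ones_like(vf)])
    coef, *_ = np.linalg.lstsq(design, cf, rcond=None)
    slope_pa_per_mv, intercept = coef
    return IVCurve(
        voltages_mv=v,
        currents_pa=i,
        slope_ps=float(slope_pa_per_mv * 1e3),
        intercept_pa=float(intercept),
        fit_range_mv=fit_range_mv if fit_range_mv is not None else (float(vf.min()), float(vf.max())),
    )


def conductance(iv: IVCurve, fit_range_mv: tuple[float, float] | None = None) -> float:
    """Slope conductance in pS from an I-V relation (refitting if a range
    is given or the curve has not been fitted yet)."""
    if fit_range_mv is not None or iv.slope_ps is None:
        iv2 = fit_iv(iv.voltages_mv, iv.currents_pa, fit_range_mv=fit_range_mv)
        return float(iv2.slope_ps)
    return float(iv.slope_ps)
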