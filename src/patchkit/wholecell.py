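"""Whole-cell step/ramp analysis: peak currents, current density,
activation time constant, and ramp reversal potential.

The activation kinetics are quantified with the standard monoexponential

    Y(t) = Y0 + A exp(-t / tau)

fitted over a window that excludes the capacitive transient at the step
edge; tau is reported in ms.
"""

from __future__ import annotations

import numpy as np
import lmfit

from .models import ActivationFit, IVCurve, StepFamily, Trace

__all__ = [
    "max_current_per_step",
    "current_density",
    "density_curve",
    "fit_activation_tau",
    "reversal_potential",
    "ReversalOutOfRange",
]

BLANK_MS = 2.0  # capacitive-transient blanking at each step edge


def max_current_per_step(
    family: StepFamily,
    blank_ms: float = BLANK_MS,
) -> IVCurve:
    """Per-step extremum current: the sample of largest magnitude inside the
    step window (sign preserved), after blanking ``blank_ms`` at each edge.

    Outward (depolarising) steps therefore report their maximum and inward
    steps their minimum, matching how maximum current amplitudes are read
    off a step family.
    """
    t0, t1 = family.protocol.step_window_s()
    fs = family.sampling_rate_hz
    expected = set(np.round(family.protocol.step_voltages(), 6))
    have = set(np.round(family.voltages(), 6))
    missing = sorted(expected - have)
    if missing:
        raise ValueError(f"missing voltage levels in the family: {missing}")

    voltages, peaks = [], []
    for v in sorted(family.traces):
        trace = family.traces[v]
        a = int(round((t0 + blank_ms * 1e-3) * fs))
        b = int(round((t1 - blank_ms * 1e-3) * fs))
        seg = trace.samples[a:b]
        if seg.size == 0:
            raise ValueError(f"step window empty after blanking at {v} mV")
        peak = seg[np.argmax(np.abs(seg))]
        voltages.append(v)
        peaks.append(float(peak))
    return IVCurve(voltages_mv=np.array(voltages), currents_pa=np.array(peaks))


def current_density(current_pa: float | np.ndarray, capacitance_pf: float):
    """Current density I / Cm in pA/pF (sign preserved)."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return current_pa / capacitance_pf


def density_curve(family: StepFamily, blank_ms: float = BLANK_MS) -> IVCurve:
    """Current-density I-V: the peak-current curve scaled by 1/Cm."""
    iv = max_current_per_step(family, blank_ms=blank_ms)
    return IVCurve(
        voltages_mv=iv.voltages_mv,
        currents_pa=current_density(iv.currents_pa, family.capacitance_pf),
    )


def fit_activation_tau(
    trace: Trace,
    window_s: tuple[float, float],
    min_amplitude_pa: float = 1e-9,
) -> ActivationFit:
    """Fit Y(t) = Y0 + A exp(-t/tau) to a current segment; tau in ms.

    t is measured from the start of the window.  A flat segment (|A| below
    ``min_amplitude_pa``) makes tau unidentifiable; the fit is returned
    flagged rather than raising.  A tau pinned at the parameter bounds is
    flagged as well.
    """
    t0, t1 = window_s
    if not (0 <= t0 < t1 <= trace.duration_s + 1e-12):
        raise ValueError("fit window must lie inside the trace")
    fs = trace.sampling_rate_hz
    a, b = int(round(t0 * fs)), int(round(t1 * fs))
    y = trace.samples[a:b]
    if y.size < 10:
        raise ValueError(f"need at least 10 samples in the window, got {y.size}")
    t = np.arange(y.size) / fs

    y0_init = float(y[-max(3, y.size // 10):].mean())  # plateau
    a_init = float(y[0] - y0_init)
    if abs(a_init) < min_amplitude_pa and np.ptp(y) < 10 * min_amplitude_pa:
        return ActivationFit(
            y0_pa=y0_init, amplitude_pa=0.0, tau_ms=np.nan,
            window_s=window_s, converged=False,
            message="segment is flat: amplitude ~ 0, tau unidentifiable",
            flags=["flat_segment"],
        )

    # log-linear initial tau from the early decaying part
    resid0 = (y - y0_init) * np.sign(a_init)
    good = resid0 > max(resid0.max() * 1e-3, 1e-12)
    if good.sum() >= 2:
        slope = np.polyfit(t[good], np.log(resid0[good]), 1)[0]
        tau_init = -1.0 / slope if slope < 0 else (t1 - t0) / 3
    else:
        tau_init = (t1 - t0) / 3
    tau_init = min(max(tau_init, t[1] * 0.1), (t1 - t0) * 10)

    params = lmfit.Parameters()
    params.add("y0", value=y0_init)
    params.add("amp", value=a_init)
    params.add("tau", value=tau_init, min=t[1] * 1e-4, max=(t1 - t0) * 1e3)

    def resid(p):
        return p["y0"].value + p["amp"].value * np.exp(-t / p["tau"].value) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    tau_s = float(out.params["tau"].value)
    flags = []
    if not out.success:
        flags.append("non_convergence")
    lo, hi = out.params["tau"].min, out.params["tau"].max
    if tau_s <= lo * 1.001 or tau_s >= hi * 0.999:
        flags.append("tau_at_bounds")
    return ActivationFit(
        y0_pa=float(out.params["y0"].value),
        amplitude_pa=float(out.params["amp"].value),
        tau_ms=tau_s * 1e3,
        window_s=window_s,
        converged=bool(out.success) and "tau_at_bounds" not in flags,
        message=str(out.message),
        flags=flags,
    )


class ReversalOutOfRange(ValueError):
    """The ramp current never crosses zero inside the voltage range."""


def reversal_potential(
    ramp: Trace,
    smooth_mv: float = 1.0,
) -> tuple[float, bool]:
    """Zero-current crossing of a voltage-ramp sweep, in mV.

    The I-V from the ramp is boxcar-smoothed over ``smooth_mv`` before the
    sign-change scan; the crossing is located by linear interpolation.
    Returns (V_rev, multiple_crossings); when several crossings exist the
    one nearest 0 mV is reported and the flag is set.
    """
    v = ramp.command_voltage_mv
    if np.isscalar(v):
        raise ValueError("ramp trace needs a per-sample command voltage")
    v = np.asarray(v, dtype=float)
    i = ramp.samples
    order = np.argsort(v, kind="stable")
    v, i = v[order], i[order]

    if smooth_mv > 0 and v.size > 2:
        dv = np.median(np.diff(v))
        w = max(int(round(smooth_mv / dv)), 1) if dv > 0 else 1
        if w > 1:
            kernel = np.ones(w) / w
            i = np.convolve(i, kernel, mode="same")

    s = np.sign(i)
    nz = s != 0
    crossings = []
    idx = np.flatnonzero(np.diff(s[nz]) != 0)
    vi, ii = v[nz], i[nz]
    for k in idx:
        v0, v1 = vi[k], vi[k + 1]
        i0, i1 = ii[k], ii[k + 1]
        crossings.append(v0 - i0 * (v1 - v0) / (i1 - i0))
    # exact zeros count as crossings too
    crossings.extend(v[~nz].tolist())
    if not crossings:
        raise ReversalOutOfRange(
            f"current never crosses zero between {v.min():.1f} and {v.max():.1f} mV"
        )
    crossings = sorted(set(np.round(crossings, 9)))
    best = min(crossings, key=abs)
    return float(best), len(crossings) > 1
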