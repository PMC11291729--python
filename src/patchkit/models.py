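"""Core data containers for patch-clamp traces, gating models and protocols.

Units convention (used throughout the package): current in pA, voltage in
mV, conductance in pS, time in s unless a field name says ms, capacitance
in pF. Outward (positive-voltage-driven) current is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ChannelModel",
    "AcquisitionSpec",
    "VoltageProtocol",
    "Trace",
    "IdealizedTrace",
    "AmplitudeHistogram",
    "GaussianComponent",
    "GaussianMixtureFit",
    "OpenProbabilityResult",
    "IVCurve",
    "StepFamily",
    "ActivationFit",
]


@dataclass
class ChannelModel:
    """A continuous-time Markov gating scheme for N identical channels.

    Parameters
    ----------
    state_levels
        Integer conductance level of each state; 0 means non-conducting
        (closed), 1 a fully open channel, and larger values sublevel-free
        multiples of the unitary current.
    rates
        (n_states, n_states) array of transition rates in 1/s at 0 mV.
        Off-diagonal entries are the rates; the diagonal is ignored (the
        generator diagonal is derived so each row sums to zero).
    v_slopes
        Optional (n_states, n_states) array of exponential voltage slopes
        in mV: rate(V) = rates * exp(V / v_slope).  ``inf`` (the default)
        makes a transition voltage independent.
    conductance_ps
        Unitary (single-level) conductance G in pS.
    reversal_mv
        Reversal potential V_rev in mV.
    n_channels
        Number of independent identical channels in the patch (N >= 1).
    """

    state_levels: tuple[int, ...]
    rates: np.ndarray
    v_slopes: np.ndarray | None = None
    conductance_ps: float = 96.5
    reversal_mv: float = 0.0
    n_channels: int = 1
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.state_levels = tuple(int(v) for v in self.state_levels)
        self.rates = np.asarray(self.rates, dtype=float)
        n = len(self.state_levels)
        if self.rates.shape != (n, n):
            raise ValueError(
                f"rates must be ({n}, {n}) to match state_levels, got {self.rates.shape}"
            )
        off = self.rates[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("transition rates must be finite")
        if np.any(off < 0):
            raise ValueError("transition rates must be non-negative")
        if self.v_slopes is not None:
            self.v_slopes = np.asarray(self.v_slopes, dtype=float)
            if self.v_slopes.shape != (n, n):
                raise ValueError("v_slopes must match the rates shape")
            if np.any(self.v_slopes == 0):
                raise ValueError("v_slopes must be nonzero (use inf for no dependence)")
        if any(lv < 0 for lv in self.state_levels):
            raise ValueError("conductance levels must be >= 0")
        if not (self.conductance_ps > 0):
            raise ValueError("conductance must be positive")
        if int(self.n_channels) < 1:
            raise ValueError("n_channels must be >= 1")
        self.n_channels = int(self.n_channels)
        if self.labels is None:
            self.labels = tuple(
                ("C" if lv == 0 else "O") + str(i) for i, lv in enumerate(self.state_levels)
            )

    @property
    def n_states(self) -> int:
        return len(self.state_levels)

    @property
    def max_level(self) -> int:
        return max(self.state_levels)

    def rate_matrix(self, voltage_mv: float) -> np.ndarray:
        """Off-diagonal transition rates (1/s) at a command voltage."""
        r = self.rates.copy()
        np.fill_diagonal(r, 0.0)
        if self.v_slopes is not None:
            with np.errstate(over="raise"):
                factor = np.exp(voltage_mv / self.v_slopes)
            r = r * factor
        return r

    def generator(self, voltage_mv: float) -> np.ndarray:
        """Infinitesimal generator Q at a voltage; rows sum to zero."""
        q = self.rate_matrix(voltage_mv)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def unitary_current_pa(self, voltage_mv: float) -> float:
        """Ohmic single-level current i = G (V - V_rev), in pA."""
        return self.conductance_ps * (voltage_mv - self.reversal_mv) * 1e-3

    def stationary_distribution(self, voltage_mv: float) -> np.ndarray:
        q = self.generator(voltage_mv)
        n = self.n_states
        if n == 1:
            return np.ones(1)
        # solve pi Q = 0 with sum(pi) = 1 via least squares
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


def two_state_model(
    opening_rate: float = 50.0,
    closing_rate: float = 50.0,
    conductance_ps: float = 96.5,
    reversal_mv: float = 0.0,
    n_channels: int = 1,
    opening_v_slope_mv: float | None = None,
) -> ChannelModel:
    """Convenience C <-> O scheme, optionally with a voltage-dependent
    opening rate beta(V) = beta0 * exp(V / slope)."""
    rates = np.array([[0.0, opening_rate], [closing_rate, 0.0]])
    v_slopes = None
    if opening_v_slope_mv is not None:
        v_slopes = np.full((2, 2), np.inf)
        v_slopes[0, 1] = opening_v_slope_mv
    return ChannelModel(
        state_levels=(0, 1),
        rates=rates,
        v_slopes=v_slopes,
        conductance_ps=conductance_ps,
        reversal_mv=reversal_mv,
        n_channels=n_channels,
        labels=("C", "O"),
    )


@dataclass(frozen=True)
class AcquisitionSpec:
    """Digitization settings mirroring a patch amplifier + digitizer chain.

    Defaults follow common practice for ciliary single-channel work:
    5 kHz low-pass, 10 kHz sampling.  ``filter_cutoff_hz=None`` disables
    filtering (useful for exact round trips).
    """

    sampling_rate_hz: float = 10_000.0
    filter_cutoff_hz: float | None = 5_000.0
    noise_sd_pa: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.filter_cutoff_hz is not None:
            if self.filter_cutoff_hz <= 0:
                raise ValueError("filter cutoff must be positive or None")
            if self.sampling_rate_hz < 2 * self.filter_cutoff_hz:
                raise ValueError("sampling rate must be >= 2 x filter cutoff (Nyquist)")
        if self.noise_sd_pa < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class VoltageProtocol:
    """Command-voltage protocol: a step family, a ramp, or a hold.

    Step defaults reproduce the standard whole-cell protocol used for
    outwardly rectifying polycystin currents: steps from -100 to +180 mV
    in 20 mV increments, 150 ms per step, 0 mV holding, -80 mV tail.
    """

    kind: str = "step"
    start_mv: float = -100.0
    stop_mv: float = 180.0
    increment_mv: float = 20.0
    step_ms: float = 150.0
    holding_mv: float = 0.0
    tail_mv: float = -80.0
    holding_ms: float = 10.0
    tail_ms: float = 20.0
    ramp_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "hold"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "step":
            if self.increment_mv <= 0:
                raise ValueError("increment must be positive")
            span = self.stop_mv - self.start_mv
            k = span / self.increment_mv
            if abs(k - round(k)) > 1e-9:
                raise ValueError("increment must divide (stop - start)")
            if min(self.step_ms, self.holding_ms, self.tail_ms) < 0 or self.step_ms <= 0:
                raise ValueError("durations must be positive")
        if self.kind == "ramp" and self.ramp_ms <= 0:
            raise ValueError("ramp duration must be positive")

    def step_voltages(self) -> np.ndarray:
        if self.kind != "step":
            raise ValueError("step_voltages only defined for step protocols")
        n = int(round((self.stop_mv - self.start_mv) / self.increment_mv)) + 1
        return self.start_mv + self.increment_mv * np.arange(n)

    def step_window_s(self) -> tuple[float, float]:
        """(start, end) of the voltage step inside each sweep, in s."""
        t0 = self.holding_ms * 1e-3
        return t0, t0 + self.step_ms * 1e-3

    def sweep_duration_s(self) -> float:
        if self.kind == "step":
            return (self.holding_ms + self.step_ms + self.tail_ms) * 1e-3
        if self.kind == "ramp":
            return self.ramp_ms * 1e-3
        raise ValueError("hold protocols have no fixed duration")

    def ramp_voltage(self, t: np.ndarray) -> np.ndarray:
        if self.kind != "ramp":
            raise ValueError("ramp_voltage only defined for ramp protocols")
        frac = np.clip(t / (self.ramp_ms * 1e-3), 0.0, 1.0)
        return self.start_mv + frac * (self.stop_mv - self.start_mv)


@dataclass
class Trace:
    """A sampled current sweep with its acquisition metadata."""

    samples: np.ndarray          # current, pA
    sampling_rate_hz: float
    command_voltage_mv: float | np.ndarray = 0.0
    capacitance_pf: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if isinstance(self.command_voltage_mv, np.ndarray):
            if self.command_voltage_mv.shape != self.samples.shape:
                raise ValueError("per-sample command voltage must match sample count")
        if self.capacitance_pf is not None and self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


@dataclass
class IdealizedTrace:
    """Piecewise-constant level sequence with dwell durations (seconds).

    Consecutive entries always differ in level; constructing one with
    equal neighbours merges them.  Dwell durations sum to the total
    duration exactly.
    """

    levels: np.ndarray
    durations: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        durations = np.asarray(self.durations, dtype=float)
        if levels.shape != durations.shape or levels.ndim != 1:
            raise ValueError("levels and durations must be matching 1-D arrays")
        if levels.size == 0:
            raise ValueError("idealized trace must contain at least one dwell")
        if np.any(durations <= 0):
            raise ValueError("dwell durations must be positive")
        if np.any(levels < 0):
            raise ValueError("levels must be >= 0")
        # merge runs of equal level so the invariant holds by construction
        if np.any(np.diff(levels) == 0):
            keep = np.concatenate(([True], np.diff(levels) != 0))
            idx = np.cumsum(keep) - 1
            merged = np.zeros(keep.sum())
            np.add.at(merged, idx, durations)
            levels = levels[keep]
            durations = merged
        self.levels = levels
        self.durations = durations

    @property
    def duration_s(self) -> float:
        return float(self.durations.sum())

    @property
    def max_level(self) -> int:
        return int(self.levels.max())

    def time_at_level(self, level: int) -> float:
        return float(self.durations[self.levels == level].sum())

    def level_times(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for lv in np.unique(self.levels):
            out[int(lv)] = self.time_at_level(int(lv))
        return out

    def window(self, start_s: float, length_s: float) -> "IdealizedTrace":
        """Slice out [start, start+length), splitting dwells at the edges."""
        end_s = start_s + length_s
        if start_s < -1e-12 or end_s > self.duration_s + 1e-9:
            raise ValueError(
                f"window [{start_s}, {end_s}) s exceeds trace duration {self.duration_s} s"
            )
        edges = np.concatenate(([0.0], np.cumsum(self.durations)))
        lv_out, du_out = [], []
        for lv, a, b in zip(self.levels, edges[:-1], edges[1:]):
            lo, hi = max(a, start_s), min(b, end_s)
            if hi - lo > 0:
                lv_out.append(lv)
                du_out.append(hi - lo)
        return IdealizedTrace(np.array(lv_out), np.array(du_out), meta=dict(self.meta))

    def sample(self, sampling_rate_hz: float) -> np.ndarray:
        """Level in each sample interval, read at the interval midpoint
        (k + 1/2)/fs — unambiguous when dwell edges sit on sample edges."""
        n = int(round(self.duration_s * sampling_rate_hz))
        t = (np.arange(n) + 0.5) / sampling_rate_hz
        edges = np.cumsum(self.durations)
        idx = np.searchsorted(edges, t, side="right")
        idx = np.clip(idx, 0, self.levels.size - 1)
        return self.levels[idx]


@dataclass
class AmplitudeHistogram:
    """All-points amplitude histogram of a current sweep."""

    bin_edges: np.ndarray
    counts: np.ndarray
    voltage_mv: float | None = None
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.n_samples == 0:
            self.n_samples = int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def density(self) -> np.ndarray:
        """Counts normalised to a probability density (1/pA)."""
        return self.counts / (self.n_samples * np.diff(self.bin_edges))


@dataclass(frozen=True)
class GaussianComponent:
    area: float     # fractional area weight A_i (density scale)
    mu: float       # mean, pA
    sigma: float    # SD, pA


@dataclass
class GaussianMixtureFit:
    """Least-squares Gaussian mixture fitted to an amplitude histogram.

    ``components`` are ordered by increasing mean.  ``offset`` is the
    constant density offset C.  ``redchi`` is the reduced chi-square of
    the fit; ``converged`` is False when the optimiser failed and the
    parameters should not be trusted.
    """

    components: list[GaussianComponent]
    offset: float
    converged: bool
    redchi: float
    message: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.components = sorted(self.components, key=lambda c: c.mu)
        for c in self.components:
            if c.sigma <= 0:
                raise ValueError("component sigma must be positive")
            if c.area < 0:
                raise ValueError("component area must be >= 0")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c.sigma for c in self.components])

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.offset)
        for c in self.components:
            y = y + c.area * np.exp(-((x - c.mu) ** 2) / (2 * c.sigma**2)) / (
                c.sigma * np.sqrt(2 * np.pi)
            )
        return y


@dataclass
class OpenProbabilityResult:
    """Open-probability statistics over an analysis window."""

    popen: float
    npo: float
    open_time_s: float     # level-weighted To
    closed_time_s: float   # fully-closed Tc
    total_time_s: float
    n_channels: int
    voltage_mv: float | None = None
    window: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.popen <= 1 + 1e-12):
            raise ValueError(f"Popen out of [0, 1]: {self.popen}")
        self.popen = float(min(max(self.popen, 0.0), 1.0))


@dataclass
class IVCurve:
    """Unitary or macroscopic current-voltage relation with a linear fit."""

    voltages_mv: np.ndarray
    currents_pa: np.ndarray
    se_pa: np.ndarray | None = None
    n_per_point: np.ndarray | None = None
    slope_ps: float | None = None
    intercept_pa: float | None = None
    fit_range_mv: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if self.voltages_mv.shape != self.currents_pa.shape:
            raise ValueError("voltages and currents must match in shape")


@dataclass
class StepFamily:
    """A whole-cell step-protocol recording: one sweep per command voltage."""

    traces: dict[float, Trace]
    capacitance_pf: float
    protocol: VoltageProtocol

    def __post_init__(self) -> None:
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        rates = {t.sampling_rate_hz for t in self.traces.values()}
        if len(rates) > 1:
            raise ValueError("all sweeps in a family must share a sampling rate")

    @property
    def sampling_rate_hz(self) -> float:
        return next(iter(self.traces.values())).sampling_rate_hz

    def voltages(self) -> np.ndarray:
        return np.array(sorted(self.traces))


@dataclass
class ActivationFit:
    """Monoexponential activation fit Y(t) = Y0 + A exp(-t/tau)."""

    y0_pa: float
    amplitude_pa: float
    tau_ms: float
    window_s: tuple[float, float]
    converged: bool
    message: str = ""
    flags: list[str] = field(default_factory=list)
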