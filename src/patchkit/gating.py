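"""Stochastic channel-gating and whole-cell current simulation.

Single-channel gating is sampled as an exact continuous-time Markov chain
(event-driven Gillespie algorithm) for each of N independent channels,
then summed into an aggregate conductance-level path.  Currents are
rendered ohmically, i = G (V - V_rev) / 10^3 pA with G in pS and V in mV,
with additive Gaussian baseline noise followed by Bessel low-pass
filtering to mimic the amplifier chain.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .models import (
    AcquisitionSpec,
    ChannelModel,
    IdealizedTrace,
    StepFamily,
    Trace,
    VoltageProtocol,
)

__all__ = [
    "simulate_gating",
    "render_current",
    "simulate_patch",
    "simulate_whole_cell",
    "steady_state_current",
]


def _single_channel_path(
    q_off: np.ndarray,
    exit_rates: np.ndarray,
    levels: np.ndarray,
    start_state: int,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Event times and levels of one channel's sample path on [0, duration].

    Returns (times, path_levels) where times[k] is when the level switches
    to path_levels[k]; times[0] == 0.
    """
    times = [0.0]
    states = [start_state]
    t = 0.0
    s = start_state
    while True:
        rate = exit_rates[s]
        if rate <= 0.0:  # absorbing (only legal for one-state models)
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        # next state with probability proportional to q_off[s, :]
        p = q_off[s] / rate
        s = int(rng.choice(len(p), p=p))
        times.append(t)
        states.append(s)
    return np.asarray(times), levels[np.asarray(states, dtype=int)]


def simulate_gating(
    model: ChannelModel,
    voltage_mv: float,
    duration_s: float,
    seed: int | np.random.SeedSequence = 0,
    start_states: np.ndarray | None = None,
) -> IdealizedTrace:
    """Exact CTMC sample path of a patch at a fixed command voltage.

    Each of the model's ``n_channels`` gates independently; their per-channel
    conductance levels are summed into one aggregate piecewise-constant
    level sequence whose dwell durations add up to ``duration_s`` exactly.

    Channels start from the stationary distribution at the given voltage
    unless ``start_states`` fixes the initial state of every channel.
    Reproducible: a fixed seed expands deterministically into independent
    per-channel streams.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    q_off = model.rate_matrix(voltage_mv)
    if not np.all(np.isfinite(q_off)):
        raise ValueError("non-finite transition rates at this voltage")
    exit_rates = q_off.sum(axis=1)
    if model.n_states > 1 and np.any(exit_rates <= 0):
        dead = [model.labels[i] for i in np.flatnonzero(exit_rates <= 0)]
        raise ValueError(f"absorbing state(s) with no escape: {dead}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(model.n_channels + 1)
    init_rng = np.random.default_rng(child_seeds[0])
    levels = np.asarray(model.state_levels)

    if start_states is None:
        pi = model.stationary_distribution(voltage_mv)
        start = init_rng.choice(model.n_states, size=model.n_channels, p=pi)
    else:
        start = np.asarray(start_states, dtype=int)
        if start.size != model.n_channels:
            raise ValueError("start_states must give one state per channel")

    # merge per-channel event paths into the aggregate level path
    all_times = [np.array([0.0])]
    deltas = []
    agg0 = 0
    for c in range(model.n_channels):
        rng = np.random.default_rng(child_seeds[c + 1])
        times, lv = _single_channel_path(
            q_off, exit_rates, levels, int(start[c]), duration_s, rng
        )
        agg0 += lv[0]
        if times.size > 1:
            all_times.append(times[1:])
            deltas.append(np.diff(lv))

    if deltas:
        ev_t = np.concatenate(all_times[1:])
        ev_d = np.concatenate(deltas)
        order = np.argsort(ev_t, kind="stable")
        ev_t, ev_d = ev_t[order], ev_d[order]
        edge_t = np.concatenate(([0.0], ev_t, [duration_s]))
        path = agg0 + np.concatenate(([0], np.cumsum(ev_d)))
    else:
        edge_t = np.array([0.0, duration_s])
        path = np.array([agg0])

    durations = np.diff(edge_t)
    keep = durations > 0  # simultaneous events have measure zero but guard anyway
    return IdealizedTrace(
        levels=path[keep],
        durations=durations[keep],
        meta={
            "voltage_mv": voltage_mv,
            "seed": int(ss.entropy) if start_states is None else None,
            "n_channels": model.n_channels,
        },
    )


def _bessel_lowpass(x: np.ndarray, cutoff_hz: float, fs_hz: float) -> np.ndarray:
    """4-pole Bessel low-pass, applied causally like an amplifier filter."""
    wn = cutoff_hz / (fs_hz / 2.0)
    if wn >= 1.0:
        return x
    sos = signal.bessel(4, wn, btype="low", norm="mag", output="sos")
    return signal.sosfilt(sos, x)


def render_current(
    ideal: IdealizedTrace,
    model: ChannelModel,
    voltage_mv: float,
    acq: AcquisitionSpec,
    apply_filter: bool = True,
) -> Trace:
    """Render an idealized level path into a sampled noisy current sweep.

    samples = level(t) * i_unitary + Gaussian noise, then low-pass
    filtered at ``acq.filter_cutoff_hz``.  With ``noise_sd_pa=0`` and
    filtering disabled the samples equal level * i_unitary exactly.
    """
    if ideal.max_level > model.n_channels * model.max_level:
        raise ValueError("idealized levels exceed what the model can produce")
    i_unit = model.unitary_current_pa(voltage_mv)
    lv = ideal.sample(acq.sampling_rate_hz)
    samples = lv * i_unit
    if acq.noise_sd_pa > 0:
        rng = np.random.default_rng(np.random.SeedSequence(acq.seed).spawn(1)[0])
        samples = samples + rng.normal(0.0, acq.noise_sd_pa, size=samples.size)
    if apply_filter and acq.filter_cutoff_hz is not None:
        samples = _bessel_lowpass(samples, acq.filter_cutoff_hz, acq.sampling_rate_hz)
    return Trace(
        samples=samples,
        sampling_rate_hz=acq.sampling_rate_hz,
        command_voltage_mv=voltage_mv,
        meta={
            "unitary_pa": i_unit,
            "noise_sd_pa": acq.noise_sd_pa,
            "filter_cutoff_hz": acq.filter_cutoff_hz if apply_filter else None,
            "seed": acq.seed,
            "true_popen": _true_popen(ideal, model.n_channels),
        },
    )


def _true_popen(ideal: IdealizedTrace, n_channels: int) -> float:
    # level-weighted per-channel Popen of the generating path
    weighted = float((ideal.levels * ideal.durations).sum())
    return weighted / (n_channels * ideal.duration_s)


def simulate_patch(
    model: ChannelModel,
    voltage_mv: float,
    duration_s: float,
    acq: AcquisitionSpec,
    seed: int | None = None,
) -> tuple[Trace, IdealizedTrace]:
    """Gating + rendering in one call; returns the trace and its truth."""
    root = acq.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    gate_ss, noise_ss = ss.spawn(2)
    ideal = simulate_gating(model, voltage_mv, duration_s, seed=gate_ss)
    noise_seed = int(noise_ss.generate_state(1)[0] % (2**31))
    acq_local = AcquisitionSpec(
        sampling_rate_hz=acq.sampling_rate_hz,
        filter_cutoff_hz=acq.filter_cutoff_hz,
        noise_sd_pa=acq.noise_sd_pa,
        seed=noise_seed,
    )
    trace = render_current(ideal, model, voltage_mv, acq_local)
    trace.meta["root_seed"] = root
    return trace, ideal


def steady_state_current(
    voltage_mv: float | np.ndarray,
    max_density_pa_per_pf: float,
    capacitance_pf: float,
    reference_mv: float = 180.0,
    reversal_mv: float = 0.0,
    v_half_mv: float = 60.0,
    v_slope_mv: float = 40.0,
) -> float | np.ndarray:
    """Outwardly rectifying steady-state I-V for the macroscopic simulator.

    I_ss(V) = g(V) (V - V_rev) with a Boltzmann conductance
    g(V) = gmax / (1 + exp(-(V - V_half)/k)), normalised so the current at
    the reference voltage equals max_density * capacitance exactly.
    """
    v = np.asarray(voltage_mv, dtype=float)
    shape = (v - reversal_mv) / (1.0 + np.exp(-(v - v_half_mv) / v_slope_mv))
    ref = (reference_mv - reversal_mv) / (
        1.0 + np.exp(-(reference_mv - v_half_mv) / v_slope_mv)
    )
    out = max_density_pa_per_pf * capacitance_pf * shape / ref
    return float(out) if np.isscalar(voltage_mv) else out


def simulate_whole_cell(
    protocol: VoltageProtocol,
    capacitance_pf: float,
    acq: AcquisitionSpec,
    max_density_pa_per_pf: float = 139.9,
    tau_ms: float = 0.06,
    reversal_mv: float = 0.0,
    reference_mv: float = 180.0,
    v_half_mv: float = 60.0,
    v_slope_mv: float = 40.0,
) -> StepFamily:
    """Macroscopic step-family simulation with monoexponential activation.

    Each step sweep is holding (0 current offset assumed leak-subtracted) ->
    step with I(V, t) = I_ss(V) (1 - exp(-t/tau)) -> tail relaxing toward
    I_ss(V_tail) with the same time constant.  Defaults place the peak
    density at +180 mV at 139.9 pA/pF, the value typical of heteromeric
    polycystin currents activated by intracellular oxysterol.
    """
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    if tau_ms <= 0:
        raise ValueError("activation time constant must be positive")
    if protocol.kind != "step":
        raise ValueError("simulate_whole_cell requires a step protocol")

    fs = acq.sampling_rate_hz
    tau_s = tau_ms * 1e-3
    ss = np.random.SeedSequence(acq.seed)
    traces: dict[float, Trace] = {}

    def iss(v: float) -> float:
        return steady_state_current(
            v, max_density_pa_per_pf, capacitance_pf,
            reference_mv=reference_mv, reversal_mv=reversal_mv,
            v_half_mv=v_half_mv, v_slope_mv=v_slope_mv,
        )

    i_hold = iss(protocol.holding_mv)
    n_hold = int(round(protocol.holding_ms * 1e-3 * fs))
    n_step = int(round(protocol.step_ms * 1e-3 * fs))
    n_tail = int(round(protocol.tail_ms * 1e-3 * fs))
    i_tail_ss = iss(protocol.tail_mv)

    for v, child in zip(protocol.step_voltages(), ss.spawn(len(protocol.step_voltages()))):
        i_ss = iss(float(v))
        t_step = np.arange(n_step) / fs
        step_cur = i_ss + (i_hold - i_ss) * np.exp(-t_step / tau_s)
        i_end = step_cur[-1] if n_step else i_hold
        t_tail = np.arange(n_tail) / fs
        tail_cur = i_tail_ss + (i_end - i_tail_ss) * np.exp(-t_tail / tau_s)
        samples = np.concatenate([np.full(n_hold, i_hold), step_cur, tail_cur])
        if acq.noise_sd_pa > 0:
            rng = np.random.default_rng(child)
            samples = samples + rng.normal(0.0, acq.noise_sd_pa, size=samples.size)
            if acq.filter_cutoff_hz is not None:
                samples = _bessel_lowpass(samples, acq.filter_cutoff_hz, fs)
        traces[float(v)] = Trace(
            samples=samples,
            sampling_rate_hz=fs,
            command_voltage_mv=float(v),
            capacitance_pf=capacitance_pf,
            meta={
                "i_ss_pa": i_ss,
                "tau_ms": tau_ms,
                "seed": acq.seed,
                "step_window_s": protocol.step_window_s(),
            },
        )
    return StepFamily(traces=traces, capacitance_pf=capacitance_pf, protocol=protocol)
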