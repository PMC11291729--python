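"""End-to-end pipeline driver: config -> simulate -> analyse -> tables.

A run is described by a structured config (YAML or dict).  The
single-channel branch simulates (or loads) one sweep per voltage,
builds amplitude histograms, fits the Gaussian mixture, idealizes,
computes Popen/NPo and assembles the unitary i-V with its slope
conductance.  The whole-cell branch simulates a step family and reports
peak currents, current density and the activation time constant.

Every output table carries the config hash and seed in comment lines, and
a ``manifest.json`` records parameters and package version so a run can
be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atf import write_trace, write_traces
from .gating import simulate_patch, simulate_whole_cell
from .models import two_state_model
from .idealize import (
    NoOpeningDetected,
    amplitude_histogram,
    default_dead_time,
    fit_gaussian_mixture,
    idealize_trace,
    unitary_amplitude,
)
from .models import AcquisitionSpec, VoltageProtocol
from .scstats import fit_iv, normalize_popen, npo, popen_multi
from .wholecell import density_curve, fit_activation_tau, max_current_per_step

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


_SC_DEFAULTS = dict(
    conductance_ps=96.5,
    reversal_mv=0.0,
    opening_rate=50.0,
    closing_rate=50.0,
    opening_v_slope_mv=None,
    n_channels=1,
    duration_s=12.0,
    voltages=tuple(range(-100, 101, 20)),
)

_WC_DEFAULTS = dict(
    capacitance_pf=20.0,
    max_density_pa_per_pf=139.9,
    tau_ms=0.06,
    reversal_mv=0.0,
    reference_mv=180.0,
)

_ANALYSIS_DEFAULTS = dict(
    bin_width_pa=None,
    n_components=2,
    dead_time_s=None,
    window_s=10.0,
    window_start_s=0.0,
    n_channels=None,          # default: max observed idealized level
    fit_range_mv=(-100.0, 100.0),
)


@dataclasses.dataclass
class RunConfig:
    mode: str = "single_channel"          # or "whole_cell"
    seed: int = 0
    out_dir: str = "patchkit_run"
    acquisition: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)
    whole_cell: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    write_traces: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("single_channel", "whole_cell"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, defaults, given in [
            ("simulate", _SC_DEFAULTS, self.simulate),
            ("whole_cell", _WC_DEFAULTS, self.whole_cell),
            ("analysis", _ANALYSIS_DEFAULTS, self.analysis),
        ]:
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
        self.simulate = {**_SC_DEFAULTS, **self.simulate}
        self.whole_cell = {**_WC_DEFAULTS, **self.whole_cell}
        self.analysis = {**_ANALYSIS_DEFAULTS, **self.analysis}

    def acquisition_spec(self) -> AcquisitionSpec:
        return AcquisitionSpec(seed=self.seed, **self.acquisition)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return RunConfig(**data)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={cfg.digest()}\n# seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured pipeline; returns a result bundle.

    The bundle maps table names to DataFrames (also written as CSV under
    ``config.out_dir``) plus the run manifest.  Deterministic for a fixed
    config and seed.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(**config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = (
        _run_single_channel(cfg, out)
        if cfg.mode == "single_channel"
        else _run_whole_cell(cfg, out)
    )
    manifest = {
        "package": "patchkit",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "tables": sorted(k for k, v in bundle.items() if isinstance(v, pd.DataFrame)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    bundle["manifest"] = manifest
    return bundle


def _run_single_channel(cfg: RunConfig, out: Path) -> dict:
    sc = cfg.simulate
    an = cfg.analysis
    acq = cfg.acquisition_spec()

    try:
        model = two_state_model(
            opening_rate=sc["opening_rate"],
            closing_rate=sc["closing_rate"],
            conductance_ps=sc["conductance_ps"],
            reversal_mv=sc["reversal_mv"],
            n_channels=sc["n_channels"],
            opening_v_slope_mv=sc["opening_v_slope_mv"],
        )
    except Exception as e:
        raise PipelineError("model", e) from e

    dead = an["dead_time_s"]
    if dead is None:
        dead = default_dead_time(acq.filter_cutoff_hz) if acq.filter_cutoff_hz else 0.0

    ss = np.random.SeedSequence(cfg.seed)
    sweep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(sc["voltages"]))]

    rows_popen, rows_iv, rows_fit, rows_events = [], [], [], []
    for v, sweep_seed in zip(sc["voltages"], sweep_seeds):
        try:
            trace, truth = simulate_patch(model, float(v), sc["duration_s"], acq, seed=sweep_seed)
        except Exception as e:
            raise PipelineError("gating_sim", e) from e
        if cfg.write_traces:
            write_trace(trace, out / f"trace_{int(v):+04d}mV.atf")

        try:
            hist = amplitude_histogram(trace, bin_width_pa=an["bin_width_pa"])
            i_expect = model.unitary_current_pa(float(v))
            if abs(i_expect) < 4 * acq.noise_sd_pa:
                # no resolvable opening at this driving force
                amp = np.nan
                fit = None
            else:
                fit = fit_gaussian_mixture(
                    hist, an["n_components"],
                    init_means=i_expect * np.arange(an["n_components"]),
                )
                amp = unitary_amplitude(fit)
        except NoOpeningDetected:
            amp, fit = np.nan, None
        except Exception as e:
            raise PipelineError("idealize.fit", e) from e

        rows_iv.append({"voltage_mv": v, "unitary_pa": amp})
        if fit is not None:
            for k, c in enumerate(fit.components):
                rows_fit.append(
                    {"voltage_mv": v, "component": k, "area": c.area,
                     "mu_pa": c.mu, "sigma_pa": c.sigma, "offset": fit.offset,
                     "converged": fit.converged, "redchi": fit.redchi}
                )
            try:
                ideal = idealize_trace(trace, fit, dead_time_s=dead)
            except Exception as e:
                raise PipelineError("idealize.trace", e) from e
            t0 = 0.0
            for lv, du in zip(ideal.levels, ideal.durations):
                rows_events.append(
                    {"voltage_mv": v, "level": int(lv), "start_s": t0, "duration_s": du}
                )
                t0 += du
            n_used = an["n_channels"] if an["n_channels"] is not None else max(ideal.max_level, 1)
            try:
                res = popen_multi(
                    ideal, n_used, window_s=an["window_s"], start_s=an["window_start_s"]
                )
                npo_val = npo(ideal, window_s=an["window_s"], start_s=an["window_start_s"])
            except Exception as e:
                raise PipelineError("sc_stats", e) from e
            rows_popen.append(
                {"voltage_mv": v, "popen": res.popen, "npo": npo_val,
                 "open_time_s": res.open_time_s, "closed_time_s": res.closed_time_s,
                 "window_s": res.total_time_s, "n_channels": n_used,
                 "true_popen": trace.meta.get("true_popen")}
            )

    iv_df = pd.DataFrame(rows_iv)
    try:
        lo, hi = an["fit_range_mv"]
        iv = fit_iv(
            iv_df["voltage_mv"].to_numpy(float),
            iv_df["unitary_pa"].to_numpy(float),
            fit_range_mv=(lo, hi),
        )
    except Exception as e:
        raise PipelineError("sc_stats.conductance", e) from e
    iv_df["slope_ps"] = iv.slope_ps
    iv_df["intercept_pa"] = iv.intercept_pa

    popen_df = pd.DataFrame(rows_popen)
    if not popen_df.empty:
        normed, all_zero = normalize_popen(popen_df["popen"].to_numpy())
        popen_df["popen_normalized"] = normed
        popen_df.attrs["all_zero"] = all_zero

    tables = {
        "iv": iv_df,
        "popen": popen_df,
        "mixture_fits": pd.DataFrame(rows_fit),
        "events": pd.DataFrame(rows_events),
    }
    for name, df in tables.items():
        _write_table(df, out / f"{name}.csv", cfg)
    tables["conductance_ps"] = iv.slope_ps
    return tables


def _run_whole_cell(cfg: RunConfig, out: Path) -> dict:
    wc = cfg.whole_cell
    acq = cfg.acquisition_spec()
    protocol = VoltageProtocol(kind="step")
    try:
        family = simulate_whole_cell(
            protocol,
            capacitance_pf=wc["capacitance_pf"],
            acq=acq,
            max_density_pa_per_pf=wc["max_density_pa_per_pf"],
            tau_ms=wc["tau_ms"],
            reversal_mv=wc["reversal_mv"],
            reference_mv=wc["reference_mv"],
        )
    except Exception as e:
        raise PipelineError("gating_sim.whole_cell", e) from e
    if cfg.write_traces:
        write_traces([family.traces[v] for v in sorted(family.traces)], out / "family.atf")

    try:
        iv = max_current_per_step(family)
        dens = density_curve(family)
    except Exception as e:
        raise PipelineError("wc_analysis.iv", e) from e

    t0, t1 = protocol.step_window_s()
    v_ref = wc["reference_mv"]
    try:
        fit = fit_activation_tau(family.traces[v_ref], window_s=(t0, t1))
    except Exception as e:
        raise PipelineError("wc_analysis.tau", e) from e

    iv_df = pd.DataFrame(
        {"voltage_mv": iv.voltages_mv, "i_max_pa": iv.currents_pa,
         "density_pa_per_pf": dens.currents_pa}
    )
    tau_df = pd.DataFrame(
        [{"voltage_mv": v_ref, "tau_ms": fit.tau_ms, "y0_pa": fit.y0_pa,
          "amplitude_pa": fit.amplitude_pa, "converged": fit.converged}]
    )
    tables = {"iv_density": iv_df, "tau": tau_df}
    for name, df in tables.items():
        _write_table(df, out / f"{name}.csv", cfg)
    tables["density_at_reference"] = float(
        dens.currents_pa[np.argmin(np.abs(dens.voltages_mv - v_ref))]
    )
    tables["tau_ms"] = fit.tau_ms
    return tables
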