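"""ATF-style tab-separated trace files.

A human-inspectable dialect of the Axon text format: a magic line, a
header-count line, quoted ``key=value`` header records, a quoted
column-title line with units in parentheses, then tab-separated data.
One time column, an optional per-sample command column, and one current
column per sweep::

    ATF\t1.0
    4\t3
    "SamplingRateHz=10000"
    "FilterCutoffHz=5000"
    "NoiseSD_pA=0.25"
    "Seed=7"
    "Time (s)"\t"Command (mV)"\t"Trace #1 (pA)"
    0.0000\t100.0\t0.0132
    ...
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .models import Trace

__all__ = ["read_trace", "read_traces", "write_trace", "write_traces", "TraceFileError"]

_MAGIC = "ATF\t1.0"
_RATE_TOL_PPM = 1.0

_HEADER_FLOATS = {
    "SamplingRateHz": "sampling_rate_hz",
    "FilterCutoffHz": "filter_cutoff_hz",
    "NoiseSD_pA": "noise_sd_pa",
    "CapacitancePF": "capacitance_pf",
    "CommandMV": "command_mv",
    "Seed": "seed",
}


class TraceFileError(ValueError):
    """Malformed, truncated or unit-inconsistent trace file."""


def _fmt_header_value(v) -> str:
    return f"{v:.12g}" if isinstance(v, float) else str(v)


def write_traces(traces: list[Trace], path: str | Path) -> None:
    """Write one or more sweeps that share a time base to an ATF-style file."""
    if not traces:
        raise ValueError("nothing to write")
    fs = traces[0].sampling_rate_hz
    n = traces[0].n_samples
    for t in traces:
        if t.sampling_rate_hz != fs or t.n_samples != n:
            raise ValueError("all sweeps in one file must share time base and length")

    per_sample_v = isinstance(traces[0].command_voltage_mv, np.ndarray)
    header: dict[str, object] = {"SamplingRateHz": float(fs)}
    meta = traces[0].meta
    if meta.get("filter_cutoff_hz") is not None:
        header["FilterCutoffHz"] = float(meta["filter_cutoff_hz"])
    if meta.get("noise_sd_pa") is not None:
        header["NoiseSD_pA"] = float(meta["noise_sd_pa"])
    if traces[0].capacitance_pf is not None:
        header["CapacitancePF"] = float(traces[0].capacitance_pf)
    for key in ("seed", "root_seed"):
        if meta.get(key) is not None:
            header["Seed"] = int(meta[key])
            break
    if not per_sample_v and len(traces) == 1:
        header["CommandMV"] = float(traces[0].command_voltage_mv)

    titles = ['"Time (s)"']
    if per_sample_v:
        titles.append('"Command (mV)"')
    if len(traces) == 1 and not per_sample_v:
        titles.append('"Current (pA)"')
    else:
        for k, t in enumerate(traces, start=1):
            label = f"Trace #{k}"
            if not per_sample_v:
                label += f" @{_fmt_header_value(float(t.command_voltage_mv))}mV"
            titles.append(f'"{label} (pA)"')

    cols = [np.arange(n) / fs]
    if per_sample_v:
        cols.append(np.asarray(traces[0].command_voltage_mv, dtype=float))
    cols.extend(t.samples for t in traces)
    data = np.column_stack(cols)

    buf = io.StringIO()
    buf.write(_MAGIC + "\n")
    buf.write(f"{len(header)}\t{len(titles)}\n")
    for k, v in header.items():
        buf.write(f'"{k}={_fmt_header_value(v)}"\n')
    buf.write("\t".join(titles) + "\n")
    np.savetxt(buf, data, fmt="%.9g", delimiter="\t")
    Path(path).write_text(buf.getvalue())


def write_trace(trace: Trace, path: str | Path) -> None:
    write_traces([trace], path)


def _parse_title(title: str) -> tuple[str, str]:
    title = title.strip().strip('"')
    if "(" not in title or not title.endswith(")"):
        raise TraceFileError(f"column title {title!r} lacks a unit in parentheses")
    name, unit = title.rsplit("(", 1)
    return name.strip(), unit[:-1].strip()


def read_traces(path: str | Path) -> list[Trace]:
    """Read an ATF-style file; returns one Trace per current column."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3 or lines[0] != _MAGIC:
        raise TraceFileError(f"{path}: not an ATF-style trace file")
    try:
        n_header, n_cols = (int(x) for x in lines[1].split("\t"))
    except ValueError as e:
        raise TraceFileError(f"{path}: malformed header-count line") from e
    if len(lines) < 2 + n_header + 1:
        raise TraceFileError(f"{path}: truncated header")

    header: dict[str, float] = {}
    for raw in lines[2 : 2 + n_header]:
        rec = raw.strip().strip('"')
        if "=" not in rec:
            raise TraceFileError(f"{path}: malformed header record {raw!r}")
        k, v = rec.split("=", 1)
        if k in _HEADER_FLOATS:
            header[_HEADER_FLOATS[k]] = float(v)

    if "sampling_rate_hz" not in header:
        raise TraceFileError(f"{path}: header lacks SamplingRateHz")
    fs = header["sampling_rate_hz"]

    titles = lines[2 + n_header].split("\t")
    if len(titles) != n_cols:
        raise TraceFileError(
            f"{path}: declared {n_cols} columns but title line has {len(titles)}"
        )
    parsed = [_parse_title(t) for t in titles]
    if parsed[0][1] != "s":
        raise TraceFileError(f"{path}: first column must be time in s, got {parsed[0][1]!r}")
    cmd_col = None
    current_cols = []
    for j, (name, unit) in enumerate(parsed[1:], start=1):
        if name.lower().startswith("command"):
            if unit != "mV":
                raise TraceFileError(f"{path}: command column must be mV, got {unit!r}")
            cmd_col = j
        else:
            if unit != "pA":
                raise TraceFileError(
                    f"{path}: current column {name!r} must be in pA, got {unit!r}"
                )
            current_cols.append((j, name))
    if not current_cols:
        raise TraceFileError(f"{path}: no current (pA) column found")

    body = [ln for ln in lines[3 + n_header :] if ln.strip()]
    if not body:
        raise TraceFileError(f"{path}: no data rows")
    try:
        data = np.array([[float(x) for x in ln.split("\t")] for ln in body])
    except ValueError as e:
        raise TraceFileError(f"{path}: non-numeric data row") from e
    if data.shape[1] != n_cols:
        raise TraceFileError(
            f"{path}: data row has {data.shape[1]} fields, expected {n_cols} (truncated?)"
        )

    t = data[:, 0]
    if t.size > 1:
        dt = np.diff(t)
        rate_seen = 1.0 / np.median(dt)
        if abs(rate_seen - fs) / fs > _RATE_TOL_PPM * 1e-6:
            raise TraceFileError(
                f"{path}: declared rate {fs} Hz does not match time column "
                f"({rate_seen:.6g} Hz)"
            )

    meta = {k: header[k] for k in ("filter_cutoff_hz", "noise_sd_pa") if k in header}
    if "seed" in header:
        meta["seed"] = int(header["seed"])
    cap = header.get("capacitance_pf")
    command: float | np.ndarray
    traces = []
    for j, name in current_cols:
        if cmd_col is not None:
            command = data[:, cmd_col]
        elif "@" in name:  # per-sweep voltage embedded in the column label
            command = float(name.split("@")[1].rstrip("mV").strip())
        else:
            command = header.get("command_mv", 0.0)
        traces.append(
            Trace(
                samples=data[:, j],
                sampling_rate_hz=fs,
                command_voltage_mv=command,
                capacitance_pf=cap,
                meta=dict(meta, source=str(path), column=name),
            )
        )
    return traces


def read_trace(path: str | Path) -> Trace:
    """Read a single-sweep file (errors if the file holds several sweeps)."""
    traces = read_traces(path)
    if len(traces) != 1:
        raise TraceFileError(f"{path}: expected one sweep, found {len(traces)}")
    return traces[0]
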