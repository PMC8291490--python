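"""Readers and writers: delimited-text traces and event lists, JSON
reports with provenance manifests, and scheme config round trips.

All on-disk formats are plain text. Traces are two-column tab-separated
tables (time_ms, value) with ``#`` metadata lines; event lists carry
(class, duration_ms) columns plus the dead time in the header; analysis
results are flat JSON with a provenance block (inputs, seeds, package
version).
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from .dwells import DwellSequence
from .macroscopic import MacroscopicTrace
from .schemes import KineticScheme

try:
    __version__ = version("gatingkit")
except PackageNotFoundError:  # running from a source tree
    __version__ = "unknown"


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# traces

def write_trace(trace: MacroscopicTrace, path: str | Path) -> None:
    lines = [f"# dt_ms: {float(trace.dt_ms)!r}"]
    if trace.app_window_ms is not None:
        lines.append(
            f"# app_window_ms: {float(trace.app_window_ms[0])!r} "
            f"{float(trace.app_window_ms[1])!r}"
        )
    lines.append("time_ms\tvalue")
    for t, v in zip(trace.times_ms, trace.values):
        lines.append(f"{t:.6g}\t{v:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> MacroscopicTrace:
    raw = Path(path).read_text().splitlines()
    meta = _parse_meta([l for l in raw if l.startswith("#")])
    rows = [l for l in raw if l and not l.startswith("#")]
    if not rows or rows[0].split("\t")[0] != "time_ms":
        raise ValueError(f"{path}: missing 'time_ms\\tvalue' header")
    data = []
    for i, line in enumerate(rows[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed line {i}: {line!r}")
        data.append((float(parts[0]), float(parts[1])))
    t, v = np.array(data).T
    dt = float(meta.get("dt_ms", t[1] - t[0] if len(t) > 1 else 1.0))
    window = None
    if "app_window_ms" in meta:
        a, b = meta["app_window_ms"].split()
        window = (float(a), float(b))
    return MacroscopicTrace(dt_ms=dt, values=v, t0_ms=float(t[0]),
                            app_window_ms=window)


# ---------------------------------------------------------------------------
# event lists

def write_events(seq: DwellSequence, path: str | Path) -> None:
    lines = [f"# t_d_ms: {float(seq.t_d_ms)!r}"]
    for k, v in seq.metadata.items():
        if isinstance(v, (str, int, float)):
            lines.append(f"# {k}: {v}")
    lines.append("class\tduration_ms")
    for c, d in zip(seq.classes, seq.durations_ms):
        lines.append(f"{c}\t{float(d)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_events(path: str | Path) -> DwellSequence:
    raw = Path(path).read_text().splitlines()
    meta = _parse_meta([l for l in raw if l.startswith("#")])
    rows = [l for l in raw if l and not l.startswith("#")]
    if not rows or not rows[0].startswith("class"):
        raise ValueError(f"{path}: missing 'class\\tduration_ms' header")
    classes, durs = [], []
    for i, line in enumerate(rows[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: malformed line {i}: {line!r}")
        classes.append(parts[0])
        durs.append(float(parts[1]))
    if not classes:
        raise ValueError(f"{path}: empty event list")
    t_d = float(meta.pop("t_d_ms", 0.0))
    return DwellSequence(
        classes=np.array(classes, dtype=object),
        durations_ms=np.array(durs), t_d_ms=t_d, metadata=meta,
    )


# ---------------------------------------------------------------------------
# schemes and reports

def read_scheme(path: str | Path) -> KineticScheme:
    return KineticScheme.load(path)


def write_scheme(scheme: KineticScheme, path: str | Path) -> None:
    scheme.save(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(payload: dict, path: str | Path,
                 inputs: list[str] | None = None,
                 seed: int | None = None) -> None:
    """Write a JSON result with a provenance manifest."""
    out = {
        "manifest": {
            "gatingkit_version": __version__,
            "inputs": [str(p) for p in (inputs or [])],
            "seed": seed,
        },
        "result": _jsonable(payload),
    }
    Path(path).write_text(json.dumps(out, indent=2, allow_nan=False) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
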