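"""File formats: DWT-style dwell lists, trace CSV / flat binary, result tables.

Durations are seconds in memory and milliseconds in files (the convention of
the QuB ecosystem's DWT dwell format).  The DWT-style writer emits one
``Segment:`` header per segment followed by tab-separated class index and
duration in ms with 3 decimals (0.001 ms precision); comment lines starting
with ``#`` are allowed anywhere and are used to carry provenance (config
hash) without breaking round trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .idealize import IdealizedEvents
from .simulate import SampledTrace

DWT_PRECISION_MS = 0.001


def write_dwt(
    path: str | Path,
    segments: Sequence[IdealizedEvents] | IdealizedEvents,
    comment: str | None = None,
) -> None:
    """Write dwell segments in DWT-style text (class index, duration in ms)."""
    if isinstance(segments, IdealizedEvents):
        segments = [segments]
    lines: list[str] = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    for i, seg in enumerate(segments, start=1):
        lines.append(f"Segment: {i} Dwells: {len(seg)}")
        for cls, dur in zip(seg.class_codes, seg.durations):
            lines.append(f"{int(cls)}\t{dur * 1e3:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dwt(path: str | Path) -> list[IdealizedEvents]:
    """Read a DWT-style file back into dwell segments (durations in s)."""
    segments: list[IdealizedEvents] = []
    codes: list[int] = []
    durs: list[float] = []

    def flush():
        if codes or durs:
            segments.append(
                IdealizedEvents(
                    class_codes=np.array(codes, dtype=np.int8),
                    durations=np.array(durs) / 1e3,
                    mean_amplitudes=np.full(len(durs), np.nan),
                )
            )
            codes.clear()
            durs.clear()

    in_segment = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("Segment:"):
            parts = line.split()
            if len(parts) < 4 or parts[2] != "Dwells:":
                raise ValueError(f"{path}:{lineno}: malformed segment header {line!r}")
            flush()
            in_segment = True
            continue
        if not in_segment:
            raise ValueError(f"{path}:{lineno}: dwell line before any segment header")
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'class<TAB>duration_ms', got {line!r}")
        try:
            codes.append(int(parts[0]))
            durs.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    flush()
    if not segments and not in_segment:
        # an empty file with only comments/headers is an empty segment list
        return []
    return segments


def write_events_csv(path: str | Path, events: IdealizedEvents, comment: str | None = None) -> None:
    """Richer CSV: class code, duration (ms), mean amplitude (pA)."""
    df = pd.DataFrame(
        {
            "class": events.class_codes.astype(int),
            "duration_ms": events.durations * 1e3,
            "mean_amplitude_pA": events.mean_amplitudes,
        }
    )
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=False)


def read_events_csv(path: str | Path) -> IdealizedEvents:
    df = pd.read_csv(path, comment="#")
    return IdealizedEvents(
        class_codes=df["class"].to_numpy(np.int8),
        durations=df["duration_ms"].to_numpy(float) / 1e3,
        mean_amplitudes=df["mean_amplitude_pA"].to_numpy(float),
    )


def write_trace_csv(path: str | Path, trace: SampledTrace, comment: str | None = None) -> None:
    """Trace as CSV (time_s, current_pA)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("time_s,current_pA\n")
        np.savetxt(fh, np.column_stack([trace.times, trace.samples]), fmt="%.6f,%.5f")


def read_trace_csv(path: str | Path, sample_rate: float | None = None,
                   amplitudes=(0.0, 7.0), noise_sd: float = 0.0,
                   filter_cutoff: float | None = None) -> SampledTrace:
    df = pd.read_csv(path, comment="#")
    t = df["time_s"].to_numpy(float)
    x = df["current_pA"].to_numpy(float)
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return SampledTrace(
        samples=x, sample_rate=sample_rate, amplitudes=tuple(amplitudes),
        noise_sd=noise_sd, filter_cutoff=filter_cutoff,
    )


def write_trace_binary(path: str | Path, trace: SampledTrace, comment: str | None = None) -> None:
    """Flat float32 binary with a JSON sidecar carrying the metadata."""
    path = Path(path)
    trace.samples.astype(np.float32).tofile(path)
    meta = {
        "sample_rate": trace.sample_rate,
        "amplitudes": list(trace.amplitudes),
        "noise_sd": trace.noise_sd,
        "filter_cutoff": trace.filter_cutoff,
        "n_samples": int(trace.samples.size),
        "dtype": "float32",
    }
    if comment:
        meta["comment"] = comment
    if trace.conditions is not None:
        meta["conditions"] = {
            "conc_ACh": trace.conditions.conc_ACh,
            "conc_blocker": trace.conditions.conc_blocker,
            "V_m": trace.conditions.V_m,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trace_binary(path: str | Path) -> SampledTrace:
    from .schemes import Conditions

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype=np.float32).astype(float)
    cond = None
    if "conditions" in meta:
        cond = Conditions(**meta["conditions"])
    return SampledTrace(
        samples=samples,
        sample_rate=meta["sample_rate"],
        amplitudes=tuple(meta["amplitudes"]),
        noise_sd=meta["noise_sd"],
        filter_cutoff=meta["filter_cutoff"],
        conditions=cond,
    )
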