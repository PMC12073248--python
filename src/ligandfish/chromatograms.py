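"""Trace-level machinery: EICs, peak detection, and chromatogram subtraction.

The screening idea at trace level is simple: acquire the extract alone
(control) and the extract incubated with the enzyme (treated), subtract the
control trace from the treated one, and read enzyme-consumed components off
the difference as negative peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ChromatogramTrace",
    "TracePeak",
    "extract_eic",
    "detect_peaks",
    "subtract_traces",
    "find_negative_peaks",
    "read_mzml_scans",
    "write_trace",
]

TRACE_KINDS = ("TIC", "EIC", "difference")


@dataclass
class ChromatogramTrace:
    """Intensity versus retention time on a strictly increasing grid (minutes)."""

    times: np.ndarray
    intensities: np.ndarray
    kind: str = "TIC"
    target_mz: Optional[float] = None
    tol_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.kind not in TRACE_KINDS:
            raise ValueError(f"kind must be one of {TRACE_KINDS}")
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind != "difference" and self.times.size and np.any(self.intensities < 0):
            raise ValueError("non-difference traces must be non-negative")


@dataclass(frozen=True)
class TracePeak:
    """One detected peak with apex, bounds, and trapezoidal area."""

    apex_time: float
    apex_intensity: float
    left: float
    right: float
    area: float
    sign: str

    def __post_init__(self) -> None:
        if not (self.left < self.apex_time < self.right):
            raise ValueError("peak bounds must enclose the apex")


def extract_eic(
    scans: Sequence[tuple[float, Sequence[float], Sequence[float]]],
    target_mz: float,
    tol_ppm: float = 10.0,
) -> ChromatogramTrace:
    """Extracted ion chromatogram from centroided scans.

    Each scan is ``(time_minutes, centroid_mz_array, intensity_array)``.  Per
    scan the intensities of all centroids within ±tol_ppm of the target are
    summed; scans with no centroid in the window contribute zero.
    """
    if not scans:
        raise ValueError("empty scan list")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half_window = target_mz * tol_ppm * 1e-6
    times = np.empty(len(scans))
    intensities = np.zeros(len(scans))
    for i, (time, mzs, ints) in enumerate(scans):
        times[i] = time
        mzs = np.asarray(mzs, dtype=float)
        if mzs.size:
            mask = np.abs(mzs - target_mz) <= half_window
            if mask.any():
                intensities[i] = np.asarray(ints, dtype=float)[mask].sum()
    return ChromatogramTrace(times, intensities, kind="EIC", target_mz=target_mz, tol_ppm=tol_ppm)


def read_mzml_scans(path: "str | Path", ms_level: int = 1) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Read centroided scans from an mzML file.

    A minimal reader for the common encoding subset: 32- or 64-bit float
    binary arrays, uncompressed or zlib-compressed.  Returns
    ``(time_minutes, mz_array, intensity_array)`` tuples sorted by time; scan
    start times recorded in seconds are converted to minutes.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    for _event, elem in ET.iterparse(str(path)):
        if elem.tag not in (f"{ns}spectrum", "spectrum"):
            continue
        prefix = ns if elem.tag.startswith(ns) else ""
        params = {cv.get("accession"): cv for cv in elem.iter(f"{prefix}cvParam")}
        level = params.get("MS:1000511")
        if level is not None and int(level.get("value")) != ms_level:
            elem.clear()
            continue
        start = params.get("MS:1000016")
        if start is None:
            elem.clear()
            continue
        minutes = float(start.get("value"))
        if "second" in (start.get("unitName") or "minute"):
            minutes /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for array_elem in elem.iter(f"{prefix}binaryDataArray"):
            cvs = {cv.get("accession") for cv in array_elem.iter(f"{prefix}cvParam")}
            binary = array_elem.find(f"{prefix}binary")
            raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
            if "MS:1000574" in cvs:  # zlib compression
                raw = zlib.decompress(raw)
            dtype = np.float32 if "MS:1000521" in cvs else np.float64
            data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<")).astype(float)
            if "MS:1000514" in cvs:
                arrays["mz"] = data
            elif "MS:1000515" in cvs:
                arrays["intensity"] = data
        elem.clear()
        if "mz" in arrays and "intensity" in arrays:
            scans.append((minutes, arrays["mz"], arrays["intensity"]))
    if not scans:
        raise ValueError(f"no MS{ms_level} scans with data arrays found in {path}")
    scans.sort(key=lambda s: s[0])
    return scans


def _bounds(signal: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk from the apex to the nearest enclosing minima (strict descent)."""
    left = apex
    while left > 0 and signal[left - 1] < signal[left]:
        left -= 1
    right = apex
    while right < signal.size - 1 and signal[right + 1] < signal[right]:
        right += 1
    return left, right


def detect_peaks(
    trace: ChromatogramTrace,
    min_prominence: float = 0.01,
    min_width: float = 0.05,
) -> list[TracePeak]:
    """Detect peaks with prominence and width thresholds.

    ``min_prominence`` is a fraction of the trace's maximum absolute intensity,
    so detection is invariant to uniform intensity scaling; ``min_width`` is in
    minutes.  For difference traces, local maxima of |intensity| are found, so
    both positive and negative excursions are reported.  Output is ordered by
    apex time.
    """
    y = trace.intensities
    t = trace.times
    if y.size == 0:
        raise ValueError("empty trace")
    scale = float(np.max(np.abs(y)))
    if scale == 0:
        return []
    prominence = min_prominence * scale
    signs = (1.0, -1.0) if trace.kind == "difference" else (1.0,)
    peaks: list[TracePeak] = []
    for sign in signs:
        s = sign * y
        idx, _ = find_peaks(s, prominence=prominence)
        for apex in idx:
            left, right = _bounds(s, apex)
            if t[right] - t[left] < min_width:
                continue
            area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
            peaks.append(
                TracePeak(
                    apex_time=float(t[apex]),
                    apex_intensity=float(y[apex]),
                    left=float(t[left]),
                    right=float(t[right]),
                    area=area,
                    sign="positive" if sign > 0 else "negative",
                )
            )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def subtract_traces(treated: ChromatogramTrace, control: ChromatogramTrace) -> ChromatogramTrace:
    """treated − control, with the control linearly interpolated onto the treated grid.

    The direction is fixed so that components consumed upon enzyme incubation
    appear as negative excursions in the difference.
    """
    if treated.kind != control.kind:
        raise ValueError("traces must share a kind")
    if treated.kind == "difference":
        raise ValueError("cannot subtract difference traces")
    if treated.target_mz is not None and control.target_mz is not None:
        if abs(treated.target_mz - control.target_mz) > 1e-9:
            raise ValueError("EIC targets differ")
    if treated.times[0] > control.times[-1] or treated.times[-1] < control.times[0]:
        raise ValueError("trace time ranges do not overlap")
    interpolated = np.interp(treated.times, control.times, control.intensities)
    return ChromatogramTrace(
        treated.times.copy(),
        treated.intensities - interpolated,
        kind="difference",
        target_mz=treated.target_mz,
        tol_ppm=treated.tol_ppm,
    )


def find_negative_peaks(
    diff: ChromatogramTrace,
    min_prominence: float = 0.01,
    min_width: float = 0.05,
) -> list[TracePeak]:
    """Negative peaks of a difference trace, largest |area| first."""
    if diff.kind != "difference":
        raise ValueError("find_negative_peaks expects a difference trace")
    peaks = [p for p in detect_peaks(diff, min_prominence, min_width) if p.sign == "negative"]
    peaks.sort(key=lambda p: abs(p.area), reverse=True)
    return peaks


def write_trace(trace: ChromatogramTrace, path: "str | Path", delimiter: str = "\t") -> None:
    """Export a trace as two-column delimited text (minutes, intensity)."""
    data = np.column_stack([trace.times, trace.intensities])
    header = f"time_min{delimiter}intensity"
    np.savetxt(path, data, delimiter=delimiter, header=header, comments="")
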