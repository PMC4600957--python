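"""Compression-test analysis of load-displacement traces.

A granule stack or bone core compressed at constant crosshead speed yields
a monotone load-displacement curve: a concave "toe" while the granules
collapse and settle, then a quasi-linear region of irreversible
compaction, stopped when the load reaches a preset cap (400 N here).
Three scalar parameters summarize the trace:

* stiffness (N/mm) — the slope of the tangent at the beginning of the
  deformation, operationalized as the steepest least-squares line over a
  sliding window spanning 10% of the total displacement range, searched
  where the load is below 50% of the cap (robust to the toe region).
  The steepest window is located on a lightly smoothed copy of the load
  signal and the reported slope is then refit on the raw samples of that
  window, so measurement noise does not inflate the maximum;
* maximum displacement (mm) — displacement at the first crossing of the
  load cap, linearly interpolated between bracketing samples;
* work to failure (N·mm) — trapezoidal area under the curve from the
  start of the trace to the cap crossing.  Compaction curves have no
  discrete yield or failure point, so the area is taken from the origin;
  this choice is recorded in the result notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import UndefinedResultError


@dataclass
class LoadDisplacementCurve:
    """A compression trace: displacement in mm (non-decreasing), load in N."""

    displacement: np.ndarray
    load: np.ndarray
    load_cap: float = 400.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.displacement.ndim != 1 or self.load.ndim != 1:
            raise ValueError("displacement and load must be 1D")
        if self.displacement.size != self.load.size:
            raise ValueError("displacement and load must have equal length")
        if self.displacement.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")

    @classmethod
    def from_csv(cls, path, load_cap: float = 400.0) -> "LoadDisplacementCurve":
        """Read a two-column CSV with header (displacement_mm, load_N)."""
        import pandas as pd
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError("curve CSV needs two columns "
                             "(displacement_mm, load_N)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   load_cap=load_cap)

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"displacement_mm": self.displacement,
                      "load_N": self.load}).to_csv(path, index=False)


@dataclass
class BiomechResult:
    stiffness: float            # N/mm
    max_displacement: float     # mm
    work_to_failure: float      # N·mm
    fit_window: tuple[int, int] = (0, 0)
    notes: str = ""


def _smooth_load(d: np.ndarray, f: np.ndarray, span_mm: float) -> np.ndarray:
    """Savitzky-Golay (locally quadratic) load smoothing over a
    displacement span.  Exact on polynomial segments — a noiseless linear
    ramp passes through unchanged, endpoints included — so smoothing only
    suppresses noise.  No-op when the span is below ~3 samples."""
    from scipy.signal import savgol_filter
    step = float(np.median(np.diff(d)))
    if step <= 0:
        return f
    w = int(round(span_mm / step))
    if w % 2 == 0:
        w += 1
    if w < 5 or w > f.size:
        return f
    return savgol_filter(f, w, polyorder=2, mode="interp")


def estimate_stiffness(curve: LoadDisplacementCurve,
                       window_span: float = 0.10,
                       search_load_frac: float = 0.50,
                       locate_smooth_mm: float = 0.2,
                       ) -> tuple[float, tuple[int, int]]:
    """Initial-slope estimate: steepest sliding-window least-squares fit.

    The window spans ``window_span`` of the total displacement range and is
    slid sample by sample over the region where the load stays below
    ``search_load_frac`` of the cap, skipping the toe.  The steepest window
    is located on the load smoothed over ``locate_smooth_mm`` (so noise does
    not bias the maximum upward); the returned slope is the raw
    least-squares fit inside that window.  Returns the slope in N/mm and
    the (start, stop) index window used.
    """
    d, f_raw = curve.displacement, curve.load
    f = _smooth_load(d, f_raw, locate_smooth_mm)
    if f.max() < 0.25 * curve.load_cap:
        raise ValueError(
            f"curve only reaches {f.max():.1f} N, below 25% of the "
            f"{curve.load_cap:.0f} N cap; stiffness undefined")
    span = window_span * (d[-1] - d[0])
    limit = search_load_frac * curve.load_cap
    # candidate region: from the start up to the first sample above the limit
    above = np.nonzero(f > limit)[0]
    stop = int(above[0]) + 1 if above.size else d.size
    best = (-np.inf, (0, 0))
    i = 0
    for j in range(stop):
        while d[j] - d[i] > span:
            i += 1
        if j - i + 1 < 3 or d[j] - d[i] < 0.5 * span:
            continue
        dd = d[i:j + 1]
        ff = f[i:j + 1]
        dc = dd - dd.mean()
        denom = float(dc @ dc)
        if denom <= 0:
            continue
        slope = float(dc @ (ff - ff.mean())) / denom
        if slope > best[0]:
            best = (slope, (i, j + 1))
    if not np.isfinite(best[0]):
        raise ValueError("no window with enough points below the search "
                         "limit; curve too short or too coarsely sampled")
    i, j = best[1]
    dd, ff = d[i:j], f_raw[i:j]
    dc = dd - dd.mean()
    slope = float(dc @ (ff - ff.mean())) / float(dc @ dc)
    return slope, (i, j)


def max_displacement_at_cap(curve: LoadDisplacementCurve,
                            cap: float | None = None) -> float:
    """Displacement at the first crossing of the load cap, interpolated
    linearly between the bracketing samples."""
    cap = curve.load_cap if cap is None else cap
    d, f = curve.displacement, curve.load
    if f.max() < cap:
        raise ValueError(f"load never reaches the {cap:.0f} N cap "
                         f"(max attained {f.max():.1f} N)")
    idx = int(np.nonzero(f >= cap)[0][0])
    if idx == 0 or f[idx] == cap:
        return float(d[idx])
    f0, f1 = f[idx - 1], f[idx]
    d0, d1 = d[idx - 1], d[idx]
    if f1 == f0:
        return float(d1)
    return float(d0 + (cap - f0) * (d1 - d0) / (f1 - f0))


def work_to_failure(curve: LoadDisplacementCurve,
                    cap: float | None = None) -> float:
    """Trapezoidal area (N·mm) under the trace from the first sample to the
    cap crossing, or to the end of the trace if the cap is never reached."""
    cap = curve.load_cap if cap is None else cap
    d, f = curve.displacement, curve.load
    if f.max() >= cap:
        d_end = max_displacement_at_cap(curve, cap)
        keep = d < d_end
        d = np.append(d[keep], d_end)
        f = np.append(f[keep], cap)
    return float(np.trapezoid(f, d))


def analyze_curve(curve: LoadDisplacementCurve,
                  condition_smooth_mm: float = 0.05) -> BiomechResult:
    """Full per-curve summary: stiffness, max displacement, work.

    The cap crossing and the work integral are evaluated on the load
    smoothed over ``condition_smooth_mm`` (a noisy signal otherwise
    crosses the cap systematically early, biasing both quantities); the
    smoothing is a no-op on noiseless or coarsely sampled curves.
    """
    stiffness, window = estimate_stiffness(curve)
    cond = LoadDisplacementCurve(
        curve.displacement,
        _smooth_load(curve.displacement, curve.load, condition_smooth_mm),
        load_cap=curve.load_cap)
    notes = ("work integrated from trace start to cap crossing "
             "(compaction curves lack a discrete yield point)")
    try:
        max_disp = max_displacement_at_cap(cond)
    except ValueError:
        max_disp = float(curve.displacement[-1])
        notes += "; cap not reached, max displacement = end of trace"
    return BiomechResult(stiffness=stiffness,
                         max_displacement=max_disp,
                         work_to_failure=work_to_failure(cond),
                         fit_window=window, notes=notes)


def summarize_replicates(results: list[BiomechResult]) -> dict:
    """Mean ± SD over replicate curves for each biomech parameter."""
    out = {}
    for name in ("stiffness", "max_displacement", "work_to_failure"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        out[name] = {"mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n": int(vals.size)}
    return out
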