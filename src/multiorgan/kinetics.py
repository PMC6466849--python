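"""Clearance-curve analysis: ROI traces, AUC statistics and exponential fits.

The functional read-outs of the contrast-agent protocols are built here:

* the liver statistic is the area under the baseline-corrected ICG
  clearance curve of an ischiatic-vessel ROI (``ICG AUC``), reported per
  mouse as the day-1 -> day-4 change (``ΔICG AUC``);
* the kidney statistic is the ratio of the cortex AUC to the pelvis AUC
  (``AUC C:P``), likewise reported as a per-mouse change (``ΔAUC C:P``).
  A ratio is used because it is invariant to common gain — overall signal
  scale cancels between numerator and denominator — and because it rises
  with both impaired cortical clearance and delayed pelvic accumulation;
* the monoexponential half-life fit of the post-peak blood curve (healthy
  ICG half-life is about 3 minutes) plus Tmax are provided for completeness
  although they are not the headline statistics.

Integration is trapezoidal on the recorded sampling grid; no resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import ComponentMap

DEFAULT_BASELINE_S = 180.0


@dataclass
class RoiTrace:
    """Mean ROI intensity over time for one mouse, day and ROI label."""

    mouse_id: str
    day: int
    roi: str
    times: np.ndarray
    values: np.ndarray
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class ClearanceMetrics:
    """Derived statistics of one clearance trace."""

    auc: float | None = None
    tmax_s: float | None = None
    half_life_min: float | None = None
    decay_rate_per_s: float | None = None
    baseline: float | None = None
    reliable: bool = True


@dataclass
class KidneyMetrics:
    """Cortex and pelvis AUCs and their ratio; ratio is None when undefined."""

    auc_cortex: float
    auc_pelvis: float
    ratio_cp: float | None


@dataclass
class SessionDelta:
    """Day-1 -> day-4 change of one metric in one mouse (delta = day4 - day1)."""

    mouse_id: str
    metric: str
    day1: float
    day4: float

    @property
    def delta(self) -> float:
        return self.day4 - self.day1


def extract_roi_trace(cmap: ComponentMap, mask: np.ndarray, label: int, component: str | None = None,
                      mouse_id: str = "", day: int = 0, roi: str | None = None) -> RoiTrace:
    """Mean amplitude over the pixels of ``label`` in each frame.

    ``component`` defaults to the map's only component.
    """
    mask = np.asarray(mask)
    if mask.shape != cmap.data.shape[2:]:
        raise ValueError(f"mask shape {mask.shape} does not match map {cmap.data.shape[2:]}")
    sel = mask == label
    if not sel.any():
        raise ValueError(f"ROI label {label} is empty in mask")
    if component is None:
        if len(cmap.components) != 1:
            raise ValueError("component must be named for a multi-component map")
        component = cmap.components[0]
    series = cmap.component(component)[:, sel].mean(axis=1)
    return RoiTrace(mouse_id=mouse_id, day=day, roi=roi or str(label), times=cmap.times, values=series)


def baseline_correct(trace: RoiTrace, baseline_window_s: float = DEFAULT_BASELINE_S) -> RoiTrace:
    """Subtract the mean of the pre-injection window; stores the level removed."""
    sel = trace.times < trace.times[0] + baseline_window_s
    if sel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 samples")
    level = float(trace.values[sel].mean())
    return replace(trace, values=trace.values - level, baseline=level)


def compute_auc(trace: RoiTrace, start_s: float | None = None, end_s: float | None = None) -> float:
    """Trapezoidal area under the trace between ``start_s`` and ``end_s``.

    Defaults to the full recorded window; no extrapolation beyond it.
    """
    t0 = trace.times[0] if start_s is None else start_s
    t1 = trace.times[-1] if end_s is None else end_s
    sel = (trace.times >= t0) & (trace.times <= t1)
    if sel.sum() < 2:
        raise ValueError("AUC window must contain at least 2 samples")
    return float(np.trapezoid(trace.values[sel], trace.times[sel]))


def auc_cp_ratio(
    cortex: RoiTrace, pelvis: RoiTrace, start_s: float | None = None, end_s: float | None = None
) -> KidneyMetrics:
    """Cortex and pelvis AUCs over a common window and their ratio.

    The ratio is flagged undefined (``None``) when the pelvis AUC is not
    positive rather than returning an infinity.
    """
    if cortex.times.shape != pelvis.times.shape or not np.allclose(cortex.times, pelvis.times):
        raise ValueError("cortex and pelvis traces are not time-aligned")
    a_c = compute_auc(cortex, start_s, end_s)
    a_p = compute_auc(pelvis, start_s, end_s)
    ratio = a_c / a_p if a_p > 0 else None
    return KidneyMetrics(auc_cortex=a_c, auc_pelvis=a_p, ratio_cp=ratio)


def session_delta(day1: float, day4: float, metric: str, mouse_id: str) -> SessionDelta:
    """Per-mouse change of a metric between imaging days (day4 - day1)."""
    if not (np.isfinite(day1) and np.isfinite(day4)):
        raise ValueError(f"non-finite values for {metric!r} in mouse {mouse_id!r}")
    return SessionDelta(mouse_id=mouse_id, metric=metric, day1=float(day1), day4=float(day4))


def fit_monoexponential(trace: RoiTrace, fit_window_s: float | None = None) -> ClearanceMetrics:
    """Log-linear least-squares fit of the post-peak decay.

    The fit uses all samples after the peak (optionally truncated to
    ``fit_window_s`` seconds past it); values are clipped to a tiny
    positive floor so that baseline-corrected traces with small negative
    excursions remain fittable.  A non-decaying window is flagged
    unreliable instead of reporting a negative half-life.
    """
    i_peak = int(np.argmax(trace.values))
    tmax = float(trace.times[i_peak])
    t = trace.times[i_peak:]
    v = trace.values[i_peak:]
    if fit_window_s is not None:
        sel = t <= tmax + fit_window_s
        t, v = t[sel], v[sel]
    if t.size < 5:
        raise ValueError("need at least 5 samples after the peak to fit a decay")
    peak = v[0]
    if peak <= 0:
        return ClearanceMetrics(tmax_s=tmax, baseline=trace.baseline, reliable=False)
    logv = np.log(np.clip(v, peak * 1e-9, None))
    slope, _ = np.polyfit(t, logv, 1)
    if slope >= 0:
        return ClearanceMetrics(tmax_s=tmax, baseline=trace.baseline, reliable=False)
    rate = -float(slope)
    return ClearanceMetrics(
        tmax_s=tmax,
        half_life_min=float(np.log(2.0) / rate / 60.0),
        decay_rate_per_s=rate,
        baseline=trace.baseline,
        reliable=True,
    )
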