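"""Assay metrics computed from simulated trajectories.

Spatial assay: the fibrin field is reduced to a clot-size curve CS(t)
by the 50%-of-initial-fibrinogen front rule; from it the lag time
(Tlag), initial velocity (Vi, least-squares slope over
Tlag+2..Tlag+6 min) and stationary velocity (Vst, slope over
Tlag+15..Tlag+25 min) are extracted.  The propagating thrombin wave is
summarized by its amplitude A (median height of the interior local
maximum during propagation).

Homogeneous assay: Amax is the maximum of the thrombin observable,
Tmax its time, and T1/2 the time at which fibrin reaches half of its
plateau.

Statuses follow the assays' reporting conventions: ``NC`` (no clotting
within the horizon) and ``NP`` (no thrombin peak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from hemosim.assay_engine.trajectory import SpatialTrajectory, Trajectory

VALUE = "value"
NC = "NC"  # no clotting
NP = "NP"  # no thrombin peak
UNDEFINED = "undefined"
TRUNCATED = "truncated"


@dataclass
class ClotFrontSeries:
    """Clot front coordinate over time; NaN where no front is detected."""

    times_min: np.ndarray
    cs_um: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.times_min) == len(self.cs_um) == len(self.detected)):
            raise ValueError("inconsistent series lengths")

    @property
    def any_detection(self) -> bool:
        return bool(np.any(self.detected))


@dataclass
class AssayMetrics:
    """Flat container for the spatial and homogeneous assay parameters."""

    tlag_min: Optional[float] = None
    vi_um_min: Optional[float] = None
    vst_um_min: Optional[float] = None
    a_nM: Optional[float] = None
    t_half_min: Optional[float] = None
    tmax_min: Optional[float] = None
    amax_nM: Optional[float] = None
    status: Dict[str, str] = field(default_factory=dict)

    _FIELDS = ("tlag_min", "vi_um_min", "vst_um_min", "a_nM",
               "t_half_min", "tmax_min", "amax_nM")

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {}
        for f in self._FIELDS:
            row[f] = getattr(self, f)
            row[f + "_status"] = self.status.get(f, UNDEFINED)
        return row

    def merged(self, other: "AssayMetrics") -> "AssayMetrics":
        out = AssayMetrics(**{f: getattr(self, f) for f in self._FIELDS})
        out.status = dict(self.status)
        for f in self._FIELDS:
            if getattr(other, f) is not None or f in other.status:
                setattr(out, f, getattr(other, f))
                if f in other.status:
                    out.status[f] = other.status[f]
        return out


def clot_front(traj: SpatialTrajectory, fibrinogen0: float,
               fibrin_observable: str = "fibrin") -> ClotFrontSeries:
    """Extract the clot-size curve from the fibrin field.

    The front is the outermost coordinate where fibrin crosses 50% of
    the initial fibrinogen concentration, located by linear
    interpolation between grid nodes.
    """
    if fibrinogen0 <= 0:
        raise ValueError("fibrinogen0 must be positive")
    fib = traj.observable_field(fibrin_observable)  # (N, T)
    thr = 0.5 * fibrinogen0
    x = traj.x_um
    T = fib.shape[1]
    cs = np.full(T, np.nan)
    detected = np.zeros(T, dtype=bool)
    above = fib >= thr
    for ti in range(T):
        col = above[:, ti]
        if not col[0]:
            # clotting starts at the activator; no front before onset
            continue
        if col.all():
            cs[ti] = x[-1]
            detected[ti] = True
            continue
        j = int(np.argmin(col))  # first node below threshold
        f1, f2 = fib[j - 1, ti], fib[j, ti]
        frac = (f1 - thr) / (f1 - f2) if f1 != f2 else 0.0
        cs[ti] = x[j - 1] + frac * (x[j] - x[j - 1])
        detected[ti] = True
    return ClotFrontSeries(times_min=traj.times_min.copy(), cs_um=cs,
                           detected=detected)


def _window_slope(series: ClotFrontSeries, t0: float, t1: float):
    m = series.detected & (series.times_min >= t0) & (series.times_min <= t1)
    if m.sum() < 2:
        return None
    t = series.times_min[m]
    c = series.cs_um[m]
    return float(np.polyfit(t, c, 1)[0])


def front_metrics(series: ClotFrontSeries,
                  detection_offset_um: float = 5.0) -> AssayMetrics:
    """Tlag, Vi and Vst from a clot-size curve.

    Tlag is the first time the front exceeds the detection offset
    (half a grid spacing at default resolution).  If the series ends
    before Tlag+25 min, Vst is fitted on the available tail (at least
    5 min) and flagged as truncated.
    """
    out = AssayMetrics()
    crossing = series.detected & (series.cs_um > detection_offset_um)
    if not np.any(crossing):
        for f in ("tlag_min", "vi_um_min", "vst_um_min"):
            out.status[f] = NC
        return out
    tlag = float(series.times_min[np.argmax(crossing)])
    out.tlag_min = tlag
    out.status["tlag_min"] = VALUE

    vi = _window_slope(series, tlag + 2.0, tlag + 6.0)
    if vi is None:
        out.status["vi_um_min"] = UNDEFINED
    else:
        out.vi_um_min = vi
        out.status["vi_um_min"] = VALUE

    t_end = series.times_min[-1]
    if t_end >= tlag + 25.0:
        vst = _window_slope(series, tlag + 15.0, tlag + 25.0)
        status = VALUE
    elif t_end >= tlag + 20.0:
        vst = _window_slope(series, tlag + 15.0, t_end)
        status = TRUNCATED
    else:
        vst, status = None, UNDEFINED
    if vst is None:
        out.status["vst_um_min"] = UNDEFINED if status != TRUNCATED else TRUNCATED
    else:
        out.vst_um_min = vst
        out.status["vst_um_min"] = status
    return out


def thrombin_amplitude(traj: SpatialTrajectory,
                       thrombin_observable: str = "thrombin",
                       boundary_exclusion_um: float = 100.0,
                       tlag_min: Optional[float] = None,
                       noise_floor_nM: float = 1.0) -> AssayMetrics:
    """Amplitude A of the propagating thrombin peak.

    The activation boundary layer (first 100 um) and the pre-lag
    transient are excluded; A is the time-median of the interior
    local-maximum height, a stable estimator of the near-constant
    amplitude of the travelling wave.  Status NP when no interior peak
    above the noise floor ever forms.
    """
    thr = traj.observable_field(thrombin_observable)  # (N, T)
    x = traj.x_um
    interior = x >= boundary_exclusion_um
    i0 = int(np.argmax(interior))
    heights = []
    positions = []
    for ti in range(thr.shape[1]):
        if tlag_min is not None and traj.times_min[ti] < tlag_min:
            continue
        prof = thr[i0:, ti]
        j = int(np.argmax(prof))
        h = prof[j]
        if h < noise_floor_nM:
            continue
        # require a genuine interior local maximum: the profile must
        # fall off on the far side and not peak at the domain edge
        if j == len(prof) - 1:
            continue
        if j == 0 and thr[max(i0 - 1, 0), ti] > h:
            continue
        heights.append(h)
        positions.append(x[i0 + j])
    out = AssayMetrics()
    if not heights:
        out.status["a_nM"] = NP
        return out
    out.a_nM = float(np.median(heights))
    out.status["a_nM"] = VALUE
    out.peak_positions_um = np.array(positions)  # type: ignore[attr-defined]
    return out


def tga_metrics(traj: Trajectory, fibrinogen0: Optional[float] = None,
                thrombin_observable: str = "thrombin",
                fibrin_observable: str = "fibrin",
                noise_floor_nM: float = 1.0) -> AssayMetrics:
    """T1/2, Tmax and Amax from a homogeneous (thrombin generation) run.

    T1/2 is the first time fibrin reaches half of its plateau;
    the run is reported NC when less than 10% of fibrinogen converts.
    """
    out = AssayMetrics()
    iia = traj.observable(thrombin_observable)
    fib = traj.observable(fibrin_observable)
    if fibrinogen0 is None:
        fg_total = fib[-1] + (traj.curve("Fg")[-1] if "Fg" in traj.species_ids else 0.0)
        fibrinogen0 = fib[0] + (traj.curve("Fg")[0] if "Fg" in traj.species_ids else fg_total)

    plateau = float(np.max(fib))
    if fibrinogen0 > 0 and plateau < 0.1 * fibrinogen0:
        out.status["t_half_min"] = NC
        out.status["tmax_min"] = NC
        out.status["amax_nM"] = NC
        return out
    half = plateau / 2.0
    idx = int(np.argmax(fib >= half))
    if idx == 0:
        out.t_half_min = float(traj.times_min[0])
    else:
        t1, t2 = traj.times_min[idx - 1], traj.times_min[idx]
        f1, f2 = fib[idx - 1], fib[idx]
        out.t_half_min = float(t1 + (half - f1) / (f2 - f1) * (t2 - t1))
    out.status["t_half_min"] = VALUE

    amax = float(np.max(iia))
    if amax < noise_floor_nM:
        out.status["tmax_min"] = NP
        out.status["amax_nM"] = NP
        return out
    out.amax_nM = amax
    out.tmax_min = float(traj.times_min[int(np.argmax(iia))])
    out.status["tmax_min"] = VALUE
    out.status["amax_nM"] = VALUE
    return out


def spatial_metrics(traj: SpatialTrajectory, fibrinogen0: float,
                    detection_offset_um: Optional[float] = None) -> AssayMetrics:
    """Convenience: full spatial metric set (Tlag, Vi, Vst, A)."""
    if detection_offset_um is None:
        detection_offset_um = 0.5 * (traj.x_um[1] - traj.x_um[0])
    series = clot_front(traj, fibrinogen0)
    fm = front_metrics(series, detection_offset_um)
    am = thrombin_amplitude(traj, tlag_min=fm.tlag_min)
    return fm.merged(am)
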