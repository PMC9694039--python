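"""Metric extraction from synthetic trajectories with known answers."""

import numpy as np
import pytest

from hemosim.assay_engine.trajectory import SpatialTrajectory, Trajectory
from hemosim.readouts import (
    NC,
    NP,
    clot_front,
    front_metrics,
    tga_metrics,
    thrombin_amplitude,
)


def _spatial(times_min, x_um, fields):
    """fields: {species: (N, T) array}"""
    ids = list(fields)
    arr = np.stack([fields[s] for s in ids])
    return SpatialTrajectory(
        times_min=np.asarray(times_min, dtype=float),
        x_um=np.asarray(x_um, dtype=float),
        fields=arr,
        volume_ids=ids,
        surface=np.zeros((0, len(times_min))),
        surface_ids=[],
        observables={"fibrin": {"Fn": 1.0}, "thrombin": {"IIa": 1.0}},
    )


class TestClotFront:
    def test_step_profile_at_node(self):
        x = np.arange(0, 210, 10.0)
        fib = np.zeros((len(x), 2))
        fib[:11, 1] = 9000.0  # above half of 8800 up to x = 100 um
        traj = _spatial([0, 1], x, {"Fn": fib})
        series = clot_front(traj, fibrinogen0=8800.0)
        assert not series.detected[0]
        # crossing interpolated between 100 (9000) and 110 (0): 4400 sits
        # at 100 + (9000-4400)/9000*10
        assert series.cs_um[1] == pytest.approx(100 + 4600 / 900, rel=1e-6)

    def test_linear_profile_subgrid_interpolation(self):
        x = np.arange(0, 110, 10.0)
        prof = 8800.0 - 80.0 * x  # crosses 4400 at x = 55
        fib = np.repeat(prof[:, None], 2, axis=1)
        traj = _spatial([0, 1], x, {"Fn": fib})
        series = clot_front(traj, fibrinogen0=8800.0)
        assert series.cs_um[1] == pytest.approx(55.0)

    def test_subthreshold_field_yields_no_detection(self):
        x = np.arange(0, 110, 10.0)
        fib = np.full((len(x), 3), 100.0)
        traj = _spatial([0, 1, 2], x, {"Fn": fib})
        series = clot_front(traj, fibrinogen0=8800.0)
        assert not series.any_detection
        m = front_metrics(series)
        assert m.status["tlag_min"] == NC
        assert m.status["vst_um_min"] == NC


class TestFrontMetrics:
    def test_linear_front_recovers_exact_slope(self):
        """CS(t) = 30 (t - 1) for t >= 1: Tlag 1 min, Vi = Vst = 30 um/min."""
        t = np.arange(0.0, 40.0, 0.1)
        cs = np.where(t >= 1.0, 30.0 * (t - 1.0), np.nan)
        from hemosim.readouts import ClotFrontSeries
        series = ClotFrontSeries(times_min=t, cs_um=cs, detected=~np.isnan(cs))
        m = front_metrics(series, detection_offset_um=0.0)
        assert m.tlag_min == pytest.approx(1.0, abs=0.11)
        assert m.vi_um_min == pytest.approx(30.0, rel=1e-9)
        assert m.vst_um_min == pytest.approx(30.0, rel=1e-9)

    def test_truncated_series_flags_vst(self):
        t = np.arange(0.0, 22.0, 0.1)
        cs = np.where(t >= 1.0, 30.0 * (t - 1.0), np.nan)
        from hemosim.readouts import ClotFrontSeries, TRUNCATED
        series = ClotFrontSeries(times_min=t, cs_um=cs, detected=~np.isnan(cs))
        m = front_metrics(series, detection_offset_um=0.0)
        assert m.status["vst_um_min"] == TRUNCATED
        assert m.vst_um_min == pytest.approx(30.0, rel=1e-9)


class TestThrombinAmplitude:
    def test_translating_gaussian_pulse_recovers_height(self):
        x = np.arange(0, 4000.0, 10.0)
        t = np.arange(0.0, 30.0, 1.0)
        iia = np.empty((len(x), len(t)))
        for j, tj in enumerate(t):
            center = 300.0 + 30.0 * tj
            iia[:, j] = 25.0 * np.exp(-((x - center) / 80.0) ** 2)
        traj = _spatial(t, x, {"IIa": iia, "Fn": np.zeros_like(iia)})
        m = thrombin_amplitude(traj)
        assert m.a_nM == pytest.approx(25.0, rel=1e-3)

    def test_flat_low_field_reports_no_peak(self):
        x = np.arange(0, 1000.0, 10.0)
        t = np.arange(0.0, 10.0, 1.0)
        iia = np.full((len(x), len(t)), 0.2)
        traj = _spatial(t, x, {"IIa": iia, "Fn": np.zeros_like(iia)})
        m = thrombin_amplitude(traj)
        assert m.status["a_nM"] == NP


class TestTgaMetrics:
    def _traj(self, t, iia, fib):
        return Trajectory(
            times_min=np.asarray(t, dtype=float),
            conc=np.stack([iia, fib]),
            species_ids=["IIa", "Fn"],
            observables={"thrombin": {"IIa": 1.0}, "fibrin": {"Fn": 1.0}},
        )

    def test_triangular_peak(self):
        t = np.arange(0.0, 10.0, 0.1)
        iia = np.maximum(0.0, 50.0 - 12.5 * np.abs(t - 4.0))
        fib = np.minimum(8800.0, 2000.0 * t)
        m = tga_metrics(self._traj(t, iia, fib), fibrinogen0=8800.0)
        assert m.tmax_min == pytest.approx(4.0, abs=0.051)
        assert m.amax_nM == pytest.approx(50.0, rel=1e-6)
        # fibrin plateau 8800, half reached at t = 2.2
        assert m.t_half_min == pytest.approx(2.2, abs=0.01)

    def test_no_fibrin_conversion_reports_nc(self):
        t = np.arange(0.0, 10.0, 0.1)
        iia = np.zeros_like(t)
        fib = np.full_like(t, 100.0)
        m = tga_metrics(self._traj(t, iia, fib), fibrinogen0=8800.0)
        assert m.status["t_half_min"] == NC
        assert m.status["amax_nM"] == NC

    def test_cleaved_fibrin_but_no_thrombin_peak_is_np(self):
        t = np.arange(0.0, 10.0, 0.1)
        iia = np.full_like(t, 0.2)
        fib = np.minimum(8800.0, 2000.0 * t)
        m = tga_metrics(self._traj(t, iia, fib), fibrinogen0=8800.0)
        assert m.status["tmax_min"] == NP
        assert m.t_half_min is not None
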