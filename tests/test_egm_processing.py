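"""Activation detection, map smoothing, ATa and beat selection."""

import numpy as np
import pytest

from atriamap import egm_processing as proc
from atriamap.electrogram import EgmSet


def biphasic_template(t, t_star, width=8.0):
    """Smooth R/S-like deflection (negative Gaussian derivative) centered at
    ``t_star``; its steepest negative slope sits at t_star - sqrt(3)*width,
    which the dense-grid oracle in the tests computes explicitly."""
    return -np.gradient(np.exp(-((t - t_star) ** 2) / (2 * width ** 2)))


class TestActivationDetection:
    def test_known_inflection_recovered_within_half_ms(self):
        t = np.arange(400.0)
        for t_star in (97.0, 200.25, 303.6):
            w = biphasic_template(t, t_star)
            # dense-grid derivative oracle
            td = np.arange(0, 400, 0.01)
            wd = biphasic_template(td, t_star)
            oracle = td[np.argmin(np.gradient(wd, 0.01))]
            got = proc.detect_activation(w)
            assert got == pytest.approx(oracle, abs=0.5)

    def test_time_shift_equivariance(self):
        t = np.arange(400.0)
        base = proc.detect_activation(biphasic_template(t, 150.0))
        shifted = proc.detect_activation(biphasic_template(t, 170.0))
        assert shifted - base == pytest.approx(20.0, abs=0.1)

    def test_amplitude_invariance(self):
        t = np.arange(300.0)
        w = biphasic_template(t, 120.0)
        assert proc.detect_activation(3.7 * w) == proc.detect_activation(w)

    def test_flat_signal_raises(self):
        with pytest.raises(proc.FlatSignalError):
            proc.detect_activation(np.zeros(100))

    def test_window_restricts_search(self):
        # two deflections: the window must select the earlier, smaller one
        t = np.arange(500.0)
        w = biphasic_template(t, 100.0) + 2.0 * biphasic_template(t, 400.0)
        early = proc.detect_activation(w, window=(0, 250))
        late = proc.detect_activation(w)
        assert 80.0 < early < 110.0
        assert 380.0 < late < 410.0
        assert late - early == pytest.approx(300.0, abs=0.1)


class TestSmoothing:
    @pytest.fixture()
    def line_map(self):
        pos = np.column_stack([np.arange(20.0), np.zeros(20),
                               np.zeros(20)])
        return proc.ActivationMap(values=np.zeros(20), positions=pos)

    def test_uniform_map_unchanged(self, line_map):
        line_map.values = np.full(20, 7.5)
        out = proc.smooth_map(line_map, 5.0)
        np.testing.assert_allclose(out.values, 7.5)

    def test_impulse_response_matches_gaussian_weights(self, line_map):
        line_map.values = np.zeros(20)
        line_map.values[10] = 1.0
        s = 5.0
        out = proc.smooth_map(line_map, s)
        d = np.abs(np.arange(20.0) - 10.0)
        w = np.exp(-(np.arange(20.0)[:, None]
                     - np.arange(20.0)[None, :]) ** 2 / (2 * s * s))
        expected = w[:, 10] / w.sum(axis=1)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_smoothing_reduces_variance(self, line_map):
        rng = np.random.default_rng(0)
        line_map.values = rng.normal(size=20)
        out = proc.smooth_map(line_map, 5.0)
        assert out.values.var() <= line_map.values.var()

    def test_double_smoothing_approximates_sqrt2_width(self):
        # Gaussian composition on a dense 1D channel row
        pos = np.column_stack([np.linspace(0, 60, 121), np.zeros(121),
                               np.zeros(121)])
        m = proc.ActivationMap(values=np.zeros(121), positions=pos)
        m.values[60] = 1.0
        twice = proc.smooth_map(proc.smooth_map(m, 5.0), 5.0)
        once = proc.smooth_map(m, 5.0 * np.sqrt(2.0))
        num = np.linalg.norm(twice.values - once.values)
        den = np.linalg.norm(once.values)
        assert num / den < 0.05

    def test_nonpositive_space_constant_refused(self, line_map):
        with pytest.raises(ValueError):
            proc.smooth_map(line_map, 0.0)


class TestATa:
    def test_constant_signal_has_zero_area(self):
        w = np.full(500, 3.3)
        assert proc.compute_ata(w, t_a=50.0, sigma_phi=1.0) == 0.0

    def test_positive_affine_transform_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=600).cumsum()
        a1 = proc.compute_ata(w, t_a=100.0)
        a2 = proc.compute_ata(4.2 * w + 11.0, t_a=100.0)
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_half_sine_t_wave_matches_closed_form(self):
        # half-sine of amplitude A and width w fully inside the window:
        # area = 2 A w / pi, baseline 0 at the upper bound
        fs = 1000.0
        t = np.arange(600.0)
        amp, width, onset = 2.0, 120.0, 200.0
        w = np.zeros_like(t)
        sel = (t >= onset) & (t <= onset + width)
        w[sel] = amp * np.sin(np.pi * (t[sel] - onset) / width)
        t_a = 50.0
        sigma = w.std()
        expected = (2.0 * amp * width / np.pi) / ((300.0 - 35.0) * sigma)
        got = proc.compute_ata(w, t_a=t_a, t1=35.0, t2=300.0,
                               sigma_phi=sigma)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_window_beyond_record_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            proc.compute_ata(np.ones(200) + np.arange(200), t_a=100.0)

    def test_map_bounds_validated(self):
        with pytest.raises(ValueError):
            proc.ATaMap(values=np.zeros(3), positions=np.zeros((3, 3)),
                        t1=100.0, t2=50.0)


class TestDeltaATa:
    def _map(self, values):
        n = len(values)
        pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n),
                               np.zeros(n)])
        return proc.ATaMap(values=np.asarray(values, dtype=float),
                           positions=pos)

    def test_identical_maps_have_no_peak(self):
        m = self._map([0.1, 0.5, 0.3])
        d = proc.delta_ata(m, m)
        np.testing.assert_array_equal(d.values, 0.0)
        with pytest.raises(ValueError, match="uniform"):
            proc.locate_peak(d)

    def test_global_offset_flagged_as_non_localizing(self):
        a = self._map([0.1, 0.5, 0.3])
        b = self._map([0.6, 1.0, 0.8])
        d = proc.delta_ata(b, a)
        np.testing.assert_allclose(d.values, 0.5)
        with pytest.raises(ValueError, match="uniform"):
            proc.locate_peak(d)

    def test_peak_location_and_channel_mismatch(self):
        a = self._map([0.0, 0.0, 0.0, 0.0])
        b = self._map([0.0, 0.2, 0.9, 0.1])
        d = proc.delta_ata(b, a)
        np.testing.assert_array_equal(proc.locate_peak(d),
                                      b.positions[2])
        with pytest.raises(ValueError, match="channel"):
            proc.delta_ata(a, self._map([1.0, 2.0]))


class TestBeatSelection:
    def test_no_qt_intervals_accepts_all(self):
        beats = [proc.BeatWindow(0.0, 40.0), proc.BeatWindow(500.0, 540.0)]
        assert len(proc.select_beats(beats, [])) == 2

    def test_beat_inside_qt_rejected(self):
        beats = [proc.BeatWindow(100.0, 120.0)]   # activity ends at 420
        assert proc.select_beats(beats, [(50.0, 500.0)]) == []

    def test_shared_endpoint_counts_as_overlap(self):
        beats = [proc.BeatWindow(100.0, 120.0)]   # activity [100, 420]
        assert proc.select_beats(beats, [(420.0, 600.0)]) == []
        assert proc.select_beats(beats, [(30.0, 100.0)]) == []
        kept = proc.select_beats(beats, [(420.5, 600.0)])
        assert len(kept) == 1


class TestExports:
    def test_csv_and_vtk_roundtrip(self, atrium, tmp_path):
        import pandas as pd

        vals = np.linspace(0.0, 1.0, atrium.n_nodes)
        m = proc.ATaMap(values=vals[:10],
                        positions=atrium.nodes[:10])
        proc.export_map_csv(m, tmp_path / "m.csv")
        df = pd.read_csv(tmp_path / "m.csv")
        assert list(df.columns) == ["channel", "x_mm", "y_mm", "z_mm",
                                    "value"]
        np.testing.assert_allclose(df["value"], m.values)

        proc.export_map_vtk(atrium, vals, tmp_path / "m.vtk", "ata")
        text = (tmp_path / "m.vtk").read_text().splitlines()
        assert text[0].startswith("# vtk DataFile")
        assert f"POINTS {atrium.n_nodes} float" in text
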