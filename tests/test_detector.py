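import numpy as np
import pytest

from cztcam import (
    CrystalSpec, AnodeArraySpec, CIEMap, DetectorModel, SpectrumTable,
    EnergyCalibration, ResolutionModel, EnergyWindow, DEFAULT_WINDOWS,
    InteractionEvent, PhotonHistory, SourceSpec, generate_listmode,
    eval_cie, respond_history, select_winner, accumulate_spectra,
    apply_calibration, apply_resolution, calibrate, sum_spectra,
    form_image, component_spectra, sensitivity, fit_sensitivity_curve,
)
from cztcam.detector import N_BINS, BIN_WIDTH, CalibrationError, align_peaks
from cztcam.geometry import MEGP, OPEN


def uniform_cie_map(crystal, eta=0.8, half=6.15, n_lat=11, nz=11):
    """Synthetic joint map with constant CIE over its extent."""
    x = np.linspace(-half, half, n_lat)
    z = np.linspace(0, crystal.thickness, nz)
    return CIEMap(values=np.full((n_lat, n_lat, nz), eta),
                  x=x, y=x.copy(), z=z)


def peaked_cie_map(crystal, half=6.15, n_lat=41, nz=11):
    """Synthetic joint map peaking at 0.8 over the anode centre and
    decaying laterally: winner selection is unambiguous (a constant map
    would tie every covering anode to within a few ulp)."""
    x = np.linspace(-half, half, n_lat)
    z = np.linspace(0, crystal.thickness, nz)
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    lat = 0.2 + 0.6 * np.exp(-r2 / (2 * 2.5 ** 2))
    return CIEMap(values=np.broadcast_to(lat[:, :, None],
                                         (n_lat, n_lat, nz)).copy(),
                  x=x, y=x.copy(), z=z)


def linear_cie_map(crystal):
    """Values linear in x, constant in y/z: trilinear interpolation is
    exact, which pins down the interpolation arithmetic."""
    x = np.linspace(-2.0, 2.0, 5)
    z = np.linspace(0, crystal.thickness, 6)
    vals = np.broadcast_to(
        (0.5 + 0.1 * x)[:, None, None], (5, 5, 6)).copy()
    return CIEMap(values=vals, x=x, y=x.copy(), z=z)


@pytest.fixture(scope="module")
def model(crystal, anodes):
    return DetectorModel(crystal, anodes, peaked_cie_map(crystal),
                         threshold=40.0)


@pytest.fixture(scope="module")
def lin_model(crystal, anodes):
    return DetectorModel(crystal, anodes, linear_cie_map(crystal),
                         threshold=40.0)


def central_anode(anodes):
    # anode nearest the crystal centre (16x16 has no exact centre)
    centres = anodes.centres()
    return int(np.argmin(np.hypot(centres[:, 0], centres[:, 1])))


class TestEvalCie:
    def test_node_value_exact(self, lin_model, anodes):
        k = central_anode(anodes)
        cx, cy = lin_model.anode_centres[k]
        m = lin_model.cie
        pt = (cx + m.x[1], cy + m.y[2], m.z[3])
        assert eval_cie(lin_model, k, pt) == pytest.approx(
            m.values[1, 2, 3], rel=1e-12)

    def test_translation_between_anodes(self, lin_model, anodes):
        k = central_anode(anodes)
        k2 = k + 1  # lateral neighbour
        d = lin_model.anode_centres[k2] - lin_model.anode_centres[k]
        pt = np.array([0.3, -0.4, 2.0])
        a = eval_cie(lin_model, k,
                     pt + np.array([lin_model.anode_centres[k][0],
                                    lin_model.anode_centres[k][1], 0.0]))
        b = eval_cie(lin_model, k2,
                     pt + np.array([lin_model.anode_centres[k2][0],
                                    lin_model.anode_centres[k2][1], 0.0]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_midpoint_is_arithmetic_mean(self, lin_model, anodes):
        k = central_anode(anodes)
        cx, cy = lin_model.anode_centres[k]
        m = lin_model.cie
        mid_x = 0.5 * (m.x[1] + m.x[2])
        got = eval_cie(lin_model, k, (cx + mid_x, cy, m.z[0]))
        expected = 0.5 * (m.values[1, 0, 0] + m.values[2, 0, 0])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_outside_extent_is_zero(self, model, anodes):
        k = central_anode(anodes)
        cx, cy = model.anode_centres[k]
        assert eval_cie(model, k, (cx + 10.0, cy, 2.0)) == 0.0


class TestRespondAndWinner:
    def test_single_event_scaling(self, model, anodes):
        k = central_anode(anodes)
        cx, cy = model.anode_centres[k]
        h = PhotonHistory(0, [InteractionEvent("photoelectric",
                                               (cx, cy, 2.0), 100.0)],
                          100.0, "geometric_primary")
        e_out = respond_history(model, h)
        assert e_out[k] == pytest.approx(0.8 * 100.0)

    def test_empty_history_all_zero(self, model):
        h = PhotonHistory(0, [], 100.0, "geometric_primary")
        np.testing.assert_array_equal(respond_history(model, h), 0.0)

    def test_two_events_hand_sum(self, lin_model, anodes):
        k = central_anode(anodes)
        cx, cy = lin_model.anode_centres[k]
        evs = [InteractionEvent("compton", (cx + 0.5, cy, 1.0), 60.0),
               InteractionEvent("photoelectric", (cx - 1.0, cy, 3.0), 80.0)]
        h = PhotonHistory(0, evs, 140.5, "geometric_primary")
        e_out = respond_history(lin_model, h)
        expected = (0.5 + 0.1 * 0.5) * 60.0 + (0.5 - 0.1 * 1.0) * 80.0
        assert e_out[k] == pytest.approx(expected, rel=1e-12)

    def test_winner_argmax(self):
        e = np.zeros(256)
        e[17], e[40] = 50.0, 30.0
        assert select_winner(e, 40.0) == (17, 50.0)

    def test_all_below_threshold_undetected(self):
        e = np.full(256, 10.0)
        assert select_winner(e, 40.0) is None

    def test_exact_tie_lowest_index(self):
        e = np.zeros(256)
        e[100] = e[30] = 75.0
        assert select_winner(e, 40.0)[0] == 30


@pytest.fixture(scope="module")
def histories(crystal, anodes):
    src = SourceSpec(class_mixture={"geometric_primary": 0.8,
                                    "penetration": 0.2},
                     photo_fraction=0.7)
    return generate_listmode(src, crystal, anodes, MEGP, 2000, seed=5)


class TestAccumulate:
    def test_matches_per_history_path(self, model, histories):
        table = accumulate_spectra(model, histories)
        ref = np.zeros_like(table.counts)
        for h in histories:
            win = select_winner(respond_history(model, h), model.threshold)
            if win is None:
                continue
            k, e = win
            b = min(int(e / BIN_WIDTH), N_BINS - 1)
            ref[k, b] += h.events[0].weight
        np.testing.assert_allclose(table.counts, ref, atol=1e-9)

    def test_one_weighted_count_per_detected_history(self, model,
                                                     histories):
        table = accumulate_spectra(model, histories)
        detected = sum(
            1 for h in histories
            if select_winner(respond_history(model, h),
                             model.threshold) is not None)
        assert table.counts.sum() == pytest.approx(detected)

    def test_mixed_weights_sum(self, model, crystal, anodes, rng):
        hs = []
        for i in range(300):
            w = rng.random() * 2
            hs.append(PhotonHistory(i, [InteractionEvent(
                "photoelectric",
                (rng.uniform(-15, 15), rng.uniform(-15, 15),
                 rng.uniform(0, 5)), 140.5, weight=w)], 140.5,
                "geometric_primary"))
        table = accumulate_spectra(model, hs)
        expected = sum(
            h.events[0].weight for h in hs
            if select_winner(respond_history(model, h),
                             model.threshold) is not None)
        assert table.counts.sum() == pytest.approx(expected, rel=1e-9)


class TestCalibrationRebin:
    def test_identity_map(self, rng):
        s = rng.random(N_BINS)
        np.testing.assert_allclose(
            apply_calibration(s, EnergyCalibration(0.0, 1.0)), s,
            atol=1e-12)

    def test_counts_conserved(self, rng):
        s = np.zeros(N_BINS)
        s[300:900] = rng.random(600)
        out = apply_calibration(s, EnergyCalibration(3.0, 1.8))
        assert out.sum() == pytest.approx(s.sum(), rel=1e-12)

    def test_gain_two_moves_spike(self):
        s = np.zeros(N_BINS)
        s[500] = 100.0  # spike in bin [50.0, 50.1) keV
        out = apply_calibration(s, EnergyCalibration(0.0, 2.0))
        assert out.sum() == pytest.approx(100.0)
        # all counts mapped into [100.0, 100.2) keV
        assert out[1000] + out[1001] == pytest.approx(100.0)
        centroid = (np.arange(N_BINS) * out).sum() / out.sum() * BIN_WIDTH
        assert centroid == pytest.approx(100.1, abs=0.06)


class TestResolution:
    def test_degenerate_identity(self, rng):
        s = rng.random(N_BINS)
        np.testing.assert_array_equal(
            apply_resolution(s, ResolutionModel(0.0, 0.0)), s)

    def test_fwhm_model_value(self):
        # the stated linear model at 150 keV
        assert ResolutionModel(5.64, 0.00751).fwhm(150.0) == \
            pytest.approx(5.64 + 0.00751 * 150.0)

    def test_counts_conserved(self, rng):
        s = np.zeros(N_BINS)
        s[600:1800] = rng.random(1200)
        out = apply_resolution(s, ResolutionModel(5.64, 0.00751))
        assert out.sum() == pytest.approx(s.sum(), rel=1e-9)

    def test_measured_width_matches_request(self):
        s = np.zeros(N_BINS)
        s[1500] = 1000.0  # spike at 150 keV
        res = ResolutionModel(5.64, 0.00751)
        out = apply_resolution(s, res)
        half = out.max() / 2
        above = np.nonzero(out >= half)[0]
        lo, hi = above[0], above[-1]

        def crossing(i, j):
            return i + (half - out[i]) / (out[j] - out[i]) * (j - i)
        width = (crossing(hi, hi + 1) - crossing(lo, lo - 1)) * BIN_WIDTH
        assert abs(width - res.fwhm(150.05)) < BIN_WIDTH / 2


class TestCalibrate:
    def lu_spectrum(self, scale=1.0, offset=0.0):
        """Initial spectrum with 177Lu-like peaks whose positions obey a
        linear distortion E_init = (E - offset)/scale."""
        s = np.zeros(N_BINS)
        for e, h in ((55.0, 4000.0), (112.9, 9000.0), (208.4, 15000.0)):
            pos = (e - offset) / scale
            b = int(round(pos / BIN_WIDTH))
            s[b - 2:b + 3] += h * np.array([0.1, 0.6, 1.0, 0.6, 0.1])
        return s

    def test_already_calibrated_fixed_point(self):
        s = self.lu_spectrum()
        cal = calibrate(None, s, [55.0, 112.9, 208.4],
                        ResolutionModel(5.64, 0.00751))
        assert abs(cal.a0) < 0.1
        assert abs(cal.a1 - 1.0) < 1e-3

    def test_gain_recovery(self):
        # peaks at 0.8x their true energies require a1 ~ 1.25
        s = self.lu_spectrum(scale=1.25)
        cal = calibrate(None, s, [55.0, 112.9, 208.4],
                        ResolutionModel(5.64, 0.00751))
        assert cal.a1 == pytest.approx(1.25, rel=5e-3)

    def test_peaks_placed_within_one_bin(self):
        from cztcam.detector import _peak_centroid
        peaks = [55.0, 112.9, 208.4]
        res = ResolutionModel(5.64, 0.00751)
        s = self.lu_spectrum(scale=1.25, offset=-2.0)
        cal = calibrate(None, s, peaks, res)
        out = apply_resolution(apply_calibration(s, cal), res)
        for p in peaks:
            c = _peak_centroid(out, p, max(2.0, res.fwhm(p)), "pk")
            assert abs(c - p) <= BIN_WIDTH

    def test_missing_peak_raises(self):
        s = np.zeros(N_BINS)
        s[550] = 10.0
        with pytest.raises(CalibrationError, match="208.4"):
            calibrate(None, s, [55.0, 208.4], ResolutionModel(5.64, 0.00751),
                      initial=EnergyCalibration(0.0, 1.0))

    def test_align_peaks_no_double_blur(self):
        """Aligning already blurred spectra leaves correct peaks alone."""
        res = ResolutionModel(5.64, 0.00751)
        s = apply_resolution(self.lu_spectrum(), res)
        cal = align_peaks(s, [55.0, 112.9, 208.4], res)
        assert abs(cal.a0) < 0.2
        assert abs(cal.a1 - 1.0) < 2e-3


@pytest.fixture(scope="module")
def table():
    counts = np.random.default_rng(42).random((256, N_BINS))
    return SpectrumTable(counts, 16, 16,
                         {"activity": 10.0, "duration": 100.0})


class TestSelectionsImages:
    def test_full_sum(self, table):
        np.testing.assert_allclose(sum_spectra(table, "all"),
                                   table.counts.sum(axis=0))

    def test_central_excludes_60_edge_anodes(self, table):
        from cztcam.detector import _selection_indices
        idx = _selection_indices(table, "central")
        assert idx.size == 14 * 14
        assert 256 - idx.size == 60
        ix, iy = idx % 16, idx // 16
        assert ix.min() == 1 and ix.max() == 14
        assert iy.min() == 1 and iy.max() == 14

    def test_single_anode_identity(self, table):
        np.testing.assert_array_equal(sum_spectra(table, [37]),
                                      table.counts[37])

    def test_empty_selection_zero(self, table):
        np.testing.assert_array_equal(sum_spectra(table, []), 0.0)

    def test_image_total_matches_windowed_spectrum(self, table):
        w = DEFAULT_WINDOWS["113"]
        img = form_image(table, w)
        assert img.shape == (16, 16)
        centres = (np.arange(N_BINS) + 0.5) * BIN_WIDTH
        m = (centres >= w.low) & (centres < w.high)
        assert img.sum() == pytest.approx(sum_spectra(table, "all")[m].sum())

    def test_empty_window_zero_image(self, table):
        # no bin centre falls inside this sliver between centres
        img = form_image(table, EnergyWindow("w", 249.96, 249.99))
        assert img.sum() == 0.0

    def test_point_source_image_argmax(self, model, anodes):
        k = central_anode(anodes)
        cx, cy = model.anode_centres[k]
        hs = [PhotonHistory(i, [InteractionEvent(
            "photoelectric", (cx, cy, 1.0), 140.5)], 140.5,
            "geometric_primary") for i in range(50)]
        img = form_image(accumulate_spectra(model, hs),
                         EnergyWindow("w", 100.0, 130.0))
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert iy * 16 + ix == k


class TestComponents:
    def test_partition_bin_by_bin(self, model, crystal, anodes):
        src = SourceSpec(class_mixture={"geometric_primary": 0.6,
                                        "penetration": 0.3,
                                        "collimator_xray": 0.1})
        hs = generate_listmode(src, crystal, anodes, MEGP, 1500, seed=13)
        total = accumulate_spectra(model, hs)
        parts = component_spectra(model, hs, "transport_class")
        summed = sum(p.counts for p in parts.values())
        np.testing.assert_allclose(summed, total.counts, atol=1e-9)

    def test_single_line_single_component(self, model, crystal, anodes):
        src = SourceSpec(lines=((140.5, 1.0),), photo_fraction=1.0)
        hs = generate_listmode(src, crystal, anodes, OPEN, 200, seed=3)
        parts = component_spectra(model, hs, "emission_energy")
        assert list(parts) == [140.5]


class TestSensitivity:
    def test_rate_arithmetic(self):
        counts = np.zeros((256, N_BINS))
        counts[0, 550] = 1000.0
        t = SpectrumTable(counts, 16, 16,
                          {"activity": 10.0, "duration": 100.0})
        assert sensitivity(t, DEFAULT_WINDOWS["55"]) == pytest.approx(1.0)

    def test_metadata_required(self):
        t = SpectrumTable(np.zeros((256, N_BINS)), 16, 16, {})
        with pytest.raises(ValueError, match="activity"):
            sensitivity(t, DEFAULT_WINDOWS["55"])

    def test_noise_free_recovery(self):
        d = np.linspace(0, 130, 14)
        s = 2.0 + 5.0 * np.exp(-0.03 * d)
        c0, c1, c2 = fit_sensitivity_curve(d, s)
        assert c0 == pytest.approx(2.0, rel=1e-6)
        assert c1 == pytest.approx(5.0, rel=1e-6)
        assert c2 == pytest.approx(0.03, rel=1e-6)

    def test_flat_data_degenerate_rule(self):
        d = np.linspace(0, 100, 8)
        s = np.full(8, 3.5)
        c0, c1, c2 = fit_sensitivity_curve(d, s)
        assert (c0, c1, c2) == (3.5, 0.0, 0.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sensitivity_curve([0, 10, 20], [1, 2, 3])


class TestSpectrumTableIO:
    def test_text_round_trip(self, tmp_path, rng):
        counts = np.round(rng.random((256, N_BINS)) * 5)
        t = SpectrumTable(counts, 16, 16,
                          {"activity": 10.0, "duration": 100.0,
                           "distance": 25.0})
        p = tmp_path / "spec.txt"
        t.to_text(p)
        back = SpectrumTable.from_text(p)
        np.testing.assert_array_equal(back.counts, t.counts)
        assert back.metadata["activity"] == 10.0
        assert back.n_x == 16
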