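import numpy as np
import pytest

from cztcam import (
    CrystalSpec, AnodeArraySpec, FieldConfig, CarrierParams, ScalarField,
    CIEMap, CIEFormatError, build_grid,
    solve_electric_potential, solve_weighting_potential, gradient,
    adjoint_source, solve_adjoint_cie, direct_cie_oracle, hecht_cie,
    combine_components, compute_cie_map, write_cie, read_cie,
)
from cztcam.cie import THERMAL_VOLTAGE_293K


class TestCarrierParams:
    def test_einstein_relation_default(self):
        p = CarrierParams(mobility=1000.0, lifetime=1.0)
        assert p.diffusion_cm2_s == pytest.approx(
            1000.0 * THERMAL_VOLTAGE_293K)
        assert CarrierParams(mobility=1000.0, lifetime=1.0,
                             diffusion=0.0).diffusion_cm2_s == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            CarrierParams(mobility=-1, lifetime=1)
        with pytest.raises(ValueError):
            CarrierParams(mobility=1, lifetime=1, carrier="muon")


class TestAdjointSource:
    def test_uniform_closed_form(self, plate_grid, plate_fields):
        c, a, grid = plate_grid
        phi, phi_k = plate_fields
        el = CarrierParams(mobility=1000.0, lifetime=1.0)
        g = adjoint_source(grid, gradient(phi), gradient(phi_k), el)
        # mu * E_z * (1/L): 0.1 mm^2/(V us) * 120 V/mm / 5 mm = 2.4 /us
        np.testing.assert_allclose(g.values, 2.4, rtol=1e-9)

    def test_constant_weighting_gives_zero(self, plate_grid, plate_fields):
        _, _, grid = plate_grid
        phi, _ = plate_fields
        flat = ScalarField(grid, np.full(grid.shape, 0.5))
        el = CarrierParams(mobility=1000.0, lifetime=1.0)
        g = adjoint_source(grid, gradient(phi), gradient(flat), el)
        np.testing.assert_allclose(g.values, 0.0, atol=1e-12)

    def test_hand_evaluated_dot_product(self, plate_grid):
        _, _, grid = plate_grid
        el = CarrierParams(mobility=500.0, lifetime=1.0)
        e_grad = np.zeros((3,) + grid.shape)
        w_grad = np.zeros((3,) + grid.shape)
        e_grad[0], e_grad[2] = 3.0, -4.0
        w_grad[0], w_grad[2] = 0.5, 0.25
        g = adjoint_source(grid, e_grad, w_grad, el)
        # 0.05 * (3*0.5 + (-4)*0.25) = 0.05 * 0.5 = 0.025
        np.testing.assert_allclose(g.values, 0.025, rtol=1e-12)

    def test_grid_mismatch_rejected(self, plate_grid):
        _, _, grid = plate_grid
        el = CarrierParams(mobility=500.0, lifetime=1.0)
        with pytest.raises(ValueError, match="grid"):
            adjoint_source(grid, np.zeros((3, 2, 2, 2)),
                           np.zeros((3, 2, 2, 2)), el)


class TestHecht:
    def test_infinite_drift_length_limit(self):
        z = np.linspace(0, 5, 11)
        eta = hecht_cie(z, 5.0, 1e6, 1e6, field=120.0)
        np.testing.assert_allclose(eta, 1.0, rtol=1e-4)

    def test_electrons_only_zero_at_anode(self):
        assert hecht_cie(5.0, 5.0, 1e-3, field=120.0) == 0.0

    def test_cathode_value_closed_form(self):
        # mu*tau = 1e-3 cm^2/V at 120 V/mm: drift length 12 mm;
        # eta(0) = (12/5) (1 - exp(-5/12))
        expected = 2.4 * (1.0 - np.exp(-5.0 / 12.0))
        assert hecht_cie(0.0, 5.0, 1e-3, field=120.0) == \
            pytest.approx(expected, rel=1e-12)

    def test_nonpositive_drift_rejected(self):
        with pytest.raises(ValueError):
            hecht_cie(1.0, 5.0, -1e-3, field=120.0)


@pytest.fixture(scope="module")
def plate_adjoint():
    """Electrons-only, diffusion-off adjoint solution on a parallel plate."""
    c = CrystalSpec(width_x=6, width_y=6, thickness=5.0)
    a = AnodeArraySpec(n_x=1, n_y=1, pitch=0.4, pad_size=0.4)
    grid = build_grid(c, a, neighbourhood=1, step=0.1)
    cfg = FieldConfig("A1", weighting_alternative="B1")
    phi = solve_electric_potential(grid, c, cfg)
    phi_k = solve_weighting_potential(grid, 0, cfg)
    el = CarrierParams(mobility=1000.0, lifetime=1.0, diffusion=0.0)
    eta = solve_adjoint_cie(grid, phi, phi_k, el)
    return grid, phi, phi_k, el, eta


class TestAdjointSolve:
    def test_hecht_depth_dependence(self, plate_adjoint):
        grid, _, _, el, eta = plate_adjoint
        ref = hecht_cie(grid.z, 5.0, 1e-3, field=120.0)
        line = eta.values[2, 2, :]
        rel = np.abs(line[:-1] - ref[:-1]) / ref[:-1]
        assert rel.max() < 0.01

    def test_zero_source_gives_zero(self, plate_adjoint):
        grid, phi, _, el, _ = plate_adjoint
        flat = ScalarField(grid, np.zeros(grid.shape))
        eta = solve_adjoint_cie(grid, phi, flat, el)
        np.testing.assert_array_equal(eta.values, 0.0)

    def test_monotone_in_depth(self, plate_adjoint):
        _, _, _, _, eta = plate_adjoint
        line = eta.values[2, 2, :]
        assert np.all(np.diff(line) <= 1e-12)

    def test_monotone_in_lifetime(self, plate_adjoint):
        grid, phi, phi_k, el, eta = plate_adjoint
        longer = CarrierParams(mobility=el.mobility, lifetime=4.0,
                               diffusion=0.0)
        eta2 = solve_adjoint_cie(grid, phi, phi_k, longer)
        assert np.all(eta2.values >= eta.values - 1e-12)

    def test_bounds(self, plate_adjoint):
        _, _, _, _, eta = plate_adjoint
        assert eta.values.min() >= 0.0
        assert eta.values.max() <= 1.0 + 1e-9


class TestDirectOracle:
    def test_full_collection_without_trapping(self, plate_grid,
                                              plate_fields):
        c, a, grid = plate_grid
        phi, phi_k = plate_fields
        eta = 0.0
        for carrier in ("electron", "hole"):
            p = CarrierParams(mobility=1000.0, lifetime=1e6,
                              carrier=carrier, diffusion=0.0)
            # holes drift at 0.96 mm/us: allow the full 5.2 us collection
            eta += direct_cie_oracle((0.0, 0.0, 2.5), grid, phi, phi_k, p,
                                     dt=0.004, t_end=12.0)
        assert eta == pytest.approx(1.0, rel=0.01)

    def test_charge_on_collecting_anode_gives_zero(self, plate_grid,
                                                   plate_fields):
        _, _, grid = plate_grid
        phi, phi_k = plate_fields
        el = CarrierParams(mobility=1000.0, lifetime=1.0, diffusion=0.0)
        eta = direct_cie_oracle((0.0, 0.0, 5.0), grid, phi, phi_k, el,
                                dt=0.005, t_end=2.0)
        assert eta == 0.0

    def test_mid_depth_matches_hecht(self, plate_grid, plate_fields):
        _, _, grid = plate_grid
        phi, phi_k = plate_fields
        el = CarrierParams(mobility=1000.0, lifetime=1.0, diffusion=0.0)
        eta = direct_cie_oracle((0.0, 0.0, 2.5), grid, phi, phi_k, el,
                                dt=0.002, t_end=8.0)
        ref = hecht_cie(2.5, 5.0, 1e-3, field=120.0)
        assert eta == pytest.approx(ref, rel=0.02)

    def test_cfl_violation_rejected(self, plate_grid, plate_fields):
        _, _, grid = plate_grid
        phi, phi_k = plate_fields
        el = CarrierParams(mobility=1000.0, lifetime=1.0, diffusion=0.0)
        with pytest.raises(ValueError, match="CFL"):
            direct_cie_oracle((0, 0, 2.5), grid, phi, phi_k, el,
                              dt=1.0, t_end=2.0)


class TestCombineAndMap:
    def test_c1_is_electron_component(self, plate_adjoint):
        _, _, _, el, eta = plate_adjoint
        m = combine_components(eta, None, "C1", electron=el)
        np.testing.assert_array_equal(m.values, eta.values)
        assert m.signal_mode == "C1"

    def test_c2_with_zero_holes_equals_c1(self, plate_adjoint):
        grid, _, _, el, eta = plate_adjoint
        hole = CarrierParams(mobility=80.0, lifetime=0.5, carrier="hole")
        zero = ScalarField(grid, np.zeros(grid.shape))
        m1 = combine_components(eta, None, "C1", electron=el)
        m2 = combine_components(eta, zero, "C2", electron=el, hole=hole)
        np.testing.assert_array_equal(m2.values, m1.values)

    def test_c2_missing_holes_rejected(self, plate_adjoint):
        _, _, _, el, eta = plate_adjoint
        with pytest.raises(ValueError, match="hole"):
            combine_components(eta, None, "C2", electron=el)

    def test_holes_raise_near_anode(self, plate_adjoint):
        """Including holes lifts the CIE toward a non-zero value at the
        selected anode, where the electron term alone goes to zero."""
        grid, phi, phi_k, el, eta_e = plate_adjoint
        hole = CarrierParams(mobility=80.0, lifetime=2.0, carrier="hole",
                             diffusion=0.0)
        eta_h = solve_adjoint_cie(grid, phi, phi_k, hole)
        c2 = combine_components(eta_e, eta_h, "C2", electron=el, hole=hole)
        c1 = combine_components(eta_e, None, "C1", electron=el)
        near_anode = (2, 2, -2)
        assert c2.values[near_anode] > c1.values[near_anode]
        # the added term approximates the Hecht hole term at that depth:
        # (lam_h/L)(1 - exp(-z/lam_h)), lam_h = mu_h tau_h E = 1.92 mm
        z = grid.z[-2]
        lam_h = 80.0 * 2.0 * 1e-6 * 120.0 * 100.0
        hole_term = (lam_h / 5.0) * (1.0 - np.exp(-z / lam_h))
        got = c2.values[near_anode] - c1.values[near_anode]
        assert got == pytest.approx(hole_term, rel=0.05)

    def test_joint_map_quarter_symmetry(self, crystal, anodes):
        cfg = FieldConfig("A1", weighting_alternative="B1")
        el = CarrierParams(mobility=1000.0, lifetime=3.0)
        m = compute_cie_map(crystal, anodes, cfg, electron=el,
                            neighbourhood=3, step=0.41)
        np.testing.assert_allclose(m.values, m.values[::-1, :, :],
                                   atol=1e-9)
        np.testing.assert_allclose(m.values, m.values[:, ::-1, :],
                                   atol=1e-9)
        assert 0.0 <= m.values.min() and m.values.max() <= 1.0


class TestPersistence:
    @pytest.fixture
    def sample_map(self, rng):
        vals = rng.random((5, 5, 7))
        return CIEMap(values=vals, x=np.linspace(-1, 1, 5),
                      y=np.linspace(-1, 1, 5), z=np.linspace(0, 5, 7),
                      signal_mode="C1", field_config=FieldConfig(),
                      electron=CarrierParams(mobility=1000.0, lifetime=3.0))

    def test_round_trip_bit_exact(self, sample_map, tmp_path):
        p = tmp_path / "m.cie"
        write_cie(sample_map, p)
        back = read_cie(p)
        np.testing.assert_array_equal(back.values, sample_map.values)
        np.testing.assert_array_equal(back.z, sample_map.z)
        assert back.signal_mode == sample_map.signal_mode
        assert back.field_config == sample_map.field_config
        assert back.electron == sample_map.electron

    def test_corrupt_magic_rejected(self, sample_map, tmp_path):
        p = tmp_path / "m.cie"
        write_cie(sample_map, p)
        raw = bytearray(p.read_bytes())
        raw[0] ^= 0xFF
        p.write_bytes(bytes(raw))
        with pytest.raises(CIEFormatError, match="magic"):
            read_cie(p)

    def test_truncated_file_rejected(self, sample_map, tmp_path):
        p = tmp_path / "m.cie"
        write_cie(sample_map, p)
        p.write_bytes(p.read_bytes()[:60])
        with pytest.raises(CIEFormatError, match="truncated"):
            read_cie(p)

    def test_metadata_only_read(self, sample_map, tmp_path):
        p = tmp_path / "m.cie"
        write_cie(sample_map, p)
        meta = read_cie(p, metadata_only=True)
        assert meta["signal_mode"] == "C1"
        assert meta["electron"]["mobility"] == 1000.0
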