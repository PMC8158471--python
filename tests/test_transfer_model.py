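"""The compliance recursion, interlayer ratios and frequency responses,
checked against closed forms and the independent network solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pacinian as pc
from pacinian.oracle import driving_point_compliance, random_model

CORE = pc.CoreCoefficients(K_sc=2.2e6, K_Pc=2.2e5, B_sc=1e-3, M_c=1.1e-3)


def s_of(f):
    return 1j * 2 * np.pi * f


class TestBranchCompliance:
    def test_static_spring(self):
        c = pc.LayerCoefficients(K_L=0, K_M=50.0, B=1.0, M=1.0)
        assert pc.branch_compliance(c, 0j) == 1 / 50.0

    def test_pure_spring_branch_is_frequency_independent(self):
        c = pc.LayerCoefficients(K_L=0, K_M=7.0, B=0.0, M=0.0)
        for f in (0.0, 10.0, 1e4):
            assert pc.branch_compliance(c, s_of(f)) == pytest.approx(1 / 7.0)

    def test_magnitude_peaks_at_undamped_resonance(self):
        f0 = 1000.0
        m = 1.0 / (2 * np.pi * f0) ** 2
        c = pc.LayerCoefficients(K_L=0, K_M=1.0, B=1e-4 * 2 * np.sqrt(m), M=m)
        f = pc.default_grid(100, 10000, 2000)
        mags = np.abs([pc.branch_compliance(c, s_of(fk)) for fk in f])
        f_peak = f[int(np.argmax(mags))]
        assert abs(np.log(f_peak / f0)) <= np.log(f[1] / f[0])

    def test_exact_pole_raises(self):
        c = pc.LayerCoefficients(K_L=0, K_M=1.0, B=0.0, M=1.0)
        with pytest.raises(pc.PoleError):
            pc.branch_compliance(c, 1j)  # K - M w^2 = 0 at w = 1


class TestCoreCompliance:
    def test_static_series_springs(self):
        assert pc.core_compliance(CORE, 0j) == pytest.approx(
            1 / CORE.K_sc + 1 / CORE.K_Pc
        )

    def test_rigid_series_spring_leaves_branch(self):
        stiff = pc.CoreCoefficients(K_sc=1e30, K_Pc=2.2e5, B_sc=1e-3, M_c=1.1e-3)
        s = s_of(123.0)
        branch = 1.0 / (stiff.M_c * s * s + stiff.B_sc * s + stiff.K_Pc)
        assert pc.core_compliance(stiff, s) == pytest.approx(branch, rel=1e-12)

    def test_value_at_100hz_matches_high_precision(self):
        # frozen from an exact rational/pi evaluation for the printed core
        core = pc.CoreCoefficients(
            K_sc=2.2e6, K_Pc=2.2e5,
            B_sc=9.74522369471706e-4, M_c=1.10584061406361e-3,
        )
        got = pc.core_compliance(core, s_of(100.0))
        assert got.real == pytest.approx(5.00903794263498836e-6, rel=1e-12)
        assert got.imag == pytest.approx(-1.270140198220283e-11, rel=1e-9)


class TestLayerComplianceAndRatios:
    def test_no_lamellar_spring_gives_series_chain(self):
        layer = pc.LayerCoefficients(K_L=0.0, K_M=100.0, B=0.1, M=1e-3)
        model = pc.TransferModel(layers=(layer,), core=CORE)
        s = s_of(40.0)
        expected = pc.branch_compliance(layer, s) + pc.core_compliance(CORE, s)
        assert pc.layer_compliance(model, 1, s) == pytest.approx(expected, rel=1e-12)

    def test_decoupled_interior_leaves_lamella(self):
        # enormous branch compliance: the lamellar spring carries the load
        layer = pc.LayerCoefficients(K_L=500.0, K_M=1e-25, B=0.0, M=0.0)
        model = pc.TransferModel(layers=(layer,), core=CORE)
        assert pc.layer_compliance(model, 1, s_of(10.0)) == pytest.approx(
            1 / 500.0, rel=1e-6
        )

    def test_matches_network_driving_point_compliance(self):
        model = pc.TransferModel.from_design(pc.printed(2))
        s = s_of(500.0)
        a = pc.layer_compliance(model, 2, s)
        b = driving_point_compliance(model, s)
        assert abs(a - b) / abs(b) < 1e-9

    def test_rigid_branch_transmits_fully(self):
        layer = pc.LayerCoefficients(K_L=10.0, K_M=1e20, B=0.0, M=0.0)
        model = pc.TransferModel(layers=(layer,), core=CORE)
        assert pc.interlayer_transmittance(model, 1, s_of(50.0)) == pytest.approx(
            1.0, rel=1e-10
        )

    def test_free_branch_decouples(self):
        layer = pc.LayerCoefficients(K_L=10.0, K_M=1e-20, B=0.0, M=0.0)
        model = pc.TransferModel(layers=(layer,), core=CORE)
        assert abs(pc.interlayer_transmittance(model, 1, s_of(50.0))) < 1e-12

    def test_ratio_matches_network_solve(self):
        model = pc.TransferModel.from_design(pc.printed(3))
        s = s_of(100.0)
        system_ratio = 1.0 + 0.0j
        for i in range(model.n_layers, 1, -1):
            system_ratio *= pc.interlayer_transmittance(model, i, s)
        # X_2/X_3 alone against the network nodal displacements
        two_layer = pc.interlayer_transmittance(model, 3, s)
        K = pc.oracle.full_dynamic_stiffness(model, s)
        b = -K[:-1, -1]
        x = np.linalg.solve(K[:-1, :-1], b)
        assert abs(two_layer - x[-1]) / abs(x[-1]) < 1e-9


class TestCascade:
    def test_empty_product_is_unity(self):
        model = pc.TransferModel(layers=(), core=CORE)
        assert pc.cascade_transmittance(model, s_of(123.0)) == 1.0 + 0.0j

    def test_all_rigid_branches_move_as_a_body(self):
        layers = tuple(
            pc.LayerCoefficients(K_L=10.0, K_M=1e22, B=0.0, M=0.0) for _ in range(4)
        )
        model = pc.TransferModel(layers=layers, core=CORE)
        assert pc.cascade_transmittance(model, s_of(77.0)) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_equals_product_of_interlayer_ratios(self):
        model = pc.TransferModel.from_design(pc.printed(4))
        s = s_of(333.0)
        prod = np.prod(
            [pc.interlayer_transmittance(model, i, s) for i in range(1, 5)]
        )
        assert pc.cascade_transmittance(model, s) == pytest.approx(prod, rel=1e-12)

    def test_printed_five_layer_matches_network_across_band(self):
        model = pc.TransferModel.from_design(pc.printed(5))
        for f in pc.default_grid(20, 3000, 20):
            s = s_of(f)
            a = pc.cascade_transmittance(model, s)
            b = pc.solve_network(model, s)
            assert abs(a - b) / abs(b) < 1e-9


class TestFrequencyResponse:
    def test_single_point_grid(self):
        model = pc.TransferModel.from_design(pc.printed(1))
        curve = pc.frequency_response(model, np.array([100.0]))
        assert curve.frequencies.shape == (1,)
        assert np.isfinite(curve.magnitude_db).all()

    def test_rising_passband_of_printed_design(self, printed3_curve):
        """The printable corpuscle transmits more compression as frequency
        rises toward 1 kHz, by tens of dB."""
        bb = pc.magnitude_backbone(printed3_curve)
        f = printed3_curve.frequencies

        def at(fq):
            return bb[int(np.argmin(np.abs(f - fq)))]

        assert at(1000) > at(100) + 20.0
        assert at(100) > at(20)
        assert bb.max() > at(1000)

    def test_pointwise_determinism_under_grid_refinement(self):
        model = pc.TransferModel.from_design(pc.printed(2))
        coarse = pc.frequency_response(model, pc.default_grid(10, 1000, 50))
        fine_grid = np.unique(
            np.concatenate([coarse.frequencies, pc.default_grid(10, 1000, 99)])
        )
        fine = pc.frequency_response(model, fine_grid)
        idx = np.searchsorted(fine.frequencies, coarse.frequencies)
        assert np.array_equal(
            fine.transmittance[idx], coarse.transmittance
        )

    def test_isolated_pole_recorded_as_missing(self):
        layer = pc.LayerCoefficients(K_L=1.0, K_M=(2 * np.pi) ** 2, B=0.0, M=1.0)
        model = pc.TransferModel(layers=(layer,), core=CORE)
        curve = pc.frequency_response(model, np.array([0.5, 1.0, 2.0]))
        assert np.isnan(curve.transmittance[1])
        assert np.isfinite(curve.transmittance[[0, 2]]).all()

    def test_csv_round_trip(self, tmp_path, printed3_curve):
        path = tmp_path / "resp.csv"
        printed3_curve.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "frequency_hz,re_transmittance,im_transmittance,magnitude_db,phase_deg"
        )
        back = pc.ResponseCurve.from_csv(path)
        np.testing.assert_allclose(
            back.transmittance, printed3_curve.transmittance, rtol=1e-12
        )


@settings(deadline=None, max_examples=40, derandomize=True)
@given(seed=st.integers(0, 10_000), f=st.floats(min_value=0.1, max_value=1e4))
def test_recursion_matches_network_on_random_ladders(seed, f):
    """Central correctness property: the O(N) compliance recursion equals
    the dense nodal solve for arbitrary valid ladders."""
    model = random_model(np.random.default_rng(seed))
    s = s_of(f)
    a = pc.cascade_transmittance(model, s)
    b = pc.solve_network(model, s)
    assert abs(a - b) / max(abs(a), abs(b), 1e-300) < 1e-9


def test_highpass_character_of_both_presets(printed3_curve, biological_curve):
    """Transmittance at the lower band edge is far below the passband
    plateau for both the biological cell and the printable design."""
    for curve in (printed3_curve, biological_curve):
        bb = pc.magnitude_backbone(curve)
        assert curve.magnitude_db[0] < bb.max() - 20.0
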