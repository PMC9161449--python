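"""Standard-curve calibration, hydrolysis correction and Michaelis–Menten fits."""

import numpy as np
import pandas as pd
import pytest

from corefuc import kinetics as kin
from corefuc import synthetic as syn


class TestStandardCurve:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 10.0, 20.0, 40.0])
        cal = kin.fit_standard_curve(x, 2 * x + 5)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(5.0)
        assert cal.r_squared == pytest.approx(1.0)

    def test_inversion_luminescence_to_pmol(self):
        cal = kin.CalibrationCurve(slope=2.0, intercept=5.0, r_squared=1.0)
        assert cal.to_gdp_pmol(45.0) == pytest.approx(20.0)

    def test_slope_recovered_within_2se_on_noisy_curve(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 100, 8)
        y = 3.0 * x + 10.0
        y_noisy = y * (1 + 0.03 * rng.standard_normal(y.shape))
        cal = kin.fit_standard_curve(x, y_noisy)
        res = np.polyfit(x, y_noisy, 1, cov=True)
        se = np.sqrt(res[1][0, 0])
        assert abs(cal.slope - 3.0) <= 2 * se

    @pytest.mark.parametrize(
        "x, y",
        [
            ([1.0, 2.0], [2.0, 4.0]),  # too few levels
            ([1.0, 3.0, 2.0], [1.0, 2.0, 3.0]),  # non-monotone amounts
            ([1.0, 2.0, 3.0], [1.0, -2.0, 3.0]),  # negative luminescence
        ],
    )
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            kin.fit_standard_curve(x, y)


class TestCorrectAndConvert:
    def test_blank_equal_to_signal_gives_zero_velocities(self, noiseless):
        sim = syn.gen_kinetics_dataset(Km=100.0, Vmax=0.0, hydrolysis_rate=7.0,
                                       config=noiseless)
        with pytest.warns(UserWarning, match="zero"):
            vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        assert np.allclose(vel["velocity"], 0.0)

    def test_hydrolysis_background_removed(self, noiseless):
        sim = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1, hydrolysis_rate=12.0,
                                       config=noiseless)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        expected = kin.michaelis_menten(vel["acceptor_conc_uM"], 282.1, 113.1)
        assert np.allclose(vel["velocity"], expected, rtol=1e-9)

    def test_missing_blank_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            kin.KineticsDataset(
                substrate_id="x", acceptor_conc_uM=[1.0], replicate=[1],
                luminescence=[10.0], blank_luminescence=[],
            )

    def test_per_mg_normalization_matches_hand_calculation(self, noiseless):
        # 100 nM enzyme in 10 μL at 58 kg/mol is 5.8e-5 mg; 30 min incubation.
        sim = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1, hydrolysis_rate=0.0,
                                       config=noiseless)
        assert sim.dataset.enzyme_mass_mg == pytest.approx(5.8e-5)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        s = vel["acceptor_conc_uM"].iloc[0]
        pmol = (sim.dataset.luminescence[0] - 50.0) / 2.0
        v_hand = pmol * 1e-3 / (30.0 * 5.8e-5)
        assert vel["velocity"].iloc[0] == pytest.approx(v_hand)
        assert v_hand == pytest.approx(282.1 * s / (113.1 + s))


class TestMichaelisMentenFit:
    @pytest.mark.parametrize("km, vmax", [(113.1, 282.1), (14.56, 244.3), (133.1, 224.7)])
    def test_noiseless_exact_recovery(self, km, vmax, noiseless):
        sim = syn.gen_kinetics_dataset(Km=km, Vmax=vmax, config=noiseless)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        fit = kin.fit_michaelis_menten(vel)
        assert fit.saturable
        assert fit.Km == pytest.approx(km, rel=1e-6)
        assert fit.Vmax == pytest.approx(vmax, rel=1e-6)
        assert fit.efficiency == pytest.approx(fit.kcat / fit.Km)

    def test_half_maximal_velocity_at_km(self, noiseless):
        sim = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1, config=noiseless)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        fit = kin.fit_michaelis_menten(vel)
        assert fit.velocity(fit.Km) == pytest.approx(fit.Vmax / 2.0)

    def test_linear_data_flagged_non_saturable(self, noiseless):
        sim = syn.gen_kinetics_dataset(Km=1e6, Vmax=2e5, linear_in_S=True,
                                       config=noiseless)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        fit = kin.fit_michaelis_menten(vel)
        assert not fit.saturable
        assert fit.Km is None and fit.Vmax is None

    def test_fit_beats_grid_search_oracle(self):
        """NLS solution attains SSE no worse than a brute-force lattice."""
        rng = np.random.default_rng(7)
        s = np.array([5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0])
        for _ in range(20):
            km, vmax = rng.uniform(20, 300), rng.uniform(50, 400)
            v = kin.michaelis_menten(s, vmax, km) * (1 + 0.05 * rng.standard_normal(s.shape))
            df = pd.DataFrame({"substrate_id": "x", "acceptor_conc_uM": s, "velocity": v})
            fit = kin.fit_michaelis_menten(df)
            sse_fit = float(np.sum((v - kin.michaelis_menten(s, fit.Vmax, fit.Km)) ** 2))
            kms = np.linspace(5, 600, 60)
            vms = np.linspace(10, 500, 60)
            sse_grid = min(
                float(np.sum((v - kin.michaelis_menten(s, vm, k)) ** 2))
                for k in kms for vm in vms
            )
            assert sse_fit <= sse_grid + 1e-9

    def test_efficiency_invariant_under_unit_rescaling(self, noiseless):
        """μM→mM rescales Km ×10⁻³ and efficiency ×10³ consistently."""
        sim = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1, config=noiseless)
        vel = kin.correct_and_convert(sim.dataset, sim.calibration)
        fit_um = kin.fit_michaelis_menten(vel)
        vel_mm = vel.assign(acceptor_conc_uM=vel["acceptor_conc_uM"] / 1e3)
        fit_mm = kin.fit_michaelis_menten(vel_mm)
        assert fit_mm.Km == pytest.approx(fit_um.Km / 1e3, rel=1e-6)
        assert fit_mm.efficiency == pytest.approx(fit_um.efficiency * 1e3, rel=1e-6)


class TestCatalyticEfficiency:
    @pytest.mark.parametrize(
        "kcat, km, expected", [(14.17, 14.56, 0.97), (15.62, 113.1, 0.14)]
    )
    def test_published_ratio_reproduced(self, kcat, km, expected):
        fit = kin.MichaelisMentenFit(substrate_id="x", saturable=True,
                                     Km=km, Vmax=1.0, kcat=kcat)
        assert kin.catalytic_efficiency(fit, ndigits=2) == pytest.approx(expected)

    def test_unity_when_kcat_equals_km(self):
        fit = kin.MichaelisMentenFit(substrate_id="x", saturable=True,
                                     Km=5.0, Vmax=1.0, kcat=5.0)
        assert kin.catalytic_efficiency(fit) == pytest.approx(1.0)

    def test_rejected_for_non_saturable_fit(self):
        fit = kin.MichaelisMentenFit(substrate_id="x", saturable=False)
        with pytest.raises(ValueError):
            kin.catalytic_efficiency(fit)


class TestInitialVelocityComparison:
    def test_identical_velocities_fold_one(self):
        df = kin.compare_initial_velocities({"a": 5.0, "b": 5.0}, reference="a")
        assert np.allclose(df["fold_worse"], 1.0)

    def test_fold_antisymmetry(self):
        ab = kin.compare_initial_velocities({"a": 9.0, "b": 2.5}, reference="a")
        ba = kin.compare_initial_velocities({"a": 9.0, "b": 2.5}, reference="b")
        f_ab = float(ab.set_index("substrate_id").loc["b", "fold_worse"])
        f_ba = float(ba.set_index("substrate_id").loc["a", "fold_worse"])
        assert f_ab == pytest.approx(1.0 / f_ba)

    def test_known_fold_recovered_from_simulation(self):
        """A substrate generated 3.6-fold slower reports ≈3.6 at 1 mM."""
        s_fixed = 1000.0
        folds = []
        for seed in range(1, 11):
            cfg = syn.ScenarioConfig(seed=seed, noise_cv=0.03)
            fast = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1, hydrolysis_rate=0.0,
                                            acceptor_concs=[s_fixed], config=cfg)
            slow = syn.gen_kinetics_dataset(Km=113.1, Vmax=282.1 / 3.6, hydrolysis_rate=0.0,
                                            acceptor_concs=[s_fixed],
                                            config=syn.ScenarioConfig(seed=seed + 100, noise_cv=0.03))
            vf = kin.correct_and_convert(fast.dataset, fast.calibration)["velocity"].mean()
            vs = kin.correct_and_convert(slow.dataset, slow.calibration)["velocity"].mean()
            df = kin.compare_initial_velocities({"G0": vf, "M3N2-peptide": vs}, reference="G0")
            folds.append(float(df.set_index("substrate_id").loc["M3N2-peptide", "fold_worse"]))
        assert np.mean(folds) == pytest.approx(3.6, rel=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            kin.compare_initial_velocities({"a": 0.0, "b": 1.0}, reference="a")
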