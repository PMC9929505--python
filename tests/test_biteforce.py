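"""Forward bite-force model, sensor corrections, minimal models."""

import math

import numpy as np
import pytest

from bitemech.biteforce import (
    BiteApparatus,
    BiteMeasurement,
    MinimalModelInputs,
    allometric_bound,
    measured_to_bite,
    minimal_max_force,
    stimulated_rescale,
    stress_proxy_kpa,
)
from bitemech.geometry import JointFrame, LeverSet
from bitemech.muscle import FibrePopulation, ForceLengthParams, MuscleArchitecture


def simple_apparatus(phi0=0.0, l0=1.0, gamma0=90.0, theta0=60.0,
                     sigma_max=1.0, l_opt=1.0, beta=4.0):
    frame = JointFrame(centre=(0, 0, 0), axis=(0, 0, 1))
    levers = LeverSet(
        inlever=(0.0, -0.8, 0.0),
        outlever_distal=(2.0, 1.0, 0.0),
        outlever_proximal=(1.0, 0.5, 0.0),
        apodeme_axis=(-1.0, 0.0, 0.0),
        gamma0=gamma0,
        theta0=theta0,
    )
    muscle = MuscleArchitecture(
        volume=2.0,
        populations=[FibrePopulation(phi0=phi0, fibre_length0=l0)],
    )
    phys = ForceLengthParams(sigma_max=sigma_max, l_opt=l_opt, beta=beta)
    return BiteApparatus(frame=frame, levers=levers, muscle=muscle,
                         physiology=phys, theta_range=(20.0, 120.0))


class TestBiteForce:
    def test_all_factors_at_maximum(self):
        # gamma = 90 at theta0, fibre at L_opt, phi0 = 0, single population:
        # F = sigma_max * A_phys * |RxLi| |RxA| / |RxLo|
        app = simple_apparatus()
        r_li, r_lo = 0.8, np.linalg.norm(np.cross([0, 0, 1], [2.0, 1.0, 0.0]))
        expected = 1.0 * app.a_phys * r_li * 1.0 / r_lo
        assert app.bite_force(60.0) == pytest.approx(expected, rel=1e-12)

    def test_continuous_and_nonnegative(self):
        app = simple_apparatus(phi0=30.0, l0=1.2)
        th = np.linspace(20, 120, 500)
        F = app.bite_force(th)
        assert np.all(F >= 0)
        assert np.max(np.abs(np.diff(F))) < 0.05 * np.max(F)

    def test_theta_outside_admissible_range_rejected(self):
        app = simple_apparatus()
        with pytest.raises(ValueError, match="admissible range"):
            app.bite_force(125.0)

    def test_torque_balance_equals_factored_form(self, rng):
        # sigma * A * cos(phi) * inlever_eff / outlever_eff against the
        # MA-factored evaluation, for random parameter draws
        from bitemech.geometry import effective_levers

        for _ in range(30):
            app = simple_apparatus(
                phi0=rng.uniform(5, 50), l0=rng.uniform(0.8, 2.0),
                gamma0=rng.uniform(60, 120), sigma_max=rng.uniform(0.5, 2.0),
                l_opt=rng.uniform(0.7, 1.8), beta=rng.uniform(1, 10),
            )
            th = rng.uniform(40, 100)
            t = app.terms(th)
            in_eff, out_eff, _ = effective_levers(th, app.levers, app.frame)
            manual = (t["sigma_MPa_0"] * t["a_phys_0"] * t["cos_phi_0"]
                      * in_eff / out_eff)
            assert app.bite_force(th) == pytest.approx(manual, rel=1e-12)

    def test_matches_independent_brute_force_composition(self, rng):
        """Chained scalar re-implementation of the full model, 100 draws.

        The oracle composes the lever, displacement, pennation, length and
        stress relations step by step with plain math calls, independent
        of the package's vectorized implementation.
        """
        for _ in range(100):
            phi0 = rng.uniform(5, 55)
            l0 = rng.uniform(0.8, 2.2)
            lfil = rng.choice([0.0, rng.uniform(0.1, 0.8)])
            gamma0 = rng.uniform(50, 130)
            theta0 = rng.uniform(40, 90)
            sigma_max = rng.uniform(0.4, 2.2)
            l_opt = rng.uniform(0.7, 2.0)
            beta = rng.uniform(0.5, 12)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            inlever = rng.normal(size=3)
            apod = rng.normal(size=3)
            apod /= np.linalg.norm(apod)
            outlever = rng.normal(size=3) * 2
            theta = rng.uniform(theta0 - 15, theta0 + 15)

            frame = JointFrame(centre=(0, 0, 0), axis=axis)
            levers = LeverSet(inlever=inlever, outlever_distal=outlever,
                              outlever_proximal=outlever * 0.5,
                              apodeme_axis=apod, gamma0=gamma0, theta0=theta0)
            muscle = MuscleArchitecture(
                volume=rng.uniform(1, 5),
                populations=[FibrePopulation(phi0=phi0, fibre_length0=l0,
                                             filament_length=lfil)],
            )
            phys = ForceLengthParams(sigma_max=sigma_max, l_opt=l_opt, beta=beta)
            app = BiteApparatus(frame=frame, levers=levers, muscle=muscle,
                                physiology=phys, theta_range=(0.0, 180.0))

            # --- independent scalar composition -------------------------
            r_li = math.sqrt(sum(np.cross(axis, inlever) ** 2))
            r_lo = math.sqrt(sum(np.cross(axis, outlever) ** 2))
            r_a = math.sqrt(sum(np.cross(axis, apod) ** 2))
            gamma = math.radians(theta0 - theta + gamma0)
            ma = math.sin(gamma) * r_li * r_a / r_lo
            delta = (math.cos(math.radians(gamma0)) - math.cos(gamma)) * r_li * r_a
            lt0 = l0 + lfil
            lt = math.sqrt((math.cos(math.radians(phi0)) * lt0 - delta) ** 2
                           + (math.sin(math.radians(phi0)) * lt0) ** 2)
            lf = lt - lfil
            if lf <= 0:
                continue
            phi = math.atan2(math.sin(math.radians(phi0)),
                             math.cos(math.radians(phi0)) - delta / lt0)
            sigma = sigma_max * math.exp(-beta * (1 - lf / l_opt) ** 2)
            a_phys = muscle.volume / l_opt
            expected = sigma * a_phys * math.cos(phi) * ma

            assert app.bite_force(theta) == pytest.approx(expected, abs=1e-9)

    def test_reference_apparatus_peak_curve(self, reference_apparatus):
        """Curve peak sits at small opening angles with a ~5x drop to 100 deg.

        The reconstructed morphology yields a fitted-curve peak near 1.1 N;
        the largest single measured force in vivo was 1.4 N, which bounds
        the curve from above (measured scatter sits above the fit near the
        peak).  The all-optimal bound sigma_max*A_phys*cos(phi_min)*MA_max
        exceeds the curve peak by design.
        """
        th = np.linspace(35, 105, 701)
        F = reference_apparatus.bite_force(th)
        peak = F.max()
        assert 1.0 <= peak <= 1.45
        assert th[F.argmax()] < 65.0
        f100 = F[np.argmin(np.abs(th - 100.0))]
        assert 4.0 < peak / f100 < 6.5
        t = reference_apparatus.terms(th)
        bound = (reference_apparatus.physiology.sigma_max
                 * reference_apparatus.a_phys
                 * np.max(t["cos_phi"]) * np.max(t["ma"]))
        assert peak < bound <= 1.35


class TestMeasuredToBite:
    FRAME = JointFrame(centre=(0, 0, 0), axis=(0, 0, 1))

    def make(self, force=1.0, sensor=(1.0, 0.0, 0.0), cal=1.0, bite=1.0):
        # outlever (0,-1,0), axis z: bite force direction = Lo x R = (-1,0,0)
        return BiteMeasurement(theta=60.0, force_measured=force,
                               outlever=(0.0, -1.0, 0.0), sensor_axis=sensor,
                               plate_moment_cal=cal, plate_moment_bite=bite)

    def test_aligned_sensor_identity(self):
        assert measured_to_bite(self.make(), self.FRAME) == pytest.approx(1.0)

    def test_60_degree_misalignment_doubles(self):
        s = (np.cos(np.radians(60.0)), 0.0, np.sin(np.radians(60.0)))
        assert measured_to_bite(self.make(sensor=s), self.FRAME) == pytest.approx(2.0)

    def test_pure_moment_arm_correction(self):
        m = self.make(cal=1.25, bite=1.0)
        assert measured_to_bite(m, self.FRAME) == pytest.approx(1.25)

    def test_monotone_decreasing_in_alpha(self):
        alphas = np.linspace(0, 75, 16)
        forces = [
            measured_to_bite(
                self.make(sensor=(np.cos(np.radians(a)), 0, np.sin(np.radians(a)))),
                self.FRAME,
            )
            for a in alphas
        ]
        assert np.all(np.diff(forces) > 0)  # |F_b| grows as cos(alpha) falls

    def test_result_bounded_below_by_gamma_times_measured(self):
        m = self.make(force=0.8, cal=1.3, bite=1.0,
                      sensor=(np.cos(0.5), 0, np.sin(0.5)))
        assert measured_to_bite(m, self.FRAME) >= m.gamma_correction * 0.8

    def test_near_perpendicular_rejected(self):
        s = (0.1, 0.0, np.sqrt(1 - 0.01))
        with pytest.raises(ValueError, match="perpendicular"):
            measured_to_bite(self.make(sensor=s), self.FRAME)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            BiteMeasurement(theta=60.0, force_measured=-0.1)


class TestStimulatedRescale:
    def test_equal_levers_unchanged(self):
        assert stimulated_rescale(1.0, 2.0, 2.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("ratio", [0.8, 0.5])
    def test_proportional_to_lever_ratio(self, ratio):
        assert stimulated_rescale(1.0, 2.0 * ratio, 2.0) == pytest.approx(ratio)

    def test_zero_lever_rejected(self):
        with pytest.raises(ValueError):
            stimulated_rescale(1.0, 0.0, 2.0)


class TestMinimalModel:
    def test_combined_prefactor_is_8_25_kpa_per_um(self):
        # F[N] / (Hw Hl [m^2] * Sl [um] * 1e3) = 8.25 kPa/um
        inp = MinimalModelInputs(head_width=1.0, head_length=1.0,
                                 head_height=1.0, sarcomere_length=10.0,
                                 body_mass=55e-6)
        F = minimal_max_force(inp)
        prefactor = F / (1.0 * 1.0 * 1e-6 * 10.0 * 1e3)
        assert prefactor == pytest.approx(8.25, rel=1e-12)

    def test_intermediate_sarcomere_gives_83_kpa_coefficient(self):
        inp = MinimalModelInputs(head_width=1.0, head_length=1.0,
                                 head_height=1.0, sarcomere_length=10.0,
                                 body_mass=55e-6)
        coeff_kpa = minimal_max_force(inp) / (1.0 * 1.0 * 1e-6) / 1e3
        assert coeff_kpa == pytest.approx(82.5, rel=1e-12)
        assert math.floor(coeff_kpa + 0.5) == 83

    def test_stress_proxy_at_lower_bound(self):
        assert stress_proxy_kpa(3.0) == pytest.approx(150.0)

    def test_out_of_range_sarcomere_rejected_with_bounds_in_message(self):
        with pytest.raises(ValueError, match=r"\[3\.0, 17\.0\]"):
            stress_proxy_kpa(20.0)
        with pytest.raises(ValueError, match="validity"):
            MinimalModelInputs(head_width=1, head_length=1, head_height=1,
                               sarcomere_length=2.0, body_mass=1e-4)

    def test_linear_in_each_input(self):
        base = MinimalModelInputs(head_width=2.0, head_length=3.0,
                                  head_height=1.5, sarcomere_length=5.0,
                                  body_mass=55e-6)
        F0 = minimal_max_force(base)
        import dataclasses

        for name in ("head_width", "head_length", "sarcomere_length"):
            doubled = dataclasses.replace(base, **{name: 2 * getattr(base, name)})
            assert minimal_max_force(doubled) == pytest.approx(2 * F0, rel=1e-12)


class TestAllometricBound:
    def test_activity_bound_for_55_mg(self):
        val = allometric_bound(55e-6, 20.0)
        assert val == pytest.approx(526.4, abs=0.5)
        # one significant figure: ~500
        assert round(val, -2) == 500

    def test_muscle_bound_for_55_mg(self):
        val = allometric_bound(55e-6, 50.0)
        assert round(val, -2) == 1300

    def test_unit_mass_returns_coefficient(self):
        assert allometric_bound(1.0, 20.0) == pytest.approx(20.0)

    def test_positive_mass_required(self):
        with pytest.raises(ValueError):
            allometric_bound(0.0)
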