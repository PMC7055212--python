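"""Beta-spectrum sampling, CSDA ranges and the probe Monte Carlo."""

import numpy as np
import pytest

from betargs import (
    GeometrySpec,
    InjectionPlan,
    PatientRecord,
    TransportConfig,
    Y90,
    csda_range,
    disk_solid_angle_fraction,
    mean_beta_energy,
    predict_rates,
    sample_beta_energy,
    simulate_efficiency,
)
from betargs.probe_mc import (
    WATER_STOPPING_POWER,
    _isotropic_directions,
    _sample_region,
    transport_to_probe,
)


class TestBetaSpectrum:
    def test_support_bounded_by_endpoint(self, rng):
        draws = sample_beta_energy(Y90, rng, size=100_000)
        assert np.all(draws > 0)
        assert np.all(draws < Y90.beta_endpoint)

    def test_sample_mean_matches_spectrum_integral(self, rng):
        # independent check: mean of draws vs direct numeric integration
        draws = sample_beta_energy(Y90, rng, size=400_000)
        integral_mean = mean_beta_energy(Y90)
        assert integral_mean == pytest.approx(0.93, abs=0.03)
        assert draws.mean() == pytest.approx(integral_mean, abs=3 * draws.std()
                                             / np.sqrt(len(draws)))

    def test_fixed_seed_reproducible(self):
        a = sample_beta_energy(Y90, np.random.default_rng(3), size=100)
        b = sample_beta_energy(Y90, np.random.default_rng(3), size=100)
        np.testing.assert_array_equal(a, b)


class TestCsdaRange:
    def test_monotone_in_energy(self, fast_transport):
        energies = np.linspace(0.02, 2.5, 40)
        ranges = csda_range(energies, fast_transport)
        assert np.all(np.diff(ranges) > 0)

    def test_endpoint_range_is_millimetric(self, fast_transport):
        # ~11 mm in water at the 90Y endpoint energy
        assert csda_range(2.28, fast_transport) == pytest.approx(11.0, rel=0.08)

    @pytest.mark.parametrize("energy, published_mm", [
        # published CSDA ranges in liquid water (collision-dominated regime)
        (0.1, 0.1431), (0.5, 1.766), (2.0, 9.785),
    ])
    def test_against_published_csda_values(self, fast_transport, energy,
                                           published_mm):
        assert csda_range(energy, fast_transport) == pytest.approx(
            published_mm, rel=0.03)

    def test_density_scaling(self, fast_transport):
        assert csda_range(1.0, fast_transport, density=2.0) == pytest.approx(
            csda_range(1.0, fast_transport, density=1.0) / 2.0)

    def test_energy_outside_table_rejected(self, fast_transport):
        with pytest.raises(ValueError, match="table support"):
            csda_range(5.0, fast_transport)


class TestSimulateEfficiency:
    def test_source_beyond_range_gives_zero(self):
        # bury a small source 30 mm deep: beyond the ~11 mm maximum range
        geom = GeometrySpec(probe_standoff=30.0)
        cfg = TransportConfig(n_particles=20_000, rng_seed=1)
        eff, _ = simulate_efficiency("tumor", geom, cfg)
        assert eff == 0.0

    def test_point_source_matches_solid_angle_oracle(self):
        # on-axis point-like source, monoenergetic, threshold 0, absorbing
        # shield: acceptance reduces to the analytic disk solid angle
        geom = GeometrySpec(tumor_cylinder=(1e-6, 1e-6), probe_standoff=1.0)
        cfg = TransportConfig(n_particles=1_000_000, detection_threshold=0.0,
                              density_shield=1e9, rng_seed=7)
        eff, err = simulate_efficiency("tumor", geom, cfg, energy_mev=2.9)
        oracle = disk_solid_angle_fraction(1.0, geom.sensitive_cylinder[0])
        assert abs(eff - oracle) < 3 * err

    def test_efficiency_decreases_with_standoff(self):
        cfg = TransportConfig(n_particles=60_000, rng_seed=5)
        effs = [simulate_efficiency("tumor", GeometrySpec(probe_standoff=s),
                                    cfg)[0]
                for s in (0.0, 2.0, 5.0)]
        assert effs[0] > effs[1] > effs[2]

    def test_shield_only_removes_counts(self):
        geom = GeometrySpec()
        cfg = TransportConfig(n_particles=60_000, rng_seed=5)
        shielded, _ = simulate_efficiency("healthy", geom, cfg)
        no_shield, _ = simulate_efficiency(
            "healthy", GeometrySpec(shield_ring_thickness=0.0), cfg)
        assert no_shield >= shielded

    def test_unknown_region_rejected(self, fast_transport):
        with pytest.raises(ValueError, match="unknown source region"):
            simulate_efficiency("liver", GeometrySpec(), fast_transport)

    def test_seed_determinism(self, default_geometry, fast_transport):
        a = simulate_efficiency("tumor", default_geometry, fast_transport)
        b = simulate_efficiency("tumor", default_geometry, fast_transport)
        assert a == b

    def test_efficiency_bounded_by_nearest_point_solid_angle(self):
        # sources are at or below the tissue surface: no source point sees
        # the sensitive face under more than the contact solid angle
        cfg = TransportConfig(n_particles=100_000, rng_seed=3)
        for region in ("tumor", "healthy"):
            eff, _ = simulate_efficiency(region, GeometrySpec(), cfg)
            assert 0.0 <= eff <= 0.5


class TestTransportOracle:
    @pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
    def test_event_by_event_against_scalar_reimplementation(self):
        """Vectorized transport vs an independent per-track tabulation."""
        from scipy.integrate import quad
        from scipy.interpolate import interp1d

        geom = GeometrySpec()
        cfg = TransportConfig(n_particles=400, rng_seed=99)
        rng = np.random.default_rng(cfg.rng_seed)
        pos = _sample_region(rng, 400, "tumor", geom)
        direc = _isotropic_directions(rng, 400)
        energies = sample_beta_energy(Y90, rng, size=400)

        log_s = interp1d(np.log(WATER_STOPPING_POWER[:, 0]),
                         np.log(WATER_STOPPING_POWER[:, 1]))

        def mass_range(e):  # g/cm^2, term-wise quadrature
            e_min = WATER_STOPPING_POWER[0, 0]
            if e <= e_min:
                return e / WATER_STOPPING_POWER[0, 1]
            val, _ = quad(lambda x: 1.0 / np.exp(log_s(np.log(x))), e_min, e,
                          limit=200)
            return val + e_min / WATER_STOPPING_POWER[0, 1]

        rs, depth = geom.sensitive_cylinder
        ro = rs + geom.shield_ring_thickness
        thr_range = mass_range(cfg.detection_threshold / 1000.0)

        def radial_interval(p, u, radius):
            a = u[0] ** 2 + u[1] ** 2
            b = 2 * (p[0] * u[0] + p[1] * u[1])
            c = p[0] ** 2 + p[1] ** 2 - radius**2
            if a < 1e-14:
                return (-np.inf, np.inf) if c <= 0 else (np.inf, -np.inf)
            disc = b * b - 4 * a * c
            if disc <= 0:
                return (np.inf, -np.inf)
            return ((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a))

        expected = []
        for p, u, e0 in zip(pos, direc, energies):
            if u[2] <= 1e-12:
                expected.append(False)
                continue
            tz_in, tz_out = -p[2] / u[2], (depth - p[2]) / u[2]
            ri_in, ri_out = radial_interval(p, u, rs)
            t_enter, t_exit = max(tz_in, ri_in), min(tz_out, ri_out)
            if t_enter >= t_exit:
                expected.append(False)
                continue
            ro_in, ro_out = radial_interval(p, u, ro)
            shield = (max(0.0, min(ro_out, t_enter) - max(ro_in, tz_in))
                      - max(0.0, min(ri_out, t_enter) - max(ri_in, tz_in)))
            tissue = -p[2] / u[2]
            consumed = (tissue * cfg.density_tissue
                        + shield * cfg.density_shield) / 10.0
            expected.append(mass_range(e0) - consumed >= thr_range)

        detected = transport_to_probe(pos, direc, energies, geom, cfg)
        mismatches = int(np.sum(detected != np.array(expected)))
        assert mismatches == 0


class TestPredictRates:
    @pytest.fixture
    def patient(self):
        return PatientRecord(patient_id="P1", mass=70.0, suv_tumor=12.4,
                             suv_tumor_err=0.5, suv_healthy=2.4,
                             suv_healthy_err=0.1)

    def test_equal_suvs_give_similar_rates(self, fast_transport):
        rec = PatientRecord("P", 70.0, 3.0, 0.1, 3.0, 0.1)
        rp = predict_rates(rec, InjectionPlan(), config=fast_transport)
        # same specific activity everywhere: tumor and healthy scenarios see
        # the same source field up to MC fluctuations
        assert rp.rate_tumor == pytest.approx(
            rp.rate_healthy, abs=5 * (rp.mc_error_tumor + rp.mc_error_healthy))

    def test_zero_suggests_zero_rates(self, patient, fast_transport):
        plan = InjectionPlan(biodistribution_factor=1e-12)
        rp = predict_rates(patient, plan, config=fast_transport)
        assert rp.rate_tumor == pytest.approx(0.0, abs=1e-6)

    def test_linear_in_administered_activity(self, patient, fast_transport):
        r1 = predict_rates(patient, InjectionPlan(activity_per_mass=1.5),
                           config=fast_transport)
        r2 = predict_rates(patient, InjectionPlan(activity_per_mass=3.0),
                           config=fast_transport)
        assert r2.rate_tumor == pytest.approx(2 * r1.rate_tumor, rel=1e-9)
        assert r2.rate_healthy == pytest.approx(2 * r1.rate_healthy, rel=1e-9)

    def test_decay_correction_reduces_rates(self, patient, fast_transport):
        on = predict_rates(patient, InjectionPlan(decay_correct=True),
                           config=fast_transport)
        off = predict_rates(patient, InjectionPlan(decay_correct=False),
                            config=fast_transport)
        assert on.rate_tumor == pytest.approx(
            off.rate_tumor * 2 ** (-24 / 64), rel=1e-9)
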