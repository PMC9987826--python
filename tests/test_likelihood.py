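import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, norm

from trophocc.data_model import BeetleSurvey, PointInputs, build_model_inputs
from trophocc.likelihood import (
    JointModel,
    beetle_loglik,
    interval_emission,
    joint_loglik,
    log_prior,
    site_marginal_loglik,
    site_marginal_loglik_enumeration,
)
from trophocc.data_model import DetectionRecord
from trophocc.model_core import (
    BeetleParams,
    DetectionParams,
    ModelParameters,
    OccupancyParams,
    detection_prob,
    occupancy_prob,
)
from trophocc.selfcheck import random_point_instance
from trophocc.synthetic_data import GeneratorConfig, make_table1_design, simulate_dataset


class TestBeetleLoglik:
    def test_all_success_corner(self):
        # intensity 0.5 via zero gammas; 48 trials all successes
        ll = beetle_loglik(BeetleParams(), BeetleSurvey("p", 6, 48), age=0.0, pine=0.0)
        assert ll == pytest.approx(48 * math.log(0.5), abs=1e-9)

    def test_single_tree_midpoint(self):
        # one tree -> 8 trials; C(8,4) * 0.5^8
        ll = beetle_loglik(BeetleParams(), BeetleSurvey("p", 1, 4), age=0.0, pine=0.0)
        assert ll == pytest.approx(math.log(70 / 256), abs=1e-9)
        assert ll == pytest.approx(-1.2967, abs=1e-4)

    def test_pmf_normalizes(self, study_params):
        total = sum(
            math.exp(
                beetle_loglik(study_params.beetle, BeetleSurvey("p", 6, a),
                              age=0.8, pine=0.3)
            )
            for a in range(49)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestIntervalEmission:
    def rec(self, interval, stype, y, censored=False):
        return DetectionRecord("f", "p", 2018, interval, stype, y, censored)

    def test_absent_site_emits_one_for_all_nondetections(self):
        recs = [self.rec(1, 0, 0), self.rec(2, 1, 0)]
        assert interval_emission(DetectionParams(), recs, z=0) == 1.0

    def test_detection_impossible_when_absent(self):
        recs = [self.rec(1, 1, 1)]
        assert interval_emission(DetectionParams(), recs, z=0) == 0.0

    def test_occupied_broadcast_detection_matches_detection_prob(self, study_params):
        recs = [self.rec(1, 1, 1)]
        em = interval_emission(study_params.detection, recs, z=1)
        assert em == pytest.approx(detection_prob(study_params.detection, 1), abs=1e-12)
        assert em == pytest.approx(0.5744, abs=1e-4)

    def test_no_records_is_emission_free(self):
        assert interval_emission(DetectionParams(), [], z=0) == 1.0
        assert interval_emission(DetectionParams(), [], z=1) == 1.0

    def test_censored_intervals_excluded(self, study_params):
        recs = [self.rec(1, 1, 1), self.rec(2, 1, None, censored=True)]
        em_with = interval_emission(study_params.detection, recs, z=1)
        em_without = interval_emission(study_params.detection, recs[:1], z=1)
        assert em_with == em_without


def _single_year_point(det_b=0, nd_b=0, det_p=0, nd_p=0, **cov):
    defaults = dict(elev=0.0, lat=0.0, pine=0.5, snag=0.0, age_s=0.0)
    defaults.update(cov)
    return PointInputs(
        point_id="p", fire_index=0, t_start=1, T=1,
        elev=defaults["elev"], lat=defaults["lat"], pine=defaults["pine"],
        snag=np.array([defaults["snag"]]), age_s=np.array([defaults["age_s"]]),
        det_b=np.array([det_b]), nd_b=np.array([nd_b]),
        det_p=np.array([det_p]), nd_p=np.array([nd_p]),
    )


class TestSiteMarginal:
    def test_single_year_closed_form(self, study_params):
        """T = 1, one broadcast detection: marginal likelihood is psi * p."""
        point = _single_year_point(det_b=1)
        occ = study_params.occupancy
        psi = occupancy_prob(
            occ, beta0=occ.beta0[0], elev=0, lat=0, snag=0, age=0, intensity=0.5
        )
        # zero gammas in this parameterization give intensity 0.5
        params = dataclasses.replace(study_params, beetle=BeetleParams())
        p = detection_prob(study_params.detection, 1)
        assert site_marginal_loglik(params, point) == pytest.approx(
            math.log(psi * p), abs=1e-12
        )

    def test_point_with_no_surveys_contributes_zero(self, study_params):
        point = _single_year_point()
        point = dataclasses.replace(
            point, T=3,
            snag=np.zeros(3), age_s=np.zeros(3),
            det_b=np.zeros(3, int), nd_b=np.zeros(3, int),
            det_p=np.zeros(3, int), nd_p=np.zeros(3, int),
        )
        assert site_marginal_loglik(study_params, point) == 0.0

    def test_forward_equals_enumeration_over_random_instances(self):
        """Exact marginalization: forward recursion vs 2^T brute force."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            params, point = random_point_instance(rng, max_T=6)
            a = site_marginal_loglik(params, point)
            b = site_marginal_loglik_enumeration(params, point)
            assert a == pytest.approx(b, abs=1e-10)

    def test_phi_zero_factorizes_over_years(self):
        rng = np.random.default_rng(99)
        params, point = random_point_instance(rng, max_T=5)
        params = dataclasses.replace(
            params, occupancy=dataclasses.replace(params.occupancy, phi=0.0)
        )
        total = site_marginal_loglik(params, point)
        parts = 0.0
        for t in range(point.t_start, point.T + 1):
            i = t - 1
            single = _single_year_point(
                det_b=point.det_b[i], nd_b=point.nd_b[i],
                det_p=point.det_p[i], nd_p=point.nd_p[i],
                elev=point.elev, lat=point.lat, pine=point.pine,
                snag=point.snag[i], age_s=point.age_s[i],
            )
            parts += site_marginal_loglik(params, single)
        assert total == pytest.approx(parts, abs=1e-10)

    def test_outcome_probabilities_sum_to_one(self, study_params):
        """Under the removal design, the per-year outcome space of a
        2-broadcast-interval visit is {00, 1(censored), 01}; summed over two
        years the marginal likelihoods must total 1."""
        outcomes = [(0, 2), (1, 0), (1, 1)]  # (detections, non-detections)
        total = 0.0
        for o1 in outcomes:
            for o2 in outcomes:
                point = PointInputs(
                    point_id="p", fire_index=0, t_start=1, T=2,
                    elev=0.2, lat=-0.4, pine=0.6,
                    snag=np.array([0.1, 0.3]), age_s=np.array([-1.0, 1.0]),
                    det_b=np.array([o1[0], o2[0]]), nd_b=np.array([o1[1], o2[1]]),
                    det_p=np.zeros(2, int), nd_p=np.zeros(2, int),
                )
                total += math.exp(site_marginal_loglik(study_params, point))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestJointLoglik:
    def test_vectorized_matches_scalar_reference(self, study_params):
        dataset, _ = simulate_dataset(
            GeneratorConfig(design=make_table1_design(), seed=5)
        )
        inputs = build_model_inputs(dataset)
        params = study_params.with_beta0(np.full(inputs.n_fires, -1.27))
        model = JointModel(inputs)
        vec = model.site_logliks(params)
        ref = np.array([
            site_marginal_loglik(params, inputs.point(j))
            for j in range(inputs.n_points)
        ])
        np.testing.assert_allclose(vec, ref, atol=1e-10)
        total = joint_loglik(params, inputs)
        assert total == pytest.approx(
            ref.sum() + model.beetle_logliks(params.beetle).sum(), abs=1e-8
        )

    def test_additive_over_independent_points(self, tiny_dataset, study_params):
        inputs = build_model_inputs(tiny_dataset)
        params = study_params
        per_point = JointModel(inputs).site_logliks(params)
        beetle = JointModel(inputs).beetle_logliks(params.beetle)
        assert joint_loglik(params, inputs) == pytest.approx(
            per_point.sum() + beetle.sum(), abs=1e-10
        )

    def test_invariant_to_fire_relabeling(self, tiny_dataset, study_params):
        inputs = build_model_inputs(tiny_dataset)
        flipped = dataclasses.replace(
            tiny_dataset,
            design=dataclasses.replace(
                tiny_dataset.design, fires=tuple(reversed(tiny_dataset.design.fires))
            ),
        ).validate()
        inputs2 = build_model_inputs(flipped)
        assert joint_loglik(study_params, inputs) == pytest.approx(
            joint_loglik(study_params, inputs2), abs=1e-10
        )

    def test_gamma_perturbation_moves_both_components(self, tiny_dataset, study_params):
        """The shared intensity couples the occupancy and beetle parts, and
        the central-difference gradient is step-size consistent."""
        inputs = build_model_inputs(tiny_dataset)
        model = JointModel(inputs)

        def parts(g_age):
            beetle = dataclasses.replace(study_params.beetle, gamma_age=g_age)
            p = dataclasses.replace(study_params, beetle=beetle)
            inten = model.intensity(p.beetle)
            base = model.occupancy_base(p.occupancy, inten)
            site = model.site_logliks_from(
                model.emissions(p.detection), base, p.occupancy.phi
            ).sum()
            return site, model.beetle_logliks(p.beetle, inten).sum()

        g = study_params.beetle.gamma_age
        eps = 1e-4
        site_hi, beetle_hi = parts(g + eps)
        site_lo, beetle_lo = parts(g - eps)
        assert abs(site_hi - site_lo) > 0
        assert abs(beetle_hi - beetle_lo) > 0
        grad = (site_hi + beetle_hi - site_lo - beetle_lo) / (2 * eps)
        site_hi2, beetle_hi2 = parts(g + 2 * eps)
        site_lo2, beetle_lo2 = parts(g - 2 * eps)
        grad2 = (site_hi2 + beetle_hi2 - site_lo2 - beetle_lo2) / (4 * eps)
        assert grad == pytest.approx(grad2, rel=1e-5)


class TestLogPrior:
    def test_all_zero_parameters_closed_form(self):
        params = ModelParameters(
            occupancy=OccupancyParams(beta0=np.zeros(1), tau_beta0=1.0)
        )
        expected = (
            13 * norm(0, math.sqrt(10)).logpdf(0.0)      # vague fixed effects
            + norm(0, 1.0).logpdf(0.0)                   # one fire intercept
            + gamma_dist(0.1, scale=10.0).logpdf(1.0)    # precision hyperprior
        )
        assert log_prior(params) == pytest.approx(expected, abs=1e-10)
        # each vague fixed-effect term at zero
        assert norm(0, math.sqrt(10)).logpdf(0.0) == pytest.approx(
            0.5 * math.log(0.1 / (2 * math.pi)), abs=1e-12
        )

    def test_centered_intercept_is_conditional_mode(self):
        base = OccupancyParams(beta0=np.array([0.4]), mu_beta0=0.4, tau_beta0=2.0)
        off = dataclasses.replace(base, beta0=np.array([1.0]))
        assert (log_prior(ModelParameters(occupancy=base))
                > log_prior(ModelParameters(occupancy=off)))
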