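"""Observation distributions, per-sample probabilities, and gradients.

The dense full-state-space oracle transcribes the defining equations
literally; the restricted engine must reproduce it exactly.  Closed forms
for tiny systems (competing exponential races) are derived independently
inside the tests.
"""

import numpy as np
import pytest

from conftest import genotypes
from pairmhn.likelihood import (
    LikelihoodEngine,
    ZeroProbabilitySampleError,
    conditional_met_distribution,
    dataset_log_likelihood,
    first_observation_distribution,
    propagate_until_met_observation,
    sample_probability,
)
from pairmhn.model import (
    LOG_RATE_FLOOR,
    EventSystem,
    ParameterSet,
    Sample,
    build_generator_parts,
    state_index,
)


def floored_seeding_params(n, theta=None, omega_pt=None, omega_mt=None):
    """Parameters with the seeding rate at the floor and no seeding effects."""
    m = n + 1
    p = ParameterSet(
        np.zeros((m, m)) if theta is None else theta,
        np.zeros(m) if omega_pt is None else omega_pt,
        np.zeros(m) if omega_mt is None else omega_mt,
    )
    p.theta[n, n] = LOG_RATE_FLOOR
    p.theta[n, :n] = 0.0
    p.theta[:n, n] = 0.0
    return p


class TestFirstObservation:
    def test_n0_race(self):
        # seeding rate 1 vs PT observation rate 1; then two rate-1 observations
        op, om = first_observation_distribution(ParameterSet.zeros(0), EventSystem(0))
        assert op.values[state_index([], [], 0)] == pytest.approx(0.5, abs=1e-12)
        assert op.values[state_index([], [], 1)] == pytest.approx(0.25, abs=1e-12)
        assert om.total() == pytest.approx(0.25, abs=1e-12)

    def test_n0_race_general_seeding_rate(self):
        for theta_s in (0.25, 1.0, 3.0):
            p = ParameterSet.zeros(0)
            p.theta[0, 0] = np.log(theta_s)
            op, _ = first_observation_distribution(p, EventSystem(0))
            assert op.values[0] == pytest.approx(1 / (1 + theta_s), abs=1e-9)

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_absorption_conservation(self, n, rng):
        for _ in range(20):
            params = ParameterSet.random(n, rng)
            op, om = first_observation_distribution(params, EventSystem(n))
            assert op.total() + om.total() == pytest.approx(1.0, abs=1e-10)
            assert op.values.min() >= 0 and om.values.min() >= 0

    def test_monotone_in_met_observation_base_rate(self, rng):
        # raising the seeded metastasis detection rate strictly increases the
        # chance that the metastasis is observed first
        sys = EventSystem(2)
        for _ in range(5):
            params = ParameterSet.random(2, rng)
            masses = []
            for bump in (0.0, 0.5, 1.0):
                p = params.copy()
                p.omega_mt[2] += bump
                _, om = first_observation_distribution(p, sys)
                masses.append(om.total())
            assert masses[0] < masses[1] < masses[2]


class TestConditionalAndPropagation:
    def test_n1_closed_form(self):
        # seeding disabled, neutral observation: P(event at PT observation)
        # follows the single-event closed form Theta/(1+Theta)
        p = floored_seeding_params(1)
        p.theta[0, 0] = np.log(2.0)
        _, marginal = conditional_met_distribution(p, EventSystem(1), [1])
        assert marginal == pytest.approx(2 / 3, abs=1e-9)

    def test_conditional_normalized(self, random_params2, sys2):
        for xp in genotypes(2):
            cond, _ = conditional_met_distribution(random_params2, sys2, xp)
            assert cond.total() == pytest.approx(1.0, abs=1e-10)

    def test_conditional_matches_masked_renormalized(self, random_params2, sys2):
        op, _ = first_observation_distribution(random_params2, sys2)
        xp = np.array([1, 0], dtype=np.int8)
        cond, marginal = conditional_met_distribution(random_params2, sys2, xp)
        from pairmhn.likelihood import _pt_match_mask

        masked = np.where(_pt_match_mask(sys2, xp), op.values, 0.0)
        assert marginal == pytest.approx(masked.sum(), abs=1e-15)
        np.testing.assert_allclose(cond.values, masked / masked.sum(), atol=1e-15)

    def test_propagation_zero_on_preseeding_input(self, random_params2, sys2):
        from pairmhn.likelihood import DistVector

        values = np.zeros(sys2.n_states)
        values[state_index([1, 0], [1, 0], 0)] = 1.0  # entirely pre-seeding
        out = propagate_until_met_observation(
            random_params2, sys2, DistVector(values, "SD-full")
        )
        assert out.total() == 0.0

    def test_propagation_point_mass_on_full_state(self, random_params2, sys2):
        from pairmhn.likelihood import DistVector

        idx = state_index([0, 1], [1, 1], 1)  # metastasis fully progressed
        values = np.zeros(sys2.n_states)
        values[idx] = 1.0
        out = propagate_until_met_observation(
            random_params2, sys2, DistVector(values, "SD-full")
        )
        assert out.values[idx] == pytest.approx(1.0, abs=1e-10)
        assert out.total() == pytest.approx(1.0, abs=1e-10)

    def test_propagation_conserves_seeded_mass(self, random_params2, sys2):
        op, _ = first_observation_distribution(random_params2, sys2)
        from pairmhn.likelihood import DistVector
        from pairmhn.model import _bit_tables

        _, _, seed = _bit_tables(2)
        out = propagate_until_met_observation(
            random_params2, sys2, DistVector(op.values, "SD-full")
        )
        assert out.total() == pytest.approx(op.values[seed == 1].sum(), abs=1e-10)


class TestPairedProbabilities:
    def test_order_marginal_is_sum_of_orders(self, random_params2, sys2):
        eng = LikelihoodEngine(sys2)
        for xp in genotypes(2):
            for xm in genotypes(2):
                parts = [
                    eng.sample_probability(
                        random_params2, Sample("d", pt=xp, mt=xm, obs_order=order)
                    )
                    for order in ("pt_first", "mt_first")
                ]
                total = eng.sample_probability(
                    random_params2, Sample("d", pt=xp, mt=xm, obs_order="unknown")
                )
                assert total == parts[0] + parts[1]  # definitional, bit-equal

    def test_label_swap_symmetry(self, rng):
        # with no seeding environment effects and identical observation
        # vectors the model is PT/MT exchangeable after seeding
        sys = EventSystem(2)
        eng = LikelihoodEngine(sys)
        for _ in range(3):
            params = ParameterSet.random(2, rng)
            params.theta[:2, 2] = 0.0
            params.omega_mt = params.omega_pt.copy()
            for xp in genotypes(2):
                for xm in genotypes(2):
                    a = eng.sample_probability(
                        params, Sample("d", pt=xp, mt=xm, obs_order="pt_first")
                    )
                    b = eng.sample_probability(
                        params, Sample("d", pt=xm, mt=xp, obs_order="mt_first")
                    )
                    assert a == pytest.approx(b, rel=1e-9, abs=1e-15)

    def test_three_state_race_closed_form(self):
        # n=1 pair (pt=[0], mt=[1]) integrates by hand: wild type races
        # seeding vs the shared event vs detection, then the seeded state
        # races the PT event, the MT event, and two detections
        t1, ts_effect, rs = 1.7, 0.6, 0.8
        p = ParameterSet.zeros(1)
        p.theta[0, 0] = np.log(t1)
        p.theta[0, 1] = np.log(ts_effect)
        p.theta[1, 1] = np.log(rs)
        tm = t1 * ts_effect
        reach_b = rs / (t1 + rs + 1)
        po_mo = reach_b * (
            1 / (t1 + tm + 2) * (tm / (tm + 1))
            + tm / (t1 + tm + 2) * (1 / (t1 + 2))
        )
        mo_po = reach_b * (tm / (t1 + tm + 2)) * (1 / (t1 + 2)) * (1 / (t1 + 1))
        sys = EventSystem(1)
        eng = LikelihoodEngine(sys)
        got_po = eng.sample_probability(p, Sample("d", pt=[0], mt=[1], obs_order="pt_first"))
        got_mo = eng.sample_probability(p, Sample("d", pt=[0], mt=[1], obs_order="mt_first"))
        assert got_po == pytest.approx(po_mo, rel=1e-12)
        assert got_mo == pytest.approx(mo_po, rel=1e-12)


class TestUnpairedProbabilities:
    def test_pt_only_law_of_total_probability(self, rng):
        for n in (1, 2):
            sys = EventSystem(n)
            eng = LikelihoodEngine(sys)
            params = ParameterSet.random(n, rng)
            total = sum(
                eng.sample_probability(params, Sample("d", pt=xp, seeding_evidence=ev))
                for xp in genotypes(n)
                for ev in ("absent", "present")
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_mt_only_is_pair_marginalization(self, random_params2, sys2):
        # the dense path sums order-marginal pair probabilities literally
        for xm in genotypes(2):
            by_sum = sum(
                sample_probability(
                    random_params2, sys2,
                    Sample("d", pt=xp, mt=xm, obs_order="unknown"), method="dense",
                )
                for xp in genotypes(2)
            )
            direct = sample_probability(
                random_params2, sys2, Sample("d", mt=xm), method="dense"
            )
            assert direct == pytest.approx(by_sum, rel=1e-12)
            fast = sample_probability(random_params2, sys2, Sample("d", mt=xm))
            assert fast == pytest.approx(direct, abs=1e-12)

    def test_n0_pt_only_absent(self):
        p = sample_probability(
            ParameterSet.zeros(0), EventSystem(0),
            Sample("d", pt=np.zeros(0, dtype=np.int8), seeding_evidence="absent"),
        )
        assert p == pytest.approx(0.5, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_restricted_equals_dense(self, n, rng):
        sys = EventSystem(n)
        eng = LikelihoodEngine(sys)
        for _ in range(2):
            params = ParameterSet.random(n, rng)
            for xp in genotypes(n):
                for xm in genotypes(n):
                    for order in ("pt_first", "mt_first", "unknown"):
                        s = Sample("d", pt=xp, mt=xm, obs_order=order)
                        dense = sample_probability(params, sys, s, method="dense")
                        fast = eng.sample_probability(params, s)
                        assert fast == pytest.approx(dense, abs=1e-9)
            for xm in genotypes(n):
                s = Sample("d", mt=xm)
                assert eng.sample_probability(params, s) == pytest.approx(
                    sample_probability(params, sys, s, method="dense"), abs=1e-9
                )
            for xp in genotypes(n):
                for ev in ("absent", "present", "unknown"):
                    s = Sample("d", pt=xp, seeding_evidence=ev)
                    assert eng.sample_probability(params, s) == pytest.approx(
                        sample_probability(params, sys, s, method="dense"), abs=1e-9
                    )


class TestDatasetLikelihood:
    def test_n0_single_sample(self):
        ll = dataset_log_likelihood(
            ParameterSet.zeros(0), EventSystem(0),
            [Sample("d", pt=np.zeros(0, dtype=np.int8), seeding_evidence="absent")],
        )
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_duplication_invariance(self, random_params2, sys2):
        s = Sample("d", pt=[1, 0], mt=[1, 1], obs_order="unknown")
        one = dataset_log_likelihood(random_params2, sys2, [s])
        three = dataset_log_likelihood(
            random_params2, sys2,
            [s, Sample("e", pt=[1, 0], mt=[1, 1], obs_order="unknown"), s],
        )
        assert one == pytest.approx(three, abs=1e-15)

    def test_underflow_reports_patient(self):
        p = ParameterSet.zeros(1)
        p.theta[0, 0] = -700.0  # event essentially impossible
        with pytest.raises(ZeroProbabilitySampleError) as err:
            dataset_log_likelihood(
                p, EventSystem(1), [Sample("patient-7", pt=[1], seeding_evidence="unknown")]
            )
        assert err.value.patient_id == "patient-7"

    def test_gradient_matches_finite_differences(self, rng):
        for n in (1, 2):
            sys = EventSystem(n)
            eng = LikelihoodEngine(sys)
            params = ParameterSet.random(n, rng)
            samples = [
                Sample("a", pt=genotypes(n)[-1], mt=genotypes(n)[0], obs_order="unknown"),
                Sample("b", pt=genotypes(n)[0], seeding_evidence="unknown"),
                Sample("c", mt=genotypes(n)[-1]),
            ]
            ll, grad = eng.dataset_log_likelihood_and_gradient(params, samples)
            assert ll == pytest.approx(eng.dataset_log_likelihood(params, samples))
            xi = params.flatten()
            g = grad.flatten()
            h = 1e-5
            for k in range(len(xi)):
                e = np.zeros_like(xi)
                e[k] = h
                fp = eng.dataset_log_likelihood(ParameterSet.unflatten(xi + e, n), samples)
                fm = eng.dataset_log_likelihood(ParameterSet.unflatten(xi - e, n), samples)
                assert g[k] == pytest.approx((fp - fm) / (2 * h), abs=1e-4)


class TestClassicalReduction:
    def test_pt_marginal_reduces_to_classical_mhn(self, rng):
        # with seeding disabled, primary-only marginals follow the classical
        # single-tumor model; the reference distribution is built here from
        # first principles on the n-event lattice
        n = 3
        theta = rng.normal(0, 0.5, (n + 1, n + 1))
        np.fill_diagonal(theta, rng.normal(-0.5, 0.7, n + 1))
        omega = rng.normal(0, 0.4, n + 1)
        params = floored_seeding_params(n, theta=theta.copy())
        params.omega_pt = omega.copy()
        params.omega_pt[n] = 0.0
        size = 1 << n
        bits = (np.arange(size)[:, None] >> np.arange(n)[None, :]) & 1
        Q = np.zeros((size, size))
        for i in range(n):
            absent = bits[:, i] == 0
            rates = np.exp(params.theta[i, i] + bits @ params.theta[i, :n])
            src = np.nonzero(absent)[0]
            Q[src | (1 << i), src] = rates[absent]
        u = np.exp(bits @ omega[:n])
        M = np.diag(u + Q.sum(axis=0)) - Q
        b = np.zeros(size)
        b[0] = 1.0
        classical = u * np.linalg.solve(M, b)
        sys = EventSystem(n)
        eng = LikelihoodEngine(sys)
        ours = np.array([
            eng.sample_probability(params, Sample("d", pt=xp, seeding_evidence="unknown"))
            for xp in genotypes(n)
        ])
        assert 0.5 * np.abs(ours - classical).sum() < 1e-6
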