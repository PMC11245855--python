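"""Observation-time distributions and per-sample likelihoods.

Two engines compute every per-sample probability:

* a **dense oracle** that transcribes the defining linear-algebra
  operations literally on the full ``2**(2n+1)`` state space (intended for
  small ``n`` and for validation), and
* a **restricted engine** (:class:`LikelihoodEngine`) that works on
  per-sample sub-lattices, with cost exponential only in the number of
  events present in a sample, and supplies analytic gradients via adjoint
  solves.

The model distinguishes five kinds of data points: paired samples with the
primary observed first, paired with the metastasis observed first, paired
with unknown observation order (the sum of the two ordered probabilities),
primary-only samples (with evidence that a metastasis is absent, present,
or unknown), and metastasis-only samples (which imply seeding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _lattice
from .model import (
    EventSystem,
    GeneratorParts,
    PairMHNError,
    ParameterSet,
    Sample,
    _bit_tables,
    build_generator_parts,
    state_index,
)

#: probabilities below this are reported as errors rather than silently
#: underflowing into the log-likelihood
MIN_SAMPLE_PROBABILITY = 1e-300


class ImpossibleObservationError(PairMHNError):
    """A conditioning genotype has probability zero under the model."""


class ZeroProbabilitySampleError(PairMHNError):
    """A sample's probability underflowed; carries the patient id."""

    def __init__(self, patient_id: str, probability: float) -> None:
        self.patient_id = patient_id
        self.probability = probability
        super().__init__(
            f"sample {patient_id!r} has vanishing probability {probability!r}"
        )


@dataclass
class DistVector:
    """Probability vector over an explicitly indexed state space."""

    values: np.ndarray
    space_tag: str
    states: Optional[np.ndarray] = None  # explicit indices; None = full space

    def total(self) -> float:
        return float(self.values.sum())


# ---------------------------------------------------------------------------
# Dense oracle
# ---------------------------------------------------------------------------


def _first_obs_solve(
    params: ParameterSet, sys: EventSystem, parts: Optional[GeneratorParts] = None
) -> tuple[np.ndarray, GeneratorParts]:
    """Solve (US - Q) z = p0 on the full state space by sparse LU."""
    if parts is None:
        parts = build_generator_parts(params, sys)
    n = sys.n
    size = sys.n_states
    ptbits, mtbits, seed = _bit_tables(n)
    unreachable = (seed == 0) & ~(ptbits == mtbits).all(axis=1)
    d = parts.exit_rates + parts.u_pt + parts.u_mt
    d = np.where(unreachable, 1.0, d)  # keep the operator non-singular off the reachable set
    M = sp.csc_array(sp.diags_array(d) - parts.rate_matrix)
    b = np.zeros(size)
    b[0] = 1.0
    z = spla.spsolve(M, b)
    if not np.all(np.isfinite(z)):
        raise PairMHNError("first-observation solve produced non-finite values")
    return z, parts


def first_observation_distribution(
    params: ParameterSet, sys: EventSystem, parts: Optional[GeneratorParts] = None
) -> tuple[DistVector, DistVector]:
    """Distributions over states at the first observation (PT- and MT-triggered).

    Together the two vectors carry the full probability mass: the chain is
    absorbed by one of the two observations with probability 1.
    """
    z, parts = _first_obs_solve(params, sys, parts)
    return (
        DistVector(parts.u_pt * z, "SD-full"),
        DistVector(parts.u_mt * z, "SD-full"),
    )


def _pt_match_mask(sys: EventSystem, pt_genotype: np.ndarray) -> np.ndarray:
    ptbits, _, _ = _bit_tables(sys.n)
    return (ptbits == np.asarray(pt_genotype, dtype=np.int64)[None, :]).all(axis=1)


def _mt_match_mask(sys: EventSystem, mt_genotype: np.ndarray) -> np.ndarray:
    _, mtbits, _ = _bit_tables(sys.n)
    return (mtbits == np.asarray(mt_genotype, dtype=np.int64)[None, :]).all(axis=1)


def conditional_met_distribution(
    params: ParameterSet,
    sys: EventSystem,
    pt_genotype: Sequence[int],
    parts: Optional[GeneratorParts] = None,
) -> tuple[DistVector, float]:
    """Metastasis-state distribution at PT observation, given the PT genotype.

    Returns the renormalized conditional distribution together with the
    marginal probability of the conditioning PT observation.
    """
    pt_genotype = np.asarray(pt_genotype, dtype=np.int64)
    pbar_op, _ = first_observation_distribution(params, sys, parts)
    mask = _pt_match_mask(sys, pt_genotype)
    masked = np.where(mask, pbar_op.values, 0.0)
    marginal = float(masked.sum())
    if marginal <= 0.0:
        raise ImpossibleObservationError(
            f"PT genotype {pt_genotype.tolist()} has zero observation probability"
        )
    return DistVector(masked / marginal, "SD-full"), marginal


def _propagate(
    params: ParameterSet,
    sys: EventSystem,
    dist: DistVector,
    entity: str,
    parts: Optional[GeneratorParts] = None,
) -> DistVector:
    if parts is None:
        parts = build_generator_parts(params, sys)
    _, _, seed = _bit_tables(sys.n)
    s1 = np.nonzero(seed == 1)[0]
    if entity == "mt":
        q, u = parts.qm, parts.u_mt
    else:
        q, u = parts.qp, parts.u_pt
    q_exit = np.asarray(q.sum(axis=0)).ravel()
    sub = q[np.ix_(s1, s1)]
    d = (u + q_exit)[s1]
    M = sp.csc_array(sp.diags_array(d) - sub)
    z = spla.spsolve(M, dist.values[s1])
    out = np.zeros(sys.n_states)
    out[s1] = u[s1] * z
    return DistVector(out, "SD-full")


def propagate_until_met_observation(
    params: ParameterSet,
    sys: EventSystem,
    cond: DistVector,
    parts: Optional[GeneratorParts] = None,
) -> DistVector:
    """Evolve unobserved metastases until their observation.

    Seeding cannot occur after the first observation, so mass on pre-seeding
    states contributes exactly zero; the solve is restricted to the seeded
    subspace, which also keeps the operator non-singular.
    """
    return _propagate(params, sys, cond, "mt", parts)


def propagate_until_pt_observation(
    params: ParameterSet,
    sys: EventSystem,
    cond: DistVector,
    parts: Optional[GeneratorParts] = None,
) -> DistVector:
    """Mirror construction: evolve the unobserved primary after MT observation."""
    return _propagate(params, sys, cond, "pt", parts)


def _paired_probability_dense(
    params: ParameterSet,
    sys: EventSystem,
    pt: np.ndarray,
    mt: np.ndarray,
    obs_order: str,
    parts: Optional[GeneratorParts] = None,
) -> float:
    if parts is None:
        parts = build_generator_parts(params, sys)
    target = state_index(pt, mt, 1)
    if obs_order == "unknown":
        return _paired_probability_dense(
            params, sys, pt, mt, "pt_first", parts
        ) + _paired_probability_dense(params, sys, pt, mt, "mt_first", parts)
    if obs_order == "pt_first":
        cond, marginal = conditional_met_distribution(params, sys, pt, parts)
        prop = propagate_until_met_observation(params, sys, cond, parts)
        return float(prop.values[target]) * marginal
    if obs_order == "mt_first":
        _, pbar_om = first_observation_distribution(params, sys, parts)
        mask = _mt_match_mask(sys, np.asarray(mt, dtype=np.int64))
        masked = np.where(mask, pbar_om.values, 0.0)
        marginal = float(masked.sum())
        if marginal <= 0.0:
            raise ImpossibleObservationError(
                f"MT genotype {np.asarray(mt).tolist()} has zero observation probability"
            )
        cond = DistVector(masked / marginal, "SD-full")
        prop = propagate_until_pt_observation(params, sys, cond, parts)
        return float(prop.values[target]) * marginal
    raise PairMHNError(f"unknown obs_order {obs_order!r}")


def _unpaired_probability_dense(
    params: ParameterSet,
    sys: EventSystem,
    sample: Sample,
    parts: Optional[GeneratorParts] = None,
) -> float:
    if parts is None:
        parts = build_generator_parts(params, sys)
    n = sys.n
    genotypes = [np.array([(g >> i) & 1 for i in range(n)], dtype=np.int8)
                 for g in range(1 << n)]
    if sample.sample_type == "mt_only":
        # marginalize the unobserved primary over all genotypes (seeded states only)
        return float(
            sum(
                _paired_probability_dense(params, sys, xp, sample.mt, "unknown", parts)
                for xp in genotypes
            )
        )
    evidence = sample.seeding_evidence
    p_absent = p_present = 0.0
    if evidence in ("absent", "unknown"):
        pbar_op, _ = first_observation_distribution(params, sys, parts)
        p_absent = float(pbar_op.values[state_index(sample.pt, sample.pt, 0)])
    if evidence in ("present", "unknown"):
        p_present = float(
            sum(
                _paired_probability_dense(params, sys, sample.pt, xm, "unknown", parts)
                for xm in genotypes
            )
        )
    return p_absent + p_present


# ---------------------------------------------------------------------------
# Restricted engine (production path)
# ---------------------------------------------------------------------------


class LikelihoodEngine:
    """Per-sample probabilities and gradients on restricted state spaces.

    Stage structures are cached per genotype support, so repeated
    evaluations during optimization only pay for linear solves.  Identical
    sample configurations in a dataset are grouped and computed once.
    """

    def __init__(self, sys: EventSystem) -> None:
        self.sys = sys
        self.factory = _lattice.PipelineFactory(sys)

    def _check(self, params: ParameterSet, sample: Sample) -> None:
        if params.n != self.sys.n:
            raise PairMHNError("parameter dimension does not match the event system")
        for g in (sample.pt, sample.mt):
            if g is not None and len(g) != self.sys.n:
                raise PairMHNError(
                    f"sample {sample.patient_id!r}: genotype length {len(g)} != n={self.sys.n}"
                )

    def sample_probability(self, params: ParameterSet, sample: Sample) -> float:
        self._check(params, sample)
        _, pipe = self.factory.for_sample(sample)
        return pipe.probability(params.flatten())

    def sample_log_probability(self, params: ParameterSet, sample: Sample) -> float:
        p = self.sample_probability(params, sample)
        if not np.isfinite(p) or p < MIN_SAMPLE_PROBABILITY:
            raise ZeroProbabilitySampleError(sample.patient_id, p)
        return float(np.log(p))

    def _grouped(self, samples: Sequence[Sample]):
        groups: dict = {}
        for s in samples:
            self_key, pipe = self.factory.for_sample(s)
            if self_key in groups:
                groups[self_key][1] += 1
            else:
                groups[self_key] = [pipe, 1, s.patient_id]
        return groups

    def dataset_log_likelihood(
        self, params: ParameterSet, samples: Sequence[Sample]
    ) -> float:
        if not samples:
            raise PairMHNError("empty dataset")
        for s in samples:
            self._check(params, s)
        xi = params.flatten()
        total = 0.0
        for pipe, weight, pid in self._grouped(samples).values():
            p = pipe.probability(xi)
            if not np.isfinite(p) or p < MIN_SAMPLE_PROBABILITY:
                raise ZeroProbabilitySampleError(pid, p)
            total += weight * np.log(p)
        return total / len(samples)

    def dataset_log_likelihood_and_gradient(
        self, params: ParameterSet, samples: Sequence[Sample]
    ) -> tuple[float, ParameterSet]:
        """Mean log-likelihood and its gradient in ParameterSet shape."""
        if not samples:
            raise PairMHNError("empty dataset")
        for s in samples:
            self._check(params, s)
        xi = params.flatten()
        total = 0.0
        grad = np.zeros_like(xi)
        for pipe, weight, pid in self._grouped(samples).values():
            p, g = pipe.probability_and_gradient(xi)
            if not np.isfinite(p) or p < MIN_SAMPLE_PROBABILITY:
                raise ZeroProbabilitySampleError(pid, p)
            total += weight * np.log(p)
            grad += (weight / p) * g
        scale = 1.0 / len(samples)
        return total * scale, ParameterSet.unflatten(grad * scale, self.sys.n)


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------


def paired_probability(
    params: ParameterSet,
    sys: EventSystem,
    pt_genotype: Sequence[int],
    mt_genotype: Sequence[int],
    obs_order: str = "unknown",
    method: str = "restricted",
) -> float:
    """Probability of observing the given PT/MT pair (Eq-by-order or marginal)."""
    pt = np.asarray(pt_genotype, dtype=np.int8)
    mt = np.asarray(mt_genotype, dtype=np.int8)
    if method == "dense":
        return _paired_probability_dense(params, sys, pt, mt, obs_order)
    engine = LikelihoodEngine(sys)
    return engine.sample_probability(
        params, Sample("_", pt=pt, mt=mt, obs_order=obs_order)
    )


def unpaired_probability(
    params: ParameterSet, sys: EventSystem, sample: Sample, method: str = "restricted"
) -> float:
    """Probability of a single-genotype sample (marginalizing the missing tumor)."""
    if sample.sample_type == "paired":
        raise PairMHNError("unpaired_probability requires exactly one genotype")
    if method == "dense":
        return _unpaired_probability_dense(params, sys, sample)
    return LikelihoodEngine(sys).sample_probability(params, sample)


def sample_probability(
    params: ParameterSet, sys: EventSystem, sample: Sample, method: str = "restricted"
) -> float:
    if method == "dense":
        if sample.sample_type == "paired":
            return _paired_probability_dense(
                params, sys, sample.pt, sample.mt, sample.obs_order
            )
        return _unpaired_probability_dense(params, sys, sample)
    return LikelihoodEngine(sys).sample_probability(params, sample)


def dataset_log_likelihood(
    params: ParameterSet,
    sys: EventSystem,
    samples: Iterable[Sample],
    method: str = "restricted",
) -> float:
    samples = list(samples)
    if method == "dense":
        if not samples:
            raise PairMHNError("empty dataset")
        logs = []
        for s in samples:
            p = sample_probability(params, sys, s, method="dense")
            if not np.isfinite(p) or p < MIN_SAMPLE_PROBABILITY:
                raise ZeroProbabilitySampleError(s.patient_id, p)
            logs.append(np.log(p))
        return float(np.mean(logs))
    return LikelihoodEngine(sys).dataset_log_likelihood(params, samples)


def dataset_log_likelihood_and_gradient(
    params: ParameterSet, sys: EventSystem, samples: Iterable[Sample]
) -> tuple[float, ParameterSet]:
    return LikelihoodEngine(sys).dataset_log_likelihood_and_gradient(
        params, list(samples)
    )
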