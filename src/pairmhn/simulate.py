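"""Exact stochastic simulation and Monte-Carlo timing estimates.

The Gillespie sampler draws exponential waiting times against the summed
outgoing rate of the current state and picks the jump by a single uniform
against the cumulative rate vector, so it samples the continuous-time chain
exactly.  ``until_both_observations`` mode continues the not-yet-observed
tumor under its restricted dynamics after the first observation, matching
the consecutive-observation semantics of the likelihood; a primary tumor
observed before seeding halts the whole system and leaves the metastasis
forever unobservable.

Reproducibility: every run uses a dedicated bit-stream derived from
``SeedSequence(entropy=seed, spawn_key=(run_index,))``, so cohorts and
estimates are bit-identical across runs and platforms for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg as sla

from .model import EventSystem, PairMHNError, ParameterSet, Sample

MODES = ("until_first_observation", "until_both_observations")
CONDITIONS = ("observed_in_PT", "observed_in_MT")


class UndefinedEstimateError(PairMHNError):
    """No simulated history satisfied the conditioning event."""


@dataclass
class History:
    """One realization: ordered (kind, event_index, time) steps plus summaries.

    Step kinds: ``joint`` (shared pre-seeding occurrence), ``pt``/``mt``
    (post-seeding occurrences), ``seeding``, ``obs_pt``, ``obs_mt``.
    ``event_index`` is -1 for non-progression steps.  Genotypes are frozen
    at the respective observation instants.
    """

    steps: list[tuple[str, int, float]]
    pt_at_observation: Optional[np.ndarray] = None
    mt_at_observation: Optional[np.ndarray] = None
    pt_obs_time: Optional[float] = None
    mt_obs_time: Optional[float] = None
    seeding_time: Optional[float] = None

    def event_log(self, sys: EventSystem) -> list[tuple[str, float]]:
        """Human-readable (label, time) pairs."""
        out = []
        for kind, ev, t in self.steps:
            if kind == "joint":
                out.append((sys.event_names[ev], t))
            elif kind in ("pt", "mt"):
                out.append((f"{sys.event_names[ev]} ({kind.upper()})", t))
            elif kind == "seeding":
                out.append(("Seeding", t))
            else:
                out.append(("PT observation" if kind == "obs_pt" else "MT observation", t))
        return out


class _RateCache:
    """Cumulative-rate tables keyed by the dynamically relevant state parts."""

    def __init__(self, params: ParameterSet, sys: EventSystem) -> None:
        self.n = sys.n
        self.theta = params.theta
        self.omega_pt = params.omega_pt
        self.omega_mt = params.omega_mt
        self.joint: dict = {}
        self.pt_phase: dict = {}
        self.mt_phase: dict = {}

    def _logsum(self, row: int, mask: int, extra: float = 0.0) -> float:
        th = self.theta
        s = th[row, row] + extra
        g = mask
        j = 0
        while g:
            if g & 1:
                s += th[row, j]
            g >>= 1
            j += 1
        return s

    def _obs_rate(self, omega: np.ndarray, mask: int, seeded: bool) -> float:
        s = omega[self.n] if seeded else 0.0
        g = mask
        j = 0
        while g:
            if g & 1:
                s += omega[j]
            g >>= 1
            j += 1
        return math.exp(s)

    def joint_table(self, p: int, m: int, s: int):
        """Moves before the first observation: key is the full latent state."""
        key = (p, m, s)
        tab = self.joint.get(key)
        if tab is None:
            moves: list[tuple[str, int]] = []
            rates: list[float] = []
            n = self.n
            if s == 0:
                for i in range(n):
                    if not (p >> i) & 1:
                        moves.append(("joint", i))
                        rates.append(math.exp(self._logsum(i, p)))
                moves.append(("seeding", -1))
                rates.append(math.exp(self._logsum(n, p)))
                moves.append(("obs_pt", -1))
                rates.append(self._obs_rate(self.omega_pt, p, False))
            else:
                for i in range(n):
                    if not (p >> i) & 1:
                        moves.append(("pt", i))
                        rates.append(math.exp(self._logsum(i, p)))
                for i in range(n):
                    if not (m >> i) & 1:
                        moves.append(("mt", i))
                        rates.append(math.exp(self._logsum(i, m, self.theta[i, n])))
                moves.append(("obs_pt", -1))
                rates.append(self._obs_rate(self.omega_pt, p, True))
                moves.append(("obs_mt", -1))
                rates.append(self._obs_rate(self.omega_mt, m, True))
            tab = (moves, np.cumsum(rates))
            self.joint[key] = tab
        return tab

    def single_table(self, entity: str, mask: int):
        """Moves of the remaining tumor after the first observation (seeded)."""
        cache = self.pt_phase if entity == "pt" else self.mt_phase
        tab = cache.get(mask)
        if tab is None:
            moves, rates = [], []
            for i in range(self.n):
                if not (mask >> i) & 1:
                    if entity == "pt":
                        moves.append(("pt", i))
                        rates.append(math.exp(self._logsum(i, mask)))
                    else:
                        moves.append(("mt", i))
                        rates.append(math.exp(self._logsum(i, mask, self.theta[i, self.n])))
            if entity == "pt":
                moves.append(("obs_pt", -1))
                rates.append(self._obs_rate(self.omega_pt, mask, True))
            else:
                moves.append(("obs_mt", -1))
                rates.append(self._obs_rate(self.omega_mt, mask, True))
            tab = (moves, np.cumsum(rates))
            cache[mask] = tab
        return tab


def _mask_to_genotype(mask: int, n: int) -> np.ndarray:
    return np.array([(mask >> i) & 1 for i in range(n)], dtype=np.int8)


def gillespie_run(
    params: ParameterSet,
    sys: EventSystem,
    rng: np.random.Generator,
    mode: str = "until_first_observation",
    _cache: Optional[_RateCache] = None,
) -> History:
    """Sample one realization of the joint progression process."""
    if mode not in MODES:
        raise PairMHNError(f"mode must be one of {MODES}")
    cache = _cache if _cache is not None else _RateCache(params, sys)
    n = sys.n
    p = m = s = 0
    t = 0.0
    steps: list[tuple[str, int, float]] = []
    hist = History(steps)

    def draw(moves, cum):
        nonlocal t
        total = cum[-1]
        t += -math.log1p(-rng.random()) / total
        k = int(np.searchsorted(cum, rng.random() * total, side="right"))
        return moves[k]

    # phase 1: until the first observation
    while True:
        kind, ev = draw(*cache.joint_table(p, m, s))
        steps.append((kind, ev, t))
        if kind == "joint":
            p |= 1 << ev
            m |= 1 << ev
        elif kind == "pt":
            p |= 1 << ev
        elif kind == "mt":
            m |= 1 << ev
        elif kind == "seeding":
            s = 1
            hist.seeding_time = t
        elif kind == "obs_pt":
            hist.pt_at_observation = _mask_to_genotype(p, n)
            hist.pt_obs_time = t
            break
        else:  # obs_mt
            hist.mt_at_observation = _mask_to_genotype(m, n)
            hist.mt_obs_time = t
            break
    if mode == "until_first_observation":
        return hist
    # phase 2: the remaining tumor, if still observable
    if hist.mt_obs_time is None and s == 0:
        return hist  # primary observed before seeding: no metastasis, ever
    entity, mask = ("mt", m) if hist.mt_obs_time is None else ("pt", p)
    while True:
        kind, ev = draw(*cache.single_table(entity, mask))
        steps.append((kind, ev, t))
        if kind in ("pt", "mt"):
            mask |= 1 << ev
        elif kind == "obs_pt":
            hist.pt_at_observation = _mask_to_genotype(mask, n)
            hist.pt_obs_time = t
            return hist
        else:
            hist.mt_at_observation = _mask_to_genotype(mask, n)
            hist.mt_obs_time = t
            return hist


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Synthetic-cohort layout emulating a clinical sequencing study.

    Default type fractions mirror a large lung-adenocarcinoma cohort
    (roughly 47% primary-only, 44% metastasis-only, 9% paired samples).
    Annotation policies control whether the realized observation order and
    the latent seeding status at primary observation are recorded or left
    unknown.
    """

    n_patients: int
    fractions: dict = field(
        default_factory=lambda: {"pt_only": 0.4685, "mt_only": 0.4387, "paired": 0.0928}
    )
    seed: int = 0
    obs_order_policy: str = "recorded"
    seeding_evidence_policy: str = "recorded"

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise PairMHNError("n_patients must be >= 0")
        fr = self.fractions
        if set(fr) != {"pt_only", "mt_only", "paired"}:
            raise PairMHNError("fractions must have keys pt_only, mt_only, paired")
        vals = np.array([fr["pt_only"], fr["mt_only"], fr["paired"]])
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
            raise PairMHNError("fractions must be nonnegative and sum to 1")
        if self.obs_order_policy not in ("recorded", "unknown"):
            raise PairMHNError("obs_order_policy must be 'recorded' or 'unknown'")
        if self.seeding_evidence_policy not in ("recorded", "unknown"):
            raise PairMHNError("seeding_evidence_policy must be 'recorded' or 'unknown'")


def _run_rng(seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(run_index,)))


def simulate_cohort(
    params: ParameterSet, spec: CohortSpec, sys: EventSystem
) -> tuple[list[Sample], list[History]]:
    """Generate a cohort of samples with the latent histories retained.

    Sample types are assigned by the spec fractions.  A metastasis-only or
    paired patient requires an observable metastasis, so histories in which
    the primary tumor is detected before seeding are rejected and redrawn
    (their probability mass corresponds to patients who could never
    contribute such a sample).
    """
    n = sys.n
    cache = _RateCache(params, sys)
    type_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0, 0))
    )
    kinds = ("pt_only", "mt_only", "paired")
    probs = np.array([spec.fractions[k] for k in kinds])
    assignments = type_rng.choice(len(kinds), size=spec.n_patients, p=probs)
    samples: list[Sample] = []
    histories: list[History] = []
    run_index = 0
    for i, ki in enumerate(assignments):
        kind = kinds[ki]
        while True:
            rng = _run_rng(spec.seed, run_index + 1)
            run_index += 1
            hist = gillespie_run(params, sys, rng, "until_both_observations", cache)
            if kind == "pt_only" or hist.mt_obs_time is not None:
                break
        pid = f"P{i + 1:05d}"
        if kind == "pt_only":
            seeded_at_pt_obs = (
                hist.seeding_time is not None and hist.seeding_time < hist.pt_obs_time
            )
            evidence = (
                ("present" if seeded_at_pt_obs else "absent")
                if spec.seeding_evidence_policy == "recorded"
                else "unknown"
            )
            samples.append(Sample(pid, pt=hist.pt_at_observation, seeding_evidence=evidence))
        elif kind == "mt_only":
            samples.append(Sample(pid, mt=hist.mt_at_observation))
        else:
            order = "pt_first" if hist.pt_obs_time < hist.mt_obs_time else "mt_first"
            if spec.obs_order_policy == "unknown":
                order = "unknown"
            samples.append(
                Sample(pid, pt=hist.pt_at_observation, mt=hist.mt_at_observation,
                       obs_order=order)
            )
        histories.append(hist)
    return samples, histories


# ---------------------------------------------------------------------------
# Pre-seeding probabilities
# ---------------------------------------------------------------------------


def example_sparse_network(n: int = 4) -> ParameterSet:
    """Reference sparse ground-truth network for recovery experiments.

    Four progression events with realistic base rates (log scale, relative
    to the wild-type detection rate), five strong directed effects of mixed
    sign including one promoter of seeding and one post-seeding suppression,
    and mild observation effects.  Only ``n=4`` is defined.
    """
    if n != 4:
        raise PairMHNError("the reference network is defined for n=4")
    th = np.zeros((5, 5))
    np.fill_diagonal(th, [-0.3, -0.8, -1.2, -1.5, -1.0])
    th[1, 0] = 1.5   # event 1 promotes event 2
    th[0, 3] = -2.0  # event 4 suppresses event 1
    th[2, 1] = 1.2   # event 2 promotes event 3
    th[4, 0] = 1.0   # event 1 promotes seeding
    th[3, 4] = -1.5  # seeding suppresses event 4 in the metastasis
    return ParameterSet(
        th,
        np.array([0.0, 0.3, 0.0, 0.0, 0.0]),
        np.array([0.0, 0.0, 0.4, 0.0, 0.0]),
    )


@dataclass
class PreSeedingEstimate:
    probability: float
    stderr: float
    n_conditioned: int
    n_sims: int


def _occurrence_kind(hist: History, event: int) -> Optional[str]:
    for kind, ev, _ in hist.steps:
        if ev == event and kind in ("joint", "pt", "mt"):
            return kind
    return None


def pre_seeding_probability(
    params: ParameterSet,
    sys: EventSystem,
    event_index: int,
    condition: str,
    n_sims: int,
    seed: int = 0,
) -> PreSeedingEstimate:
    """Monte-Carlo probability that an event predates seeding.

    Conditions on the event being present in the primary tumor at its
    observation (``observed_in_PT``) or in the metastasis at its observation
    (``observed_in_MT``).  An event occurred pre-seeding when its occurrence
    in the conditioning tumor's lineage happened in the shared phase
    (including histories where seeding never happened at all).
    """
    if condition not in CONDITIONS:
        raise PairMHNError(f"condition must be one of {CONDITIONS}")
    if n_sims < 1:
        raise PairMHNError("n_sims must be >= 1")
    if not 0 <= event_index < sys.n:
        raise PairMHNError(f"event_index {event_index} out of range")
    cache = _RateCache(params, sys)
    hit = pre = 0
    for r in range(n_sims):
        rng = _run_rng(seed, r + 1)
        hist = gillespie_run(params, sys, rng, "until_both_observations", cache)
        if condition == "observed_in_PT":
            geno = hist.pt_at_observation
        else:
            geno = hist.mt_at_observation
        if geno is None or not geno[event_index]:
            continue
        hit += 1
        if _occurrence_kind(hist, event_index) == "joint":
            pre += 1
    if hit == 0:
        raise UndefinedEstimateError(
            f"no history satisfied condition {condition} for event {event_index}"
        )
    p = pre / hit
    se = math.sqrt(p * (1 - p) / hit)
    return PreSeedingEstimate(p, se, hit, n_sims)


def pre_seeding_probability_exact(
    params: ParameterSet, sys: EventSystem, event_index: int, condition: str
) -> float:
    """Exact pre-seeding probability by first-passage decomposition.

    Decomposes every history at the seeding jump: a forward solve on the
    shared-phase lattice yields the probability of seeding from each shared
    genotype (and of pre-seeding primary detection); triangular absorption
    solves on the single-tumor lattices yield the detection genotype
    distribution from each seeding state.  Intended for small ``n``
    (cost ``O(4**n)``); serves as the independent check for the
    Monte-Carlo estimator.
    """
    if condition not in CONDITIONS:
        raise PairMHNError(f"condition must be one of {CONDITIONS}")
    n = sys.n
    if not 0 <= event_index < n:
        raise PairMHNError(f"event_index {event_index} out of range")
    th = params.theta
    size = 1 << n
    masks = np.arange(size)
    bits = (masks[:, None] >> np.arange(n)[None, :]) & 1

    def event_lograte(i: int, extra: float) -> np.ndarray:
        return th[i, i] + bits @ th[i, :n] + extra

    u_pt0 = np.exp(bits @ params.omega_pt[:n])
    u_pt1 = u_pt0 * np.exp(params.omega_pt[n])
    u_mt1 = np.exp(bits @ params.omega_mt[:n] + params.omega_mt[n])
    seed_rate = np.exp(th[n, n] + bits @ th[n, :n])

    def absorption(entity: str) -> tuple[np.ndarray, np.ndarray]:
        """(M, u) for a single-tumor lattice: M = D - R, detection rates u."""
        M = np.zeros((size, size))
        d = np.zeros(size)
        for i in range(n):
            extra = th[i, n] if entity == "mt" else 0.0
            r = np.exp(event_lograte(i, extra))
            absent = bits[:, i] == 0
            d[absent] += r[absent]
            src = masks[absent]
            M[src | (1 << i), src] -= r[absent]
        u = u_mt1 if entity == "mt" else u_pt1
        d += u
        M[np.arange(size), np.arange(size)] += d
        return M, u

    # shared phase: mass reaching each genotype before seeding/detection
    M0 = np.zeros((size, size))
    d0 = np.zeros(size)
    for i in range(n):
        r = np.exp(event_lograte(i, 0.0))
        absent = bits[:, i] == 0
        d0[absent] += r[absent]
        src = masks[absent]
        M0[src | (1 << i), src] -= r[absent]
    d0 += seed_rate + u_pt0
    M0[np.arange(size), np.arange(size)] += d0
    b = np.zeros(size)
    b[0] = 1.0
    z0 = sla.solve_triangular(M0, b, lower=True)
    sigma = seed_rate * z0          # seeding flux per shared genotype
    phi0 = u_pt0 * z0               # pre-seeding primary detection flux

    entity = "pt" if condition == "observed_in_PT" else "mt"
    M, u = absorption(entity)
    Z = sla.solve_triangular(M, np.eye(size), lower=True)
    Abs = u[:, None] * Z            # Abs[final, start]
    has_event_final = bits[:, event_index] == 1
    has_event_start = bits[:, event_index] == 1
    reach = Abs[has_event_final, :].sum(axis=0)  # P(detected with event | start g)
    num = float((sigma * has_event_start * reach).sum())
    den = float((sigma * reach).sum())
    if condition == "observed_in_PT":
        # primaries detected before seeding count as pre-seeding occurrences
        pre0 = float((phi0 * has_event_start).sum())
        num += pre0
        den += pre0
    if den == 0.0:
        raise UndefinedEstimateError("conditioning event has zero probability")
    return num / den
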