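"""Restricted-state-space likelihood machinery.

Per-sample probabilities only require the sub-lattice of states whose
genotypes are subsets of the observed ones: paths that reach the observed
state never leave it, and states outside influence it only through total
exit rates, which are kept in the diagonal.  For samples where one tumor is
unobserved, that tumor is marginalized exactly by a reduced chain: after
seeding, each tumor's transition and observation rates depend only on its
own bits, and observing one tumor does not change the other's law, so the
unobserved side can be dropped except for the pre-seeding race against
primary-tumor detection (which halts the whole system).  Both reductions
make the cost exponential only in the number of events present in the
sample, and both are validated against the dense full-state-space oracle.

Every rate in a stage is a single exponential ``exp(a . xi)`` of the flat
log-parameter vector ``xi``, with ``a`` a 0/1 incidence row.  A stage's
linear operator ``M = D - R`` is lower triangular in the lattice
(topological) order, so solves are forward substitutions, and gradients are
obtained in closed form by one adjoint (transposed) solve per stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .model import EventSystem, PairMHNError, ParameterSet

# term kinds (transition labels, also used by trajectory reconstruction)
JOINT, PT, MT, SEED, OBS_PT, OBS_MT = range(6)
KIND_NAMES = ("joint", "pt", "mt", "seeding", "obs_pt", "obs_mt")


def flat_index_theta(n: int, i: int, j: int) -> int:
    return i * (n + 1) + j


def flat_index_omega_pt(n: int, j: int) -> int:
    return (n + 1) * (n + 1) + j


def flat_index_omega_mt(n: int, j: int) -> int:
    return (n + 1) * (n + 1) + (n + 1) + j


def _popcount(x: int) -> int:
    return bin(x).count("1")


class _StageBuilder:
    def __init__(self, n: int) -> None:
        self.n = n
        self.n_flat = (n + 1) * (n + 1) + 2 * (n + 1)
        self.keys: list = []
        self.index: dict = {}
        self.src: list[int] = []
        self.dst: list[int] = []
        self.kind: list[int] = []
        self.event: list[int] = []
        self._rows: list[list[int]] = []

    def add_state(self, key) -> int:
        pos = len(self.keys)
        self.keys.append(key)
        self.index[key] = pos
        return pos

    def add_term(self, src: int, dst: int, kind: int, event: int,
                 params: list[int]) -> int:
        t = len(self.src)
        self.src.append(src)
        self.dst.append(dst)
        self.kind.append(kind)
        self.event.append(event)
        self._rows.append(params)
        return t

    def finish(self) -> "Stage":
        T = len(self.src)
        indptr = np.zeros(T + 1, dtype=np.int64)
        for t, row in enumerate(self._rows):
            indptr[t + 1] = indptr[t] + len(row)
        indices = np.fromiter(
            (p for row in self._rows for p in row), dtype=np.int64, count=indptr[-1]
        )
        data = np.ones(indptr[-1])
        A = sp.csr_array((data, indices, indptr), shape=(T, self.n_flat))
        return Stage(
            keys=self.keys,
            index=self.index,
            src=np.asarray(self.src, dtype=np.int64),
            dst=np.asarray(self.dst, dtype=np.int64),
            kind=np.asarray(self.kind, dtype=np.int8),
            event=np.asarray(self.event, dtype=np.int64),
            A=A,
        )


@dataclass
class Stage:
    """One triangular linear stage over an explicitly enumerated state list.

    ``src[t]``/``dst[t]`` are state positions; ``dst = -1`` marks exit-only
    terms (rates that appear in the diagonal but lead outside the restricted
    space, or absorbing observation rates).  ``A`` maps the flat parameter
    vector to per-term log rates.
    """

    keys: list
    index: dict
    src: np.ndarray
    dst: np.ndarray
    kind: np.ndarray
    event: np.ndarray
    A: sp.csr_array

    @property
    def size(self) -> int:
        return len(self.keys)

    def rates(self, xi: np.ndarray) -> np.ndarray:
        return np.exp(self.A @ xi)

    def exit_diagonal(self, v: np.ndarray) -> np.ndarray:
        d = np.zeros(self.size)
        np.add.at(d, self.src, v)
        return d

    def operator(self, v: np.ndarray) -> np.ndarray:
        """Dense lower-triangular ``M = D - R`` in the stage's state order."""
        S = self.size
        M = np.zeros((S, S))
        d = self.exit_diagonal(v)
        M[np.arange(S), np.arange(S)] = d
        keep = self.dst >= 0
        np.subtract.at(M, (self.dst[keep], self.src[keep]), v[keep])
        return M

    def solve(self, M: np.ndarray, b: np.ndarray, transposed: bool = False) -> np.ndarray:
        return sla.solve_triangular(M, b, lower=True, trans="T" if transposed else "N")

    def emit_term(self, kind: int, state_pos: int) -> int:
        """Term id of the (unique) observation term of ``kind`` at a state."""
        hits = np.nonzero((self.kind == kind) & (self.src == state_pos))[0]
        if hits.size != 1:
            raise PairMHNError("no unique observation term at the requested state")
        return int(hits[0])


# ---------------------------------------------------------------------------
# Stage builders
# ---------------------------------------------------------------------------


def _present(global_events: Sequence[int], local_mask: int) -> list[int]:
    return [e for k, e in enumerate(global_events) if (local_mask >> k) & 1]


def build_joint_stage(n: int, kept: tuple[int, ...]) -> Stage:
    """Joint PT/MT stage over events ``kept`` (used for paired samples).

    States: shared pre-seeding states ``(g, g, 0)`` and all post-seeding
    pairs ``(p, m, 1)``, ordered topologically (seeding last-in-block,
    ascending total bit count).  Events outside ``kept`` contribute
    exit-only terms.  PT and MT observation rates are emission terms
    (channels ``OBS_PT`` / ``OBS_MT``); the MT observation does not exist
    before seeding.
    """
    b = _StageBuilder(n)
    k = len(kept)
    s0_states = sorted(range(1 << k), key=lambda g: (_popcount(g), g))
    s1_states = sorted(
        ((p, m) for p in range(1 << k) for m in range(1 << k)),
        key=lambda pm: (_popcount(pm[0]) + _popcount(pm[1]), pm[0], pm[1]),
    )
    for g in s0_states:
        b.add_state((0, g, g))
    for p, m in s1_states:
        b.add_state((1, p, m))

    nn = n  # seeding parameter index
    for g in s0_states:
        pos = b.index[(0, g, g)]
        pres = _present(kept, g)
        for i in range(n):
            if i in pres:
                continue
            row = [flat_index_theta(n, i, i)] + [flat_index_theta(n, i, j) for j in pres]
            if i in kept:
                kk = kept.index(i)
                dst = b.index[(0, g | (1 << kk), g | (1 << kk))]
                b.add_term(pos, dst, JOINT, i, row)
            else:
                b.add_term(pos, -1, JOINT, i, row)
        row = [flat_index_theta(n, nn, nn)] + [flat_index_theta(n, nn, j) for j in pres]
        b.add_term(pos, b.index[(1, g, g)], SEED, -1, row)
        b.add_term(pos, -1, OBS_PT, -1, [flat_index_omega_pt(n, j) for j in pres])
    for p, m in s1_states:
        pos = b.index[(1, p, m)]
        pres_p = _present(kept, p)
        pres_m = _present(kept, m)
        for i in range(n):
            if i not in pres_p:
                row = [flat_index_theta(n, i, i)] + [flat_index_theta(n, i, j) for j in pres_p]
                if i in kept:
                    dst = b.index[(1, p | (1 << kept.index(i)), m)]
                    b.add_term(pos, dst, PT, i, row)
                else:
                    b.add_term(pos, -1, PT, i, row)
            if i not in pres_m:
                row = (
                    [flat_index_theta(n, i, i)]
                    + [flat_index_theta(n, i, j) for j in pres_m]
                    + [flat_index_theta(n, i, nn)]
                )
                if i in kept:
                    dst = b.index[(1, p, m | (1 << kept.index(i)))]
                    b.add_term(pos, dst, MT, i, row)
                else:
                    b.add_term(pos, -1, MT, i, row)
        b.add_term(
            pos, -1, OBS_PT, -1,
            [flat_index_omega_pt(n, j) for j in pres_p] + [flat_index_omega_pt(n, nn)],
        )
        b.add_term(
            pos, -1, OBS_MT, -1,
            [flat_index_omega_mt(n, j) for j in pres_m] + [flat_index_omega_mt(n, nn)],
        )
    return b.finish()


def build_reduced_stage(n: int, support: tuple[int, ...], entity: str) -> Stage:
    """Reduced single-tumor chain ``(genotype, seeding)`` for unpaired samples.

    For ``entity="mt"``: the shared phase carries a primary-tumor detection
    exit (which would halt the system before seeding and leave the
    metastasis forever unobservable); after seeding the chain follows the
    metastasis alone and its detection is the emission.  For
    ``entity="pt"``: detection of the primary is the emission in both
    phases (the pre-seeding emission is the "no metastasis" branch); the
    metastasis is marginalized away entirely.
    """
    if entity not in ("pt", "mt"):
        raise PairMHNError(f"unknown entity {entity!r}")
    b = _StageBuilder(n)
    k = len(support)
    states = sorted(range(1 << k), key=lambda g: (_popcount(g), g))
    for g in states:
        b.add_state((g, 0))
    for g in states:
        b.add_state((g, 1))
    nn = n
    for g in states:
        pos = b.index[(g, 0)]
        pres = _present(support, g)
        for i in range(n):
            if i in pres:
                continue
            row = [flat_index_theta(n, i, i)] + [flat_index_theta(n, i, j) for j in pres]
            if i in support:
                dst = b.index[(g | (1 << support.index(i)), 0)]
                b.add_term(pos, dst, JOINT, i, row)
            else:
                b.add_term(pos, -1, JOINT, i, row)
        row = [flat_index_theta(n, nn, nn)] + [flat_index_theta(n, nn, j) for j in pres]
        b.add_term(pos, b.index[(g, 1)], SEED, -1, row)
        # pre-seeding primary detection: emission for the PT chain, kill for MT
        b.add_term(pos, -1, OBS_PT, -1, [flat_index_omega_pt(n, j) for j in pres])
    for g in states:
        pos = b.index[(g, 1)]
        pres = _present(support, g)
        for i in range(n):
            if i in pres:
                continue
            if entity == "pt":
                row = [flat_index_theta(n, i, i)] + [flat_index_theta(n, i, j) for j in pres]
                kind = PT
            else:
                row = (
                    [flat_index_theta(n, i, i)]
                    + [flat_index_theta(n, i, j) for j in pres]
                    + [flat_index_theta(n, i, nn)]
                )
                kind = MT
            if i in support:
                dst = b.index[(g | (1 << support.index(i)), 1)]
                b.add_term(pos, dst, kind, i, row)
            else:
                b.add_term(pos, -1, kind, i, row)
        if entity == "pt":
            b.add_term(
                pos, -1, OBS_PT, -1,
                [flat_index_omega_pt(n, j) for j in pres] + [flat_index_omega_pt(n, nn)],
            )
        else:
            b.add_term(
                pos, -1, OBS_MT, -1,
                [flat_index_omega_mt(n, j) for j in pres] + [flat_index_omega_mt(n, nn)],
            )
    return b.finish()


def build_propagation_stage(n: int, support: tuple[int, ...], entity: str) -> Stage:
    """Post-first-observation propagation of the not-yet-observed tumor.

    States are genotypes of the remaining tumor over ``support`` (seeding
    has necessarily happened).  The remaining tumor evolves under its own
    rates until its observation (the emission).
    """
    if entity not in ("pt", "mt"):
        raise PairMHNError(f"unknown entity {entity!r}")
    b = _StageBuilder(n)
    k = len(support)
    states = sorted(range(1 << k), key=lambda g: (_popcount(g), g))
    for g in states:
        b.add_state(g)
    nn = n
    for g in states:
        pos = b.index[g]
        pres = _present(support, g)
        for i in range(n):
            if i in pres:
                continue
            if entity == "pt":
                row = [flat_index_theta(n, i, i)] + [flat_index_theta(n, i, j) for j in pres]
                kind = PT
            else:
                row = (
                    [flat_index_theta(n, i, i)]
                    + [flat_index_theta(n, i, j) for j in pres]
                    + [flat_index_theta(n, i, nn)]
                )
                kind = MT
            if i in support:
                b.add_term(pos, b.index[g | (1 << support.index(i))], kind, i, row)
            else:
                b.add_term(pos, -1, kind, i, row)
        if entity == "pt":
            b.add_term(
                pos, -1, OBS_PT, -1,
                [flat_index_omega_pt(n, j) for j in pres] + [flat_index_omega_pt(n, nn)],
            )
        else:
            b.add_term(
                pos, -1, OBS_MT, -1,
                [flat_index_omega_mt(n, j) for j in pres] + [flat_index_omega_mt(n, nn)],
            )
    return b.finish()


# ---------------------------------------------------------------------------
# Pipelines
# ---------------------------------------------------------------------------


class SingleStagePipeline:
    """Probability = sum of selected emission fluxes of one stage."""

    def __init__(self, stage: Stage, target_terms: Sequence[int]) -> None:
        self.stage = stage
        self.targets = np.asarray(target_terms, dtype=np.int64)

    def probability(self, xi: np.ndarray) -> float:
        st = self.stage
        v = st.rates(xi)
        M = st.operator(v)
        b = np.zeros(st.size)
        b[0] = 1.0
        z = st.solve(M, b)
        return float(np.sum(v[self.targets] * z[st.src[self.targets]]))

    def probability_and_gradient(self, xi: np.ndarray) -> tuple[float, np.ndarray]:
        st = self.stage
        v = st.rates(xi)
        M = st.operator(v)
        b = np.zeros(st.size)
        b[0] = 1.0
        z = st.solve(M, b)
        p = float(np.sum(v[self.targets] * z[st.src[self.targets]]))
        c = np.zeros(st.size)
        np.add.at(c, st.src[self.targets], v[self.targets])
        w = st.solve(M, c, transposed=True)
        wd = np.where(st.dst >= 0, w[np.clip(st.dst, 0, None)], 0.0)
        g = -(w[st.src] - wd) * z[st.src]
        g[self.targets] += z[st.src[self.targets]]
        grad = self.stage.A.T @ (g * v)
        return p, np.asarray(grad)


class TwoStagePipeline:
    """First-observation stage chained into a propagation stage.

    ``bridge_terms`` are emission terms of stage 1 (the first observation at
    a state consistent with the conditioning genotype); their flux seeds the
    stage-2 states ``bridge_dst``.
    """

    def __init__(
        self,
        stage1: Stage,
        bridge_terms: Sequence[int],
        bridge_dst: Sequence[int],
        stage2: Stage,
        target_terms: Sequence[int],
    ) -> None:
        self.stage1 = stage1
        self.bridge = np.asarray(bridge_terms, dtype=np.int64)
        self.bridge_dst = np.asarray(bridge_dst, dtype=np.int64)
        self.stage2 = stage2
        self.targets = np.asarray(target_terms, dtype=np.int64)

    def _forward(self, xi: np.ndarray):
        s1, s2 = self.stage1, self.stage2
        v1 = s1.rates(xi)
        M1 = s1.operator(v1)
        b1 = np.zeros(s1.size)
        b1[0] = 1.0
        z1 = s1.solve(M1, b1)
        b2 = np.zeros(s2.size)
        np.add.at(b2, self.bridge_dst, v1[self.bridge] * z1[s1.src[self.bridge]])
        v2 = s2.rates(xi)
        M2 = s2.operator(v2)
        z2 = s2.solve(M2, b2)
        p = float(np.sum(v2[self.targets] * z2[s2.src[self.targets]]))
        return p, v1, M1, z1, v2, M2, z2

    def probability(self, xi: np.ndarray) -> float:
        return self._forward(xi)[0]

    def probability_and_gradient(self, xi: np.ndarray) -> tuple[float, np.ndarray]:
        s1, s2 = self.stage1, self.stage2
        p, v1, M1, z1, v2, M2, z2 = self._forward(xi)
        # stage-2 adjoint
        c2 = np.zeros(s2.size)
        np.add.at(c2, s2.src[self.targets], v2[self.targets])
        w2 = s2.solve(M2, c2, transposed=True)
        wd2 = np.where(s2.dst >= 0, w2[np.clip(s2.dst, 0, None)], 0.0)
        g2 = -(w2[s2.src] - wd2) * z2[s2.src]
        g2[self.targets] += z2[s2.src[self.targets]]
        # pull back through the bridge: dp/db2 = w2
        g1 = np.zeros(len(v1))
        g1[self.bridge] += w2[self.bridge_dst] * z1[s1.src[self.bridge]]
        c1 = np.zeros(s1.size)
        np.add.at(c1, s1.src[self.bridge], w2[self.bridge_dst] * v1[self.bridge])
        w1 = s1.solve(M1, c1, transposed=True)
        wd1 = np.where(s1.dst >= 0, w1[np.clip(s1.dst, 0, None)], 0.0)
        g1 += -(w1[s1.src] - wd1) * z1[s1.src]
        grad = s1.A.T @ (g1 * v1) + s2.A.T @ (g2 * v2)
        return p, np.asarray(grad)


class SumPipeline:
    """Sum of component probabilities (order-marginal and unknown-evidence cases)."""

    def __init__(self, parts: Sequence) -> None:
        self.parts = list(parts)

    def probability(self, xi: np.ndarray) -> float:
        return float(sum(p.probability(xi) for p in self.parts))

    def probability_and_gradient(self, xi: np.ndarray) -> tuple[float, np.ndarray]:
        tot = 0.0
        grad: Optional[np.ndarray] = None
        for part in self.parts:
            p, g = part.probability_and_gradient(xi)
            tot += p
            grad = g if grad is None else grad + g
        assert grad is not None
        return tot, grad


# ---------------------------------------------------------------------------
# Pipeline factory
# ---------------------------------------------------------------------------


def _support(genotype: np.ndarray) -> tuple[int, ...]:
    return tuple(int(i) for i in np.nonzero(np.asarray(genotype))[0])


def _local_mask(events: Sequence[int], space: Sequence[int]) -> int:
    mask = 0
    for e in events:
        mask |= 1 << space.index(e)
    return mask


class PipelineFactory:
    """Builds and caches per-sample restricted pipelines for one system."""

    def __init__(self, sys: EventSystem) -> None:
        self.sys = sys
        self._stages: dict = {}
        self._pipelines: dict = {}

    # -- stage caches --

    def joint_stage(self, kept: tuple[int, ...]) -> Stage:
        key = ("joint", kept)
        if key not in self._stages:
            self._stages[key] = build_joint_stage(self.sys.n, kept)
        return self._stages[key]

    def reduced_stage(self, support: tuple[int, ...], entity: str) -> Stage:
        key = ("reduced", support, entity)
        if key not in self._stages:
            self._stages[key] = build_reduced_stage(self.sys.n, support, entity)
        return self._stages[key]

    def propagation_stage(self, support: tuple[int, ...], entity: str) -> Stage:
        key = ("prop", support, entity)
        if key not in self._stages:
            self._stages[key] = build_propagation_stage(self.sys.n, support, entity)
        return self._stages[key]

    # -- pipelines --

    def pt_only(self, pt: np.ndarray, evidence: str):
        key = ("pt_only", _support(pt), evidence)
        if key in self._pipelines:
            return self._pipelines[key]
        support = _support(pt)
        stage = self.reduced_stage(support, "pt")
        g = _local_mask(support, support)  # full support mask
        targets = []
        if evidence in ("absent", "unknown"):
            targets.append(stage.emit_term(OBS_PT, stage.index[(g, 0)]))
        if evidence in ("present", "unknown"):
            targets.append(stage.emit_term(OBS_PT, stage.index[(g, 1)]))
        pipe = SingleStagePipeline(stage, targets)
        self._pipelines[key] = pipe
        return pipe

    def mt_only(self, mt: np.ndarray):
        key = ("mt_only", _support(mt))
        if key in self._pipelines:
            return self._pipelines[key]
        support = _support(mt)
        stage = self.reduced_stage(support, "mt")
        g = _local_mask(support, support)
        pipe = SingleStagePipeline(
            stage, [stage.emit_term(OBS_MT, stage.index[(g, 1)])]
        )
        self._pipelines[key] = pipe
        return pipe

    def paired(self, pt: np.ndarray, mt: np.ndarray, obs_order: str):
        sup_p, sup_m = _support(pt), _support(mt)
        key = ("paired", sup_p, sup_m, obs_order)
        if key in self._pipelines:
            return self._pipelines[key]
        if obs_order == "unknown":
            pipe = SumPipeline(
                [self.paired(pt, mt, "pt_first"), self.paired(pt, mt, "mt_first")]
            )
            self._pipelines[key] = pipe
            return pipe
        kept = tuple(sorted(set(sup_p) | set(sup_m)))
        stage1 = self.joint_stage(kept)
        if obs_order == "pt_first":
            cond_sup, prop_sup, chan, prop_chan = sup_p, sup_m, OBS_PT, OBS_MT
            entity = "mt"
        else:
            cond_sup, prop_sup, chan, prop_chan = sup_m, sup_p, OBS_MT, OBS_PT
            entity = "pt"
        stage2 = self.propagation_stage(prop_sup, entity)
        cond_mask = _local_mask(cond_sup, kept)
        bridge_terms, bridge_dst = [], []
        for (s, p, m), pos in stage1.index.items():
            if s != 1:
                continue  # propagation from the shared phase cannot reach an MT observation
            own, other = (p, m) if obs_order == "pt_first" else (m, p)
            if own != cond_mask:
                continue
            other_events = _present(kept, other)
            if any(e not in prop_sup for e in other_events):
                continue  # cannot shed events: such states never reach the target
            bridge_terms.append(stage1.emit_term(chan, pos))
            bridge_dst.append(stage2.index[_local_mask(other_events, prop_sup)])
        target_mask = _local_mask(prop_sup, prop_sup)
        pipe = TwoStagePipeline(
            stage1,
            bridge_terms,
            bridge_dst,
            stage2,
            [stage2.emit_term(prop_chan, stage2.index[target_mask])],
        )
        self._pipelines[key] = pipe
        return pipe

    def for_sample(self, sample) -> tuple:
        """(config key, pipeline) for a validated Sample."""
        st = sample.sample_type
        if st == "paired":
            key = ("paired", sample.pt.tobytes(), sample.mt.tobytes(), sample.obs_order)
            pipe = self.paired(sample.pt, sample.mt, sample.obs_order)
        elif st == "pt_only":
            key = ("pt_only", sample.pt.tobytes(), sample.seeding_evidence)
            pipe = self.pt_only(sample.pt, sample.seeding_evidence)
        else:
            key = ("mt_only", sample.mt.tobytes())
            pipe = self.mt_only(sample.mt)
        return key, pipe
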