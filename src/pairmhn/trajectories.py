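"""Most-likely chronological orderings and relative-timing summaries.

A fitted network induces, for every observed sample, a distribution over
the orders in which its events (including seeding and the clinical
observations) could have accumulated.  A path's probability is the product
over jumps of ``rate / total exit rate`` in the sample's restricted chain
— the embedded-jump-chain factorization with the observation events as
competing exits — times the terminal observation factor(s).  The maximizer
is found exactly by dynamic programming over the reachable sub-lattice of
the sample's events; for paired samples the reconstruction is branched
(shared prefix ending in seeding, then a primary and a metastasis branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from . import _lattice
from .model import EventSystem, PairMHNError, ParameterSet, Sample

_OBS_KINDS = {_lattice.OBS_PT: "obs_pt", _lattice.OBS_MT: "obs_mt"}


@dataclass
class TrajectoryTree:
    """Branched reconstruction of one sample's event history.

    ``shared_prefix`` lists events that occurred before seeding (ending
    with ``"Seeding"`` when seeding is part of the reconstruction);
    ``pt_branch`` / ``mt_branch`` list post-seeding events per tumor in
    chronological order.  ``steps`` is the full chronological jump sequence
    (kind, label) including the observation events; ``log_probability`` is
    the path log-probability under the embedded jump chain.
    """

    patient_id: str
    sample_type: str
    shared_prefix: list[str]
    pt_branch: list[str]
    mt_branch: list[str]
    log_probability: float
    steps: list[tuple[str, str]]
    achieved_order: Optional[str] = None

    @property
    def events(self) -> list[str]:
        """All progression events (incl. seeding) in chronological order."""
        return [lab for kind, lab in self.steps if kind not in ("obs_pt", "obs_mt")]


def _graph_stages(pipe) -> list:
    if isinstance(pipe, _lattice.SingleStagePipeline):
        return [pipe.stage]
    return [pipe.stage1, pipe.stage2]


def _edges(pipe, xi: np.ndarray):
    """Yield DP edges ((stage, pos) -> (stage, pos) | END) with log-weights.

    Edges are emitted grouped by source node in topological order, sorted by
    transition kind and event index within a source, which makes the
    tie-break of the DP deterministic (first-best kept).
    """
    single = isinstance(pipe, _lattice.SingleStagePipeline)
    stages = _graph_stages(pipe)
    values = [st.rates(xi) for st in stages]
    diags = [st.exit_diagonal(v) for st, v in zip(stages, values)]
    bridge_of = {}
    if not single:
        for t, dpos in zip(pipe.bridge, pipe.bridge_dst):
            bridge_of[int(t)] = int(dpos)
    target_stage = 0 if single else 1
    target_terms = set(int(t) for t in pipe.targets)
    for si, st in enumerate(stages):
        v, d = values[si], diags[si]
        order = np.lexsort((st.event, st.kind, st.src))
        for t in order:
            t = int(t)
            w = float(np.log(v[t]) - np.log(d[st.src[t]]))
            src = (si, int(st.src[t]))
            kind = int(st.kind[t])
            ev = int(st.event[t])
            if st.dst[t] >= 0:
                yield src, (si, int(st.dst[t])), w, kind, ev
            elif si == 0 and t in bridge_of:
                yield src, (1, bridge_of[t]), w, kind, ev
            elif si == target_stage and t in target_terms:
                yield src, "END", w, kind, ev


def _best_path(pipe, xi: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Exact max-probability path from wild type to the terminal observation."""
    best: dict = {(0, 0): 0.0}
    back: dict = {}
    for src, dst, w, kind, ev in _edges(pipe, xi):
        if src not in best:
            continue
        cand = best[src] + w
        if dst not in best or cand > best[dst]:
            best[dst] = cand
            back[dst] = (src, kind, ev)
    if "END" not in best:
        raise PairMHNError("no valid path to the observed genotype(s)")
    steps = []
    node = "END"
    while node != (0, 0):
        prev, kind, ev = back[node]
        steps.append((kind, ev))
        node = prev
    steps.reverse()
    return best["END"], steps


def enumerate_path_log_probabilities(pipe, xi: np.ndarray) -> list[tuple[float, tuple]]:
    """Exhaustive path enumeration over the same jump graph (reference oracle).

    Returns every complete path as (log-probability, step tuple); log
    probabilities are accumulated left-to-right exactly as in the DP, so the
    maximum is bit-identical to :func:`_best_path`.  Exponential in the
    number of events — use on small samples only.
    """
    adj: dict = {}
    for src, dst, w, kind, ev in _edges(pipe, xi):
        adj.setdefault(src, []).append((dst, w, kind, ev))
    out: list[tuple[float, tuple]] = []

    def dfs(node, logp, steps):
        if node == "END":
            out.append((logp, tuple(steps)))
            return
        for dst, w, kind, ev in adj.get(node, ()):
            steps.append((kind, ev))
            dfs(dst, logp + w, steps)
            steps.pop()

    dfs((0, 0), 0.0, [])
    return out


def _label(sys: EventSystem, kind: int, ev: int) -> str:
    if kind == _lattice.SEED:
        return "Seeding"
    if kind in _OBS_KINDS:
        return _OBS_KINDS[kind]
    return sys.event_names[ev]


def _tree_from_steps(
    sys: EventSystem,
    sample: Sample,
    steps: Sequence[tuple[int, int]],
    logp: float,
    achieved_order: Optional[str],
) -> TrajectoryTree:
    shared, pt_branch, mt_branch, chronology = [], [], [], []
    for kind, ev in steps:
        if kind in _OBS_KINDS:
            chronology.append((_OBS_KINDS[kind], _OBS_KINDS[kind]))
            continue
        lab = _label(sys, kind, ev)
        if kind == _lattice.JOINT:
            shared.append(lab)
            chronology.append(("joint", lab))
        elif kind == _lattice.SEED:
            shared.append(lab)
            chronology.append(("seeding", lab))
        elif kind == _lattice.PT:
            pt_branch.append(lab)
            chronology.append(("pt", lab))
        else:
            mt_branch.append(lab)
            chronology.append(("mt", lab))
    return TrajectoryTree(
        patient_id=sample.patient_id,
        sample_type=sample.sample_type,
        shared_prefix=shared,
        pt_branch=pt_branch,
        mt_branch=mt_branch,
        log_probability=logp,
        steps=chronology,
        achieved_order=achieved_order,
    )


def most_likely_ordering(
    params: ParameterSet,
    sys: EventSystem,
    sample: Sample,
    max_events: int = 14,
    factory: Optional[_lattice.PipelineFactory] = None,
) -> TrajectoryTree:
    """Most probable chronological ordering of a sample's observed events.

    For paired samples with unknown observation order, both orders are
    maximized and the better one reported (``achieved_order``); exact ties
    resolve to primary-first.  Raises when more than ``max_events`` events
    are present (the sub-lattice grows exponentially).
    """
    n_present = sum(int(g.sum()) for g in (sample.pt, sample.mt) if g is not None)
    if n_present > max_events:
        raise PairMHNError(
            f"sample {sample.patient_id!r} has {n_present} events, over the cap "
            f"{max_events}"
        )
    factory = factory or _lattice.PipelineFactory(sys)
    xi = params.flatten()
    _, pipe = factory.for_sample(sample)
    if isinstance(pipe, _lattice.SumPipeline):
        results = [_best_path(part, xi) for part in pipe.parts]
        orders = ("pt_first", "mt_first") if sample.sample_type == "paired" else (None, None)
        idx = int(results[1][0] > results[0][0])
        logp, steps = results[idx]
        achieved = orders[idx]
    else:
        logp, steps = _best_path(pipe, xi)
        achieved = sample.obs_order if sample.sample_type == "paired" else None
    tree = _tree_from_steps(sys, sample, steps, logp, achieved)
    # pre-seeding segment is common to both branches by construction
    assert all(kind in ("joint", "seeding") for kind, _ in tree.steps[: len(tree.shared_prefix)])
    return tree


# ---------------------------------------------------------------------------
# Timing summaries
# ---------------------------------------------------------------------------


def metastasis_chain(tree: TrajectoryTree) -> list[str]:
    """Linear event chain of the metastasis lineage (shared prefix + MT branch)."""
    return list(tree.shared_prefix) + list(tree.mt_branch)


def primary_chain(tree: TrajectoryTree) -> list[str]:
    """Linear event chain of the primary lineage (seeding included if inferred)."""
    return list(tree.shared_prefix) + list(tree.pt_branch)


def _as_chain(item: Union[TrajectoryTree, Sequence[str]]) -> list[str]:
    if isinstance(item, TrajectoryTree):
        if item.sample_type in ("mt_only", "paired"):
            return metastasis_chain(item)
        return primary_chain(item)
    return list(item)


@dataclass
class RelativePositionSummary:
    """Relative positions (0 = first, 1 = last) of each event across chains."""

    positions: dict[str, list[float]]
    n_trajectories: int

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.positions.items()}

    def histogram(self, event: str, bins: int = 10) -> np.ndarray:
        h, _ = np.histogram(self.positions.get(event, []), bins=bins, range=(0.0, 1.0))
        return h

    def mean_position(self, event: str) -> float:
        return float(np.mean(self.positions[event]))


def relative_positions(
    trajectories: Iterable[Union[TrajectoryTree, Sequence[str]]]
) -> RelativePositionSummary:
    """Per-event relative positions across a trajectory collection.

    In a linear chain of ``L`` events the event at rank ``k`` (1-based) gets
    position ``(k - 1) / (L - 1)``; a singleton chain maps to 0.  Seeding
    counts as an event; observation steps do not.
    """
    chains = [_as_chain(t) for t in trajectories]
    if not chains:
        raise PairMHNError("relative_positions requires a nonempty collection")
    positions: dict[str, list[float]] = {}
    for chain in chains:
        L = len(chain)
        for k, lab in enumerate(chain):
            pos = 0.0 if L == 1 else k / (L - 1)
            positions.setdefault(lab, []).append(pos)
    return RelativePositionSummary(positions, len(chains))


def stratify_by_initial_event(
    trajectories: Iterable[Union[TrajectoryTree, Sequence[str]]],
    top_k: int = 3,
) -> list[tuple[str, int, RelativePositionSummary]]:
    """Group trajectories by their first event; largest ``top_k`` strata.

    Returns (initial event, stratum size, per-stratum summary) tuples sorted
    by decreasing size (name breaks ties).  Empty chains are ignored.
    """
    chains = [_as_chain(t) for t in trajectories]
    groups: dict[str, list[list[str]]] = {}
    for chain in chains:
        if chain:
            groups.setdefault(chain[0], []).append(chain)
    if not groups:
        raise PairMHNError("no nonempty trajectories to stratify")
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        (lab, len(ch), relative_positions(ch)) for lab, ch in ranked[:top_k]
    ]


def to_dot(tree: TrajectoryTree) -> str:
    """Graphviz DOT rendering of a branched reconstruction."""
    lines = ["digraph trajectory {", "  rankdir=LR;", "  node [shape=box];"]
    counter = [0]

    def node(label: str, color: str) -> str:
        counter[0] += 1
        name = f"n{counter[0]}"
        lines.append(f'  {name} [label="{label}", color="{color}"];')
        return name

    prev = node("WT", "black")
    for lab in tree.shared_prefix:
        cur = node(lab, "black")
        lines.append(f"  {prev} -> {cur};")
        prev = cur
    fork = prev
    for branch, color in ((tree.pt_branch, "blue"), (tree.mt_branch, "red")):
        prev = fork
        for lab in branch:
            cur = node(lab, color)
            lines.append(f'  {prev} -> {cur} [color="{color}"];')
            prev = cur
    lines.append("}")
    return "\n".join(lines)
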