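"""Core state space, parameter containers, and transition-rate construction.

State-space convention
----------------------
A system with ``n`` progression events has a joint state described by
``2n + 1`` bits laid out as ``(x1P, x1M, x2P, x2M, ..., xnP, xnM, xseed)``:
for event ``i`` (0-based) the primary-tumor (PT) bit sits at position
``2i`` and the metastasis (MT) bit at position ``2i + 1``; the seeding bit
sits at position ``2n``.  A state's integer index is the little-endian
value of its bits, so the wild type is index 0 and flipping bit ``k`` adds
``2**k``.  All engines in this package share this convention.

Before seeding (seeding bit 0) the metastasis precursor is part of the
primary tumor, so reachable pre-seeding states satisfy ``PT == MT`` and
events flip both bits at once.  After seeding, PT and MT bits evolve
independently; MT rates carry one extra multiplicative environment effect
per event.  Clinical detection of either tumor is modeled by absorbing
observation events whose rates are modulated by the events present in the
observed tumor.

Rates are parameterized on the log scale: ``theta`` is the
``(n+1) x (n+1)`` matrix of log base rates (diagonal) and log pairwise
effects (off-diagonal), with row/column ``n`` belonging to the seeding
event; ``omega_pt`` and ``omega_mt`` are the log effects of each event
(and of seeding itself, entry ``n``) on the PT and MT observation rates.
The wild-type PT observation rate is the empty product, identically 1,
which fixes the model's time unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

#: Log-rate floor standing in for "rate exactly zero".  exp(-30) ~ 9.4e-14
#: keeps every linear system well posed while making the transition
#: dynamically irrelevant.
LOG_RATE_FLOOR = -30.0

SEEDING_NAME = "Seeding"


class PairMHNError(ValueError):
    """Base class for validation errors raised by pairmhn."""


# ---------------------------------------------------------------------------
# Event system and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventSystem:
    """Names and count of progression events plus the implicit seeding event.

    Parameters
    ----------
    n:
        Number of genomic progression events (``n == 0`` means a
        seeding-only system).
    event_names:
        ``n`` unique, non-empty names.  Defaults to ``E1..En``.

    The seeding event is not named by the caller; it always occupies
    parameter index ``n`` (0-based) and is labeled ``"Seeding"`` in files.
    """

    n: int
    event_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 0:
            raise PairMHNError(f"n must be >= 0, got {self.n}")
        names = tuple(self.event_names) if self.event_names else tuple(
            f"E{i + 1}" for i in range(self.n)
        )
        if len(names) != self.n:
            raise PairMHNError(
                f"expected {self.n} event names, got {len(names)}"
            )
        if any(not isinstance(s, str) or not s for s in names):
            raise PairMHNError("event names must be non-empty strings")
        if len(set(names)) != len(names):
            raise PairMHNError("event names must be unique")
        if SEEDING_NAME in names:
            raise PairMHNError(f"{SEEDING_NAME!r} is reserved for the seeding event")
        object.__setattr__(self, "event_names", names)

    @property
    def seeding_index(self) -> int:
        """0-based parameter index of the seeding event (``n``)."""
        return self.n

    @property
    def n_bits(self) -> int:
        return 2 * self.n + 1

    @property
    def n_states(self) -> int:
        """Size of the full (unrestricted) joint state space."""
        return 1 << self.n_bits

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.event_names + (SEEDING_NAME,)


@dataclass
class ParameterSet:
    """Log-scale model parameters.

    ``theta[i, j]`` is the log effect of event ``j`` on the rate of event
    ``i`` (``i == j``: log base rate); index ``n`` is the seeding event.
    ``omega_pt[j]`` / ``omega_mt[j]`` are the log effects of event ``j`` on
    the PT / MT observation rate; entry ``n`` is the effect of the seeding
    status itself (for the MT observation this acts as the base detection
    rate of a seeded metastasis, since the MT is unobservable before
    seeding).
    """

    theta: np.ndarray
    omega_pt: np.ndarray
    omega_mt: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega_pt = np.asarray(self.omega_pt, dtype=float)
        self.omega_mt = np.asarray(self.omega_mt, dtype=float)
        m = self.theta.shape[0]
        if self.theta.shape != (m, m) or m < 1:
            raise PairMHNError(f"theta must be square (n+1)x(n+1), got {self.theta.shape}")
        if self.omega_pt.shape != (m,) or self.omega_mt.shape != (m,):
            raise PairMHNError("omega_pt/omega_mt must have length n+1")
        for arr, name in ((self.theta, "theta"), (self.omega_pt, "omega_pt"),
                          (self.omega_mt, "omega_mt")):
            if not np.all(np.isfinite(arr)):
                raise PairMHNError(
                    f"{name} contains non-finite entries; represent a disabled "
                    f"rate by a large negative log value (e.g. LOG_RATE_FLOOR)"
                )

    @property
    def n(self) -> int:
        """Number of progression events (theta is (n+1)x(n+1))."""
        return self.theta.shape[0] - 1

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.theta.copy(), self.omega_pt.copy(), self.omega_mt.copy())

    # -- flat vector view (used by the optimizer and the adjoint engine) --

    @property
    def n_flat(self) -> int:
        m = self.n + 1
        return m * m + 2 * m

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.theta.ravel(), self.omega_pt, self.omega_mt])

    @classmethod
    def unflatten(cls, xi: np.ndarray, n: int) -> "ParameterSet":
        m = n + 1
        xi = np.asarray(xi, dtype=float)
        if xi.shape != (m * m + 2 * m,):
            raise PairMHNError(f"flat parameter vector has wrong length {xi.shape}")
        return cls(xi[: m * m].reshape(m, m), xi[m * m : m * m + m], xi[m * m + m :])

    @classmethod
    def zeros(cls, n: int) -> "ParameterSet":
        m = n + 1
        return cls(np.zeros((m, m)), np.zeros(m), np.zeros(m))

    @classmethod
    def random(
        cls,
        n: int,
        rng: np.random.Generator,
        base_rate_scale: float = 1.0,
        effect_scale: float = 0.5,
        obs_effect_scale: float = 0.3,
    ) -> "ParameterSet":
        """Draw a random model (used for property tests and benchmarks).

        Diagonals (log base rates) are N(-0.5, base_rate_scale); off-diagonal
        effects and observation effects are centered normals.  The seeding
        entries of the observation vectors are drawn like other effects.
        """
        m = n + 1
        theta = rng.normal(0.0, effect_scale, (m, m))
        np.fill_diagonal(theta, rng.normal(-0.5, base_rate_scale, m))
        omega_pt = rng.normal(0.0, obs_effect_scale, m)
        omega_mt = rng.normal(0.0, obs_effect_scale, m)
        return cls(theta, omega_pt, omega_mt)


# ---------------------------------------------------------------------------
# Sample records
# ---------------------------------------------------------------------------

SAMPLE_TYPES = ("paired", "pt_only", "mt_only")
OBS_ORDERS = ("pt_first", "mt_first", "unknown")
SEEDING_EVIDENCE = ("absent", "present", "unknown")


@dataclass
class Sample:
    """One patient record: PT and/or MT genotype plus annotations.

    ``seeding_evidence`` is meaningful for PT-only samples ("absent" means
    there is clinical evidence that no metastasis exists; "present" means a
    metastasis exists but was not sequenced).  ``obs_order`` is meaningful
    for paired samples.
    """

    patient_id: str
    pt: Optional[np.ndarray] = None
    mt: Optional[np.ndarray] = None
    seeding_evidence: Optional[str] = None
    obs_order: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pt is not None:
            self.pt = np.asarray(self.pt, dtype=np.int8)
        if self.mt is not None:
            self.mt = np.asarray(self.mt, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if self.pt is None and self.mt is None:
            raise PairMHNError(f"sample {self.patient_id!r}: at least one genotype required")
        for g, lab in ((self.pt, "pt"), (self.mt, "mt")):
            if g is not None and not np.isin(g, (0, 1)).all():
                raise PairMHNError(f"sample {self.patient_id!r}: {lab} genotype must be 0/1")
        st = self.sample_type
        if st == "paired":
            if self.obs_order not in OBS_ORDERS:
                raise PairMHNError(
                    f"sample {self.patient_id!r}: paired sample needs obs_order in {OBS_ORDERS}"
                )
            if len(self.pt) != len(self.mt):
                raise PairMHNError(f"sample {self.patient_id!r}: genotype length mismatch")
        else:
            if self.obs_order is not None:
                raise PairMHNError(
                    f"sample {self.patient_id!r}: obs_order only applies to paired samples"
                )
        if st == "pt_only":
            if self.seeding_evidence not in SEEDING_EVIDENCE:
                raise PairMHNError(
                    f"sample {self.patient_id!r}: PT-only sample needs seeding_evidence in "
                    f"{SEEDING_EVIDENCE}"
                )
        elif st == "mt_only":
            if self.seeding_evidence == "absent":
                raise PairMHNError(
                    f"sample {self.patient_id!r}: an observed metastasis implies seeding"
                )

    @property
    def sample_type(self) -> str:
        if self.pt is not None and self.mt is not None:
            return "paired"
        return "pt_only" if self.pt is not None else "mt_only"


# ---------------------------------------------------------------------------
# State encoding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FullState:
    """Bit vector of length ``2n + 1`` plus the two observation flags."""

    bits: tuple[int, ...]
    pt_observed: bool = False
    mt_observed: bool = False

    @property
    def n(self) -> int:
        return (len(self.bits) - 1) // 2

    @property
    def index(self) -> int:
        return int(sum(b << k for k, b in enumerate(self.bits)))

    @property
    def pt(self) -> np.ndarray:
        return np.array(self.bits[0 : 2 * self.n : 2], dtype=np.int8)

    @property
    def mt(self) -> np.ndarray:
        return np.array(self.bits[1 : 2 * self.n : 2], dtype=np.int8)

    @property
    def seeding(self) -> int:
        return self.bits[-1]


def state_index(pt: Sequence[int], mt: Sequence[int], seeding: int) -> int:
    """Integer index of the state with the given PT/MT genotypes and seeding bit."""
    return encode_state(pt, mt, seeding).index


def encode_state(pt: Sequence[int], mt: Sequence[int], seeding: int) -> FullState:
    """Encode genotypes into a :class:`FullState`.

    Raises if the state is unreachable: before seeding the metastasis
    precursor is identical to the primary tumor, so ``seeding == 0``
    requires ``pt == mt``.
    """
    pt = np.asarray(pt, dtype=np.int8)
    mt = np.asarray(mt, dtype=np.int8)
    if pt.shape != mt.shape or pt.ndim != 1:
        raise PairMHNError(f"genotype length mismatch: {pt.shape} vs {mt.shape}")
    if seeding not in (0, 1):
        raise PairMHNError("seeding bit must be 0 or 1")
    if seeding == 0 and not np.array_equal(pt, mt):
        raise PairMHNError("unreachable state: seeding=0 requires PT == MT")
    n = len(pt)
    bits = [0] * (2 * n + 1)
    bits[0 : 2 * n : 2] = [int(b) for b in pt]
    bits[1 : 2 * n : 2] = [int(b) for b in mt]
    bits[2 * n] = int(seeding)
    return FullState(tuple(bits))


def decode_state(index: int, n: int) -> FullState:
    """Inverse of :func:`state_index` (does not check reachability)."""
    nb = 2 * n + 1
    if not 0 <= index < (1 << nb):
        raise PairMHNError(f"state index {index} out of range for n={n}")
    bits = tuple((index >> k) & 1 for k in range(nb))
    return FullState(bits)


def _bit_tables(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PT-bit matrix, MT-bit matrix (n_states x n) and seeding vector."""
    size = 1 << (2 * n + 1)
    idx = np.arange(size, dtype=np.int64)
    if n > 0:
        shifts = 2 * np.arange(n, dtype=np.int64)
        ptbits = (idx[:, None] >> shifts[None, :]) & 1
        mtbits = (idx[:, None] >> (shifts + 1)[None, :]) & 1
    else:
        ptbits = np.zeros((size, 0), dtype=np.int64)
        mtbits = np.zeros((size, 0), dtype=np.int64)
    seed = (idx >> (2 * n)) & 1
    return ptbits, mtbits, seed


def reachable_state_indices(n: int) -> np.ndarray:
    """Indices of reachable pre-observation states (``2**n + 4**n`` of them).

    Pre-seeding states with ``PT != MT`` are formally part of the bit-string
    space but can never acquire probability mass; they are excluded here.
    """
    ptbits, mtbits, seed = _bit_tables(n)
    shared = (ptbits == mtbits).all(axis=1)
    keep = (seed == 1) | shared
    return np.nonzero(keep)[0]


# ---------------------------------------------------------------------------
# Generator construction
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParts:
    """Transition-rate structures over the full ``2**(2n+1)`` state space.

    ``q0``/``qs``/``qp``/``qm`` are sparse matrices of off-diagonal rates
    with the convention ``M[y, x] = rate of x -> y`` (shared by every engine
    in the package); diagonals are implicit (negative column sums).  ``u_pt``
    and ``u_mt`` are the diagonal observation-rate vectors.
    """

    n: int
    q0: sp.csr_array
    qs: sp.csr_array
    qp: sp.csr_array
    qm: sp.csr_array
    u_pt: np.ndarray
    u_mt: np.ndarray

    @property
    def rate_matrix(self) -> sp.csr_array:
        """Off-diagonal rates of the full progression generator Q0+QS+QP+QM."""
        return (self.q0 + self.qs + self.qp + self.qm).tocsr()

    @property
    def exit_rates(self) -> np.ndarray:
        """Total progression exit rate per state (column sums of the rates)."""
        return np.asarray(self.rate_matrix.sum(axis=0)).ravel()


def build_generator_parts(
    params: ParameterSet, sys: EventSystem, max_n: int = 10
) -> GeneratorParts:
    """Construct the four transition-rate parts and observation diagonals.

    Rates follow the coupled-progression model: before seeding, events occur
    jointly in PT and MT at the classical MHN rate over the shared genotype;
    seeding moves a shared state to its post-seeding twin; after seeding PT
    events depend only on the PT genotype and MT events only on the MT
    genotype plus the seeding environment effect ``theta[i, n]``.

    ``u_pt`` is 1 at the unseeded wild type (empty product), fixing the time
    unit; ``u_mt`` is identically 0 before seeding.
    """
    n = sys.n
    if params.n != n:
        raise PairMHNError(f"parameters are for n={params.n}, system has n={n}")
    if n > max_n:
        raise PairMHNError(f"n={n} exceeds the full-state-space guard max_n={max_n}")
    size = sys.n_states
    th = params.theta
    ptbits, mtbits, seed = _bit_tables(n)
    shared = (ptbits == mtbits).all(axis=1)
    s0 = (seed == 0) & shared
    s1 = seed == 1
    idx = np.arange(size, dtype=np.int64)

    def _coo(rows, cols, vals) -> sp.csr_array:
        rows = np.concatenate(rows) if rows else np.zeros(0, dtype=np.int64)
        cols = np.concatenate(cols) if cols else np.zeros(0, dtype=np.int64)
        vals = np.concatenate(vals) if vals else np.zeros(0)
        return sp.csr_array(sp.coo_array((vals, (rows, cols)), shape=(size, size)))

    r0, c0, v0 = [], [], []
    rp, cp, vp = [], [], []
    rm, cm, vm = [], [], []
    for i in range(n):
        # joint (pre-seeding) occurrences of event i
        src = np.nonzero(s0 & (ptbits[:, i] == 0))[0]
        if src.size:
            lograte = th[i, i] + ptbits[src] @ th[i, :n]
            c0.append(src)
            r0.append(src + (1 << (2 * i)) + (1 << (2 * i + 1)))
            v0.append(np.exp(lograte))
        # PT-only occurrences (post-seeding), depend on PT(x) only
        src = np.nonzero(s1 & (ptbits[:, i] == 0))[0]
        if src.size:
            lograte = th[i, i] + ptbits[src] @ th[i, :n]
            cp.append(src)
            rp.append(src + (1 << (2 * i)))
            vp.append(np.exp(lograte))
        # MT-only occurrences (post-seeding), with the environment effect
        src = np.nonzero(s1 & (mtbits[:, i] == 0))[0]
        if src.size:
            lograte = th[i, i] + mtbits[src] @ th[i, :n] + th[i, n]
            cm.append(src)
            rm.append(src + (1 << (2 * i + 1)))
            vm.append(np.exp(lograte))
    # seeding transitions S0 -> S1
    src = np.nonzero(s0)[0]
    lograte = th[n, n] + ptbits[src] @ th[n, :n]
    qs = _coo([src + (1 << (2 * n))], [src], [np.exp(lograte)])

    u_pt = np.exp(ptbits @ params.omega_pt[:n] + seed * params.omega_pt[n])
    u_mt = np.where(s1, np.exp(mtbits @ params.omega_mt[:n] + params.omega_mt[n]), 0.0)
    # unreachable states (seed=0, PT != MT) keep zero observation rates too
    unreachable = (seed == 0) & ~shared
    u_pt = np.where(unreachable, 0.0, u_pt)
    _ = idx  # (idx retained for clarity; sources were built from masks)
    return GeneratorParts(
        n=n,
        q0=_coo(r0, c0, v0),
        qs=qs,
        qp=_coo(rp, cp, vp),
        qm=_coo(rm, cm, vm),
        u_pt=u_pt,
        u_mt=u_mt,
    )


def assemble_dense_generator(parts: GeneratorParts, max_n: int = 4) -> np.ndarray:
    """Dense CTMC generator on the extended (observation-flagged) space.

    The extended space stacks three copies of the progression space in block
    order (no observation, PT observed, MT observed).  Observation events
    move probability into the flagged blocks, which are absorbing: states
    with a flag set have zero outgoing rate.  Convention ``G[y, x]`` = rate
    of ``x -> y``; every column sums to zero.

    Only intended for small systems (memory grows as ``(3 * 2**(2n+1))**2``).
    """
    n = parts.n
    if n > max_n:
        raise PairMHNError(f"n={n} exceeds the dense-assembly guard max_n={max_n}")
    size = 1 << (2 * n + 1)
    R = parts.rate_matrix.toarray()
    G = np.zeros((3 * size, 3 * size))
    G[:size, :size] = R
    d = R.sum(axis=0) + parts.u_pt + parts.u_mt
    G[:size, :size] -= np.diag(d)
    G[size : 2 * size, :size] = np.diag(parts.u_pt)
    G[2 * size : 3 * size, :size] = np.diag(parts.u_mt)
    return G
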