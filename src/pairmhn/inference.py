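"""Penalized maximum-likelihood inference of the interaction network.

The objective is the mean per-sample log-likelihood minus ``lambda`` times a
sparsity penalty on the log parameters.  The default penalty groups the two
directed effects between a pair of events into one square-root term,

    sum_{i<j} sqrt(th_ij^2 + th_ji^2 - th_ij th_ji) + sum_j (|wP_j| + |wM_j|),

which shrinks pairs jointly to zero (group-lasso behavior) and promotes
symmetric selection; the radicand equals ``(th_ij - th_ji/2)^2 + 3/4 th_ji^2``
and is never negative.  A plain quadratic variant (same terms without the
square root) is available behind ``penalty_variant="quadratic"``.  Base
rates (diagonal of theta) and the base observation effects of the seeding
event are never penalized: they set the scale of the process and of the two
observation clocks.

Optimization is plain gradient ascent with a backtracking (Armijo) line
search, so the trace of accepted objective values is non-decreasing by
construction.  Near-zero penalty terms use an epsilon-smoothed gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .likelihood import LikelihoodEngine
from .model import EventSystem, PairMHNError, ParameterSet, Sample

logger = logging.getLogger(__name__)

_SMOOTH_EPS = 1e-10


@dataclass
class FitConfig:
    """Optimizer and cross-validation settings.

    ``lambda_`` is the regularization weight used by :func:`fit`;
    ``lambda_grid`` the candidates scanned by :func:`cross_validate`.
    ``seed`` controls the fold assignment only.
    """

    lambda_: float = 1e-3
    lambda_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1)
    folds: int = 5
    max_iterations: int = 500
    step_init: float = 0.5
    step_shrink: float = 0.5
    step_grow: float = 1.3
    convergence_tol: float = 1e-7
    seed: int = 0
    penalty_variant: str = "grouped_sqrt"

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise PairMHNError("lambda_ must be >= 0")
        if self.folds < 2:
            raise PairMHNError("folds must be >= 2")
        if self.penalty_variant not in ("grouped_sqrt", "quadratic"):
            raise PairMHNError(f"unknown penalty_variant {self.penalty_variant!r}")

    # -- plain-text round trip (key = value lines) --

    _FIELD_TYPES = {
        "lambda_": float,
        "lambda_grid": "floats",
        "folds": int,
        "max_iterations": int,
        "step_init": float,
        "step_shrink": float,
        "step_grow": float,
        "convergence_tol": float,
        "seed": int,
        "penalty_variant": str,
    }

    def to_file(self, path) -> None:
        lines = []
        for name in self._FIELD_TYPES:
            value = getattr(self, name)
            if name == "lambda_grid":
                value = ",".join(repr(v) for v in value)
            lines.append(f"{name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise PairMHNError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in cls._FIELD_TYPES:
                raise PairMHNError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = cls._FIELD_TYPES[key]
            if typ == "floats":
                kwargs[key] = tuple(float(v) for v in value.split(","))
            elif typ is str:
                kwargs[key] = value
            else:
                kwargs[key] = typ(value)
        return cls(**kwargs)


@dataclass
class FitResult:
    params: ParameterSet
    objective_trace: list[float]
    log_likelihood: float
    converged: bool
    cv_table: Optional[list[tuple[float, float]]] = None  # (lambda, held-out ll)
    chosen_lambda: Optional[float] = None


def _penalty_masks(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-diagonal pair index arrays (i<j) and the omega shrink mask."""
    m = n + 1
    iu = np.triu_indices(m, k=1)
    omega_mask = np.ones(m, dtype=bool)
    omega_mask[n] = False  # base observation effects are scale parameters
    return iu[0], iu[1], omega_mask


def penalty(
    params: ParameterSet, variant: str = "grouped_sqrt"
) -> tuple[float, ParameterSet]:
    """Penalty value and its (epsilon-smoothed) gradient.

    Diagonal entries of theta and the seeding entries of the observation
    vectors are excluded from shrinkage; their gradient entries are zero.
    """
    n = params.n
    rows, cols, omask = _penalty_masks(n)
    th = params.theta
    a = th[rows, cols]
    b = th[cols, rows]
    radicand = a * a + b * b - a * b
    grad = ParameterSet.zeros(n)
    if variant == "grouped_sqrt":
        value = float(np.sum(np.sqrt(radicand)))
        root = np.sqrt(radicand + _SMOOTH_EPS**2)
        grad.theta[rows, cols] = (2 * a - b) / (2 * root)
        grad.theta[cols, rows] = (2 * b - a) / (2 * root)
    elif variant == "quadratic":
        value = float(np.sum(radicand))
        grad.theta[rows, cols] = 2 * a - b
        grad.theta[cols, rows] = 2 * b - a
    else:
        raise PairMHNError(f"unknown penalty variant {variant!r}")
    for om, gom in ((params.omega_pt, grad.omega_pt), (params.omega_mt, grad.omega_mt)):
        value += float(np.sum(np.abs(om[omask])))
        gom[omask] = om[omask] / np.sqrt(om[omask] ** 2 + _SMOOTH_EPS**2)
    return value, grad


def default_initialization(sys: EventSystem, samples: Sequence[Sample]) -> ParameterSet:
    """Zero interactions; base rates set to the logit of marginal frequencies.

    An event observed in fraction f of tumors gets a log base rate
    ``log(f / (1 - f))``, matching the single-event closed form
    ``Theta / (1 + Theta)``; the seeding base rate is initialized from the
    fraction of samples with evidence of metastasis.
    """
    n = sys.n
    init = ParameterSet.zeros(n)
    counts = np.zeros(n)
    total = 0
    seeded = 0
    n_seed_informative = 0
    for s in samples:
        for g in (s.pt, s.mt):
            if g is not None:
                counts += g
                total += 1
        if s.sample_type in ("paired", "mt_only"):
            seeded += 1
            n_seed_informative += 1
        elif s.seeding_evidence in ("absent", "present"):
            seeded += s.seeding_evidence == "present"
            n_seed_informative += 1
    freq = np.clip(counts / max(total, 1), 0.01, 0.99)
    init.theta[np.arange(n), np.arange(n)] = np.log(freq / (1 - freq))
    sfreq = np.clip(seeded / max(n_seed_informative, 1), 0.01, 0.99)
    init.theta[n, n] = np.log(sfreq / (1 - sfreq))
    return init


def fit(
    samples: Sequence[Sample],
    sys: EventSystem,
    config: Optional[FitConfig] = None,
    init: Optional[ParameterSet] = None,
    engine: Optional[LikelihoodEngine] = None,
) -> FitResult:
    """Maximize the penalized mean log-likelihood by gradient ascent.

    Deterministic given (samples, config, init).  The returned
    ``objective_trace`` contains the penalized objective at every accepted
    iterate and is non-decreasing up to line-search tolerance.
    """
    if not samples:
        raise PairMHNError("fit requires a nonempty dataset")
    config = config or FitConfig()
    engine = engine or LikelihoodEngine(sys)
    params = (init or default_initialization(sys, samples)).copy()
    lam = config.lambda_

    def objective_and_grad(p: ParameterSet) -> tuple[float, np.ndarray]:
        ll, gll = engine.dataset_log_likelihood_and_gradient(p, samples)
        pen, gpen = penalty(p, config.penalty_variant)
        f = ll - lam * pen
        g = gll.flatten() - lam * gpen.flatten()
        return f, g

    xi = params.flatten()
    f, g = objective_and_grad(ParameterSet.unflatten(xi, sys.n))
    if not np.isfinite(f):
        raise PairMHNError("objective is non-finite at the initial point")
    trace = [f]
    step = config.step_init
    converged = False
    for it in range(config.max_iterations):
        gnorm2 = float(g @ g)
        if np.sqrt(gnorm2) < config.convergence_tol:
            converged = True
            break
        accepted = False
        while step > 1e-14:
            xi_new = xi + step * g
            try:
                f_new, g_new = objective_and_grad(ParameterSet.unflatten(xi_new, sys.n))
            except PairMHNError:
                f_new = -np.inf
                g_new = g
            if np.isfinite(f_new) and f_new >= f + 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= config.step_shrink
        if not accepted:
            converged = abs(trace[-1] - f) <= max(1e-12, config.convergence_tol)
            break
        if f_new - f < config.convergence_tol * (1 + abs(f)):
            xi, f, g = xi_new, f_new, g_new
            trace.append(f)
            converged = True
            break
        xi, f, g = xi_new, f_new, g_new
        trace.append(f)
        step *= config.step_grow
        if it % 50 == 0:
            logger.info("iter %d objective %.6f step %.3g", it, f, step)
    final = ParameterSet.unflatten(xi, sys.n)
    ll = engine.dataset_log_likelihood(final, samples)
    if not converged:
        logger.warning(
            "gradient ascent stopped after %d iterations without meeting the "
            "convergence tolerance (last objective %.6f)", len(trace) - 1, f,
        )
    return FitResult(final, trace, ll, converged)


def assign_folds(
    patient_ids: Sequence[str], folds: int, seed: int
) -> dict[str, int]:
    """Seeded patient-level fold assignment (a patient is never split)."""
    unique = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    return {unique[p]: k % folds for k, p in enumerate(np.argsort(perm))}


def cross_validate(
    samples: Sequence[Sample],
    sys: EventSystem,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Select lambda by patient-level k-fold CV on held-out log-likelihood.

    The selection statistic is the mean held-out *unpenalized*
    log-likelihood; ties are broken toward the larger (more parsimonious)
    lambda.  Returns the final fit on the full dataset at the chosen lambda,
    with the CV table attached.
    """
    config = config or FitConfig()
    if not config.lambda_grid:
        raise PairMHNError("lambda_grid must be nonempty")
    fold_of = assign_folds([s.patient_id for s in samples], config.folds, config.seed)
    fold_samples = [[] for _ in range(config.folds)]
    for s in sorted(samples, key=lambda s: s.patient_id):
        fold_samples[fold_of[s.patient_id]].append(s)
    if any(len(f) == 0 for f in fold_samples):
        raise PairMHNError("a cross-validation fold received zero samples")
    engine = LikelihoodEngine(sys)
    table: list[tuple[float, float]] = []
    for lam in config.lambda_grid:
        cfg = FitConfig(**{**config.__dict__, "lambda_": lam})
        held_out = []
        for k in range(config.folds):
            train = [s for j in range(config.folds) if j != k for s in fold_samples[j]]
            test = fold_samples[k]
            res = fit(train, sys, cfg, engine=engine)
            held_out.append(engine.dataset_log_likelihood(res.params, test))
        table.append((lam, float(np.mean(held_out))))
        logger.info("lambda %.4g held-out ll %.6f", lam, table[-1][1])
    best = max(table, key=lambda row: (row[1], row[0]))
    cfg = FitConfig(**{**config.__dict__, "lambda_": best[0]})
    result = fit(samples, sys, cfg, engine=engine)
    result.cv_table = table
    result.chosen_lambda = best[0]
    return result
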