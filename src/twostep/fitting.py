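"""Per-subject likelihood fitting of the hybrid model and its nested
special cases.

The hybrid model has seven free parameters; the restricted models pin one
of them (TD-only: w=0; model-based-only: w=1; the direct-reinforcement and
value-chaining variants: lam=1 / lam=0).  Maximum-likelihood fits
constrain the learning rates to [0, 1] but let lam and w float beyond the
unit interval (box [-2, 3]) so boundary tests on their estimates are
meaningful; maximum-a-posteriori fits add the priors used for Laplace
model evidence (Beta(1.1, 1.1) on unit-range parameters, Normal(0, 1) on
perseveration, Gamma(1.2, 5) on the softmax temperatures), which confine
lam and w to their support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .agent import PARAM_NAMES, AgentParams, _compact, replay
from .task import Session

__all__ = [
    "ModelSpec", "FitResult", "PriorSpec", "MODELS",
    "fit_mle", "fit_map", "fit_shared_w", "fd_hessian",
]

LN2 = math.log(2.0)
_EPS = 1e-6

# MLE boxes; lam/w deliberately wider than [0,1]
_MLE_BOUNDS = {
    "beta1": (0.0, 30.0),
    "beta2": (0.0, 30.0),
    "alpha1": (0.0, 1.0),
    "alpha2": (0.0, 1.0),
    "lam": (-2.0, 3.0),
    "p": (-10.0, 10.0),
    "w": (-2.0, 3.0),
}
# MAP boxes restricted to the prior support
_MAP_BOUNDS = {
    "beta1": (_EPS, 30.0),
    "beta2": (_EPS, 30.0),
    "alpha1": (_EPS, 1.0 - _EPS),
    "alpha2": (_EPS, 1.0 - _EPS),
    "lam": (_EPS, 1.0 - _EPS),
    "p": (-10.0, 10.0),
    "w": (_EPS, 1.0 - _EPS),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named model: the hybrid or one of its parametric restrictions."""

    name: str
    restrictions: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(PARAM_NAMES) - len(self.restrictions)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAM_NAMES if n not in self.restrictions)

    def full_params(self, free_values: Sequence[float]) -> AgentParams:
        vals = dict(zip(self.free_names, map(float, free_values)))
        vals.update(self.restrictions)
        return AgentParams(**vals)


MODELS: dict[str, ModelSpec] = {
    "hybrid": ModelSpec("hybrid"),
    "td_only": ModelSpec("td_only", {"w": 0.0}),
    "mb_only": ModelSpec("mb_only", {"w": 1.0}),
    "lam0": ModelSpec("lam0", {"lam": 0.0}),
    "lam1": ModelSpec("lam1", {"lam": 1.0}),
}


@dataclass(frozen=True)
class PriorSpec:
    """Parameter priors for MAP fitting and Laplace evidence.

    Unit-range parameters (learning rates, lam, w) get Beta(a, b);
    perseveration gets Normal(mean, sd); the softmax temperatures get a
    Gamma whose second hyperparameter is a scale by default
    (``gamma_parameterization="rate"`` switches interpretation).
    """

    unit_a: float = 1.1
    unit_b: float = 1.1
    p_mean: float = 0.0
    p_sd: float = 1.0
    gamma_shape: float = 1.2
    gamma_second: float = 5.0
    gamma_parameterization: str = "scale"

    @property
    def gamma_scale(self) -> float:
        if self.gamma_parameterization == "scale":
            return self.gamma_second
        if self.gamma_parameterization == "rate":
            return 1.0 / self.gamma_second
        raise ValueError("gamma_parameterization must be 'scale' or 'rate'")

    def log_prior(self, params: AgentParams, free_names: Sequence[str]) -> float:
        """Sum of log prior densities over the free parameters only.

        Densities are written out directly (this sits inside the MAP
        optimizer's inner loop); they agree with scipy.stats to rounding.
        """
        from scipy.special import betaln, gammaln

        k, theta = self.gamma_shape, self.gamma_scale
        a, b = self.unit_a, self.unit_b
        lbeta = betaln(a, b)
        lgam = gammaln(k) + k * math.log(theta)
        total = 0.0
        for name in free_names:
            v = getattr(params, name)
            if name in ("beta1", "beta2"):
                if v <= 0:
                    return -math.inf
                total += (k - 1.0) * math.log(v) - v / theta - lgam
            elif name == "p":
                z = (v - self.p_mean) / self.p_sd
                total += -0.5 * z * z - math.log(self.p_sd) - 0.5 * math.log(2.0 * math.pi)
            else:  # alpha1, alpha2, lam, w
                if not (0.0 < v < 1.0):
                    return -math.inf
                total += (a - 1.0) * math.log(v) + (b - 1.0) * math.log1p(-v) - lbeta
        return float(total)


@dataclass
class FitResult:
    """One subject x one model fit."""

    model: str
    params: AgentParams
    neg_ll: float
    pseudo_r2: float
    hessian: Optional[np.ndarray]
    free_names: tuple[str, ...]
    n_restarts_used: int
    converged: bool
    n_completed: int
    log_prior: Optional[float] = None  # set for MAP fits
    log_evidence: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "params": {n: getattr(self.params, n) for n in PARAM_NAMES},
            "neg_ll": self.neg_ll,
            "pseudo_r2": self.pseudo_r2,
            "free_names": list(self.free_names),
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
            "n_completed": self.n_completed,
            "log_prior": self.log_prior,
            "log_evidence": self.log_evidence,
        }
        if self.hessian is not None:
            d["hessian"] = self.hessian.tolist()
        return d


def _negll_factory(session: Session, spec: ModelSpec) -> Callable[[np.ndarray], float]:
    trials = _compact(session)
    if not trials:
        raise ValueError("session has at least one completed trial required")

    def negll(x: np.ndarray) -> float:
        params = spec.full_params(x)
        ll1, ll2, _, _ = replay(session, params, _trials=trials)
        return -(ll1.sum() + ll2.sum())

    return negll


def _start_point(spec: ModelSpec, rng: np.random.Generator, map_fit: bool) -> np.ndarray:
    draw = {
        "beta1": rng.uniform(0.2, 8.0),
        "beta2": rng.uniform(0.2, 8.0),
        "alpha1": rng.uniform(0.05, 0.95),
        "alpha2": rng.uniform(0.05, 0.95),
        "lam": rng.uniform(0.05, 0.95),
        "p": rng.normal(0.0, 0.3),
        "w": rng.uniform(0.05, 0.95),
    }
    return np.array([draw[n] for n in spec.free_names])


def fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
               rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with per-coordinate relative
    steps; symmetrized by construction."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _pseudo_r2(neg_ll: float, n_completed: int) -> float:
    return 1.0 - neg_ll / (n_completed * 2.0 * LN2)


def _optimize(objective, spec: ModelSpec, bounds_map: dict,
              n_restarts: int, rng: np.random.Generator, map_fit: bool):
    bounds = [bounds_map[n] for n in spec.free_names]
    best = None
    n_ok = 0
    for _ in range(n_restarts):
        x0 = np.clip(_start_point(spec, rng, map_fit),
                     [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        except (FloatingPointError, OverflowError):
            continue
        if not np.isfinite(res.fun):
            continue
        n_ok += int(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimizer restarts failed")
    return best, n_ok > 0


def fit_mle(
    session: Session,
    spec: ModelSpec,
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
    compute_hessian: bool = True,
) -> FitResult:
    """Maximum-likelihood fit from ``n_restarts`` jittered starting points."""
    rng = rng if rng is not None else np.random.default_rng()
    negll = _negll_factory(session, spec)
    best, converged = _optimize(negll, spec, _MLE_BOUNDS, n_restarts, rng, map_fit=False)
    n_completed = len(_compact(session))
    H = fd_hessian(negll, best.x) if compute_hessian else None
    return FitResult(
        model=spec.name,
        params=spec.full_params(best.x),
        neg_ll=float(best.fun),
        pseudo_r2=_pseudo_r2(float(best.fun), n_completed),
        hessian=H,
        free_names=spec.free_names,
        n_restarts_used=n_restarts,
        converged=converged,
        n_completed=n_completed,
    )


def fit_map(
    session: Session,
    spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 10,
    rng: Optional[np.random.Generator] = None,
    compute_hessian: bool = True,
) -> FitResult:
    """Maximum-a-posteriori fit; the retained Hessian is of the penalized
    objective (negative log-likelihood minus log-prior), as needed for the
    Laplace evidence."""
    rng = rng if rng is not None else np.random.default_rng()
    priors = priors or PriorSpec()
    negll = _negll_factory(session, spec)

    def objective(x: np.ndarray) -> float:
        params = spec.full_params(x)
        lp = priors.log_prior(params, spec.free_names)
        if not np.isfinite(lp):
            return np.inf
        return negll(x) - lp

    best, converged = _optimize(objective, spec, _MAP_BOUNDS, n_restarts, rng, map_fit=True)
    if not np.isfinite(objective(best.x)):
        raise RuntimeError("prior density vanished at every optimum candidate")
    n_completed = len(_compact(session))
    params = spec.full_params(best.x)
    data_negll = float(negll(best.x))
    H = fd_hessian(objective, best.x) if compute_hessian else None
    return FitResult(
        model=spec.name,
        params=params,
        neg_ll=data_negll,
        pseudo_r2=_pseudo_r2(data_negll, n_completed),
        hessian=H,
        free_names=spec.free_names,
        n_restarts_used=n_restarts,
        converged=converged,
        n_completed=n_completed,
        log_prior=float(priors.log_prior(params, spec.free_names)),
    )


_SHARED_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "p")


def fit_shared_w(
    sessions: Sequence[Session],
    n_restarts: int = 5,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict, list[float]]:
    """Joint fit with common (beta1, beta2, alpha1, alpha2, lam, p) across
    subjects and one w per subject.

    This is the mixed-effects style refit used to put regressors on a
    common scale across subjects.  Returns ``(shared, w_list)`` where
    ``shared`` maps the six shared names to estimates and also reports the
    mean, SD and joint negative log-likelihood.
    """
    if len(sessions) < 2:
        raise ValueError("shared-w fitting requires at least 2 sessions")
    rng = rng if rng is not None else np.random.default_rng()
    n_sub = len(sessions)
    trial_lists = [_compact(s) for s in sessions]

    def unpack(x):
        shared = dict(zip(_SHARED_NAMES, x[:6]))
        ws = x[6:]
        return shared, ws

    def objective(x: np.ndarray) -> float:
        shared, ws = unpack(x)
        total = 0.0
        for sess, trials, w in zip(sessions, trial_lists, ws):
            params = AgentParams(w=float(w), **{k: float(v) for k, v in shared.items()})
            ll1, ll2, _, _ = replay(sess, params, _trials=trials)
            total -= ll1.sum() + ll2.sum()
        return total

    bounds = [_MLE_BOUNDS[n] for n in _SHARED_NAMES] + [_MLE_BOUNDS["w"]] * n_sub
    best = None
    for _ in range(n_restarts):
        x0 = np.concatenate([
            [rng.uniform(0.2, 8.0), rng.uniform(0.2, 8.0),
             rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95),
             rng.uniform(0.05, 0.95), rng.normal(0.0, 0.3)],
            rng.uniform(0.05, 0.95, size=n_sub),
        ])
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("shared-w optimization failed")
    shared, ws = unpack(best.x)
    ws = [float(v) for v in ws]
    shared = {k: float(v) for k, v in shared.items()}
    shared["w_mean"] = float(np.mean(ws))
    shared["w_sd"] = float(np.std(ws, ddof=1))
    shared["neg_ll"] = float(best.fun)
    return shared, ws
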