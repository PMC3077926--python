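"""Model comparison: nested likelihood-ratio tests, Laplace approximation
to the model evidence, and random-effects Bayesian model selection.

The random-effects scheme treats model identity as a random effect across
subjects: a Dirichlet prior over model frequencies is updated by a
variational loop alternating posterior model assignments with Dirichlet
counts; exceedance probabilities (the posterior probability that each
model is the most common in the population) come from Monte-Carlo draws
of the posterior Dirichlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import digamma, logsumexp

from .fitting import FitResult, PriorSpec

__all__ = ["ComparisonReport", "lrt", "laplace_evidence", "bms_random_effects", "compare_models"]

_LRT_TOL = 1e-6


def lrt(negll_full: float, negll_restricted: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio test of a nested restriction.

    statistic = 2*(negLL_restricted - negLL_full), chi-square with ``df``
    degrees of freedom under the null (for aggregate tests df = subjects x
    restricted parameters).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (negll_restricted - negll_full)
    if stat < -_LRT_TOL * max(1.0, abs(negll_full)):
        raise ValueError(
            f"restricted model fit better than the full model (statistic {stat:.3g}); "
            "refit the full model with more restarts"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def laplace_evidence(fit: FitResult, priors: Optional[PriorSpec] = None) -> float:
    """Laplace approximation to the log model evidence around a MAP fit:

    log P(D|M) ~= log lik(theta-hat) + log prior(theta-hat)
                  + (d/2) log 2*pi - (1/2) log det H,

    with H the Hessian of the penalized objective at the optimum.
    """
    if fit.log_prior is None:
        raise ValueError("laplace_evidence requires a MAP fit (log_prior set)")
    if fit.hessian is None:
        raise ValueError("MAP fit lacks a Hessian")
    H = np.asarray(fit.hessian, dtype=float)
    eigvals = np.linalg.eigvalsh(0.5 * (H + H.T))
    if eigvals.min() <= 0:
        raise ValueError(
            f"penalized Hessian not positive definite (min eigenvalue {eigvals.min():.3g}); "
            "the MAP optimum is suspect — refit advised"
        )
    d = H.shape[0]
    logdet = float(np.sum(np.log(eigvals)))
    return float(-fit.neg_ll + fit.log_prior + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet)


def bms_random_effects(
    log_evidences: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    n_samples: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random-effects Bayesian model selection over a subjects x models
    matrix of log evidences.

    Returns ``(alpha, expected_frequencies, exceedance_probabilities)``:
    the posterior Dirichlet parameters, their normalized means, and the
    Monte-Carlo estimate of each model's probability of being the most
    frequent.
    """
    lme = np.asarray(log_evidences, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("need a (>=2 subjects) x (>=2 models) log-evidence matrix")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidences must be finite")
    n_sub, n_mod = lme.shape
    rng = rng if rng is not None else np.random.default_rng()

    alpha = np.full(n_mod, alpha0, dtype=float)
    for _ in range(max_iter):
        # E-step: posterior model assignment per subject
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        # M-step: Dirichlet counts
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise RuntimeError(f"variational scheme did not converge in {max_iter} iterations")

    expected = alpha / alpha.sum()
    # exceedance by sampling the posterior Dirichlet in chunks
    counts = np.zeros(n_mod)
    remaining = n_samples
    while remaining > 0:
        m = min(remaining, 200_000)
        draws = rng.dirichlet(alpha, size=m)
        winners = np.argmax(draws, axis=1)
        counts += np.bincount(winners, minlength=n_mod)
        remaining -= m
    exceedance = counts / n_samples
    return alpha, expected, exceedance


@dataclass
class ComparisonReport:
    """Aggregated classical + Bayesian comparison of one full model
    against its restrictions, across subjects."""

    models: list[str]
    neg_ll: dict[str, float]
    per_subject_lrt_favoring_full: dict[str, int]
    aggregate_lrt: dict[str, tuple[float, int, float]]  # statistic, df, p
    neg_log_evidence: dict[str, float]
    per_subject_evidence_favoring_full: dict[str, int]
    aggregate_log_bayes_factor: dict[str, float]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "neg_ll": self.neg_ll,
            "per_subject_lrt_favoring_full": self.per_subject_lrt_favoring_full,
            "aggregate_lrt": {k: list(v) for k, v in self.aggregate_lrt.items()},
            "neg_log_evidence": self.neg_log_evidence,
            "per_subject_evidence_favoring_full": self.per_subject_evidence_favoring_full,
            "aggregate_log_bayes_factor": self.aggregate_log_bayes_factor,
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_probabilities": self.exceedance_probabilities.tolist(),
        }

    def table(self) -> str:
        """Plain-text table: one row per model, columns mirroring the
        classical and Bayesian comparison summaries."""
        full = self.models[0]
        lines = [
            f"{'model':<12}{'-LL':>10}{'#fav':>6}{'agg LRT':>12}{'df':>5}{'p':>12}"
            f"{'-logEv':>10}{'#fav(Ev)':>9}{'aggLogBF':>10}{'exceed':>8}"
        ]
        for i, m in enumerate(self.models):
            if m == full:
                lrt_s = df = pv = nfav = nfav_e = bf = "-"
            else:
                stat, dfv, p = self.aggregate_lrt[m]
                lrt_s, df, pv = f"{stat:.1f}", str(dfv), f"{p:.2g}"
                nfav = str(self.per_subject_lrt_favoring_full[m])
                nfav_e = str(self.per_subject_evidence_favoring_full[m])
                bf = f"{self.aggregate_log_bayes_factor[m]:.1f}"
            lines.append(
                f"{m:<12}{self.neg_ll[m]:>10.1f}{nfav:>6}{lrt_s:>12}{df:>5}{pv:>12}"
                f"{self.neg_log_evidence[m]:>10.1f}{nfav_e:>9}{bf:>10}"
                f"{self.exceedance_probabilities[i]:>8.3f}"
            )
        return "\n".join(lines)


def compare_models(
    mle_fits: dict[str, list[FitResult]],
    map_fits: dict[str, list[FitResult]],
    priors: Optional[PriorSpec] = None,
    full: str = "hybrid",
    rng: Optional[np.random.Generator] = None,
    lrt_alpha: float = 0.05,
    n_samples: int = 1_000_000,
) -> ComparisonReport:
    """Assemble the full comparison report from per-subject fits.

    ``mle_fits``/``map_fits`` map model names to per-subject FitResult
    lists (same subject order).  Per-subject LRT df = number of restricted
    parameters; aggregate df = subjects x restricted parameters.
    """
    from .fitting import MODELS

    priors = priors or PriorSpec()
    models = [full] + [m for m in mle_fits if m != full]
    n_sub = len(mle_fits[full])

    neg_ll = {m: float(sum(f.neg_ll for f in mle_fits[m])) for m in models}
    log_ev = {
        m: np.array([laplace_evidence(f, priors) if f.log_evidence is None else f.log_evidence
                     for f in map_fits[m]])
        for m in models
    }
    neg_log_evidence = {m: float(-log_ev[m].sum()) for m in models}

    per_lrt: dict[str, int] = {}
    agg_lrt: dict[str, tuple[float, int, float]] = {}
    per_ev: dict[str, int] = {}
    agg_bf: dict[str, float] = {}
    for m in models[1:]:
        df_per = len(MODELS[m].restrictions) if m in MODELS else 1
        wins = 0
        for f_full, f_res in zip(mle_fits[full], mle_fits[m]):
            stat, p = lrt(f_full.neg_ll, f_res.neg_ll, df_per)
            wins += int(p < lrt_alpha)
        per_lrt[m] = wins
        stat, p = lrt(neg_ll[full], neg_ll[m], df_per * n_sub)
        agg_lrt[m] = (stat, df_per * n_sub, p)
        per_ev[m] = int(np.sum(log_ev[full] > log_ev[m]))
        agg_bf[m] = float(log_ev[full].sum() - log_ev[m].sum())

    lme = np.column_stack([log_ev[m] for m in models])
    alpha, expected, exceed = bms_random_effects(lme, rng=rng, n_samples=n_samples)

    return ComparisonReport(
        models=models,
        neg_ll=neg_ll,
        per_subject_lrt_favoring_full=per_lrt,
        aggregate_lrt=agg_lrt,
        neg_log_evidence=neg_log_evidence,
        per_subject_evidence_favoring_full=per_ev,
        aggregate_log_bayes_factor=agg_bf,
        dirichlet_alpha=alpha,
        expected_frequencies=expected,
        exceedance_probabilities=exceed,
    )
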