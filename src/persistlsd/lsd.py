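"""Latent selection difference (LSD) modelling of persistence.

The LSD contrasts two sets of already-selected resource units — here,
lakes where a population persisted (1) versus lakes where it was
extirpated (0) — by logistic discrimination.  The fitted exponential
score

    w(x) = exp(beta_1 x_1 + ... + beta_n x_n)

is *proportional* to the probability of persistence: the intercept of
the logistic fit is dropped, so only ratios of scores between sites are
meaningful.  Detection error is ignored at this stage; see
:mod:`persistlsd.occupancy` for the detection-corrected likelihood.

Also here: covariate preparation (natural-log transform with a recorded
offset for zero-containing variables) and pairwise-collinearity
screening that keeps, within each highly correlated pair, the covariate
with the better single-variable model score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import EstimationError, FormatError
from .io import CovariateBundle, PersistenceLabels
from .selection import aicc

#: |beta| beyond this on the logit scale is treated as (quasi-)complete
#: separation: the odds ratio is numerically indistinguishable from infinity.
SEPARATION_BOUND = 15.0

_RESTART_SEED = 20140527  # fixed; only used to jitter optimizer restarts


@dataclass(frozen=True)
class LsdFit:
    """Fitted LSD logistic discrimination.

    ``betas``/``ses`` exclude the intercept, which is reported separately
    (and excluded from :func:`lsd_score` altogether).
    """

    name: str
    intercept: float
    intercept_se: float
    betas: dict[str, float]
    ses: dict[str, float]
    logL: float
    n_used: int
    converged: bool
    separation_flag: bool
    condition_number: float = np.nan

    @property
    def K(self) -> int:
        """Number of estimated parameters (intercept + slopes)."""
        return 1 + len(self.betas)

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.logL

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "betas": dict(self.betas),
            "ses": dict(self.ses),
            "logL": self.logL,
            "K": self.K,
            "n_used": self.n_used,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
        }


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of pairwise collinearity screening."""

    correlations: pd.DataFrame
    dropped: tuple[tuple[str, str, float], ...]  # (dropped, kept, |r|)
    retained: tuple[str, ...]
    univariate_scores: dict[str, float]
    excluded_constant: tuple[str, ...] = ()

    def to_json(self) -> dict:
        return {
            "correlations": self.correlations.to_dict(),
            "dropped": [list(d) for d in self.dropped],
            "retained": list(self.retained),
            "univariate_scores": dict(self.univariate_scores),
            "excluded_constant": list(self.excluded_constant),
        }


def prepare_covariates(
    bundle: CovariateBundle, log_transform: Sequence[str]
) -> CovariateBundle:
    """Replace each listed site covariate x by ln(x + c).

    The offset c is half the smallest positive observed value of x
    (c = 1 if every value is 0), recorded in ``bundle.transforms`` so the
    transform is reproducible and invertible.  Negative values are a
    domain error.
    """
    site_covs = dict(bundle.site_covs)
    transforms = dict(bundle.transforms)
    for name in log_transform:
        if name not in site_covs:
            raise KeyError(f"{name!r} is not a site-level covariate")
        x = site_covs[name]
        if (x < 0).any():
            raise ValueError(f"covariate {name!r} has negative values; cannot log-transform")
        positive = x[x > 0]
        c = 0.5 * positive.min() if positive.size else 1.0
        site_covs[name] = np.log(x + c)
        transforms[name] = c
    return CovariateBundle(bundle.site_ids, site_covs, dict(bundle.occasion_covs), transforms)


def back_transform(bundle: CovariateBundle, name: str) -> np.ndarray:
    """Invert a recorded log transform: exp(v) - c."""
    c = bundle.transforms[name]
    return np.exp(bundle.site_covs[name]) - c


def fit_lsd(
    labels: PersistenceLabels,
    bundle: CovariateBundle,
    terms: Sequence[str],
    name: str | None = None,
) -> LsdFit:
    """Maximum-likelihood logistic discrimination of persisted vs
    extirpated sites over intercept + ``terms``.

    Standard errors come from the inverse of the analytic Hessian
    X'WX.  (Quasi-)complete separation — any |beta| beyond
    ``SEPARATION_BOUND`` — is flagged rather than raised.
    """
    terms = list(terms)
    z = np.asarray(labels.z, dtype=float)
    n = z.size
    if z.min() == z.max():
        raise EstimationError("all labels identical: no persisted/extirpated contrast to fit")
    cols = [np.ones(n)]
    for t in terms:
        if t not in bundle.site_covs:
            raise KeyError(f"{t!r} is not a site-level covariate in the bundle")
        cols.append(np.asarray(bundle.site_covs[t], dtype=float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise FormatError("non-finite covariate values in LSD design")

    def nll(beta: np.ndarray) -> float:
        eta = X @ beta
        return float(np.sum(np.logaddexp(0.0, eta) - z * eta))

    def grad(beta: np.ndarray) -> np.ndarray:
        return X.T @ (expit(X @ beta) - z)

    rng = np.random.default_rng(_RESTART_SEED)
    start = np.zeros(X.shape[1])
    best = None
    for attempt in range(6):  # zero start + up to 5 jittered restarts
        res = minimize(nll, start, jac=grad, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        start = rng.normal(scale=0.5, size=X.shape[1])
    beta = best.x

    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = X.T @ (w[:, None] * X)
    cond = float(np.linalg.cond(H))
    with np.errstate(all="ignore"):
        vcov = np.linalg.pinv(H)
        ses_vec = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    # separation manifests as a diverging slope; the intercept is allowed
    # to be large (it absorbs covariate location shifts)
    separation = bool(beta.size > 1 and np.abs(beta[1:]).max() > SEPARATION_BOUND)
    converged = bool(best.success) and not separation
    if separation:
        warnings.warn(
            f"LSD fit {name or terms}: |beta| exceeds {SEPARATION_BOUND} — "
            "(quasi-)complete separation; estimates unreliable",
            stacklevel=2,
        )
    return LsdFit(
        name=name or f"psi({'+'.join(terms) if terms else '.'}) p(.)",
        intercept=float(beta[0]),
        intercept_se=float(ses_vec[0]),
        betas={t: float(b) for t, b in zip(terms, beta[1:])},
        ses={t: float(s) for t, s in zip(terms, ses_vec[1:])},
        logL=-float(best.fun),
        n_used=n,
        converged=converged,
        separation_flag=separation,
        condition_number=cond,
    )


def screen_collinearity(
    bundle: CovariateBundle,
    candidates: Sequence[str],
    labels: PersistenceLabels,
    threshold: float = 0.65,
) -> ScreeningReport:
    """Pairwise Pearson screening of site covariates.

    For every pair with |r| strictly above ``threshold`` (pairs exactly
    at the threshold are both kept), the member with the worse
    single-variable score is dropped; the score is the AICc of the
    one-covariate LSD fit against the persistence labels (lower is
    better, ties broken alphabetically).  Dropping proceeds greedily
    from the largest |r| downward.  Zero-variance covariates are
    excluded from the correlation step with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate covariates to screen")
    usable, constant = [], []
    for c in candidates:
        x = bundle.site_covs[c]
        if np.ptp(x) == 0:
            constant.append(c)
            warnings.warn(f"covariate {c!r} is constant; excluded from screening", stacklevel=2)
        else:
            usable.append(c)

    n = len(labels.z)
    scores = {
        c: aicc(fit_lsd(labels, bundle, [c]).logL, K=2, n=n) for c in usable
    }
    mat = np.corrcoef(np.vstack([bundle.site_covs[c] for c in usable])) if usable else np.empty((0, 0))
    corr = pd.DataFrame(mat, index=usable, columns=usable)

    pairs = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            pairs.append((abs(corr.loc[a, b]), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped_set: set[str] = set()
    dropped: list[tuple[str, str, float]] = []
    for r_abs, a, b in pairs:
        if r_abs <= threshold or a in dropped_set or b in dropped_set:
            continue
        # worse = higher AICc; scores within 1e-6 are a tie, broken by
        # keeping the alphabetically first name
        if abs(scores[a] - scores[b]) < 1e-6:
            keep, drop = (a, b) if a < b else (b, a)
        elif scores[a] < scores[b]:
            keep, drop = a, b
        else:
            keep, drop = b, a
        dropped_set.add(drop)
        dropped.append((drop, keep, float(r_abs)))

    retained = tuple(c for c in usable if c not in dropped_set)
    return ScreeningReport(
        correlations=corr,
        dropped=tuple(dropped),
        retained=retained,
        univariate_scores=scores,
        excluded_constant=tuple(constant),
    )


def lsd_score(fit: LsdFit, x: Mapping[str, float | np.ndarray]) -> np.ndarray | float:
    """Relative persistence score exp(sum_k beta_k x_k).

    The intercept is deliberately excluded: the LSD is defined only up
    to proportionality, so scores carry meaning only as ratios between
    sites.  ``x`` must supply a value (scalar or vector) for every term
    in the fit.
    """
    missing = [t for t in fit.betas if t not in x]
    if missing:
        raise KeyError(f"missing covariate values for terms {missing}")
    exponent = 0.0
    for t, b in fit.betas.items():
        exponent = exponent + b * np.asarray(x[t], dtype=float)
    return np.exp(exponent)


def lsd_scores(fit: LsdFit, bundle: CovariateBundle) -> np.ndarray:
    """Per-site relative persistence scores from a bundle."""
    return np.asarray(lsd_score(fit, bundle.site_covs), dtype=float)
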