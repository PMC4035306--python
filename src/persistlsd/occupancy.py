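"""Single-season persistence likelihood with imperfect detection.

Each site i is latently persistent with probability psi_i and, when
persistent, detected on surveyed occasion j with probability p_ij; a
site with no detections is ambiguous between true extirpation and
repeated non-detection.  The site's likelihood contribution is

    L_i = psi_i * prod_{j surveyed} p_ij^{y_ij} (1 - p_ij)^{1 - y_ij}
          + (1 - psi_i) * I[no detection among surveyed occasions]

with unsurveyed occasions contributing factor 1 (a never-surveyed site
contributes exactly 1).  Both psi and p are logit-linear in covariates:
psi over site-level terms, p over site- or occasion-level terms.

Assumptions inherited from the repeat-survey design: closure of the
persistence state within the season, no false-positive detections, and
independence of detections across occasions given the state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess

from .errors import IdentifiabilityError
from .io import MISSING, CovariateBundle, DetectionHistoryTable, ModelSpec

_RESTART_SEED = 98126  # jittered optimizer restarts only
_BOUNDARY_EPS = 1e-6
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one psi/p covariate structure.

    ``beta_psi``/``alpha_p`` are intercept-first coefficient vectors on
    the scale the optimizer used (occasion-level p covariates are
    standardized; see ``p_scaling`` and :meth:`coef_table`).  ``K``
    counts every estimated parameter: two intercepts plus one slope per
    term.
    """

    spec: ModelSpec
    beta_psi: np.ndarray
    alpha_p: np.ndarray
    logL: float
    vcov: np.ndarray | None
    ses: np.ndarray | None
    converged: bool
    boundary_flag: bool
    condition_number: float
    n_sites: int
    psi_names: tuple[str, ...]
    p_names: tuple[str, ...]
    p_scaling: dict[str, tuple[float, float]]

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def K(self) -> int:
        return len(self.beta_psi) + len(self.alpha_p)

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.logL

    def coef_table(self) -> "np.recarray | list[dict]":
        """Coefficients with SEs on both the fitting scale and (for
        standardized occasion covariates) the natural scale."""
        rows = []
        names = [f"psi:{t}" for t in self.psi_names] + [f"p:{t}" for t in self.p_names]
        est = np.concatenate([self.beta_psi, self.alpha_p])
        ses = self.ses if self.ses is not None else np.full(est.shape, np.nan)
        for name, e, s in zip(names, est, ses):
            term = name.split(":", 1)[1]
            mean, sd = self.p_scaling.get(term, (0.0, 1.0)) if name.startswith("p:") else (0.0, 1.0)
            natural = e / sd if term in self.p_scaling else e
            rows.append({"parameter": name, "estimate": float(e), "se": float(s),
                         "estimate_natural": float(natural),
                         "se_natural": float(s / sd) if term in self.p_scaling else float(s)})
        return rows

    def to_json(self) -> dict:
        return {
            "model": self.spec.to_json(),
            "coefficients": self.coef_table(),
            "logL": self.logL,
            "minus2LL": self.minus2ll,
            "K": self.K,
            "n_sites": self.n_sites,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
            "condition_number": self.condition_number,
            "p_scaling": {k: list(v) for k, v in self.p_scaling.items()},
        }


def site_likelihood(psi: float, p: Sequence[float], history: Sequence[int]) -> float:
    """Likelihood of one site's detection history given psi and per-occasion
    detection probabilities; MISSING occasions contribute factor 1."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must be in [0, 1]")
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("each detection probability must be in [0, 1]")
    h = np.asarray(history)
    surveyed = h != MISSING
    y = h[surveyed].astype(float)
    pj = p[surveyed]
    detected_part = psi * float(np.prod(np.where(y == 1, pj, 1 - pj)))
    no_detection = float((y == 0).all())  # vacuously true when nothing surveyed
    return detected_part + (1.0 - psi) * no_detection


def _designs(h: DetectionHistoryTable, bundle: CovariateBundle, spec: ModelSpec):
    """Build the psi design (n x 1+q) and p design (n x K x 1+r).

    Occasion-level p covariates are standardized over surveyed cells for
    optimizer stability; the (mean, sd) pairs are returned so fits can
    report natural-scale coefficients and predict on new data."""
    spec.resolve(bundle)
    bundle.validate_for(h, spec.psi_terms + spec.p_terms)
    n, K = h.n_sites, h.n_occasions
    for t in spec.psi_terms:
        if bundle.level(t) != "site":
            raise ValueError(f"psi term {t!r} must be site-level (occasion terms enter p only)")
    X = np.column_stack([np.ones(n)] + [bundle.site_covs[t] for t in spec.psi_terms])
    V = np.ones((n, K, 1 + len(spec.p_terms)))
    scaling: dict[str, tuple[float, float]] = {}
    surveyed = h.surveyed
    for k, t in enumerate(spec.p_terms, start=1):
        if bundle.level(t) == "site":
            V[:, :, k] = bundle.site_covs[t][:, None]
        else:
            m = np.array(bundle.occasion_covs[t], dtype=float)
            vals = m[surveyed]
            mean, sd = float(vals.mean()), float(vals.std())
            sd = sd if sd > 0 else 1.0
            scaling[t] = (mean, sd)
            m = (m - mean) / sd
            m[~surveyed] = 0.0  # unused cells; zero keeps the design finite
            V[:, :, k] = m
    return X, V, scaling


def _site_loglik_terms(theta, X, V, y, surveyed, no_detection):
    npsi = X.shape[1]
    psi = expit(X @ theta[:npsi])
    p = expit(V @ theta[npsi:])
    logp = np.where(surveyed & (y == 1), np.log(np.clip(p, 1e-12, None)), 0.0)
    log1mp = np.where(surveyed & (y == 0), np.log(np.clip(1 - p, 1e-12, None)), 0.0)
    cond = np.exp((logp + log1mp).sum(axis=1))
    L = psi * cond + (1 - psi) * no_detection
    return np.log(np.clip(L, _LOG_FLOOR, None)), psi, p


def _neg_score(theta, X, V, y, surveyed, no_detection):
    """Analytic gradient of the negative log-likelihood.

    d logL_i / d eta_psi = psi(1-psi)(c_i - I_i)/L_i;
    d logL_i / d eta_p_ij = psi c_i (y_ij - p_ij)/L_i on surveyed occasions.
    """
    npsi = X.shape[1]
    psi = expit(X @ theta[:npsi])
    p = expit(V @ theta[npsi:])
    logp = np.where(surveyed & (y == 1), np.log(np.clip(p, 1e-12, None)), 0.0)
    log1mp = np.where(surveyed & (y == 0), np.log(np.clip(1 - p, 1e-12, None)), 0.0)
    cond = np.exp((logp + log1mp).sum(axis=1))
    L = np.clip(psi * cond + (1 - psi) * no_detection, _LOG_FLOOR, None)
    g_psi = psi * (1 - psi) * (cond - no_detection) / L
    g_p = np.where(surveyed, (psi * cond / L)[:, None] * (y - p), 0.0)
    grad_beta = X.T @ g_psi
    grad_alpha = np.einsum("nk,nkq->q", g_p, V)
    return -np.concatenate([grad_beta, grad_alpha])


def fit_occupancy(
    h: DetectionHistoryTable,
    bundle: CovariateBundle,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Maximize the detection-corrected persistence likelihood.

    Quasi-Newton from a zero (or supplied) start with up to 5 jittered
    restarts; SEs from the inverse observed-information matrix.
    Optimizer failure yields ``converged=False``, never an exception;
    a fitted probability pinned within 1e-6 of 0/1 sets
    ``boundary_flag``.  The Hessian condition number is reported so
    callers can exclude ill-behaved covariate structures from ranking.
    """
    if h.n_occasions == 1 and not spec.psi_terms and not spec.p_terms:
        raise IdentifiabilityError(
            "psi and p are confounded with a single occasion and no covariates"
        )
    X, V, scaling = _designs(h, bundle, spec)
    y = h.y.astype(float)
    surveyed = h.surveyed
    no_detection = (~((y == 1) & surveyed).any(axis=1)).astype(float)
    dim = X.shape[1] + V.shape[2]

    def nll(theta: np.ndarray) -> float:
        ll, _, _ = _site_loglik_terms(theta, X, V, y, surveyed, no_detection)
        return -float(ll.sum())

    def grad(theta: np.ndarray) -> np.ndarray:
        return _neg_score(theta, X, V, y, surveyed, no_detection)

    rng = np.random.default_rng(_RESTART_SEED)
    x0 = np.zeros(dim) if start is None else np.asarray(start, dtype=float)
    best = None
    optimizer_ok = False
    for attempt in range(6):
        res = minimize(nll, x0, jac=grad, method="BFGS",
                       options={"maxiter": 1000, "gtol": 1e-6})
        # precision-loss near a probability boundary still counts as an
        # optimum when the score is (relatively) flat
        ok = res.success or float(np.abs(res.jac).max()) < 1e-4 * (1 + abs(res.fun))
        if best is None or res.fun < best.fun:
            best, optimizer_ok = res, ok
        if ok:
            break
        x0 = rng.normal(scale=0.75, size=dim)
    theta = best.x

    ll, psi, p = _site_loglik_terms(theta, X, V, y, surveyed, no_detection)
    boundary = bool(
        (np.minimum(psi, 1 - psi) < _BOUNDARY_EPS).any()
        or (np.minimum(p, 1 - p)[surveyed] < _BOUNDARY_EPS).any()
    )

    vcov = ses = None
    cond = np.nan
    converged = optimizer_ok
    if compute_vcov:
        with np.errstate(all="ignore"):
            try:
                H = approx_hess(theta, nll)
                cond = float(np.linalg.cond(H))
                vcov = np.linalg.pinv(H)
                ses = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
                if not np.isfinite(H).all():
                    converged = False
            except Exception:  # numerical Hessian failure is a diagnostics failure
                converged = False
    if not converged:
        warnings.warn(f"fit of {spec.name!r} did not converge cleanly", stacklevel=2)

    npsi = X.shape[1]
    return FitResult(
        spec=spec,
        beta_psi=theta[:npsi].copy(),
        alpha_p=theta[npsi:].copy(),
        logL=float(ll.sum()),
        vcov=vcov,
        ses=ses,
        converged=converged,
        boundary_flag=boundary,
        condition_number=cond,
        n_sites=h.n_sites,
        psi_names=("(intercept)",) + spec.psi_terms,
        p_names=("(intercept)",) + spec.p_terms,
        p_scaling=scaling,
    )


def predict_psi(fit: FitResult, bundle: CovariateBundle) -> np.ndarray:
    """Per-site persistence probability logistic(x_i' beta)."""
    missing = [t for t in fit.spec.psi_terms if t not in bundle.site_covs]
    if missing:
        raise KeyError(f"bundle lacks psi terms {missing}")
    X = np.column_stack(
        [np.ones(len(bundle.site_ids))] + [bundle.site_covs[t] for t in fit.spec.psi_terms]
    )
    return expit(X @ fit.beta_psi)


def predict_p(fit: FitResult, h: DetectionHistoryTable, bundle: CovariateBundle) -> np.ndarray:
    """Per-site-and-occasion detection probability, applying the stored
    standardization of occasion-level covariates."""
    n, K = h.n_sites, h.n_occasions
    V = np.ones((n, K, len(fit.alpha_p)))
    for k, t in enumerate(fit.spec.p_terms, start=1):
        if t not in bundle:
            raise KeyError(f"bundle lacks p term {t!r}")
        if bundle.level(t) == "site":
            V[:, :, k] = bundle.site_covs[t][:, None]
        else:
            m = np.array(bundle.occasion_covs[t], dtype=float)
            mean, sd = fit.p_scaling.get(t, (0.0, 1.0))
            m = (m - mean) / sd
            m[~h.surveyed] = 0.0
            V[:, :, k] = m
    return expit(V @ fit.alpha_p)


def naive_estimate(h: DetectionHistoryTable) -> float:
    """Fraction of sites with at least one detection — the persistence
    estimate uncorrected for imperfect detection."""
    return float(h.detected.mean())
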