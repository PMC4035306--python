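"""Parametric-bootstrap goodness-of-fit for a fitted detection model.

The Pearson statistic compares observed and expected detection-history
frequencies.  Sites are grouped into cohorts by their pattern of
surveyed occasions (missingness pattern); within a cohort every
possible 0/1 history over the surveyed occasions is a cell.  Because the
statistic's null distribution is unknown at realistic sample sizes, the
reference distribution is built by simulating histories from the fitted
model itself, refitting, and recomputing the statistic; the
overdispersion ratio c-hat is the observed statistic divided by the
bootstrap mean.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStatisticError
from .io import MISSING, CovariateBundle, DetectionHistoryTable
from .occupancy import FitResult, fit_occupancy, predict_p, predict_psi

#: Expected counts below this are pooled into a cohort-level "other" cell.
POOL_THRESHOLD = 0.5


@dataclass(frozen=True)
class GofResult:
    """Observed statistic, bootstrap reference summary, p-value and c-hat."""

    chi2_obs: float
    p_value: float
    c_hat: float
    boot_mean: float
    boot_quantiles: dict[str, float]
    nboot: int
    n_failed: int
    seed: int
    warning: str | None = None

    def to_json(self) -> dict:
        return {
            "chi2_obs": self.chi2_obs,
            "p_value": self.p_value,
            "c_hat": self.c_hat,
            "boot_mean": self.boot_mean,
            "boot_quantiles": dict(self.boot_quantiles),
            "nboot": self.nboot,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "warning": self.warning,
        }


def _cohorts(h: DetectionHistoryTable) -> dict[tuple[bool, ...], np.ndarray]:
    """Site indices grouped by surveyed-occasion pattern."""
    out: dict[tuple[bool, ...], list[int]] = {}
    for i, mask in enumerate(h.surveyed):
        out.setdefault(tuple(bool(m) for m in mask), []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def _pattern_prob(psi: np.ndarray, p: np.ndarray, pattern: tuple[int, ...]) -> np.ndarray:
    """P(pattern | psi_i, p_i.) for every site in a cohort (vectorized)."""
    y = np.asarray(pattern, dtype=float)
    cond = np.prod(np.where(y == 1, p, 1 - p), axis=1)
    no_det = float((y == 0).all())
    return psi * cond + (1 - psi) * no_det


def expected_history_counts(
    fit: FitResult, h: DetectionHistoryTable, bundle: CovariateBundle
) -> dict[tuple[bool, ...], dict[tuple[int, ...], float]]:
    """Expected count of each possible 0/1 history, per missingness cohort.

    Within a cohort the expectations sum exactly to the cohort size (the
    pattern probabilities of each site sum to 1)."""
    psi = predict_psi(fit, bundle)
    p = predict_p(fit, h, bundle)
    out: dict[tuple[bool, ...], dict[tuple[int, ...], float]] = {}
    for mask, idx in _cohorts(h).items():
        occ = [j for j, m in enumerate(mask) if m]
        psi_c = psi[idx]
        p_c = p[np.ix_(idx, occ)]
        cells: dict[tuple[int, ...], float] = {}
        for pattern in itertools.product((0, 1), repeat=len(occ)):
            cells[pattern] = float(_pattern_prob(psi_c, p_c, pattern).sum())
        out[mask] = cells
    return out


def observed_history_counts(
    h: DetectionHistoryTable,
) -> dict[tuple[bool, ...], dict[tuple[int, ...], float]]:
    """Observed frequency of each 0/1 history, per missingness cohort,
    with zero-count patterns included so keys match the expectations."""
    out: dict[tuple[bool, ...], dict[tuple[int, ...], float]] = {}
    for mask, idx in _cohorts(h).items():
        occ = [j for j, m in enumerate(mask) if m]
        cells = {pat: 0.0 for pat in itertools.product((0, 1), repeat=len(occ))}
        for i in idx:
            cells[tuple(int(v) for v in h.y[i, occ])] += 1.0
        out[mask] = cells
    return out


def pearson_chi2(observed: dict, expected: dict, pool_threshold: float = POOL_THRESHOLD) -> float:
    """Sum of (O - E)^2 / E over cells, after pooling cells with
    E < ``pool_threshold`` into a single "other" cell.

    Raises :class:`DegenerateStatisticError` when pooling leaves nothing
    to sum over."""
    if set(observed) != set(expected):
        raise ValueError("observed and expected must share the same pattern keys")
    o_other = e_other = 0.0
    chi2 = 0.0
    n_cells = 0
    for key in expected:
        e, o = expected[key], observed[key]
        if e < pool_threshold:
            o_other += o
            e_other += e
        else:
            chi2 += (o - e) ** 2 / e
            n_cells += 1
    if e_other > 0:
        chi2 += (o_other - e_other) ** 2 / e_other
        n_cells += 1
    if n_cells == 0:
        raise DegenerateStatisticError("all cells pooled away; statistic undefined")
    return float(chi2)


def gof_statistic(fit: FitResult, h: DetectionHistoryTable, bundle: CovariateBundle) -> float:
    """Pearson statistic summed over missingness cohorts."""
    exp = expected_history_counts(fit, h, bundle)
    obs = observed_history_counts(h)
    return float(sum(pearson_chi2(obs[m], exp[m]) for m in exp))


def _simulate_from_fit(
    fit: FitResult, h: DetectionHistoryTable, bundle: CovariateBundle, rng: np.random.Generator
) -> DetectionHistoryTable:
    """Parametric-bootstrap histories: z ~ Bern(psi-hat), detections
    z * Bern(p-hat) on the original surveyed occasions."""
    psi = predict_psi(fit, bundle)
    p = predict_p(fit, h, bundle)
    z = rng.random(h.n_sites) < psi
    y = (rng.random(h.y.shape) < p) & z[:, None]
    out = np.where(h.surveyed, y.astype(np.int8), np.int8(MISSING))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # bootstrap tables may repeat all-MISSING flags
        return DetectionHistoryTable(h.site_ids, out)


def gof_test(
    fit: FitResult,
    h: DetectionHistoryTable,
    bundle: CovariateBundle,
    nboot: int = 1000,
    seed: int = 0,
) -> GofResult:
    """MacKenzie–Bailey-style parametric bootstrap.

    Each replicate simulates histories from the fitted model (preserving
    each site's missingness pattern), refits the same covariate
    structure warm-started at the original estimates, and recomputes the
    Pearson statistic.  ``p_value`` is the proportion of bootstrap
    statistics >= the observed one; ``c_hat`` is observed / bootstrap
    mean.  Replicates whose refit fails are dropped and counted; more
    than 20% failures attaches a reliability warning to the result.
    """
    rng = np.random.default_rng(seed)
    chi2_obs = gof_statistic(fit, h, bundle)
    start = np.concatenate([fit.beta_psi, fit.alpha_p])
    stats = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(nboot):
            h_b = _simulate_from_fit(fit, h, bundle, rng)
            try:
                refit = fit_occupancy(h_b, bundle, fit.spec, start=start, compute_vcov=False)
                if not refit.converged:
                    n_failed += 1
                    continue
                stats.append(gof_statistic(refit, h_b, bundle))
            except Exception:
                n_failed += 1
    if not stats:
        raise DegenerateStatisticError("every bootstrap replicate failed")
    boot = np.asarray(stats)
    warning = None
    if n_failed > 0.2 * nboot:
        warning = f"unreliable: {n_failed}/{nboot} bootstrap refits failed"
        warnings.warn(warning, stacklevel=2)
    return GofResult(
        chi2_obs=float(chi2_obs),
        p_value=float((boot >= chi2_obs).mean()),
        c_hat=float(chi2_obs / boot.mean()),
        boot_mean=float(boot.mean()),
        boot_quantiles={
            "q025": float(np.quantile(boot, 0.025)),
            "q50": float(np.quantile(boot, 0.5)),
            "q975": float(np.quantile(boot, 0.975)),
        },
        nboot=nboot,
        n_failed=n_failed,
        seed=seed,
        warning=warning,
    )
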