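"""AICc model selection: ranking, Akaike weights, candidate sets, and the
persistence-vs-occupancy prediction comparison.

The effective sample size for the small-sample correction is the number
of sites, the dominant convention for single-season occupancy-style
likelihoods where each site contributes one (possibly multi-occasion)
independent term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SelectionError
from .io import ModelSpec

#: Hessian condition number above which a fit is excluded from ranking.
ILL_CONDITIONED = 1e8

#: Detection structures crossed with the persistence structures when
#: detection error is brought into the candidate set.
DETECTION_P_STRUCTURES: tuple[tuple[str, ...], ...] = ((), ("Rush",), ("Date",), ("Rush", "Date"))


def aicc(logL: float, K: int, n: int) -> float:
    """Akaike information criterion with small-sample correction:
    -2 logL + 2K + 2K(K+1)/(n - K - 1).  Undefined for n <= K + 1."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n}, K={K} (need n > K + 1)")
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def model_likelihood(delta_aicc: float) -> float:
    """Likelihood of a model relative to the best: exp(-dAICc / 2)."""
    return math.exp(-0.5 * delta_aicc)


@dataclass(frozen=True)
class RankTable:
    """AICc ranking of a candidate set.

    ``frame`` has columns model, K, AICc, dAICc, model_likelihood,
    weight, minus2LL sorted by AICc ascending; ``excluded`` lists
    (model, reason) for fits dropped before ranking.
    """

    frame: pd.DataFrame
    n_used: int
    excluded: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def top_model(self) -> str:
        return str(self.frame.iloc[0]["model"])

    def top_models(self, delta_cutoff: float = 4.0, max_models: int = 4) -> list[str]:
        """Names of models with similar support: dAICc <= cutoff, capped."""
        sel = self.frame[self.frame["dAICc"] <= delta_cutoff]
        return [str(m) for m in sel["model"].head(max_models)]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {
            "n_used": self.n_used,
            "rows": self.frame.to_dict(orient="records"),
            "excluded": [list(e) for e in self.excluded],
        }


def rank_models(fits: Sequence, n: int) -> RankTable:
    """Rank fitted models by AICc.

    Accepts any mix of fit objects exposing ``name``, ``K``, ``logL``,
    ``converged`` and ``condition_number`` (both the LSD and the
    detection-corrected fits do).  Non-converged or ill-conditioned fits
    are excluded with a recorded reason; identical AICc values are
    ordered by smaller K, then name.
    """
    included, excluded = [], []
    for f in fits:
        name = getattr(f, "name", None) or f.spec.name
        if not f.converged:
            excluded.append((name, "non-convergence"))
        elif np.isfinite(f.condition_number) and f.condition_number > ILL_CONDITIONED:
            excluded.append((name, f"ill-conditioned Hessian (cond={f.condition_number:.3g})"))
        else:
            included.append((name, f))
    if not included:
        raise SelectionError("every candidate fit was excluded; nothing to rank")

    rows = []
    for name, f in included:
        a = aicc(f.logL, f.K, n)
        rows.append({"model": name, "K": int(f.K), "AICc": a, "minus2LL": -2.0 * f.logL})
    df = pd.DataFrame(rows)
    df = df.sort_values(["AICc", "K", "model"], kind="mergesort").reset_index(drop=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    df["model_likelihood"] = np.exp(-0.5 * df["dAICc"])
    df["weight"] = df["model_likelihood"] / df["model_likelihood"].sum()
    df = df[["model", "K", "AICc", "dAICc", "model_likelihood", "weight", "minus2LL"]]
    return RankTable(frame=df, n_used=n, excluded=tuple(excluded))


def build_candidate_set(
    stage: str,
    psi_structures: Sequence[ModelSpec | Sequence[str]] | None = None,
) -> list[ModelSpec]:
    """Construct the a-priori candidate set.

    ``stage="persistence"`` returns the fixed 13-model set over psi with
    p(.): single lake/vegetation/development covariates, their
    combinations, a global model and a null.  The bulrush covariate
    appears twice in the a-priori set (once as a vegetation model, once
    as a buffer-category model); the two entries share the term but keep
    distinct names.

    ``stage="detection"`` crosses the supplied psi structures with the
    four detection structures p(.), p(Rush), p(Date), p(Rush+Date).
    """
    if stage == "persistence":
        entries: list[tuple[Sequence[str], str | None]] = [
            (("Shore",), None),
            (("Fish",), None),
            (("Shore", "Fish"), None),
            (("Rush",), None),
            (("Develop",), None),
            (("Rush",), "psi(Rush)[Buffer] p(.)"),
            (("Develop", "Forest"), None),
            (("Shore", "Fish", "Rush"), None),
            (("Shore", "Fish", "Develop"), None),
            (("Shore", "Fish", "Forest"), None),
            (("Rush", "Forest", "Develop"), None),
            (("Shore", "Fish", "Rush", "Forest", "Develop"), None),
            ((), None),  # null
        ]
        specs = [ModelSpec.build(psi, (), name) for psi, name in entries]
    elif stage == "detection":
        if not psi_structures:
            raise ValueError("detection stage needs psi structures to cross")
        specs = []
        for s in psi_structures:
            psi_terms = s.psi_terms if isinstance(s, ModelSpec) else tuple(s)
            for p_terms in DETECTION_P_STRUCTURES:
                specs.append(ModelSpec.build(psi_terms, p_terms))
    else:
        raise ValueError(f"unknown stage {stage!r}")
    names = [s.name for s in specs]
    assert len(set(names)) == len(names), "candidate names must be unique"
    return specs


def compare_predictions(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Pearson correlation between two per-site score vectors with the
    t-based two-sided p-value (df = n - 2).

    Used to contrast relative persistence scores with an externally
    supplied occupancy prediction for the same sites.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in score vectors")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a score vector; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
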