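"""Core data containers and the CSV/JSON formats every other module consumes.

A detection history is the per-site record of repeat-survey outcomes:
1 = detected, 0 = surveyed but not detected, MISSING = occasion not
surveyed.  Covariates come in two flavours: site-level (one number per
site, e.g. shoreline perimeter) and occasion-level (one number per
site x visit, e.g. Julian date of the survey).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

#: Sentinel for an occasion that was not surveyed (internal representation).
MISSING: int = -1

#: Tokens accepted as MISSING on read; "." is always written.
_MISSING_TOKENS = {"", ".", "NA"}
_MISSING_OUT = "."


@dataclass(frozen=True)
class DetectionHistoryTable:
    """n sites x K occasions of {0, 1, MISSING} survey outcomes.

    ``y`` is an int8 matrix; ``site_ids`` is the canonical site order that
    covariate bundles are aligned to.
    """

    site_ids: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.int8)
        if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 1:
            raise FormatError("detection matrix must be 2-D with n >= 1, K >= 1")
        if len(self.site_ids) != y.shape[0]:
            raise FormatError("site_ids length does not match matrix rows")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise FormatError("duplicate site ids")
        bad = ~np.isin(y, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"entry y[{self.site_ids[i]}, occ{j + 1}] = {y[i, j]} "
                "is not one of 0, 1, MISSING"
            )
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        y.setflags(write=False)
        object.__setattr__(self, "y", y)
        if self.all_missing_sites:
            warnings.warn(
                f"sites never surveyed (all-MISSING rows): {self.all_missing_sites}; "
                "they contribute a constant factor to the likelihood",
                stacklevel=2,
            )

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def surveyed(self) -> np.ndarray:
        """Boolean n x K mask of occasions that were actually surveyed."""
        return self.y != MISSING

    @property
    def detected(self) -> np.ndarray:
        """Boolean vector: site had at least one detection."""
        return (self.y == 1).any(axis=1)

    @property
    def all_missing_sites(self) -> tuple[str, ...]:
        rows = ~self.surveyed.any(axis=1)
        return tuple(s for s, r in zip(self.site_ids, rows) if r)


@dataclass(frozen=True)
class PersistenceLabels:
    """Binary persistence outcome per site: 1 = persisted (detected at
    least once), 0 = extirpated / never detected."""

    site_ids: tuple[str, ...]
    z: np.ndarray
    flagged_all_missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int8)
        if not np.isin(z, (0, 1)).all():
            raise FormatError("labels must be 0/1")
        z.setflags(write=False)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))


@dataclass
class CovariateBundle:
    """Named site-level vectors and occasion-level matrices aligned to a
    :class:`DetectionHistoryTable`.

    ``transforms`` records log-transform offsets applied by
    :func:`persistlsd.lsd.prepare_covariates` so scores can be
    back-transformed and runs reproduced.
    """

    site_ids: tuple[str, ...]
    site_covs: dict[str, np.ndarray] = field(default_factory=dict)
    occasion_covs: dict[str, np.ndarray] = field(default_factory=dict)
    transforms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_ids = tuple(self.site_ids)
        n = len(self.site_ids)
        for name, v in self.site_covs.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (n,):
                raise FormatError(f"site covariate {name!r} has shape {v.shape}, expected ({n},)")
            self.site_covs[name] = v
        for name, m in self.occasion_covs.items():
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != n:
                raise FormatError(f"occasion covariate {name!r} has shape {m.shape}")
            self.occasion_covs[name] = m

    def __contains__(self, name: str) -> bool:
        return name in self.site_covs or name in self.occasion_covs

    def level(self, name: str) -> str:
        if name in self.site_covs:
            return "site"
        if name in self.occasion_covs:
            return "occasion"
        raise KeyError(name)

    def aligned_to(self, site_ids: Sequence[str]) -> "CovariateBundle":
        """Return a copy re-ordered to ``site_ids`` (the canonical history
        order).  Sites absent from the bundle raise ``AlignmentError``;
        extra bundle sites are dropped with a logged warning."""
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in index]
        if missing:
            raise AlignmentError(f"sites in histories but not in covariates: {missing}")
        extra = [s for s in self.site_ids if s not in set(site_ids)]
        if extra:
            logger.warning("covariate sites not in histories, ignored: %s", extra)
        order = np.array([index[s] for s in site_ids])
        return CovariateBundle(
            site_ids=tuple(site_ids),
            site_covs={k: v[order] for k, v in self.site_covs.items()},
            occasion_covs={k: m[order] for k, m in self.occasion_covs.items()},
            transforms=dict(self.transforms),
        )

    def validate_for(self, h: DetectionHistoryTable, terms: Sequence[str]) -> None:
        """Check that every referenced covariate is present and non-missing
        wherever the history has a surveyed occasion."""
        if self.site_ids != h.site_ids:
            raise AlignmentError("bundle is not aligned to the detection-history site order")
        for t in terms:
            if t not in self:
                raise KeyError(f"covariate {t!r} not in bundle")
            if t in self.site_covs:
                if not np.isfinite(self.site_covs[t]).all():
                    raise FormatError(f"site covariate {t!r} has missing values")
            else:
                m = self.occasion_covs[t]
                if m.shape != h.y.shape:
                    raise FormatError(f"occasion covariate {t!r} shape mismatch")
                if not np.isfinite(m[h.surveyed]).all():
                    raise FormatError(f"occasion covariate {t!r} missing at a surveyed occasion")


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate structure for persistence (psi) and detection (p).

    Empty term lists denote intercept-only structures, conventionally
    written "psi(.)" and "p(.)".
    """

    name: str
    psi_terms: tuple[str, ...] = ()
    p_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "psi_terms", tuple(self.psi_terms))
        object.__setattr__(self, "p_terms", tuple(self.p_terms))
        for terms, which in ((self.psi_terms, "psi"), (self.p_terms, "p")):
            if len(set(terms)) != len(terms):
                raise FormatError(f"duplicate {which} terms in model {self.name!r}")

    @staticmethod
    def default_name(psi_terms: Sequence[str], p_terms: Sequence[str]) -> str:
        psi = "+".join(psi_terms) if psi_terms else "."
        p = "+".join(p_terms) if p_terms else "."
        return f"psi({psi}) p({p})"

    @classmethod
    def build(cls, psi_terms: Sequence[str] = (), p_terms: Sequence[str] = (),
              name: str | None = None) -> "ModelSpec":
        return cls(name or cls.default_name(psi_terms, p_terms),
                   tuple(psi_terms), tuple(p_terms))

    def resolve(self, bundle: CovariateBundle) -> None:
        for t in self.psi_terms + self.p_terms:
            if t not in bundle:
                raise KeyError(f"model {self.name!r} references unknown covariate {t!r}")

    def to_json(self) -> dict:
        return {"name": self.name, "psi": list(self.psi_terms), "p": list(self.p_terms)}

    @classmethod
    def from_json(cls, obj: Mapping) -> "ModelSpec":
        return cls.build(obj.get("psi", []), obj.get("p", []), obj.get("name"))


# ---------------------------------------------------------------------------
# Readers / writers


def read_detection_csv(path: str | Path) -> DetectionHistoryTable:
    """Read a wide detection-history CSV with header ``site,occ1..occK``.

    Cells are 0, 1, or one of "", ".", "NA" for a missing (unsurveyed)
    occasion; any other value is a :class:`FormatError` naming the cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0] != "site":
        raise FormatError(f"{path}: expected header 'site,occ1,...,occK'")
    sites = df["site"].tolist()
    if len(set(sites)) != len(sites):
        dupes = sorted({s for s in sites if sites.count(s) > 1})
        raise FormatError(f"{path}: duplicate site ids {dupes}")
    occ_cols = list(df.columns[1:])
    y = np.empty((len(sites), len(occ_cols)), dtype=np.int8)
    for j, col in enumerate(occ_cols):
        for i, raw in enumerate(df[col]):
            cell = raw.strip()
            if cell in _MISSING_TOKENS:
                y[i, j] = MISSING
            elif cell in ("0", "1"):
                y[i, j] = int(cell)
            else:
                raise FormatError(
                    f"{path}: invalid cell {raw!r} at site {sites[i]!r}, column {col!r}"
                )
    return DetectionHistoryTable(tuple(sites), y)


def write_detection_csv(h: DetectionHistoryTable, path: str | Path) -> None:
    """Write the wide CSV form; MISSING is always written as ``.``."""
    with open(path, "w") as fh:
        fh.write("site," + ",".join(f"occ{j + 1}" for j in range(h.n_occasions)) + "\n")
        for s, row in zip(h.site_ids, h.y):
            cells = [_MISSING_OUT if v == MISSING else str(int(v)) for v in row]
            fh.write(s + "," + ",".join(cells) + "\n")


def read_covariates_csv(
    site_path: str | Path | None,
    occasion_path: str | Path | None = None,
    histories: DetectionHistoryTable | None = None,
) -> CovariateBundle:
    """Read site-level (keyed by ``site``) and optional occasion-level
    (long form, keyed by ``site,occasion``) covariate CSVs.

    If ``histories`` is given the bundle is re-ordered to its site order
    (the canonical order); covariate files never reorder histories.
    """
    site_covs: dict[str, np.ndarray] = {}
    occasion_covs: dict[str, np.ndarray] = {}

    if site_path is not None:
        df = pd.read_csv(site_path)
        if "site" not in df.columns:
            raise FormatError(f"{site_path}: missing 'site' key column")
        df["site"] = df["site"].astype(str)
        sites = tuple(df["site"])
        for col in df.columns.drop("site"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if (vals.isna() & df[col].notna()).any():
                bad = df.loc[vals.isna() & df[col].notna(), "site"].tolist()
                raise FormatError(f"{site_path}: non-numeric {col!r} at sites {bad}")
            site_covs[col] = vals.to_numpy(dtype=float)
    elif histories is not None:
        sites = histories.site_ids
    else:
        raise FormatError("need at least a site covariate file or a history table")

    if occasion_path is not None:
        long = pd.read_csv(occasion_path)
        for key in ("site", "occasion"):
            if key not in long.columns:
                raise FormatError(f"{occasion_path}: missing {key!r} key column")
        long["site"] = long["site"].astype(str)
        k_max = int(long["occasion"].max())
        site_index = {s: i for i, s in enumerate(sites)}
        unknown = sorted(set(long["site"]) - set(sites))
        if unknown:
            logger.warning("occasion covariates for unknown sites ignored: %s", unknown)
            long = long[long["site"].isin(site_index)]
        for col in long.columns.drop(["site", "occasion"]):
            m = np.full((len(sites), k_max), np.nan)
            vals = pd.to_numeric(long[col], errors="coerce")
            if (vals.isna() & long[col].notna()).any():
                raise FormatError(f"{occasion_path}: non-numeric value in column {col!r}")
            for s, occ, v in zip(long["site"], long["occasion"], vals):
                m[site_index[s], int(occ) - 1] = v
            occasion_covs[col] = m

    bundle = CovariateBundle(tuple(sites), site_covs, occasion_covs)
    if histories is not None:
        bundle = bundle.aligned_to(histories.site_ids)
    return bundle


def write_covariates_csv(
    bundle: CovariateBundle,
    site_path: str | Path,
    occasion_path: str | Path | None = None,
) -> None:
    df = pd.DataFrame({"site": list(bundle.site_ids), **bundle.site_covs})
    df.to_csv(site_path, index=False)
    if occasion_path is not None and bundle.occasion_covs:
        k = next(iter(bundle.occasion_covs.values())).shape[1]
        rows = []
        for i, s in enumerate(bundle.site_ids):
            for j in range(k):
                rows.append({"site": s, "occasion": j + 1,
                             **{name: m[i, j] for name, m in bundle.occasion_covs.items()}})
        pd.DataFrame(rows).to_csv(occasion_path, index=False)


def read_model_spec_json(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return ModelSpec.from_json(json.load(fh))


def labels_from_histories(h: DetectionHistoryTable) -> PersistenceLabels:
    """Persisted (1) iff the site has at least one detection; sites never
    surveyed are labelled 0 and flagged."""
    z = h.detected.astype(np.int8)
    flagged = h.all_missing_sites
    if flagged:
        warnings.warn(
            f"all-MISSING sites labelled extirpated by convention: {flagged}",
            stacklevel=2,
        )
    return PersistenceLabels(h.site_ids, z, flagged)
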