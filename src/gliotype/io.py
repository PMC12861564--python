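"""Core data containers and delimited-text I/O.

The package exchanges three kinds of tables: per-modality radiomic feature
matrices (samples x features), a clinical table (survival, demographics,
molecular markers), and optionally a gene-expression matrix.  All of them
are plain CSV with a header row and a leading ``sample_id`` column; loaders
validate rather than repair (no imputation anywhere — a missing or
non-numeric cell is a load error).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gliotype")

MODALITIES = ("T1CE", "T2FLAIR")

GENDER_LEVELS = ("female", "male")
IDH_LEVELS = ("wild", "mutant")
MGMT_LEVELS = ("unmethylated", "methylated")
GRADE_LEVELS = (2, 3, 4)


class LoadError(ValueError):
    """Raised when a table fails validation on load."""


@dataclass
class FeatureTable:
    """One modality's samples x features matrix of finite reals.

    Parameters
    ----------
    frame : pandas.DataFrame
        Numeric values indexed by sample ID, columns are feature names.
    modality : str
        Sequence label, e.g. ``"T1CE"`` or ``"T2FLAIR"``.
    """

    frame: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        idx = self.frame.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].tolist()
            raise LoadError(f"duplicate sample IDs: {dup[:5]}")
        if self.frame.columns.has_duplicates:
            dup = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise LoadError(f"duplicate feature names: {dup[:5]}")
        values = self.frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(self.frame)
            raise LoadError(f"non-numeric cell at {bad}")
        if values.size and not np.all(np.isfinite(values.astype(float))):
            i, j = np.argwhere(~np.isfinite(values.astype(float)))[0]
            raise LoadError(
                f"non-finite value at sample {idx[i]!r}, "
                f"feature {self.frame.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.frame.loc[:, list(names)], self.modality)

    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.frame.loc[list(ids)], self.modality)

    def standardized(self, ddof: int = 1) -> "FeatureTable":
        """Per-feature z-scores; constant features map to all-zero columns."""
        x = self.values
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=ddof)
        sd = np.where(sd > 0, sd, 1.0)
        z = (x - mu) / sd
        return FeatureTable(
            pd.DataFrame(z, index=self.frame.index, columns=self.frame.columns),
            self.modality,
        )


def _first_non_numeric(frame: pd.DataFrame) -> str:
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            return f"sample {frame.index[bad.argmax()]!r}, feature {col!r}"
    return "unknown cell"


@dataclass
class ClinicalTable:
    """Per-sample survival, demographic and molecular annotations."""

    frame: pd.DataFrame

    REQUIRED = (
        "os_days",
        "event",
        "age_years",
        "gender",
        "grade",
        "tumor_volume_cm3",
        "idh",
        "mgmt",
    )

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise LoadError("duplicate sample IDs in clinical table")
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise LoadError(f"clinical table missing columns: {missing}")
        f = self.frame
        if (f["os_days"].astype(float) < 0).any():
            raise LoadError("os_days must be nonnegative")
        if not set(f["event"].astype(int)) <= {0, 1}:
            raise LoadError("event must be 0/1")
        for col, levels in (
            ("gender", GENDER_LEVELS),
            ("idh", IDH_LEVELS),
            ("mgmt", MGMT_LEVELS),
        ):
            extra = set(f[col]) - set(levels)
            if extra:
                raise LoadError(f"{col} has values outside {levels}: {sorted(extra)}")
        extra = set(f["grade"].astype(int)) - set(GRADE_LEVELS)
        if extra:
            raise LoadError(f"grade outside {GRADE_LEVELS}: {sorted(extra)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def select_samples(self, ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.frame.loc[list(ids)])


@dataclass
class RunConfig:
    """Run-level knobs shared by the pipeline stages.

    All randomized operations derive their generators from ``seed``; it is
    recorded in every provenance sidecar so a run can be replayed exactly.
    """

    seed: int = 20240101
    sigma_grid: tuple[float, ...] = (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5)
    knn_grid: tuple[int, ...] = (10, 15, 20, 25, 30)
    k_min: int = 2
    k_max: int = 8
    cv_cutoff_percent: float = 30.0
    fdr_level: float = 0.05
    stability_threshold: float = 0.10
    n_resample: int = 1000

    def __post_init__(self) -> None:
        for name in ("fdr_level", "stability_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1.01:
                raise ValueError(f"{name} must lie in (0, 1]: {v}")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        for key in ("sigma_grid", "knn_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_feature_table(path: str | Path, modality: str) -> FeatureTable:
    """Load a CSV feature table (header row, first column ``sample_id``)."""
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise LoadError(f"{path}: empty feature table")
    frame.index = frame.index.astype(str)
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not frame.isna().to_numpy().any():
        raise LoadError(f"{path}: {_first_non_numeric(frame)}")
    if frame.isna().to_numpy().any():
        i, j = np.argwhere(frame.isna().to_numpy())[0]
        raise LoadError(
            f"{path}: missing value at sample {frame.index[i]!r}, "
            f"feature {frame.columns[j]!r}"
        )
    table = FeatureTable(numeric.astype(float), modality)
    logger.info(
        "read %s: %d samples x %d features (%s)",
        path, table.n_samples, table.n_features, modality,
    )
    return table


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise LoadError(f"{path}: empty clinical table")
    frame.index = frame.index.astype(str)
    return ClinicalTable(frame)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    frame = table.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path)


@dataclass
class Cohort:
    """Feature tables plus clinical data restricted to one shared sample order."""

    tables: list[FeatureTable]
    clinical: ClinicalTable | None = None
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.tables[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.tables[0].n_samples


def align_cohort(
    tables: Sequence[FeatureTable],
    clinical: ClinicalTable | None = None,
) -> Cohort:
    """Restrict all components to the common sample IDs, in one canonical order.

    The canonical order is the first table's order filtered to the common set,
    so the result does not depend on how the *other* inputs were sorted.
    Raises if the intersection is empty.
    """
    if not tables:
        raise ValueError("need at least one feature table")
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if clinical is not None:
        common &= set(clinical.sample_ids)
    if not common:
        raise LoadError("empty sample-ID intersection across cohort components")
    order = [s for s in tables[0].sample_ids if s in common]
    all_ids = set().union(*(t.sample_ids for t in tables))
    if clinical is not None:
        all_ids |= set(clinical.sample_ids)
    dropped = sorted(all_ids - common)
    if dropped:
        logger.info("align_cohort: dropped %d samples (%s...)", len(dropped), dropped[:3])
    aligned = [t.select_samples(order) for t in tables]
    clin = clinical.select_samples(order) if clinical is not None else None
    return Cohort(aligned, clin, dropped)


def write_provenance(path: str | Path, config: RunConfig, **extra) -> None:
    """Write the JSON sidecar recording seed, thresholds and stage extras."""
    payload = {"config": config.to_dict(), **extra}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
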