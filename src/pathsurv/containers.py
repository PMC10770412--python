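"""Core data containers shared across the pipeline.

All containers are light dataclasses around NumPy arrays with explicit
sample/feature identifiers, so that every downstream stage can assert
alignment by id rather than by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "ClinicalTable",
    "PathwayCollection",
    "PathwayMask",
    "SplitPlan",
]


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class OmicsMatrix:
    """A named samples x features block of continuous expression values.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float array; must be finite.
    sample_ids, feature_ids
        Unique string identifiers for rows and columns.
    omics_kind
        ``"gene"`` or ``"miRNA"``.
    """

    values: np.ndarray
    sample_ids: list
    feature_ids: list
    omics_kind: str = "gene"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, omics_kind: str = "gene") -> "OmicsMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            omics_kind=omics_kind,
        )

    def subset_samples(self, ids) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return OmicsMatrix(self.values[idx], list(ids), list(self.feature_ids), self.omics_kind)

    def subset_features(self, ids) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in ids]
        return OmicsMatrix(self.values[:, idx], list(self.sample_ids), list(ids), self.omics_kind)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes: follow-up time and event indicator."""

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event must be one value per sample")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("follow-up times must be finite and non-negative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, ids) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return SurvivalTable(list(ids), self.time[idx], self.event[idx])


@dataclass
class ClinicalTable:
    """Numeric clinical covariates (age plus dummy-encoded categories)."""

    sample_ids: list
    values: np.ndarray
    columns: list

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.columns = _check_unique(self.columns, "covariate")
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("clinical values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("clinical covariates must be finite after encoding")

    def subset(self, ids) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return ClinicalTable(list(ids), self.values[idx], list(self.columns))


@dataclass
class PathwayCollection:
    """Pathway id -> gene-id set membership, with optional descriptions."""

    pathways: dict
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        for pid, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            self.pathways[pid] = set(genes)


@dataclass
class PathwayMask:
    """Binary gene x pathway membership matrix driving sparse VAE connections."""

    mask: np.ndarray
    gene_ids: list
    pathway_ids: list

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != (len(self.gene_ids), len(self.pathway_ids)):
            raise ValueError("mask shape mismatch")
        if not np.isin(self.mask, [0, 1]).all():
            raise ValueError("mask must be binary")
        if np.any(self.mask.sum(axis=1) < 1):
            raise ValueError("every retained gene must belong to >= 1 pathway")

    @property
    def n_genes(self) -> int:
        return self.mask.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.mask.shape[1]


@dataclass
class SplitPlan:
    """Reproducible test / train / validation partition of the cohort.

    ``tuning_ids = train_ids + valid_ids`` is the 80% used for model fitting;
    ``test_ids`` never participate in training or hyperparameter selection.
    """

    seed: int
    test_ids: list
    train_ids: list
    valid_ids: list

    @property
    def tuning_ids(self) -> list:
        return list(self.train_ids) + list(self.valid_ids)

    def __post_init__(self):
        all_ids = list(self.test_ids) + list(self.train_ids) + list(self.valid_ids)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split partitions overlap")
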