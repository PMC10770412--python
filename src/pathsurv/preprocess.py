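"""Normalization, filtering, pathway-mask construction and data splits.

The preprocessing contract mirrors the study protocol: expression blocks are
min-max rescaled to [0, 1] per feature, low-variance features (variance
< 0.02 computed on the normalized tuning set) are removed, the gene/pathway
membership is turned into a binary mask after dropping pathways with fewer
than 15 or more than 300 realized genes, and the cohort is split 20% test /
80% tuning with the tuning set further divided 4:1 into train/validation.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import ClinicalTable, OmicsMatrix, PathwayCollection, PathwayMask, SplitPlan

__all__ = [
    "minmax_normalize",
    "variance_filter",
    "build_pathway_mask",
    "make_splits",
    "split_tuning",
    "align_cohorts",
    "encode_clinical",
    "feature_minmax",
]


def feature_minmax(matrix: OmicsMatrix):
    """Per-feature (min, max) of a matrix, for reuse as reference statistics."""
    return matrix.values.min(axis=0), matrix.values.max(axis=0)


def minmax_normalize(matrix: OmicsMatrix, reference_stats=None) -> OmicsMatrix:
    """Rescale every feature to [0, 1] via (v - v_min) / (v_max - v_min).

    ``reference_stats`` — optional ``(min, max)`` arrays from another split
    (e.g. tuning-set statistics applied to test data); values landing outside
    [0, 1] under reference statistics are clipped. Constant features map to
    all zeros with a warning.
    """
    if reference_stats is None:
        vmin, vmax = feature_minmax(matrix)
    else:
        vmin, vmax = (np.asarray(a, dtype=float) for a in reference_stats)
        if vmin.shape != (matrix.n_features,) or vmax.shape != (matrix.n_features,):
            raise ValueError("reference_stats do not match the feature set")
    span = vmax - vmin
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) mapped to 0 "
            "(min == max under the normalization statistics)",
            UserWarning,
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    out = (matrix.values - vmin) / safe_span
    out[:, constant] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return OmicsMatrix(out, list(matrix.sample_ids), list(matrix.feature_ids), matrix.omics_kind)


def variance_filter(matrix: OmicsMatrix, threshold: float = 0.02):
    """Drop features whose sample variance (n-1 divisor) is below ``threshold``.

    Computed on the matrix it is given — by protocol, the min-max normalized
    tuning set — and the resulting feature list is then applied to every
    split. Returns ``(filtered_matrix, removed_feature_ids)``.
    """
    if matrix.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    var = matrix.values.var(axis=0, ddof=1)
    # constant features are always dropped (detected exactly via the range,
    # not the variance, which accumulates rounding), so threshold 0 removes
    # exactly the constant features
    constant = np.ptp(matrix.values, axis=0) == 0
    keep = (var >= threshold) & ~constant
    if not keep.any():
        raise ValueError(
            f"variance filter at threshold {threshold} removed every feature"
        )
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    removed = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    return matrix.subset_features(kept_ids), removed


def build_pathway_mask(
    pathways: PathwayCollection,
    dataset_genes,
    min_genes: int = 15,
    max_genes: int = 300,
) -> PathwayMask:
    """Binary gene x pathway mask restricted to pathways of usable size.

    Membership is intersected with ``dataset_genes`` first; pathways whose
    realized gene count falls outside [min_genes, max_genes] are dropped, and
    genes belonging to no surviving pathway are dropped from the mask rows.
    """
    dataset_genes = list(dataset_genes)
    if not dataset_genes:
        raise ValueError("dataset gene list is empty")
    gene_set = set(dataset_genes)
    kept = {}
    for pid, members in pathways.pathways.items():
        realized = members & gene_set
        if min_genes <= len(realized) <= max_genes:
            kept[pid] = realized
    if not kept:
        raise ValueError(
            f"no pathway has between {min_genes} and {max_genes} genes in this dataset"
        )
    covered = set().union(*kept.values())
    gene_ids = [g for g in dataset_genes if g in covered]  # keep dataset order
    pathway_ids = sorted(kept)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros((len(gene_ids), len(pathway_ids)))
    for j, pid in enumerate(pathway_ids):
        for g in kept[pid]:
            mask[gpos[g], j] = 1.0
    return PathwayMask(mask=mask, gene_ids=gene_ids, pathway_ids=pathway_ids)


def make_splits(sample_ids, seed: int, test_fraction: float = 0.2,
                valid_fraction: float = 0.2) -> SplitPlan:
    """20% test, remaining tuning set split 4:1 into train/validation.

    Sizes are floored: ``|test| = floor(0.2 n)``, ``|valid| = floor(0.2 |tuning|)``.
    Deterministic under ``seed``.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(np.floor(test_fraction * n))
    test_ids = [sample_ids[i] for i in order[:n_test]]
    tuning = [sample_ids[i] for i in order[n_test:]]
    n_valid = int(np.floor(valid_fraction * len(tuning)))
    valid_ids = tuning[:n_valid]
    train_ids = tuning[n_valid:]
    if not test_ids or not valid_ids or not train_ids:
        raise ValueError("too few samples for a non-empty test/train/valid split")
    return SplitPlan(seed=seed, test_ids=test_ids, train_ids=train_ids, valid_ids=valid_ids)


def split_tuning(tuning_ids, seed: int, valid_fraction: float = 0.2):
    """Re-split an existing tuning set 4:1 (train, valid); used for repeats."""
    tuning_ids = list(tuning_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tuning_ids))
    n_valid = int(np.floor(valid_fraction * len(tuning_ids)))
    if n_valid == 0 or n_valid == len(tuning_ids):
        raise ValueError("tuning set too small for a 4:1 split")
    valid_ids = [tuning_ids[i] for i in order[:n_valid]]
    train_ids = [tuning_ids[i] for i in order[n_valid:]]
    return train_ids, valid_ids


def align_cohorts(a: OmicsMatrix, b: OmicsMatrix):
    """Restrict two cohorts to their common features, in identical order."""
    if a.omics_kind != b.omics_kind:
        raise ValueError("cannot align matrices of different omics kinds")
    common = [f for f in a.feature_ids if f in set(b.feature_ids)]
    if not common:
        raise ValueError("feature intersection between cohorts is empty")
    return a.subset_features(common), b.subset_features(common)


def encode_clinical(table, age_column: str = "age") -> ClinicalTable:
    """Min-max scale the age column to [0, 1]; other columns must already be
    numeric dummies. Accepts a ClinicalTable and returns a new one."""
    values = table.values.copy()
    if age_column in table.columns:
        j = table.columns.index(age_column)
        col = values[:, j]
        span = col.max() - col.min()
        values[:, j] = 0.0 if span == 0 else (col - col.min()) / span
    return ClinicalTable(list(table.sample_ids), values, list(table.columns))
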