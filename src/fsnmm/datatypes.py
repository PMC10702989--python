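"""Core containers shared across the pipeline.

Everything is a thin dataclass around numpy arrays plus identifier
metadata; alignment between containers is always by ``subject_ids``,
never by row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "ModalityMatrix",
    "DiagnosisLabels",
    "SelfExpressiveNetwork",
    "LocalAffinity",
    "FusionNetwork",
    "SnpResponse",
    "AssociationWeights",
    "GenotypeTable",
]


def _as_2d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class RoiTimeSeries:
    """Per-subject ROI-averaged BOLD series: T timepoints x r ROIs."""

    subject_id: str
    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values, "time series")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 ROIs, got {r}")
        if len(self.roi_labels) != r:
            raise ValueError("roi_labels length does not match number of columns")

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson functional-connectivity matrix."""

    values: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        v = _as_2d(self.values, "connectivity matrix")
        r = v.shape[0]
        if v.shape[1] != r or len(self.roi_labels) != r:
            raise ValueError("connectivity matrix must be square with matching labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if v.min() < -1 - 1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class ModalityMatrix:
    """One phenotype modality: N subjects x d ROI features.

    ``modality_name`` is "node" (per-ROI gray-matter volume), "edge"
    (per-ROI weighted clustering coefficient of the FC graph), or any
    other label; both study modalities have d equal to the ROI count.
    """

    modality_name: str
    values: np.ndarray
    subject_ids: list[str]
    feature_labels: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values, f"modality '{self.modality_name}'")
        n, d = self.values.shape
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match number of rows")
        if len(self.feature_labels) != d:
            raise ValueError("feature_labels length does not match number of columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class DiagnosisLabels:
    """Diagnosis class per subject (e.g. HC / MD / SD) plus index sets.

    ``class_index_sets[i]`` is the array of subject indices sharing
    subject i's label (including i itself) — the set C_i that restricts
    both self-expression donors and the fusion diffusion kernel.
    """

    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if self.labels.size == 0:
            raise ValueError("labels must be non-empty")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:04d}" for i in range(self.labels.size)]
        if len(self.subject_ids) != self.labels.size:
            raise ValueError("subject_ids length does not match labels")
        self._members = {
            c: np.flatnonzero(self.labels == c) for c in np.unique(self.labels)
        }

    @property
    def n_subjects(self) -> int:
        return self.labels.size

    @property
    def classes(self) -> list:
        return sorted(self._members)

    def members(self, cls) -> np.ndarray:
        """Indices of all subjects with class ``cls``."""
        return self._members[cls]

    def class_index_set(self, i: int) -> np.ndarray:
        """C_i: indices of subjects sharing subject i's label (incl. i)."""
        return self._members[self.labels[i]]

    def same_class_mask(self) -> np.ndarray:
        """Boolean N x N matrix, True where labels agree."""
        return self.labels[:, None] == self.labels[None, :]

    def subset(self, idx: np.ndarray) -> "DiagnosisLabels":
        idx = np.asarray(idx)
        return DiagnosisLabels(
            labels=self.labels[idx],
            subject_ids=[self.subject_ids[j] for j in idx],
        )


def _check_network(values: np.ndarray, labels: DiagnosisLabels | None) -> np.ndarray:
    v = _as_2d(values, "network")
    n = v.shape[0]
    if v.shape[1] != n:
        raise ValueError("network matrix must be square")
    if labels is not None and labels.n_subjects != n:
        raise ValueError("labels do not match network size")
    return v


@dataclass
class SelfExpressiveNetwork:
    """Symmetric nonnegative zero-diagonal subject-subject weight matrix.

    Entry (i, j) is subject j's sparse-reconstruction contribution to
    subject i (symmetrized); it is zero whenever diagnoses differ.
    """

    weights: np.ndarray
    lambda_sparse: float
    modality_name: str = ""

    def __post_init__(self) -> None:
        self.weights = _check_network(self.weights, None)
        if self.lambda_sparse < 0:
            raise ValueError("lambda_sparse must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]


@dataclass
class LocalAffinity:
    """Within-class row-normalized network: the fusion diffusion kernel."""

    values: np.ndarray
    modality_name: str = ""

    def __post_init__(self) -> None:
        self.values = _check_network(self.values, None)


@dataclass
class FusionNetwork:
    """Fused self-expressive matrix with its convergence trace."""

    values: np.ndarray
    n_iterations_run: int
    relative_changes: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_network(self.values, None)
        self.relative_changes = np.asarray(self.relative_changes, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class SnpResponse:
    """Additively coded genotype response for a single SNP.

    coding "additive_012": minor-allele dosage in {0, 1, 2};
    coding "continuous": real-valued (synthetic data).
    """

    snp_id: str
    values: np.ndarray
    coding: str = "additive_012"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("response must be a vector")
        if not np.isfinite(self.values).all():
            raise ValueError("response contains non-finite values")
        if self.coding == "additive_012" and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("additive coding requires values in {0, 1, 2}")
        if self.coding not in ("additive_012", "continuous"):
            raise ValueError(f"unknown coding '{self.coding}'")

    @property
    def n_subjects(self) -> int:
        return self.values.size


@dataclass
class AssociationWeights:
    """d x M regression coefficients with row-wise group structure."""

    weights: np.ndarray
    lambda_assoc: float
    modality_names: list[str] = field(default_factory=list)
    feature_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = _as_2d(self.weights, "association weights")
        if self.lambda_assoc < 0:
            raise ValueError("lambda_assoc must be nonnegative")
        d, m = self.weights.shape
        if not self.modality_names:
            self.modality_names = [f"m{j}" for j in range(m)]
        if not self.feature_labels:
            self.feature_labels = [f"f{j}" for j in range(d)]

    @property
    def row_group_norms(self) -> np.ndarray:
        """Per-feature l2 norm across modalities (the L2,1 row norms)."""
        return np.linalg.norm(self.weights, axis=1)

    @property
    def support(self) -> np.ndarray:
        """Indices of features with nonzero row-group norm."""
        return np.flatnonzero(self.row_group_norms > 0)


@dataclass
class GenotypeTable:
    """Subjects x SNPs genotype calls.

    ``calls`` holds either raw biallelic strings ("AG") or additive
    integer codes; ``coded`` distinguishes the two. ``missing`` marks
    no-calls (empty / NA raw cells, negative codes).
    """

    subject_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    coded: bool = False
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        n, m = len(self.subject_ids), len(self.snp_ids)
        if self.calls.shape != (n, m):
            raise ValueError("calls shape does not match subject/SNP ids")
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise ValueError("missing mask shape mismatch")
        if self.coded:
            vals = np.asarray(self.calls, dtype=float)
            ok = np.isin(vals, (0, 1, 2)) | self.missing
            if not ok.all():
                raise ValueError("coded genotype values must be in {0, 1, 2}")
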