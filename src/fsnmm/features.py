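"""Multi-modality phenotype feature construction.

Node features are per-ROI mean gray-matter volumes taken from a
precomputed table. Edge features are per-ROI weighted clustering
coefficients of the subject's functional-connectivity (FC) graph, the
ROI x ROI Pearson correlation matrix of ROI-averaged BOLD series. The
clustering coefficient is threshold-free: it is computed on the fully
weighted graph, so no arbitrary binarization of the FC matrix is
needed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .datatypes import ConnectivityMatrix, ModalityMatrix, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fc",
    "clustering_coefficients",
    "edge_features",
    "assemble_modalities",
    "Standardizer",
]


def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson functional connectivity of ROI-averaged time series.

    Each ROI series is standardized to zero mean and unit variance;
    the FC entry for a pair of ROIs is their Pearson correlation.

    Raises
    ------
    ValueError
        If any ROI series has zero variance (correlation undefined);
        the offending ROI is named.
    """
    x = ts.values
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_labels[j] for j in dead)
        raise ValueError(f"zero-variance ROI series: {names}")
    z = (x - x.mean(axis=0)) / sd
    r = (z.T @ z) / z.shape[0]
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, roi_labels=list(ts.roi_labels))


def clustering_coefficients(
    fc: ConnectivityMatrix, negative_weights: str = "abs"
) -> np.ndarray:
    """Per-ROI weighted clustering coefficient of the FC graph.

    Uses the Onnela geometric-mean-of-triangles statistic on the fully
    weighted graph: with off-diagonal weights rescaled to [0, 1] by
    their maximum, w_hat = |w| / max|w|,

        c_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3)

    where k_i counts nonzero weights incident to ROI i. Nodes of degree
    < 2 get coefficient 0. Results lie in [0, 1] and are invariant to a
    global positive rescaling of the weights.

    Parameters
    ----------
    negative_weights : {"abs", "zero"}
        "abs" (default) uses absolute correlation weights; "zero"
        discards negative correlations instead.
    """
    r = fc.n_rois
    if r < 3:
        raise ValueError(f"need at least 3 ROIs to form triangles, got {r}")
    w = fc.values.copy()
    np.fill_diagonal(w, 0.0)
    if negative_weights == "abs":
        w = np.abs(w)
    elif negative_weights == "zero":
        w = np.where(w > 0, w, 0.0)
    else:
        raise ValueError(f"unknown negative_weights mode '{negative_weights}'")
    wmax = w.max()
    if wmax == 0:
        return np.zeros(r)
    w_hat = np.cbrt(w / wmax)
    # (w_hat^{1/3})^3 diagonal counts weighted triangles through each node
    tri = np.diag(w_hat @ w_hat @ w_hat)
    k = np.count_nonzero(w > 0, axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return np.clip(c, 0.0, 1.0)


def edge_features(
    series: Iterable[RoiTimeSeries], negative_weights: str = "abs"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Clustering-coefficient edge features for a cohort of subjects.

    Returns the N x r feature matrix, subject ids and ROI labels. All
    subjects must share one ROI label set.
    """
    rows, ids, labels = [], [], None
    for ts in series:
        if labels is None:
            labels = list(ts.roi_labels)
        elif list(ts.roi_labels) != labels:
            raise ValueError(
                f"ROI labels of subject {ts.subject_id} do not match the cohort"
            )
        fc = compute_fc(ts)
        rows.append(clustering_coefficients(fc, negative_weights=negative_weights))
        ids.append(ts.subject_id)
    if labels is None:
        raise ValueError("no subjects provided")
    return np.vstack(rows), ids, labels


class Standardizer:
    """Per-feature z-scoring fit on training subjects, applied to any.

    Scaling parameters must come from training subjects only so that
    held-out subjects never influence the fit (no leakage).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, x: np.ndarray, feature_labels: Sequence[str] | None = None):
        x = np.asarray(x, dtype=float)
        self.mean_ = x.mean(axis=0)
        self.sd_ = x.std(axis=0, ddof=0)
        dead = np.flatnonzero(self.sd_ == 0)
        if dead.size:
            if feature_labels is not None:
                names = ", ".join(str(feature_labels[j]) for j in dead)
            else:
                names = ", ".join(map(str, dead))
            raise ValueError(f"constant feature column(s): {names}")
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(x, dtype=float) - self.mean_) / self.sd_

    def fit_transform(self, x, feature_labels=None) -> np.ndarray:
        return self.fit(x, feature_labels).transform(x)


def _align_by_subject(values, ids: list[str], order: list[str], what: str):
    pos = {s: i for i, s in enumerate(ids)}
    missing = [s for s in order if s not in pos]
    if missing:
        raise ValueError(f"{what}: missing subjects {missing}")
    return values[[pos[s] for s in order]]


def assemble_modalities(
    node_table: tuple[np.ndarray, list[str], list[str]],
    edge_source,
    standardize: bool = True,
    negative_weights: str = "abs",
) -> list[ModalityMatrix]:
    """Assemble aligned node and edge ``ModalityMatrix`` objects.

    Parameters
    ----------
    node_table : (values, subject_ids, roi_labels)
        Per-subject mean GMV per ROI.
    edge_source
        Either a like-shaped tuple of precomputed edge features, or an
        iterable of ``RoiTimeSeries`` (edge features are then computed
        via ``compute_fc`` -> ``clustering_coefficients`` per subject).
    standardize : bool
        Column z-score each modality over these subjects. When the
        matrices feed a train/test split, standardize inside the split
        instead (see ``Standardizer``).

    Subjects are aligned by id to the node-table order; ROI label sets
    must agree between the modalities.
    """
    node_vals, node_ids, node_rois = node_table
    node_vals = np.asarray(node_vals, dtype=float)

    if isinstance(edge_source, tuple):
        edge_vals, edge_ids, edge_rois = edge_source
        edge_vals = np.asarray(edge_vals, dtype=float)
    else:
        edge_vals, edge_ids, edge_rois = edge_features(
            edge_source, negative_weights=negative_weights
        )

    if list(edge_rois) != list(node_rois):
        raise ValueError("ROI labels differ between node and edge modalities")
    edge_vals = _align_by_subject(edge_vals, list(edge_ids), list(node_ids), "edge modality")

    out = []
    for name, vals in (("node", node_vals), ("edge", edge_vals)):
        if standardize:
            vals = Standardizer().fit_transform(vals, node_rois)
        out.append(
            ModalityMatrix(
                modality_name=name,
                values=vals,
                subject_ids=list(node_ids),
                feature_labels=list(node_rois),
            )
        )
    return out
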