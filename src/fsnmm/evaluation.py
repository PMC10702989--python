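"""Repeated nested cross-validation of the association variants.

The comparison ladder crosses three model kinds with three feature
representations:

* model — SM (one lasso per modality), CM (lasso on concatenated
  modalities), MM (joint L2,1 multi-modality model);
* representation — none (raw features), SN (per-modality
  self-expressive reconstruction), FSN (fusion-network reconstruction).

Variants are named ``"MM"``, ``"SN-MM"``, ``"FSN-MM"``, ``"SM"``, ... .
Scoring is the Pearson correlation (CC) between predicted and actual
genotype codes on held-out subjects. The penalty weight lambda is
selected by an inner cross-validation on each outer training fold;
networks are always estimated from the outer training fold only, so no
held-out subject influences model fitting (except in the clearly
labelled transductive mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .association import GramStats, fit_l21, predict
from .datatypes import (
    AssociationWeights,
    ConnectivityMatrix,
    DiagnosisLabels,
    ModalityMatrix,
    SnpResponse,
)
from .features import Standardizer
from .fusion import fuse
from .self_expressive import build_sen, sparse_code_against

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "CvConfig",
    "CvReport",
    "cc_metric",
    "run_variant",
    "screen_snps",
    "rank_rois",
    "top_edges",
]

#: The lambda tuning grid {1e-5, 3e-5, 1e-4, ..., 1, 3}.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(
    float(f"{c}e{e}") for e in range(-5, 1) for c in (1, 3)
)

MODELS = ("SM", "CM", "MM")
NETWORKS = ("none", "SN", "FSN")


def cc_metric(y_true, y_pred) -> float:
    """Pearson correlation between predicted and actual responses.

    Defined as 0 when either vector is constant: a degenerate
    (e.g. all-zero) prediction scores 0 rather than NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    if y_true.std() == 0 or y_pred.std() == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def parse_variant(variant: str) -> tuple[str, str]:
    """Split a variant name into (network, model), e.g. "FSN-MM" -> ("FSN", "MM")."""
    parts = variant.upper().split("-")
    if len(parts) == 1:
        net, model = "none", parts[0]
    elif len(parts) == 2:
        net, model = parts
    else:
        raise ValueError(f"unrecognized variant '{variant}'")
    if net not in ("NONE", "SN", "FSN") and net != "none":
        raise ValueError(f"unrecognized network prefix in '{variant}'")
    net = "none" if net.upper() == "NONE" else net
    if model not in MODELS:
        raise ValueError(f"unrecognized model kind in '{variant}'")
    return net, model


@dataclass(frozen=True)
class CvConfig:
    """Evaluation protocol parameters.

    ``repeats`` independent non-repetitive stratified five-fold CVs
    (fold seeds ``seed + repeat``); lambda tuned on the default grid by
    an inner five-fold CV. ``test_reconstruction`` controls how
    held-out subjects enter the SN/FSN representations:

    * ``"sparse_code_on_train"`` (default) — each test subject is
      nonneg-sparse-coded against all training subjects, without label
      restriction (test diagnoses are treated as unknown);
    * ``"raw"`` — test features are used as-is;
    * ``"transductive"`` — networks are built over all subjects with
      all labels before splitting. This leaks test labels and exists
      only to reproduce a literal all-subjects reading of the fused
      reconstruction; never use it for honest evaluation.
    """

    variant: str = "FSN-MM"
    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 5
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    seed: int = 0
    test_reconstruction: str = "sparse_code_on_train"
    lambda_frac_sen: float = 0.1
    fusion_max_iter: int = 10
    fusion_tol: float = 1e-6
    solver_max_iter: int = 5000
    inner_solver_max_iter: int = 1000
    cross_class: str = "zero"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        grid = tuple(float(g) for g in self.lambda_grid)
        if any(g <= 0 for g in grid) or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("lambda_grid must be strictly increasing and positive")
        if self.test_reconstruction not in ("raw", "sparse_code_on_train", "transductive"):
            raise ValueError(
                f"unknown test_reconstruction '{self.test_reconstruction}'"
            )
        parse_variant(self.variant)


@dataclass
class CvReport:
    """Aggregated scores of one variant on one SNP.

    ``train_cc`` / ``test_cc`` map each reported modality (or task,
    e.g. "concat" for CM) to (mean, SD) across repeats of the
    fold-averaged CC. ``chosen_lambda`` maps task -> per (repeat, fold)
    selections; ``weights`` maps task -> fitted ``AssociationWeights``
    per (repeat, fold).
    """

    variant: str
    snp_id: str
    config: CvConfig
    modalities: list[str]
    train_cc: dict[str, tuple[float, float]]
    test_cc: dict[str, tuple[float, float]]
    per_repeat: pd.DataFrame
    chosen_lambda: dict[str, list[float]]
    weights: dict[str, list[AssociationWeights]] = field(default_factory=dict)

    @property
    def mean_test_cc(self) -> float:
        """Test CC averaged over the reported modalities."""
        return float(np.mean([v[0] for v in self.test_cc.values()]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mod in self.modalities:
            rows.append(
                {
                    "variant": self.variant,
                    "snp_id": self.snp_id,
                    "modality": mod,
                    "train_cc_mean": self.train_cc[mod][0],
                    "train_cc_sd": self.train_cc[mod][1],
                    "test_cc_mean": self.test_cc[mod][0],
                    "test_cc_sd": self.test_cc[mod][1],
                }
            )
        return pd.DataFrame(rows)


def _stratified_folds(labels: np.ndarray, n_splits: int, seed: int):
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_splits:
        raise ValueError(
            f"stratification error: smallest class has {counts.min()} subjects, "
            f"need at least {n_splits} for {n_splits}-fold CV"
        )
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(labels.size), labels))


def _modality_values(Xs) -> tuple[list[np.ndarray], list[str], list[str]]:
    mats, names = [], []
    feature_labels = None
    for j, x in enumerate(Xs):
        if isinstance(x, ModalityMatrix):
            mats.append(x.values)
            names.append(x.modality_name)
            if feature_labels is None:
                feature_labels = list(x.feature_labels)
        else:
            mats.append(np.asarray(x, dtype=float))
            names.append(f"m{j}")
    if feature_labels is None:
        feature_labels = [f"f{j}" for j in range(mats[0].shape[1])]
    return mats, names, feature_labels


def _build_representation(net, train_mats, test_mats, labels_train, cfg: CvConfig):
    """Reconstructed train/test feature matrices for one outer fold.

    ``train_mats``/``test_mats`` are already standardized (train-fit).
    Returns (train_rep, test_rep).
    """
    if net == "none":
        return train_mats, test_mats

    sens = [
        build_sen(x, labels_train, lambda_frac=cfg.lambda_frac_sen)
        for x in train_mats
    ]
    if net == "SN":
        rep_networks = [s.weights for s in sens]
    else:  # FSN
        fused = fuse(
            sens,
            labels_train,
            max_iter=cfg.fusion_max_iter,
            tol=cfg.fusion_tol,
            cross_class=cfg.cross_class,
        )
        rep_networks = [fused.values] * len(train_mats)

    train_rep = [w @ x for w, x in zip(rep_networks, train_mats)]

    if cfg.test_reconstruction == "raw":
        test_rep = list(test_mats)
    else:  # sparse_code_on_train
        # A test subject is sparse-coded against the raw training
        # features (its diagnosis is unknown, so no label restriction)
        # and the code is applied to the RECONSTRUCTED training rows,
        # expressing the subject in the same representation the model
        # was fit in.
        test_rep = []
        for x_tr, x_tr_rep, x_te, sen in zip(train_mats, train_rep, test_mats, sens):
            rows = np.empty_like(x_te)
            for i in range(x_te.shape[0]):
                w = sparse_code_against(x_te[i], x_tr, sen.lambda_sparse)
                rows[i] = w @ x_tr_rep
            test_rep.append(rows)
    return train_rep, test_rep


def _transductive_representation(net, mats_std, labels, cfg: CvConfig):
    """All-subject networks and reconstruction (label-leaking mode)."""
    sens = [
        build_sen(x, labels, lambda_frac=cfg.lambda_frac_sen) for x in mats_std
    ]
    if net == "SN":
        nets = [s.weights for s in sens]
    else:
        fused = fuse(
            sens,
            labels,
            max_iter=cfg.fusion_max_iter,
            tol=cfg.fusion_tol,
            cross_class=cfg.cross_class,
        )
        nets = [fused.values] * len(mats_std)
    return [w @ x for w, x in zip(nets, mats_std)]


def _tasks(model: str, names: list[str]):
    """Task list: (task_name, modality indices, reported score names)."""
    if model == "MM":
        return [("MM", list(range(len(names))), list(names))]
    if model == "CM":
        return [("concat", list(range(len(names))), ["concat"])]
    return [(nm, [j], [nm]) for j, nm in enumerate(names)]  # SM


def _task_matrices(model: str, mats: list[np.ndarray], idx: list[int]):
    if model == "CM":
        return [np.hstack([mats[j] for j in idx])]
    if model == "MM":
        return [mats[j] for j in idx]
    return [mats[idx[0]]]


def _fit_task(
    model, y, mats, lam, cfg: CvConfig, W0=None, stats=None, inner=False
) -> AssociationWeights:
    # inner-CV fits run at a reduced iteration cap: they only steer the
    # lambda choice, the final refit runs at full precision
    cap = cfg.inner_solver_max_iter if inner else cfg.solver_max_iter
    return fit_l21(y, mats, lam, max_iter=cap, W0=W0, stats=stats)


def _score_task(aw: AssociationWeights, mats, y, score_names) -> dict[str, float]:
    preds = predict(mats, aw)
    if len(preds) == 1:
        return {score_names[0]: cc_metric(y, preds[0])}
    return {nm: cc_metric(y, p) for nm, p in zip(score_names, preds)}


def _select_lambda(model, y_tr, train_rep_mats, labels_tr, cfg: CvConfig, rs: int):
    """Inner-CV lambda choice: max mean CC summed over modalities; ties -> smaller."""
    inner = _stratified_folds(labels_tr, cfg.inner_folds, rs)
    grid = cfg.lambda_grid
    scores = np.zeros(len(grid))
    for tr_i, te_i in inner:
        y_a, y_b = y_tr[tr_i], y_tr[te_i]
        m_a = [x[tr_i] for x in train_rep_mats]
        m_b = [x[te_i] for x in train_rep_mats]
        stats = GramStats(y_a - y_a.mean(), m_a)
        W_warm = None
        for g in range(len(grid) - 1, -1, -1):  # descending, warm-started
            aw = _fit_task(
                model, y_a, m_a, grid[g], cfg, W0=W_warm, stats=stats, inner=True
            )
            W_warm = aw.weights
            cc_sum = sum(
                _score_task(aw, m_b, y_b, [str(j) for j in range(len(m_b))]).values()
            )
            scores[g] += cc_sum
    best = 0
    for g in range(1, len(grid)):
        if scores[g] > scores[best]:  # strict: ties keep the smaller lambda
            best = g
    return float(grid[best])


def run_variant(
    Xs,
    labels: DiagnosisLabels,
    y,
    config: CvConfig,
    keep_weights: bool = True,
) -> CvReport:
    """Repeated nested cross-validation of one variant on one SNP.

    Parameters
    ----------
    Xs : list of ModalityMatrix or arrays
        Raw (unstandardized) modality features; standardization is fit
        inside each training fold.
    labels : DiagnosisLabels
    y : SnpResponse or vector
        Genotype response.
    config : CvConfig

    Returns a :class:`CvReport` with per-modality train/test CC
    aggregated as mean +/- SD across repeats of fold-averaged scores.
    """
    net, model = parse_variant(config.variant)
    mats, names, feature_labels = _modality_values(Xs)
    yv = y.values if isinstance(y, SnpResponse) else np.asarray(y, dtype=float)
    snp_id = y.snp_id if isinstance(y, SnpResponse) else ""
    n = yv.size
    if any(x.shape[0] != n for x in mats) or labels.n_subjects != n:
        raise ValueError("subjects misaligned across features, labels and response")

    tasks = _tasks(model, names)
    score_names = [nm for _, _, out in tasks for nm in out]
    per_repeat_rows = []
    chosen_lambda: dict[str, list[float]] = {t[0]: [] for t in tasks}
    weights: dict[str, list[AssociationWeights]] = {t[0]: [] for t in tasks}

    for rep in range(config.repeats):
        rep_seed = config.seed + rep
        folds = _stratified_folds(labels.labels, config.outer_folds, rep_seed)
        fold_scores = {nm: {"train": [], "test": []} for nm in score_names}
        for f, (tr, te) in enumerate(folds):
            labels_tr = labels.subset(tr)
            std_tr, std_te = [], []
            for x in mats:
                sc = Standardizer().fit(x[tr], feature_labels)
                std_tr.append(sc.transform(x[tr]))
                std_te.append(sc.transform(x[te]))
            if config.test_reconstruction == "transductive" and net != "none":
                full = [
                    np.vstack([a, b]) for a, b in zip(std_tr, std_te)
                ]
                order = np.concatenate([tr, te])
                rec = _transductive_representation(
                    net, full, labels.subset(order), config
                )
                k = tr.size
                train_rep = [r[:k] for r in rec]
                test_rep = [r[k:] for r in rec]
            else:
                train_rep, test_rep = _build_representation(
                    net, std_tr, std_te, labels_tr, config
                )
            y_tr, y_te = yv[tr], yv[te]
            for task_name, idx, out_names in tasks:
                t_tr = _task_matrices(model, train_rep, idx)
                t_te = _task_matrices(model, test_rep, idx)
                rs = (rep_seed * 1009 + f * 131 + 7) % (2**31 - 1)
                lam = _select_lambda(model, y_tr, t_tr, labels_tr.labels, config, rs)
                aw = _fit_task(model, y_tr, t_tr, lam, config)
                aw.modality_names = (
                    list(out_names) if model != "CM" else ["concat"]
                )
                aw.feature_labels = (
                    feature_labels
                    if model != "CM"
                    else [
                        f"{names[j]}:{fl}" for j in idx for fl in feature_labels
                    ]
                )
                chosen_lambda[task_name].append(lam)
                if keep_weights:
                    weights[task_name].append(aw)
                tr_cc = _score_task(aw, t_tr, y_tr, out_names)
                te_cc = _score_task(aw, t_te, y_te, out_names)
                for nm in out_names:
                    fold_scores[nm]["train"].append(tr_cc[nm])
                    fold_scores[nm]["test"].append(te_cc[nm])
        for nm in score_names:
            per_repeat_rows.append(
                {
                    "repeat": rep,
                    "modality": nm,
                    "train_cc": float(np.mean(fold_scores[nm]["train"])),
                    "test_cc": float(np.mean(fold_scores[nm]["test"])),
                }
            )

    per_repeat = pd.DataFrame(per_repeat_rows)
    train_cc, test_cc = {}, {}
    for nm in score_names:
        sub = per_repeat[per_repeat["modality"] == nm]
        train_cc[nm] = (float(sub["train_cc"].mean()), float(sub["train_cc"].std(ddof=0)))
        test_cc[nm] = (float(sub["test_cc"].mean()), float(sub["test_cc"].std(ddof=0)))

    return CvReport(
        variant=config.variant,
        snp_id=snp_id,
        config=config,
        modalities=score_names,
        train_cc=train_cc,
        test_cc=test_cc,
        per_repeat=per_repeat,
        chosen_lambda=chosen_lambda,
        weights=weights,
    )


def screen_snps(
    Xs,
    labels: DiagnosisLabels,
    genotype_table: pd.DataFrame,
    config: CvConfig,
    keep_weights: bool = False,
) -> tuple[pd.DataFrame, dict[str, CvReport]]:
    """Run the configured variant on every SNP column of a table.

    Monomorphic SNPs are skipped (logged). Returns the summary table
    sorted by mean test CC (descending) and the per-SNP reports; node
    and edge test CCs are reported in separate columns.
    """
    reports: dict[str, CvReport] = {}
    skipped = 0
    for snp in genotype_table.columns:
        vals = np.asarray(genotype_table[snp], dtype=float)
        if np.unique(vals).size < 2:
            skipped += 1
            logger.warning("SNP %s is monomorphic; skipped", snp)
            continue
        coding = "additive_012" if np.isin(vals, (0, 1, 2)).all() else "continuous"
        y = SnpResponse(snp_id=str(snp), values=vals, coding=coding)
        reports[str(snp)] = run_variant(Xs, labels, y, config, keep_weights=keep_weights)
    if skipped:
        logger.info("skipped %d monomorphic SNP(s)", skipped)
    rows = []
    for snp, rep in reports.items():
        row = {"snp_id": snp, "mean_test_cc": rep.mean_test_cc}
        for nm in rep.modalities:
            row[f"test_cc_{nm}"] = rep.test_cc[nm][0]
            row[f"test_cc_{nm}_sd"] = rep.test_cc[nm][1]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "mean_test_cc", ascending=False, ignore_index=True
    )
    return table, reports


def rank_rois(weights, k: int, feature_labels: list[str] | None = None) -> dict:
    """Rank ROIs by averaged association weight magnitude.

    Parameters
    ----------
    weights : CvReport or list of AssociationWeights
        Fitted weight matrices across repeats x folds.
    k : int
        Number of top ROIs per ranking.

    Per modality, absolute weights are averaged over the fits and
    max-normalized; the joint ranking uses the averaged row-group
    norms. Returns a dict with per-modality tables, the joint table,
    and the "consistent" ROI set (intersection of per-modality top-k).
    """
    if isinstance(weights, CvReport):
        aws = [aw for lst in weights.weights.values() for aw in lst]
    else:
        aws = list(weights)
    if not aws:
        raise ValueError("no weight matrices supplied")
    d, m = aws[0].weights.shape
    if k > d:
        raise ValueError(f"k={k} exceeds the number of features d={d}")
    labels_ = feature_labels or aws[0].feature_labels
    mod_names = aws[0].modality_names

    abs_mean = np.mean([np.abs(aw.weights) for aw in aws], axis=0)
    group_mean = np.mean([aw.row_group_norms for aw in aws], axis=0)
    if group_mean.max() == 0:
        logger.warning("all association weights are zero; empty ranking")
        return {
            "per_modality": {},
            "joint": pd.DataFrame(columns=["roi", "weight"]),
            "consistent": [],
        }

    def _table(v: np.ndarray) -> pd.DataFrame:
        vn = v / v.max() if v.max() > 0 else v
        order = np.argsort(-vn, kind="stable")[:k]
        return pd.DataFrame(
            {"roi": [labels_[j] for j in order], "weight": vn[order]}
        )

    per_mod = {nm: _table(abs_mean[:, j]) for j, nm in enumerate(mod_names)}
    joint = _table(group_mean)
    if per_mod:
        consistent = set.intersection(*(set(t["roi"]) for t in per_mod.values()))
    else:
        consistent = set()
    consistent = [r for r in joint["roi"] if r in consistent]
    return {"per_modality": per_mod, "joint": joint, "consistent": consistent}


def top_edges(fc_by_group, roi: str, k: int) -> dict[str, pd.DataFrame]:
    """Strongest group-mean FC edges incident to one ROI.

    ``fc_by_group`` maps a diagnosis-group name to that group's
    ``ConnectivityMatrix`` list; per group the matrices are averaged
    and the k edges at ``roi`` with the largest mean connection values
    are returned.
    """
    out = {}
    for group, fcs in fc_by_group.items():
        fcs = list(fcs)
        if not fcs:
            raise ValueError(f"group '{group}' has no connectivity matrices")
        labels_ = fcs[0].roi_labels
        if roi not in labels_:
            raise ValueError(f"unknown ROI '{roi}'")
        if k > len(labels_) - 1:
            raise ValueError(f"k={k} exceeds the number of possible edges")
        mean_fc = np.mean([fc.values for fc in fcs], axis=0)
        i = labels_.index(roi)
        row = mean_fc[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")[:k]
        out[group] = pd.DataFrame(
            {
                "roi_a": roi,
                "roi_b": [labels_[j] for j in order],
                "mean_connectivity": row[order],
            }
        )
    return out
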