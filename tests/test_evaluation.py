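"""Nested cross-validation engine tests: scoring, leakage, determinism."""

import numpy as np
import pandas as pd
import pytest

from fsnmm import (
    ConnectivityMatrix,
    CvConfig,
    SimulationConfig,
    cc_metric,
    make_screen_table,
    rank_rois,
    run_variant,
    screen_snps,
    simulate,
    top_edges,
)
from fsnmm.evaluation import DEFAULT_LAMBDA_GRID, parse_variant


class TestCcMetric:
    def test_perfect_prediction(self):
        y = np.array([0.0, 1.0, 2.0, 1.0])
        assert cc_metric(y, y) == pytest.approx(1.0)

    def test_affine_invariance(self):
        y = np.array([0.0, 1.0, 2.0, 1.0])
        assert cc_metric(y, 2 * y + 3) == pytest.approx(1.0)

    def test_constant_prediction_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0])
        assert cc_metric(y, np.full(3, 7.0)) == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cc_metric(np.array([1.0]), np.array([1.0]))


def test_lambda_grid_matches_protocol():
    # {1e-5, 3e-5, ..., 1, 3}: six decades, two points per decade
    assert len(DEFAULT_LAMBDA_GRID) == 12
    assert DEFAULT_LAMBDA_GRID[0] == pytest.approx(1e-5)
    assert DEFAULT_LAMBDA_GRID[-1] == pytest.approx(3.0)
    assert all(a < b for a, b in zip(DEFAULT_LAMBDA_GRID, DEFAULT_LAMBDA_GRID[1:]))


def test_parse_variant():
    assert parse_variant("FSN-MM") == ("FSN", "MM")
    assert parse_variant("SM") == ("none", "SM")
    assert parse_variant("SN-CM") == ("SN", "CM")
    with pytest.raises(ValueError):
        parse_variant("XX-MM")


@pytest.fixture(scope="module")
def cv_dataset():
    return simulate(
        SimulationConfig(n_per_class=(12, 12, 12), d=16, subspace_dim=3, seed=21)
    )


FAST = dict(repeats=1, outer_folds=3, inner_folds=3)


class TestRunVariant:
    def test_noiseless_planted_model_recovered(self):
        """With y exactly linear in 4 ROIs shared by both modalities, the
        joint model attains near-perfect held-out correlation."""
        from fsnmm import DiagnosisLabels, ModalityMatrix, SnpResponse

        rng = np.random.default_rng(33)
        n, d = 45, 12
        x = rng.normal(size=(n, d))
        y = x[:, :4] @ np.array([1.0, -0.8, 0.6, 1.2])
        labels = DiagnosisLabels(labels=np.repeat(["HC", "MD", "SD"], n // 3))
        mods = [
            ModalityMatrix(nm, x, labels.subject_ids, [f"R{j}" for j in range(d)])
            for nm in ("node", "edge")
        ]
        rep = run_variant(
            mods,
            labels,
            SnpResponse("lin", y, coding="continuous"),
            CvConfig(variant="MM", **FAST, seed=1),
        )
        assert all(v[0] > 0.99 for v in rep.test_cc.values())

    def test_deterministic_under_seed(self, cv_dataset):
        ds = cv_dataset
        cfg = CvConfig(variant="FSN-MM", **FAST, seed=5)
        a = run_variant(ds.modalities, ds.labels, ds.response, cfg)
        b = run_variant(ds.modalities, ds.labels, ds.response, cfg)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)
        assert a.chosen_lambda == b.chosen_lambda
        for ta, tb in zip(a.weights["MM"], b.weights["MM"]):
            assert (ta.weights == tb.weights).all()

    def test_no_test_fold_leakage(self, cv_dataset):
        """Replacing held-out subjects' features with noise leaves every
        training-side fit bitwise identical."""
        ds = cv_dataset
        cfg = CvConfig(variant="SN-MM", **FAST, seed=5)
        base = run_variant(ds.modalities, ds.labels, ds.response, cfg)

        # corrupt the subjects of the first outer test fold of repeat 0
        from fsnmm.evaluation import _stratified_folds

        folds = _stratified_folds(ds.labels.labels, cfg.outer_folds, cfg.seed)
        te = folds[0][1]
        rng = np.random.default_rng(999)
        mods = []
        for mm in ds.modalities:
            vals = mm.values.copy()
            vals[te] = rng.normal(size=(te.size, vals.shape[1]))
            mods.append(
                type(mm)(
                    modality_name=mm.modality_name,
                    values=vals,
                    subject_ids=mm.subject_ids,
                    feature_labels=mm.feature_labels,
                )
            )
        noisy = run_variant(mods, ds.labels, ds.response, cfg)
        # training fits of that fold: identical chosen lambda and weights
        assert noisy.chosen_lambda["MM"][0] == base.chosen_lambda["MM"][0]
        assert (
            noisy.weights["MM"][0].weights == base.weights["MM"][0].weights
        ).all()

    def test_sm_reports_per_modality(self, cv_dataset):
        ds = cv_dataset
        rep = run_variant(
            ds.modalities, ds.labels, ds.response, CvConfig(variant="SM", **FAST, seed=2)
        )
        assert set(rep.modalities) == {"node", "edge"}

    def test_cm_reports_concat(self, cv_dataset):
        ds = cv_dataset
        rep = run_variant(
            ds.modalities, ds.labels, ds.response, CvConfig(variant="CM", **FAST, seed=2)
        )
        assert rep.modalities == ["concat"]
        d = ds.modalities[0].n_features
        assert rep.weights["concat"][0].weights.shape == (2 * d, 1)

    def test_stratification_error_when_class_too_small(self):
        ds = simulate(SimulationConfig(n_per_class=(3, 12), d=8, seed=1))
        with pytest.raises(ValueError, match="stratification"):
            run_variant(
                ds.modalities,
                ds.labels,
                ds.response,
                CvConfig(variant="MM", repeats=1, outer_folds=5, seed=0),
            )

    def test_report_frame_schema(self, cv_dataset):
        ds = cv_dataset
        rep = run_variant(
            ds.modalities, ds.labels, ds.response, CvConfig(variant="MM", **FAST, seed=0)
        )
        df = rep.to_frame()
        assert set(df.columns) >= {
            "variant",
            "modality",
            "train_cc_mean",
            "test_cc_mean",
            "test_cc_sd",
        }
        assert ((df["test_cc_mean"] <= 1) & (df["test_cc_mean"] >= -1)).all()


class TestScreenSnps:
    def test_planted_snp_ranks_first(self, cv_dataset):
        ds = cv_dataset
        table = make_screen_table(ds, n_null=4, seed=3)
        cfg = CvConfig(variant="MM", **FAST, seed=4)
        summary, reports = screen_snps(ds.modalities, ds.labels, table, cfg)
        assert summary.iloc[0]["snp_id"] == ds.response.snp_id
        assert len(reports) == 5

    def test_monomorphic_snp_skipped(self, cv_dataset):
        ds = cv_dataset
        table = make_screen_table(ds, n_null=1, seed=3)
        table["mono"] = 1.0
        cfg = CvConfig(variant="MM", **FAST, seed=4)
        summary, reports = screen_snps(ds.modalities, ds.labels, table, cfg)
        assert "mono" not in set(summary["snp_id"])


class TestRankRois:
    def test_single_nonzero_row_ranks_first(self):
        from fsnmm import AssociationWeights

        w = np.zeros((6, 2))
        w[3] = (0.5, -0.5)
        aw = AssociationWeights(
            weights=w, lambda_assoc=0.1, feature_labels=[f"R{i}" for i in range(6)]
        )
        out = rank_rois([aw], k=2)
        assert out["joint"].iloc[0]["roi"] == "R3"
        assert out["joint"].iloc[0]["weight"] == pytest.approx(1.0)
        assert out["consistent"][0] == "R3"

    def test_all_zero_weights_empty_ranking(self):
        from fsnmm import AssociationWeights

        aw = AssociationWeights(weights=np.zeros((4, 2)), lambda_assoc=9.0)
        out = rank_rois([aw], k=2)
        assert out["joint"].empty
        assert out["consistent"] == []

    def test_k_larger_than_d_rejected(self):
        from fsnmm import AssociationWeights

        aw = AssociationWeights(weights=np.zeros((4, 2)), lambda_assoc=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            rank_rois([aw], k=5)


class TestTopEdges:
    def _fc(self, vals):
        return ConnectivityMatrix(
            values=vals, roi_labels=[f"R{i}" for i in range(len(vals))]
        )

    def test_identical_matrices_mean_is_common(self, rng):
        w = rng.uniform(-0.5, 0.5, size=(5, 5))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        fcs = [self._fc(w)] * 3
        out = top_edges({"HC": fcs}, "R2", k=2)
        row = w[2].copy()
        row[2] = -np.inf
        want = np.sort(row)[::-1][:2]
        assert out["HC"]["mean_connectivity"].to_numpy() == pytest.approx(want)

    def test_dominant_edge_returned(self):
        w = np.eye(4)
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.1
        out = top_edges({"g": [self._fc(w)]}, "R0", k=1)
        assert out["g"].iloc[0]["roi_b"] == "R1"

    def test_matches_exhaustive_sort(self, rng):
        mats = []
        for _ in range(10):
            w = rng.uniform(-1, 1, size=(8, 8)) * 0.9
            w = (w + w.T) / 2
            np.fill_diagonal(w, 1.0)
            mats.append(self._fc(w))
        out = top_edges({"g": mats}, "R3", k=7)
        mean = np.mean([m.values for m in mats], axis=0)
        pairs = sorted(
            ((mean[3, j], j) for j in range(8) if j != 3), reverse=True
        )[:7]
        assert list(out["g"]["roi_b"]) == [f"R{j}" for _, j in pairs]

    def test_unknown_roi_rejected(self, rng):
        w = np.eye(3)
        with pytest.raises(ValueError, match="unknown ROI"):
            top_edges({"g": [self._fc(w)]}, "R9", k=1)
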