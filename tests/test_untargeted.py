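"""Feature filtering, carrier normalization, greedy RLS and annotation."""

import numpy as np
import pandas as pd
import pytest

from scamine import (
    ImpurityMatrix,
    SimConfig,
    annotate_by_mass,
    carrier_normalize,
    compound_table,
    default_plex,
    generate_feature_table,
    greedy_forward_select,
    loocv_mse,
    nested_leave_cell_out,
    pca_project,
    presence_filter,
    rls_fit,
    simulate_run_amounts,
)
from scamine.channels import PROTON_MASS, TMT10_TAG_MASS
from scamine.reporter_extraction import ReporterReading, extract_reporters
from scamine.untargeted import FeatureTable, prepare_matrix
from conftest import FAST_ANALYTES


def _table(values, n_cells, n_reps=1, mz=None):
    """FeatureTable from a (features × samples) array."""
    n_feat = values.shape[0]
    fids = [f"F{i}" for i in range(n_feat)]
    features = pd.DataFrame(
        {"mz": mz if mz is not None else np.linspace(300, 400, n_feat),
         "rt": np.linspace(5, 25, n_feat)},
        index=pd.Index(fids, name="feature_id"))
    sample_rows, cols = [], []
    types = ["A", "B", "C"]
    for c in range(n_cells):
        for r in range(1, n_reps + 1):
            sid = f"c{c}_r{r}"
            cols.append(sid)
            sample_rows.append({"sample_id": sid, "cell_id": f"c{c}",
                                "cell_type": types[c % 3], "replicate_id": r})
    vals = pd.DataFrame(values, index=features.index, columns=cols)
    return FeatureTable(features, vals, pd.DataFrame(sample_rows).set_index("sample_id"))


class TestPresenceFilter:
    def test_boundary_inclusive_at_25_percent(self):
        vals = np.zeros((2, 48))
        vals[0, :12] = 5.0   # exactly 25 % of cells
        vals[1, :11] = 5.0   # just below
        vals[vals == 0] = np.nan
        table = _table(vals, 48)
        kept = presence_filter(table, 0.25)
        assert list(kept.features.index) == ["F0"]

    def test_presence_counts_cells_not_replicates(self):
        # one feature seen in 1 of 4 cells but in all 3 of its replicates
        vals = np.full((1, 12), np.nan)
        vals[0, 0:3] = 7.0
        table = _table(vals, 4, n_reps=3)
        assert len(presence_filter(table, 0.25).features) == 1
        assert len(presence_filter(table, 0.26).features) == 0

    def test_survivors_match_direct_count_oracle(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(1, 10, (30, 16 * 2))
        vals[rng.random(vals.shape) < 0.6] = np.nan
        table = _table(vals, 16, n_reps=2)
        kept = set(presence_filter(table, 0.25).features.index)
        expected = set()
        for fi, fid in enumerate(table.features.index):
            present = 0
            for c in range(16):
                cols = [2 * c, 2 * c + 1]
                if np.any(~np.isnan(vals[fi, cols])):
                    present += 1
            if present / 16 >= 0.25:
                expected.add(fid)
        assert kept == expected

    def test_empty_table_rejected(self):
        table = _table(np.ones((1, 3)), 3)
        with pytest.raises(ValueError):
            presence_filter(table.subset_features([]), 0.25)


class TestCarrierNormalize:
    def _reading(self, values):
        chans = ["126", "128N", "128C"]
        return ReporterReading("s", 1.0, dict(zip(chans, values)))

    def test_simple_ratio(self):
        out = carrier_normalize(self._reading([100.0, 10.0, 20.0]),
                                "126", ["128N", "128C"])
        assert out == {"128N": 0.1, "128C": 0.2}

    def test_global_scan_scaling_cancels_exactly(self):
        a = carrier_normalize(self._reading([100.0, 10.0, 20.0]),
                              "126", ["128N", "128C"])
        b = carrier_normalize(self._reading([30.0, 3.0, 6.0]),
                              "126", ["128N", "128C"])
        assert a == b

    def test_zero_carrier_marks_missing(self):
        out = carrier_normalize(self._reading([0.0, 10.0, 20.0]),
                                "126", ["128N", "128C"])
        assert out == {"128N": None, "128C": None}

    def test_normalized_values_track_true_amount_ratios(self):
        # noise-free simulation under heavy AGC rescaling: cell/carrier
        # ratios must equal the true amount ratios
        cfg = SimConfig(analytes=FAST_ANALYTES, noise_sd=0.0, noise_cv=0.0,
                        impurity=ImpurityMatrix.identity(), agc_target=2e4,
                        rng_seed=0)
        plex = default_plex("r", [f"c{i}" for i in range(6)])
        amounts = {"valine": {"126": 80.0, "128N": 4.0, "129C": 16.0}}
        run = simulate_run_amounts(plex, amounts, cfg)
        apex = min(run.scans, key=lambda s: abs(s.rt - 20.96))
        reading = extract_reporters(apex)
        out = carrier_normalize(reading, "126", ["128N", "129C"])
        assert out["128N"] == pytest.approx(4.0 / 80.0, rel=1e-6)
        assert out["129C"] == pytest.approx(16.0 / 80.0, rel=1e-6)


class TestRls:
    def test_small_system_matches_hand_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 3))
        y = rng.standard_normal(8)
        lam = 0.7
        w, b = rls_fit(x, y, lam)
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        w_hand = np.linalg.solve(xc.T @ xc + lam * np.eye(3), xc.T @ yc)
        np.testing.assert_allclose(w, w_hand, rtol=1e-12)
        assert b == pytest.approx(y.mean() - x.mean(axis=0) @ w_hand)

    def test_lambda_limits(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 6)) + np.eye(6)
        y = rng.standard_normal(6)
        w_small, b_small = rls_fit(x, y, 1e-10)
        xc = x - x.mean(axis=0)
        exact = np.linalg.lstsq(xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(w_small, exact, rtol=1e-4)
        w_big, b_big = rls_fit(x, y, 1e12)
        np.testing.assert_allclose(w_big, np.zeros(6), atol=1e-10)
        assert b_big == pytest.approx(y.mean())

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rls_fit(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]), 1.0)


def _explicit_loo(x, y, lam):
    n = x.shape[0]
    errs = []
    for i in range(n):
        keep = np.arange(n) != i
        w, b = rls_fit(x[keep], y[keep], lam)
        errs.append((y[i] - (x[i] @ w + b)) ** 2)
    return float(np.mean(errs))


class TestLoocv:
    def test_shortcut_equals_explicit_refit_on_20_seeds(self):
        worst = 0.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((10, 5))
            y = rng.standard_normal(10)
            short = loocv_mse(x, y, 0.8)
            full = _explicit_loo(x, y, 0.8)
            worst = max(worst, abs(short - full) / abs(full))
        assert worst < 1e-8

    def test_shortcut_still_exact_with_duplicated_rows(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        x2, y2 = np.vstack([x, x]), np.concatenate([y, y])
        assert loocv_mse(x2, y2, 1.0) == pytest.approx(
            _explicit_loo(x2, y2, 1.0), rel=1e-10)

    def test_interpolation_limit(self):
        # y in the column space, n > p, λ→0⁺: LOO errors vanish
        rng = np.random.default_rng(4)
        x = rng.standard_normal((12, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 3.0
        assert loocv_mse(x, y, 1e-10) < 1e-12

    def test_degenerate_leverage_rejected(self):
        x = np.array([[1.0], [0.0], [0.0]])
        with pytest.raises(ValueError, match="leverage"):
            loocv_mse(x, np.array([1.0, 0.0, 0.0]), 1e-13)


class TestGreedy:
    def test_perfect_predictor_selected_first(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 12))
        y = x[:, 7].copy()
        model = greedy_forward_select(x, y, lam=1e-6, k=1)
        assert model.selected == [7]

    def test_first_step_equals_exhaustive_search(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((25, 15))
        y = rng.standard_normal(25)
        lam = 1.0
        model = greedy_forward_select(x, y, lam=lam, k=3)
        exhaustive = min(range(15), key=lambda j: loocv_mse(x[:, [j]], y, lam))
        assert model.selected[0] == exhaustive

    def test_tie_break_prefers_lowest_index(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(20)
        x = np.column_stack([col, col, rng.standard_normal(20)])
        y = col + 0.1 * rng.standard_normal(20)
        model = greedy_forward_select(x, y, lam=1.0, k=1)
        assert model.selected == [0]

    def test_k_exceeding_feature_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            greedy_forward_select(np.ones((5, 2)), np.ones(5), k=3)

    def test_planted_informative_features_recovered(self):
        from scamine.untargeted import select_features
        cfg = SimConfig(rng_seed=1)
        table, truth = generate_feature_table(cfg)
        ranked, _ = select_features(table, k=10)
        hits = set(ranked["feature_id"]) & set(truth["informative"])
        assert len(hits) >= 2


class TestNestedCv:
    def _separable(self, seed=2):
        cfg = SimConfig(rng_seed=seed, missing_feature_prob=0.0)
        table, _ = generate_feature_table(
            cfg, n_features=60, n_informative=6, effect_sd_units=8.0,
            n_cells_per_type=4)
        return table

    def test_perfectly_separable_data_classified_perfectly(self):
        res = nested_leave_cell_out(self._separable(), k=3)
        assert res.accuracy == 1.0

    def test_fold_count_equals_number_of_cells(self):
        table = self._separable()
        res = nested_leave_cell_out(table, k=2)
        assert len(res.folds) == table.n_cells
        held_out = [f.cell_id for f in res.folds]
        assert sorted(held_out) == sorted(table.samples["cell_id"].unique())

    def test_permuted_labels_drop_accuracy_to_chance(self):
        cfg = SimConfig(rng_seed=3)
        table, _ = generate_feature_table(
            cfg, n_features=40, n_informative=4, n_cells_per_type=4)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(10):
            perm = table.samples.copy()
            cells = perm["cell_id"].unique()
            type_of = {c: perm.loc[perm.cell_id == c, "cell_type"].iloc[0]
                       for c in cells}
            shuffled = rng.permutation([type_of[c] for c in cells])
            mapping = dict(zip(cells, shuffled))
            perm["cell_type"] = perm["cell_id"].map(mapping)
            res = nested_leave_cell_out(
                FeatureTable(table.features, table.values, perm), k=2)
            accs.append(res.accuracy)
        mean_acc = float(np.mean(accs))
        # chance level for 3 balanced classes, generous binomial band
        assert 1 / 3 - 0.15 < mean_acc < 1 / 3 + 0.15

    def test_held_out_cell_never_influences_selection(self):
        table = self._separable(seed=4)
        res = nested_leave_cell_out(table, k=3)
        cell = res.folds[0].cell_id
        poisoned_vals = table.values.copy()
        cols = table.samples.index[table.samples["cell_id"] == cell]
        poisoned_vals[cols] = 1e9
        res2 = nested_leave_cell_out(
            FeatureTable(table.features, poisoned_vals, table.samples), k=3)
        fold = next(f for f in res.folds if f.cell_id == cell)
        fold2 = next(f for f in res2.folds if f.cell_id == cell)
        assert fold.selected == fold2.selected

    def test_unequal_replicate_counts_rejected(self):
        table = self._separable()
        samples = table.samples.iloc[:-1]
        values = table.values[samples.index]
        with pytest.raises(ValueError, match="replicate count"):
            nested_leave_cell_out(FeatureTable(table.features, values, samples))


class TestPca:
    def test_rank_one_matrix_explained_by_pc1(self):
        u = np.outer(np.arange(1, 5), np.linspace(1, 2, 6))
        table = _table(2.0**u - 1.0, 6)  # log2(1+x) recovers the rank-1 u
        _, evr = pca_project(table)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        table = _table(rng.uniform(1, 50, (5, 9)), 9)
        _, evr = pca_project(table)
        assert evr.sum() == pytest.approx(1.0, rel=1e-12)

    def test_variances_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(9)
        table = _table(rng.uniform(1, 50, (4, 12)), 12)
        x, _, _ = prepare_matrix(table)
        eig = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1]
        _, evr = pca_project(table)
        np.testing.assert_allclose(evr, eig[:len(evr)] / eig.sum(), rtol=1e-8)

    def test_scores_reconstruct_data(self):
        rng = np.random.default_rng(10)
        table = _table(rng.uniform(1, 50, (4, 8)), 8)
        x, _, _ = prepare_matrix(table)
        from sklearn.decomposition import PCA
        pca = PCA()
        scores = pca.fit_transform(x)
        back = scores @ pca.components_ + x.mean(axis=0)
        np.testing.assert_allclose(back, x, atol=1e-10)

    def test_drop_strategy_with_all_missing_rejected(self):
        vals = np.ones((2, 6))
        vals[0, 0] = np.nan
        vals[1, 3] = np.nan
        table = _table(vals, 6)
        with pytest.raises(ValueError, match="missing"):
            pca_project(table, missing="drop")


class TestAnnotation:
    def test_forward_constructed_glycine_feature_matches(self):
        compounds = compound_table()
        gly = compounds.loc[compounds["name"] == "glycine",
                            "monoisotopic_mass"].iloc[0]
        mz = gly + TMT10_TAG_MASS + PROTON_MASS
        ann = annotate_by_mass("f1", mz, compounds)
        assert ann.compound == "glycine"
        assert ann.level == "4"
        assert abs(ann.mass_error_mda) < 1.0

    def test_zero_tolerance_leaves_unannotated(self):
        compounds = compound_table()
        gly = compounds.loc[compounds["name"] == "glycine",
                            "monoisotopic_mass"].iloc[0]
        # half a mDa off: survives the 5 mDa default but not tol=0
        mz = gly + TMT10_TAG_MASS + PROTON_MASS + 5e-4
        assert annotate_by_mass("f1", mz, compounds, tol_mda=5.0).level == "4"
        assert annotate_by_mass("f1", mz, compounds, tol_mda=1e-9).level == "unannotated"

    def test_doubly_labeled_doubly_charged_lysine(self):
        compounds = compound_table()
        lys = compounds.loc[compounds["name"] == "lysine",
                            "monoisotopic_mass"].iloc[0]
        mz = (lys + 2 * TMT10_TAG_MASS + 2 * PROTON_MASS) / 2
        right = annotate_by_mass("f1", mz, compounds, n_labels=2, charge=2)
        assert right.compound == "lysine"
        wrong = annotate_by_mass("f1", mz, compounds, n_labels=1, charge=1)
        assert wrong.compound != "lysine"

    def test_spectral_match_is_level_2(self):
        ann = annotate_by_mass("f1", 400.0, compound_table(),
                               spectral_match="valine")
        assert ann.level == "2" and ann.compound == "valine"

    def test_empty_compound_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_by_mass("f1", 400.0, compound_table().iloc[0:0])


class TestPrepareMatrix:
    def test_zero_fill_log2(self):
        vals = np.array([[3.0, np.nan], [1.0, 7.0]])
        table = _table(vals, 2)
        x, fids, sids = prepare_matrix(table, missing="zero")
        np.testing.assert_allclose(x[1, 0], 0.0)
        np.testing.assert_allclose(x[0, 0], np.log2(4.0))
        assert fids == ["F0", "F1"] and len(sids) == 2

    def test_median_fill(self):
        vals = np.array([[2.0, np.nan, 6.0]])
        table = _table(vals, 3)
        x, _, _ = prepare_matrix(table, missing="median")
        assert x[1, 0] == pytest.approx(np.log2(1 + 4.0))

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            prepare_matrix(_table(np.ones((1, 2)), 2), missing="magic")
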