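import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from negprog import (
    CohortConfig,
    LeakageError,
    add_outcome_labels,
    apply_external,
    evaluate_scores,
    fit_view,
    generate_cohort,
    generate_null_cohort,
    make_lso_scheme,
    train_stacker,
)
from negprog.features import apply_scaler, build_features, fit_scaler, normalize_by_icv
from negprog.nested_cv import train_nested

FAST_GRID = (0.1, 1.0)


def _labelled(config):
    generated = generate_cohort(config)
    table = add_outcome_labels(generated.table)
    return table, table["negsym_bad"].to_numpy()


class TestScheme:
    def test_seven_sites_make_seven_outer_folds(self, signal_cohort):
        table, _ = signal_cohort
        scheme = make_lso_scheme(table, table["negsym_bad"].to_numpy())
        assert len(scheme.outer) == 7
        sites = table["site_id"].to_numpy()
        for train_idx, test_idx, test_site in scheme.outer:
            assert set(sites[test_idx]) == {test_site}
            assert test_site not in set(sites[train_idx])
        covered = np.concatenate([t for _, t, _ in scheme.outer])
        assert sorted(covered) == list(range(len(table)))

    def test_two_sites_swap_symmetrically(self):
        table, y = _labelled(CohortConfig(n_sites=2, n_per_site=30, seed=1))
        scheme = make_lso_scheme(table, y)
        assert len(scheme.outer) == 2
        (tr0, te0, _), (tr1, te1, _) = scheme.outer
        assert sorted(tr0) == sorted(te1) and sorted(tr1) == sorted(te0)

    def test_single_class_outer_training_set_is_an_error(self):
        table, y = _labelled(CohortConfig(n_sites=2, n_per_site=20, seed=2))
        # all positives in site01: holding out site01 leaves a one-class train set
        y_bad = np.where(table["site_id"].to_numpy() == "site01", 1, 0)
        with pytest.raises(ValueError, match="single class"):
            make_lso_scheme(table, y_bad)

    def test_requires_two_sites(self):
        table, y = _labelled(CohortConfig(n_sites=1, n_per_site=40, seed=3))
        with pytest.raises(ValueError, match="2 sites"):
            make_lso_scheme(table, y)


class TestTrainNested:
    def test_strong_signal_reaches_high_out_of_site_bac(self):
        table, y = _labelled(
            CohortConfig(n_per_site=100, roi_effect=1.5, n_signal_rois=8, seed=5)
        )
        scheme = make_lso_scheme(table, y, inner_r=2, seed=5)
        model = fit_view(table, y, scheme, "gyrification", grid=FAST_GRID)
        assert evaluate_scores(model.scores, y).bac >= 0.90

    def test_null_cohort_stays_near_chance(self):
        generated = generate_null_cohort(CohortConfig(n_per_site=100, seed=6))
        table = add_outcome_labels(generated.table)
        y = table["negsym_bad"].to_numpy()
        scheme = make_lso_scheme(table, y, inner_r=2, seed=6)
        model = fit_view(table, y, scheme, "gyrification", grid=FAST_GRID)
        assert 0.40 <= evaluate_scores(model.scores, y).bac <= 0.60

    def test_same_seed_gives_identical_scores(self, signal_cohort):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        runs = []
        for _ in range(2):
            scheme = make_lso_scheme(table, y, inner_r=1, seed=42)
            runs.append(fit_view(table, y, scheme, "sips_n", grid=FAST_GRID).scores)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_out_of_site_purity(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "sips_n", grid=FAST_GRID)
        site_of = dict(zip(table["subject_id"], table["site_id"]))
        assert (model.scores["fold"] == model.scores["subject_id"].map(site_of)).all()
        assert model.scores["subject_id"].is_unique
        # no member of a fold ensemble was trained on its own test site either:
        # preprocessing references differ from test-site statistics
        for fe in model.fold_ensembles:
            assert fe.test_site in set(table["site_id"])

    def test_ensemble_mean_is_member_permutation_invariant(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "sips_n", grid=FAST_GRID)
        fe = model.fold_ensembles[0]
        X = build_features(table, "sips_n").matrix[:10]
        before = fe.decision(X, None)
        rng = np.random.default_rng(0)
        rng.shuffle(fe.members)
        assert np.allclose(before, fe.decision(X, None))

    def test_empty_grid_rejected(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        with pytest.raises(ValueError, match="grid"):
            fit_view(table, y, signal_scheme, "sips_n", grid=())

    def test_refit_rule_with_single_grid_matches_direct_fit(self):
        """Degenerate settings reduce each outer fold to one train/test split:
        the out-of-site scores must equal a hand-rolled fit on the outer
        training set."""
        table, y = _labelled(CohortConfig(n_sites=2, n_per_site=40, seed=9))
        scheme = make_lso_scheme(table, y, inner_k=2, inner_r=1, seed=9)
        model = fit_view(
            table, y, scheme, "sips_n", grid=(1.0,),
            ensemble_rule="refit", balance_classes=False,
        )
        X = build_features(table, "sips_n").matrix
        for train_idx, test_idx, site in scheme.outer:
            scaler = fit_scaler(X[train_idx])
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
            clf.fit(apply_scaler(scaler, X[train_idx]), y[train_idx])
            expected = apply_scaler(scaler, X[test_idx]) @ clf.coef_[0] + clf.intercept_[0]
            got = model.scores.set_index("subject_id").loc[
                [table["subject_id"].iloc[i] for i in test_idx], "score"
            ].to_numpy()
            assert np.allclose(got, expected, atol=1e-8)


@pytest.fixture(scope="module")
def base_models(signal_cohort, signal_scheme):
    table, _ = signal_cohort
    y = table["negsym_bad"].to_numpy()
    sips = fit_view(table, y, signal_scheme, "sips_n", grid=FAST_GRID)
    gyri = fit_view(table, y, signal_scheme, "gyrification", grid=FAST_GRID)
    return table, y, sips, gyri


class TestStacking:
    def test_stack_of_complementary_signals_keeps_up(self, base_models, signal_scheme):
        table, y, sips, gyri = base_models
        stack = train_stacker([sips, gyri], y, signal_scheme, grid=FAST_GRID)
        bacs = {m: evaluate_scores(mdl.scores, y).bac for m, mdl in
                [("sips", sips), ("gyri", gyri), ("stack", stack)]}
        assert bacs["stack"] >= max(bacs["sips"], bacs["gyri"]) - 0.02

    def test_stack_with_noise_base_tracks_informative_base(self, base_models, signal_scheme):
        table, y, sips, gyri = base_models
        noise = fit_view(table, y, signal_scheme, "gyrification", grid=FAST_GRID)
        rng = np.random.default_rng(0)
        noise.scores = noise.scores.assign(score=rng.standard_normal(len(y)))
        noise.scores["pred"] = (noise.scores["score"] > 0).astype(int)
        stack = train_stacker([gyri, noise], y, signal_scheme, grid=FAST_GRID)
        assert abs(
            evaluate_scores(stack.scores, y).bac - evaluate_scores(gyri.scores, y).bac
        ) <= 0.05

    def test_duplicated_base_is_redundant(self, base_models, signal_scheme):
        table, y, sips, _ = base_models
        stack = train_stacker([sips, sips], y, signal_scheme, grid=FAST_GRID)
        assert abs(
            evaluate_scores(stack.scores, y).bac - evaluate_scores(sips.scores, y).bac
        ) <= 0.05

    def test_in_sample_base_scores_raise_leakage_error(self, base_models, signal_scheme):
        table, y, sips, gyri = base_models
        tampered = fit_view(table, y, signal_scheme, "sips_n", grid=FAST_GRID)
        tampered.scores = tampered.scores.assign(fold="site01")  # wrong provenance
        with pytest.raises(LeakageError):
            train_stacker([tampered, gyri], y, signal_scheme, grid=FAST_GRID)


class TestExternalApplication:
    def test_external_cohort_with_same_signal_scores_above_chance(
        self, signal_cohort, signal_scheme
    ):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "gyrification", grid=FAST_GRID)
        # ROP-like external cohort sharing the planted ROI structure
        _, meta = signal_cohort
        ext = add_outcome_labels(
            generate_cohort(
                CohortConfig(group="ROP", n_per_site=40, target_prevalence=0.59,
                             seed=77, n_signal_rois=8, roi_effect=0.8,
                             signal_rois=tuple(meta["signal_rois"]),
                             signal_signs=tuple(meta["signal_signs"][r]
                                                for r in meta["signal_rois"]))
            ).table
        )
        scores = apply_external(model, ext)
        report = evaluate_scores(scores, ext["negsym_bad"].to_numpy())
        assert report.auc > 0.6

    def test_external_cohort_without_shared_signal_is_chance(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "gyrification", grid=FAST_GRID)
        # signal planted in freshly drawn (almost surely different) ROIs
        ext = add_outcome_labels(
            generate_cohort(CohortConfig(group="ROD", n_per_site=60, seed=99)).table
        )
        report = evaluate_scores(
            apply_external(model, ext), ext["negsym_bad"].to_numpy()
        )
        assert 0.35 <= report.auc <= 0.65

    def test_scoring_training_cohort_is_refused(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "sips_n", grid=FAST_GRID)
        with pytest.raises(LeakageError):
            apply_external(model, table)

    def test_missing_columns_rejected(self, signal_cohort, signal_scheme):
        table, _ = signal_cohort
        y = table["negsym_bad"].to_numpy()
        model = fit_view(table, y, signal_scheme, "gyrification", grid=FAST_GRID)
        ext = generate_cohort(CohortConfig(group="ROP", n_per_site=10, seed=8)).table
        with pytest.raises(KeyError):
            apply_external(model, ext.drop(columns=["rh_insula"]))
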