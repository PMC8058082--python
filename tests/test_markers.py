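"""Per-class classification, direction calls, canonical correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from rfsubtype import CohortConfig, cca, classify_contrast, compare_marker_panels, generate_cohort, marker_direction_tests
from rfsubtype.markers import group_vector
from rfsubtype.synthetic import CLASS_BIOMARKER


def grid_cca_first_correlation(X, Y):
    """Independent oracle for u = v = 2: maximize |corr| over unit-norm
    weight angles by coarse grid + local refinement."""
    Zx = (X - X.mean(0)) / X.std(0, ddof=1)
    Zy = (Y - Y.mean(0)) / Y.std(0, ddof=1)

    def corr_at(ta, tb):
        a = np.array([np.cos(ta), np.sin(ta)])
        b = np.array([np.cos(tb), np.sin(tb)])
        return abs(np.corrcoef(Zx @ a, Zy @ b)[0, 1])

    grid = np.linspace(0, np.pi, 181)
    best = max(((corr_at(ta, tb), ta, tb) for ta in grid for tb in grid))
    _, ta0, tb0 = best
    for _ in range(40):  # coordinate-wise Brent refinement
        ta0 = minimize_scalar(lambda t: -corr_at(t, tb0), bracket=(ta0 - 0.02, ta0, ta0 + 0.02), method="brent", options={"xtol": 1e-14}).x
        tb0 = minimize_scalar(lambda t: -corr_at(ta0, t), bracket=(tb0 - 0.02, tb0, tb0 + 0.02), method="brent", options={"xtol": 1e-14}).x
    return corr_at(ta0, tb0)


class TestCca:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        M = np.array([[1.0, 0.2, 0.0], [0.5, -1.0, 0.3], [0.1, 0.0, 2.0]])
        res = cca(X, X @ M)
        assert np.allclose(res.correlations, 1.0, atol=1e-8)

    def test_independent_sets_low_correlations(self):
        rng = np.random.default_rng(1)
        res = cca(rng.normal(size=(500, 3)), rng.normal(size=(500, 2)))
        assert (res.correlations < 0.2).all()
        assert len(res.correlations) == 2

    def test_agrees_with_grid_search_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=50)
        X = np.column_stack([z + rng.normal(scale=1.0, size=50), rng.normal(size=50)])
        Y = np.column_stack([z + rng.normal(scale=1.0, size=50), rng.normal(size=50)])
        res = cca(X, Y)
        oracle = grid_cca_first_correlation(X, Y)
        assert res.correlations[0] == pytest.approx(oracle, abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.normal(size=(80, 3))
            Y = np.column_stack([X[:, 0] + rng.normal(size=80), rng.normal(size=80)])
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            B = rng.normal(size=(2, 2)) + 3 * np.eye(2)
            r0 = cca(X, Y).correlations
            r1 = cca(X @ A + rng.normal(size=3), Y @ B + 1.5).correlations
            assert np.allclose(r0, r1, atol=1e-8)

    def test_variates_mutually_uncorrelated(self):
        rng = np.random.default_rng(4)
        X, Y = rng.normal(size=(100, 4)), rng.normal(size=(100, 3))
        res = cca(X, Y)
        Zx = (X - X.mean(0)) / X.std(0, ddof=1)
        U = Zx @ res.x_weights
        G = U.T @ U
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"ok": np.random.default_rng(5).normal(size=20), "flat": np.ones(20)})
        with pytest.raises(ValueError, match="flat"):
            cca(X, X[["ok"]])


class TestComparePanels:
    def test_identical_panels_error(self, default_cohort):
        ids = default_cohort.feature_ids(CLASS_BIOMARKER)[:5]
        with pytest.raises(ValueError, match="non-overlap"):
            compare_marker_panels(default_cohort.values, ids, ids)

    def test_shared_latent_factor_high_first_correlation(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=500)
        cols = {f"a{i}": z + rng.normal(scale=0.5, size=500) for i in range(4)}
        cols |= {f"b{i}": z + rng.normal(scale=0.5, size=500) for i in range(4)}
        values = pd.DataFrame(cols)
        res = compare_marker_panels(values, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
        assert res.correlations[0] >= 0.9

    def test_disjoint_noise_panels_below_permutation_null(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(size=(120, 8)), columns=[f"f{i}" for i in range(8)])
        res = compare_marker_panels(values, [f"f{i}" for i in range(4)], [f"f{i}" for i in range(4, 8)])
        null = []
        X = values.iloc[:, :4].to_numpy()
        for _ in range(200):
            perm = rng.permutation(len(values))
            null.append(cca(X[perm], values.iloc[:, 4:]).correlations[0])
        assert res.correlations[0] < np.quantile(null, 0.95)

    def test_overlap_removed(self, default_cohort):
        ids = default_cohort.feature_ids(CLASS_BIOMARKER)
        res = compare_marker_panels(default_cohort.values, ids[:6], ids[3:9])
        assert res.correlations.shape[0] == min(3, 3)
        assert res.x_columns == ids[:3] and res.y_columns == ids[6:9]


@pytest.fixture(scope="module")
def recovery_cohort():
    """Few strong planted markers so the selected set is informative-dominated."""
    return CohortConfig(
        seed=0,
        n_informative_markers=6,
        marker_effect_size=1.1,
        block_correlation=0.1,
        n_biomarkers_per_class={"methylation": 30, "mirna": 12, "metabolite": 8},
    )


class TestClassifyContrast:
    def test_recovers_planted_markers(self, recovery_cohort):
        import dataclasses

        hits, aucs = 0, []
        for seed in range(10):
            cfg = dataclasses.replace(recovery_cohort, seed=seed)
            c = generate_cohort(cfg)
            disc = c.subset(role="discovery")
            groups = pd.Series(
                np.where(disc.subjects["group"] == "hc", "HC", disc.subjects["true_subtype"]),
                index=disc.subjects.index,
            )
            rep = classify_contrast(disc, groups, ("S2", "HC"), n_trees=150, seed=seed + 30, drop_fraction=0.25)
            planted = set(c.features.index[(c.features["class"] == CLASS_BIOMARKER) & (c.features["expected_direction"] != "")])
            recovered = len(planted & set(rep.importance_ranks)) / len(planted)
            hits += recovered >= 0.8
            aucs.append(rep.auc)
        assert hits >= 8
        assert sum(a >= 0.9 for a in aucs) >= 8

    def test_pure_noise_class_auc_band(self):
        """Markers with no planted effect: selected-model AUC shows no
        strong spurious signal."""
        aucs = []
        for seed in range(5):
            cfg = CohortConfig(
                seed=seed, marker_effect_size=0.0,
                n_biomarkers_per_class={"methylation": 12}, n_informative_markers=4,
                n_hc_discovery=200, n_case_discovery=200,
                n_hc_validation=0, n_case_validation=0,
                subtype_proportions=(1.0,), severity_means=(-0.6, 2.0),
            )
            c = generate_cohort(cfg)
            disc = c.subset(role="discovery")
            groups = pd.Series(
                np.where(disc.subjects["group"] == "hc", "HC", "S2"), index=disc.subjects.index
            )
            rep = classify_contrast(disc, groups, ("S2", "HC"), n_trees=150, seed=seed, drop_fraction=0.3, min_features=3)
            aucs.append(rep.auc)
        assert all(0.35 <= a <= 0.65 for a in aucs)

    def test_pooled_not_worse_than_best_class(self, default_cohort, subtype_run):
        groups = group_vector(default_cohort, subtype_run)
        disc = default_cohort.subset(role="discovery")
        by_class = {}
        for fclass in (CLASS_BIOMARKER, "psychiatric_history", "pooled"):
            rep = classify_contrast(disc, groups, ("S2", "HC"), feature_class=fclass,
                                    n_trees=150, seed=3, drop_fraction=0.3)
            by_class[fclass] = rep.auc
        best_single = max(v for k, v in by_class.items() if k != "pooled")
        assert by_class["pooled"] >= best_single - 0.05

    def test_errors(self, default_cohort, subtype_run):
        groups = group_vector(default_cohort, subtype_run)
        disc = default_cohort.subset(role="discovery")
        with pytest.raises(ValueError, match="feature class"):
            classify_contrast(disc, groups, ("S2", "HC"), feature_class="astrology")
        with pytest.raises(ValueError, match="empty group"):
            classify_contrast(disc, groups, ("S3", "HC"))


class TestMarkerDirections:
    def test_bonferroni_layout(self, default_cohort, subtype_run):
        groups = group_vector(default_cohort, subtype_run)
        disc = default_cohort.subset(role="discovery")
        markers = default_cohort.feature_ids(CLASS_BIOMARKER)[:5]
        layout = {c: markers for c in (("S1", "HC"), ("S2", "HC"), ("S2", "S1"), ("case", "HC"))}
        res = marker_direction_tests(disc, groups, layout)
        assert res.attrs["n_tests"] == 20
        assert res.attrs["threshold"] == pytest.approx(0.0025, abs=1e-12)

    def test_planted_marker_flagged_down(self):
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(seed=seed, marker_effect_size=1.5)
            c = generate_cohort(cfg)
            disc = c.subset(role="discovery")
            groups = pd.Series(
                np.where(disc.subjects["group"] == "hc", "HC", disc.subjects["true_subtype"]),
                index=disc.subjects.index,
            )
            meta = c.features
            down = meta.index[(meta["class"] == CLASS_BIOMARKER) & (meta["expected_direction"] == "down")][0]
            null = meta.index[(meta["class"] == CLASS_BIOMARKER) & (meta["expected_direction"] == "")][0]
            res = marker_direction_tests(disc, groups, {("S2", "HC"): [down, null]}, alpha_fwer=0.05)
            row = res[res.marker == down].iloc[0]
            nrow = res[res.marker == null].iloc[0]
            hits += (row.direction == "down") and (nrow.direction == "ns")
        assert hits >= 9

    def test_direction_flips_with_group_swap(self, default_cohort, subtype_run):
        groups = group_vector(default_cohort, subtype_run)
        disc = default_cohort.subset(role="discovery")
        meta = default_cohort.features
        down = meta.index[(meta["class"] == CLASS_BIOMARKER) & (meta["expected_direction"] == "down")][0]
        res_a = marker_direction_tests(disc, groups, {("S2", "HC"): [down]})
        res_b = marker_direction_tests(disc, groups, {("HC", "S2"): [down]})
        # severe group identified by severity rank, not argument order
        assert res_a.iloc[0].direction == res_b.iloc[0].direction
        assert res_a.iloc[0].p == pytest.approx(res_b.iloc[0].p, abs=1e-15)

    def test_constant_marker_untestable(self, default_cohort, subtype_run):
        groups = group_vector(default_cohort, subtype_run)
        disc = default_cohort.subset(role="discovery")
        disc = type(disc)(disc.values.copy(), disc.subjects, disc.features)
        fid = default_cohort.feature_ids(CLASS_BIOMARKER)[0]
        disc.values[fid] = 1.0
        res = marker_direction_tests(disc, groups, {("S2", "HC"): [fid]})
        assert res.iloc[0].direction == "untestable"
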