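"""PERMANOVA, partial R², per-landmark localization and disparity tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morpholong.io import DesignTable
from morpholong.permstats import (
    PermutationScheme,
    disparity_test,
    gower_center,
    pairwise_distance_matrix,
    pairwise_posthoc,
    partial_r2,
    per_landmark_analysis,
    permanova,
    procrustes_variance,
    run_form_analysis,
)


def _design(n_subjects, stages, groups=None):
    rows = []
    for i in range(n_subjects):
        g = groups[i] if groups is not None else "g"
        for s in stages:
            rows.append({"subject_id": f"S{i:02d}", "stage": s, "group": g})
    return DesignTable(pd.DataFrame(rows), stages=tuple(stages))


def _random_cohort(rng, n_subjects, stages, k=6, stage_effect=0.0, groups=None):
    design = _design(n_subjects, stages, groups)
    shapes = []
    base = rng.normal(size=(k, 3))
    for i in range(n_subjects):
        subj = rng.normal(scale=0.3, size=(k, 3))
        for j, _ in enumerate(stages):
            shapes.append(
                base + subj + stage_effect * j * np.ones((k, 3))
                + rng.normal(scale=0.1, size=(k, 3))
            )
    return design, np.array(shapes)


class TestDistanceMatrix:
    def test_identical_shapes_zero_matrix(self, rng):
        s = rng.normal(size=(4, 5, 3))
        s[:] = s[0]
        np.testing.assert_array_equal(pairwise_distance_matrix(s), np.zeros((4, 4)))

    def test_two_shapes_mirrored_entry(self, rng):
        s = rng.normal(size=(2, 5, 3))
        d = pairwise_distance_matrix(s)
        expected = np.sqrt(((s[0] - s[1]) ** 2).sum())
        assert d[0, 1] == d[1, 0] == pytest.approx(expected, rel=1e-12)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_matches_element_loop_oracle(self, rng):
        s = rng.normal(size=(5, 4, 3))
        d = pairwise_distance_matrix(s)
        for i in range(5):
            for j in range(5):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((s[i] - s[j]) ** 2).sum()), abs=1e-12
                )


class TestPermanova:
    def test_constant_response_raises(self):
        design = _design(4, ("T0", "T1"))
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99)
        with pytest.raises(ValueError, match="zero"):
            permanova(np.zeros((8, 8)), design, scheme, terms=("stage",))

    def test_ss_additivity(self, rng):
        design, shapes = _random_cohort(
            rng, 6, ("T0", "T1", "T2"),
            groups=["a"] * 3 + ["b"] * 3, stage_effect=0.05,
        )
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = permanova(pairwise_distance_matrix(shapes), design, scheme)
        terms_ss = t.loc[["stage", "group", "stage:group"], "SS"].sum()
        assert terms_ss + t.loc["Residual", "SS"] == pytest.approx(
            t.loc["Total", "SS"], rel=1e-9
        )

    def test_distance_decomposition_equals_coordinate_ss(self, rng):
        """For Euclidean distances the Gower-trace partition equals the
        direct coordinate-space linear-model decomposition."""
        design, shapes = _random_cohort(
            rng, 4, ("T0", "T1", "T2"), groups=["a", "a", "b", "b"],
            stage_effect=0.05,
        )
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = permanova(pairwise_distance_matrix(shapes), design, scheme)

        y = shapes.reshape(len(shapes), -1)
        y = y - y.mean(axis=0)
        stage, group = design.stage_labels, design.groups

        def hat(*label_sets):
            from scipy.linalg import orth

            cols = [np.ones(len(y))]
            for labels in label_sets:
                cols.extend(
                    (labels == lev).astype(float) for lev in pd.unique(labels)[1:]
                )
            q = orth(np.column_stack(cols))  # rank-safe orthonormal basis
            return q @ q.T

        inter = np.array([f"{s}|{g}" for s, g in zip(stage, group)])
        h1, h2, h3 = hat(stage), hat(stage, group), hat(stage, group, inter)
        ss_stage = float(((h1 - np.full_like(h1, 1 / len(y))) @ y @ y.T).trace())
        ss_group = float(((h2 - h1) @ y @ y.T).trace())
        ss_inter = float(((h3 - h2) @ y @ y.T).trace())
        assert t.loc["stage", "SS"] == pytest.approx(ss_stage, rel=1e-9)
        assert t.loc["group", "SS"] == pytest.approx(ss_group, rel=1e-9)
        assert t.loc["stage:group", "SS"] == pytest.approx(ss_inter, rel=1e-9)

    def test_exact_enumeration_matches_flip_oracle(self, rng):
        """5 subjects x 2 stages: returned p equals exact enumeration of all
        2^5 within-subject stage-label flips via an independent
        coordinate-space F computation."""
        design, shapes = _random_cohort(rng, 5, ("T0", "T1"), stage_effect=0.15)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=9999, seed=1)
        t = permanova(pairwise_distance_matrix(shapes), design, scheme,
                      terms=("stage",))

        y = shapes.reshape(10, -1)
        y = y - y.mean(axis=0)

        def f_of(stagevec):
            x = np.column_stack([np.ones(10), (stagevec == "T1").astype(float)])
            q, _ = np.linalg.qr(x)
            fit = q @ (q.T @ y)
            ss_res = ((y - fit) ** 2).sum()
            ss_stage = (fit**2).sum() - len(y) * 0.0  # y centered; intercept fit = 0
            return (ss_stage / 1) / (ss_res / (10 - 2))

        st = design.stage_labels.copy()
        f_obs = f_of(st)
        fs = []
        for flips in itertools.product([0, 1], repeat=5):
            sv = st.copy()
            for s, flip in enumerate(flips):
                if flip:
                    idx = np.flatnonzero(design.subjects == f"S{s:02d}")
                    sv[idx] = sv[idx][::-1]
            fs.append(f_of(sv))
        p_exact = np.mean(np.array(fs) >= f_obs - 1e-12)
        assert t.loc["stage", "p"] == p_exact

    def test_seed_reproducibility_and_p_positive(self, rng):
        design, shapes = _random_cohort(rng, 12, ("T0", "T1", "T2"),
                                        stage_effect=0.3)
        d = pairwise_distance_matrix(shapes)
        s1 = PermutationScheme(subjects=design.subjects, n_perms=199, seed=5)
        s2 = PermutationScheme(subjects=design.subjects, n_perms=199, seed=5)
        t1 = permanova(d, design, s1, terms=("stage",))
        t2 = permanova(d, design, s2, terms=("stage",))
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.loc["stage", "p"] >= 1 / 200

    def test_matches_skbio_oneway_pseudo_f(self, rng):
        """Independent cross-check: one-way pseudo-F equals scikit-bio's
        PERMANOVA on the same distance matrix."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        design, shapes = _random_cohort(
            rng, 8, ("T0",), groups=["a"] * 4 + ["b"] * 4,
        )
        shapes[design.groups == "b"] += 0.1
        d = pairwise_distance_matrix(shapes)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = permanova(d, design, scheme, terms=("group",))
        dm = skbio_stats.DistanceMatrix(d)
        ref = skbio_stats.permanova(dm, list(design.groups), permutations=99)
        assert t.loc["group", "F"] == pytest.approx(ref["test statistic"], rel=1e-10)


class TestPartialR2:
    def test_trivial_values(self):
        assert partial_r2(0.0, 5.0) == 0.0
        assert partial_r2(2.0, 8.0) == pytest.approx(0.2, abs=1e-15)

    def test_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            partial_r2(0.0, 0.0)

    def test_matches_reduced_model_refit(self, rng):
        """On an orthogonal worked design (n=6, 2 balanced terms) partial R²
        equals (SSE_reduced - SSE_full)/SSE_reduced from explicit refits."""
        design = DesignTable(pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(3) for _ in range(2)],
            "stage": ["T0", "T1"] * 3,
            "group": ["a", "a", "a", "a", "b", "b"],
        }), stages=("T0", "T1"))
        shapes = rng.normal(size=(6, 4, 3))
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = permanova(pairwise_distance_matrix(shapes), design, scheme,
                      terms=("stage", "group"))

        y = shapes.reshape(6, -1)

        def sse(cols):
            x = np.column_stack([np.ones(6)] + cols)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return ((y - x @ beta) ** 2).sum()

        stage_col = (design.stage_labels == "T1").astype(float)
        group_col = (design.groups == "b").astype(float)
        sse_full = sse([stage_col, group_col])
        for term, cols_red in [("stage", [group_col]), ("group", [stage_col])]:
            kleinbaum = (sse(cols_red) - sse_full) / sse(cols_red)
            assert t.loc[term, "partial_R2"] == pytest.approx(kleinbaum, abs=1e-10)


class TestPairwisePosthoc:
    def test_duplicate_stages_give_zero_pd(self, rng):
        design = _design(6, ("T0", "T1"))
        base = rng.normal(size=(6, 5, 3))
        shapes = np.repeat(base, 2, axis=0)  # T1 identical to T0 per subject
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = pairwise_posthoc(shapes, design, scheme, terms=("stage",))
        assert t.loc["T0-T1", "PD"] == pytest.approx(0.0, abs=1e-12)
        assert t.loc["T0-T1", "p"] > 0.9

    def test_schema_lists_all_stage_pairs(self, rng):
        design, shapes = _random_cohort(rng, 6, ("T0", "T1", "T2"),
                                        stage_effect=0.05)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = pairwise_posthoc(shapes, design, scheme, terms=("stage",))
        assert list(t.index) == ["T0-T1", "T0-T2", "T1-T2"]
        assert {"PD", "partial_R2", "p"} <= set(t.columns)

    def test_mean_offset_recovered(self, rng):
        """With noise -> 0 the pairwise PD equals the injected mean offset."""
        design = _design(10, ("T0", "T1"))
        k = 8
        base = rng.normal(size=(k, 3))
        delta = rng.normal(size=(k, 3))
        delta -= delta.mean(axis=0)
        delta *= 0.01 / np.sqrt((delta**2).sum())
        shapes = []
        for i in range(10):
            subj = 1e-6 * rng.normal(size=(k, 3))
            shapes.extend([base + subj, base + subj + delta])
        shapes = np.asarray(shapes)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t = pairwise_posthoc(shapes, design, scheme, terms=("stage",))
        assert t.loc["T0-T1", "PD"] == pytest.approx(0.01, abs=1e-3)


class TestPerLandmark:
    def test_no_effect_no_noise_zero_magnitudes(self):
        design = _design(5, ("T0", "T1"))
        base = np.arange(18, dtype=float).reshape(6, 3)
        shapes = np.tile(base, (10, 1, 1))
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        res = per_landmark_analysis(shapes, design, scheme, mm_scale=100.0,
                                    terms=("stage",), n_perms=0)
        np.testing.assert_allclose(res["magnitudes"]["T0-T1"], 0.0, atol=1e-12)

    def test_single_displaced_landmark_recovered_within_leakage(self, rng):
        """A 2 mm displacement of one landmark between stages is recovered to
        within 5% after GPA; the leakage is quantified against a no-GPA
        oracle that sees the raw displacement exactly."""
        from morpholong.procrustes import gpa

        k, n_subj = 100, 15
        base = rng.normal(size=(k, 3)) * 50
        disp = np.zeros((k, 3))
        disp[7] = [2.0, 0.0, 0.0]
        design = _design(n_subj, ("T0", "T1"))
        configs = []
        for i in range(n_subj):
            subj = rng.normal(scale=0.05, size=(k, 3))
            configs.append(base + subj)
            configs.append(base + subj + disp)
        res = gpa(configs)
        mm_scale = float(res.centroid_sizes.mean())
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        out = per_landmark_analysis(res.shapes, design, scheme,
                                    mm_scale=mm_scale, terms=("stage",),
                                    n_perms=0)
        est = out["magnitudes"]["T0-T1"][7]
        # no-GPA oracle: raw stage difference of the untouched configurations
        raw = np.array(configs).reshape(n_subj, 2, k, 3)
        oracle = np.linalg.norm((raw[:, 1] - raw[:, 0]).mean(axis=0), axis=1)[7]
        assert oracle == pytest.approx(2.0, abs=1e-9)
        assert abs(est - oracle) / oracle < 0.05

    def test_summary_schema(self, rng):
        design, shapes = _random_cohort(rng, 6, ("T0", "T1", "T2"),
                                        stage_effect=0.05)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=49, seed=0)
        res = per_landmark_analysis(shapes, design, scheme, mm_scale=100.0,
                                    terms=("stage",), n_perms=49)
        assert list(res["summary"].columns) == ["mean_mm", "sd_mm", "median_mm"]
        assert set(res["summary"].index) == {"T0-T1", "T0-T2", "T1-T2"}
        stats = res["stats"]
        assert ((stats["p_stage"] > 0) & (stats["p_stage"] <= 1)).all()
        assert (stats["p_stage_bh"] >= stats["p_stage"] - 1e-12).all()


class TestDisparity:
    def test_identical_shapes_zero_variance(self, rng):
        shapes = np.tile(rng.normal(size=(5, 3)), (6, 1, 1))
        pv = procrustes_variance(shapes, np.array(["a"] * 3 + ["b"] * 3))
        assert pv["a"] == pytest.approx(0.0, abs=1e-30)
        assert pv["b"] == pytest.approx(0.0, abs=1e-30)

    def test_two_shapes_quarter_squared_distance(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        d = np.sqrt(((a - b) ** 2).sum())
        pv = procrustes_variance(np.stack([a, b]), np.array(["g", "g"]))
        assert pv["g"] == pytest.approx(d**2 / 4, rel=1e-12)

    def test_matches_naive_two_pass_oracle(self, rng):
        shapes = rng.normal(size=(9, 6, 3))
        groups = np.array(["a"] * 4 + ["b"] * 5)
        pv = procrustes_variance(shapes, groups)
        for g in ("a", "b"):
            sel = shapes[groups == g].reshape((groups == g).sum(), -1)
            mean = sel.mean(axis=0)
            naive = sum(((x - mean) ** 2).sum() for x in sel) / len(sel)
            assert pv[g] == pytest.approx(naive, abs=1e-12)

    def test_identical_groups_delta_zero_p_one(self, rng):
        half = rng.normal(size=(8, 5, 3))
        shapes = np.concatenate([half, half])
        groups = np.array(["a"] * 8 + ["b"] * 8)
        t = disparity_test(shapes, groups, n_perms=199, seed=0)
        assert t.loc["a-b", "delta_var"] == pytest.approx(0.0, abs=1e-15)
        assert t.loc["a-b", "p"] == 1.0

    def test_singleton_group_skipped_with_warning(self, rng):
        shapes = rng.normal(size=(5, 4, 3))
        groups = np.array(["a"] * 4 + ["b"])
        with pytest.warns(RuntimeWarning, match="size 1"):
            t = disparity_test(shapes, groups, n_perms=99, seed=0)
        assert np.isnan(t.loc["a-b", "p"])
        assert np.isfinite(t.loc["a-b", "PV_a"])


class TestFormAnalysis:
    def test_equal_sizes_reproduce_shape_results(self, rng):
        """With all centroid sizes equal, form analysis is a rescaling of
        shape analysis: identical F and p."""
        design, shapes = _random_cohort(
            rng, 6, ("T0", "T1", "T2"), groups=["a"] * 3 + ["b"] * 3,
            stage_effect=0.05,
        )
        scheme = PermutationScheme(subjects=design.subjects, n_perms=99, seed=0)
        t_shape = permanova(pairwise_distance_matrix(shapes), design, scheme)
        forms = shapes * 120.0
        res = run_form_analysis(forms, design, scheme, n_perms_disparity=99)
        t_form = res["permanova"]
        np.testing.assert_allclose(
            t_form["F"].to_numpy(), t_shape["F"].to_numpy(), rtol=1e-9
        )
        np.testing.assert_array_equal(
            t_form["p"].to_numpy(), t_shape["p"].to_numpy()
        )
        np.testing.assert_allclose(
            t_form["SS"].to_numpy(), t_shape["SS"].to_numpy() * 120.0**2,
            rtol=1e-9,
        )

    def test_size_only_effect_seen_in_form_not_shape(self, rng):
        """Identical shapes whose size grows with stage: null for shape,
        detected in form space."""
        design = _design(10, ("T0", "T1"))
        base = rng.normal(size=(12, 3))
        base = base - base.mean(axis=0)
        base /= np.sqrt((base**2).sum())
        shapes, forms = [], []
        for i in range(10):
            for j, _ in enumerate(("T0", "T1")):
                size = 100.0 + 10.0 * j + rng.normal(scale=0.5)
                shapes.append(base)
                forms.append(base * size)
        shapes = np.asarray(shapes) + rng.normal(scale=1e-4, size=(20, 12, 3))
        forms = np.asarray(forms)
        scheme = PermutationScheme(subjects=design.subjects, n_perms=199, seed=0)
        t_shape = permanova(pairwise_distance_matrix(shapes), design, scheme,
                            terms=("stage",))
        t_form = permanova(pairwise_distance_matrix(forms), design, scheme,
                           terms=("stage",))
        assert t_shape.loc["stage", "p"] > 0.2
        assert t_form.loc["stage", "p"] <= 0.01
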