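"""Conjunction, overlap, preference, RGB, and network comparison analyses."""

import numpy as np
import pytest

from mdsurf import (
    ContrastCohort,
    GroundTruth,
    MultipleComparisonConfig,
    areal_conjunction,
    areal_mean,
    composite_rgb,
    network_compare,
    simulate_cohort,
    subject_conjunction_overlap,
    task_preference,
    to_percent_signal_change,
)
from mdsurf.activation import NO_PREFERENCE


def _cohort(values, se=None, tasks=None):
    values = np.asarray(values, dtype=float)
    return ContrastCohort(
        values=values,
        task_names=tasks or [f"t{i}" for i in range(values.shape[1])],
        se=se,
        se_df=np.inf,
    )


class TestPercentSignalChange:
    @pytest.mark.parametrize(
        "beta,expected", [(10000.0, 100.0), (0.0, 0.0), (250.0, 2.5), (-100.0, -1.0)]
    )
    def test_formula(self, beta, expected):
        assert to_percent_signal_change(beta) == pytest.approx(expected)


class TestArealMean:
    def test_small_area(self, bihemi_parc):
        n_el = bihemi_parc.area_label.shape[0]
        vals = np.zeros((1, 2, n_el))
        area = bihemi_parc.areas[0]
        idx = bihemi_parc.vertices_of(area)
        vals[0, 0, idx[:3]] = [1.0, 2.0, 3.0]
        am = areal_mean(_cohort(vals), bihemi_parc)
        assert am[0, 0, 0] == pytest.approx((1 + 2 + 3) / idx.size)

    def test_constant_map(self, bihemi_parc):
        n_el = bihemi_parc.area_label.shape[0]
        am = areal_mean(_cohort(np.full((2, 2, n_el), 0.7)), bihemi_parc)
        np.testing.assert_allclose(am, 0.7)

    def test_matches_explicit_loop(self, bihemi_parc, default_cohort):
        am = areal_mean(default_cohort, bihemi_parc)
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = rng.integers(default_cohort.n_subjects)
            t = rng.integers(default_cohort.n_tasks)
            j = rng.integers(len(bihemi_parc.areas))
            idx = bihemi_parc.vertices_of(bihemi_parc.areas[j])
            acc = sum(default_cohort.values[s, t, v] for v in idx) / idx.size
            assert am[s, t, j] == pytest.approx(acc, rel=1e-12)


@pytest.fixture(scope="module")
def planted():
    # areas A (all 3 tasks, standardized effect 2.0) and B (2 of 3 tasks)
    rng = np.random.default_rng(10)
    n, T, A = 20, 3, 6
    effects = np.zeros((T, A))
    effects[:, 0] = 2.0
    effects[[0, 1], 1] = 2.0
    return rng.normal(size=(n, T, A)) + effects


class TestArealConjunction:
    def test_planted_conjunction(self, planted):
        cfg = MultipleComparisonConfig(method="bonferroni", n_comparisons=6)
        conj = areal_conjunction(planted, cfg)
        assert conj == [0]

    def test_all_zero_empty(self):
        cfg = MultipleComparisonConfig(method="bonferroni", n_comparisons=4)
        rng = np.random.default_rng(1)
        conj = areal_conjunction(rng.normal(size=(15, 3, 4)), cfg)
        assert conj == []

    def test_monotone_in_alpha(self, planted):
        lo = areal_conjunction(
            planted, MultipleComparisonConfig(alpha=0.05, method="bonferroni", n_comparisons=6)
        )
        hi = areal_conjunction(
            planted, MultipleComparisonConfig(alpha=0.10, method="bonferroni", n_comparisons=6)
        )
        assert set(lo) <= set(hi)

    def test_either_hemisphere_union(self):
        # effect lives in L-area only; union mode promotes both homologs
        rng = np.random.default_rng(2)
        areal = rng.normal(size=(20, 3, 2)) * 0.5
        areal[:, :, 0] += 3.0
        cfg = MultipleComparisonConfig(method="bonferroni", n_comparisons=2)
        plain = areal_conjunction(areal, cfg, areas=["L0", "R0"])
        union = areal_conjunction(
            areal, cfg, areas=["L0", "R0"], homolog_area_pairs={"L0": "R0", "R0": "L0"}
        )
        assert plain == ["L0"]
        assert union == ["L0", "R0"]


class TestSubjectConjunctionOverlap:
    def test_huge_effects_full_count(self):
        vals = np.full((8, 3, 50), 5.0)
        se = np.full_like(vals, 0.1)
        om = subject_conjunction_overlap(_cohort(vals, se=se))
        assert np.all(om.counts == 8)

    def test_effect_missing_in_one_task_zero(self):
        vals = np.full((8, 3, 50), 5.0)
        vals[:, 2, :] = 0.0
        se = np.full_like(vals, 0.1)
        om = subject_conjunction_overlap(_cohort(vals, se=se))
        assert np.all(om.counts == 0)

    def test_planted_zone_recovered(self, bihemi_mesh, bihemi_parc, bihemi_borders):
        # zone areas at 4x noise sd in every task; SE = noise_sd / sqrt(4 runs)
        areas = bihemi_parc.areas
        means = np.zeros((len(areas), 3))
        zone = [areas[0], areas[1]]
        for j, a in enumerate(areas):
            if a in zone:
                means[j, :] = 1.2  # 4 x noise_sd
        truth = GroundTruth(
            task_names=["t0", "t1", "t2"], area_task_means=means, noise_sd=0.3,
            noise_fwhm_mm=0.0, subject_sd=0.0,
        )
        cohort = simulate_cohort(
            bihemi_mesh, bihemi_parc, truth, n_subjects=12, seed=7, borders=bihemi_borders
        )
        om = subject_conjunction_overlap(cohort)
        zone_idx = np.concatenate([bihemi_parc.vertices_of(a) for a in zone])
        frac = np.mean(om.counts[zone_idx] > 6)
        assert frac >= 0.90

    def test_antitone_in_alpha(self, default_cohort):
        strict = subject_conjunction_overlap(
            default_cohort,
            MultipleComparisonConfig(alpha=0.01, method="bh_fdr",
                                     n_comparisons=default_cohort.n_elements),
        )
        lax = subject_conjunction_overlap(
            default_cohort,
            MultipleComparisonConfig(alpha=0.05, method="bh_fdr",
                                     n_comparisons=default_cohort.n_elements),
        )
        assert np.all(strict.counts <= lax.counts)

    def test_missing_se_error(self):
        with pytest.raises(ValueError):
            subject_conjunction_overlap(_cohort(np.zeros((3, 3, 10))))


class TestTaskPreference:
    def test_strong_preference_labeled(self):
        rng = np.random.default_rng(3)
        n, T, E = 20, 3, 40
        vals = 0.2 + rng.normal(scale=0.1, size=(n, T, E))
        vals[:, 0, :] += 0.8
        pref = task_preference(_cohort(vals, tasks=["one", "two", "three"]))
        assert np.mean(pref.label == "one") > 0.99

    def test_symmetric_null_controls_labeling(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(20, 3, 300))
        pref = task_preference(_cohort(vals))
        assert pref.labeled_fraction() <= 0.07

    def test_exact_tie_unlabeled(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(10, 1, 20))
        third = base - 1.0
        vals = np.concatenate([base, base.copy(), third], axis=1)
        pref = task_preference(_cohort(vals))
        assert np.all(pref.label == NO_PREFERENCE)

    def test_at_most_one_label(self, default_cohort):
        pref = task_preference(default_cohort)
        assert pref.label.shape == (default_cohort.n_elements,)
        assert set(pref.label.tolist()) <= set(default_cohort.task_names) | {NO_PREFERENCE}

    def test_restrict_limits_labels(self, default_cohort):
        restrict = np.arange(50)
        pref = task_preference(default_cohort, restrict=restrict)
        assert np.all(pref.label[50:] == NO_PREFERENCE)


class TestCompositeRgb:
    def test_extremes(self):
        g = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        rgb = composite_rgb(g).rgb
        assert rgb[0].tolist() == [0, 0, 0]
        assert rgb[1].tolist() == [255, 255, 255]

    def test_halfway_rounds_up(self):
        # halfway in channel 1 only: 0.5 * 255 = 127.5 -> 128
        g = np.array([[0.0, 0.5, 1.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        rgb = composite_rgb(g).rgb
        assert rgb[1].tolist() == [128, 0, 0]

    def test_joint_affine_invariance(self):
        rng = np.random.default_rng(6)
        g = rng.normal(size=(3, 30))
        a = composite_rgb(g).rgb
        b = composite_rgb(2.5 * g - 1.0).rgb
        np.testing.assert_array_equal(a, b)

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            composite_rgb(np.ones((3, 10)))


class TestNetworkCompare:
    def test_symmetric_cohort_zero_lateralization(self, bihemi_mesh, bihemi_parc):
        # mirror each subject's left-hemisphere values onto the right
        rng = np.random.default_rng(7)
        n_el = bihemi_mesh.n_vertices
        vals = rng.normal(size=(10, 3, n_el))
        for v, h in bihemi_mesh.homolog_map.items():
            if v < h:
                vals[:, :, h] = vals[:, :, v]
        cohort = ContrastCohort(values=vals, task_names=["a", "b", "c"],
                                element_space=bihemi_mesh)
        out = network_compare(cohort, bihemi_parc, ["coreMD"], mesh=bihemi_mesh)
        for task, res in out["networks"]["coreMD"]["lateralization"].items():
            assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_right_bias_detected(self, bihemi_mesh, bihemi_parc):
        rng = np.random.default_rng(8)
        n_el = bihemi_mesh.n_vertices
        comp = np.asarray(bihemi_mesh.component_id)
        vals = rng.normal(scale=0.2, size=(20, 3, n_el))
        vals[:, 1, comp == "R"] += 0.3
        cohort = ContrastCohort(values=vals, task_names=["a", "b", "c"],
                                element_space=bihemi_mesh)
        out = network_compare(cohort, bihemi_parc, ["coreMD"], mesh=bihemi_mesh)
        lat = out["networks"]["coreMD"]["lateralization"]
        assert lat["b"]["p"] < 0.05
        assert lat["b"]["direction"] == -1  # left minus right is negative
        assert lat["a"]["p"] > 0.05 or abs(lat["a"]["t"]) < abs(lat["b"]["t"])

    def test_network_means_equal_vertex_mean(self, bihemi_parc, default_cohort, bihemi_mesh):
        out = network_compare(default_cohort, bihemi_parc, ["DAN"], mesh=bihemi_mesh)
        verts = bihemi_parc.vertices_of_network("DAN")
        t0 = default_cohort.task_names[0]
        expected = default_cohort.values[:, 0, verts].mean(axis=1).mean()
        assert out["networks"]["DAN"]["tasks"][t0]["all"]["mean"] == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_network_error(self, bihemi_parc, default_cohort, bihemi_mesh):
        with pytest.raises(ValueError):
            network_compare(default_cohort, bihemi_parc, ["no-such-network"],
                            mesh=bihemi_mesh)
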