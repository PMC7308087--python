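"""Volume-to-surface sampling, subdivision summaries, ANOVA, post-hocs,
and the subsampling stability analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtopmap.surface import (
    merge_multimodal_labels,
    posthoc_paired_ttests,
    sample_volume_to_surface,
    stability_analysis,
    subdivision_means,
    two_way_rm_anova,
)
from rtopmap.synthetic import SurfaceMesh, make_parcel_table, make_surface_phantom


@pytest.fixture(scope="module")
def phantom():
    return make_surface_phantom(seed=0)


class TestSampling:
    def test_constant_volume(self, phantom):
        mesh = phantom.meshes["L"]
        vol = np.full((30, 15, 5), 3.7)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        vals = sample_volume_to_surface(vol, affine, mesh)
        np.testing.assert_allclose(vals[np.isfinite(vals)], 3.7)

    def test_trilinear_exact_on_linear_ramp(self, phantom):
        mesh = phantom.meshes["L"]
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-2.0, -2.0, -2.0]
        i, j, k = np.meshgrid(*[np.arange(s) for s in (25, 15, 5)],
                              indexing="ij")
        # world-linear field: f = 2x + 3y - z + 1 evaluated at voxel centers
        x, y, z = 2 * i - 2, 2 * j - 2, 2 * k - 2
        vol = 2 * x + 3 * y - z + 1.0
        vals = sample_volume_to_surface(vol, affine, mesh, "trilinear")
        v = mesh.vertices
        expected = 2 * v[:, 0] + 3 * v[:, 1] - v[:, 2] + 1.0
        inside = np.isfinite(vals)
        assert inside.sum() > 100
        np.testing.assert_allclose(vals[inside], expected[inside], atol=1e-6)

    def test_outside_fov_is_missing(self, phantom):
        mesh = phantom.meshes["R"]  # sheet at z = 30, outside a thin volume
        vol = np.ones((30, 15, 3))
        vals = sample_volume_to_surface(vol, np.eye(4), mesh)
        assert np.all(np.isnan(vals))

    def test_singular_affine_rejected(self, phantom):
        bad = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singular"):
            sample_volume_to_surface(np.ones((5, 5, 5)), bad,
                                     phantom.meshes["L"])


class TestSubdivisionMeans:
    def test_planted_means_recovered_exactly(self, phantom):
        labels = phantom.labels["L"]
        vals = np.where(labels == "vAI", 1.0,
                        np.where(labels == "dAI", 2.0, 3.0))
        out = subdivision_means(vals, labels)
        assert dict(zip(out.subdivision, out.mean_rtop)) == {
            "vAI": 1.0, "dAI": 2.0, "PI": 3.0}

    def test_permutation_invariance(self, phantom):
        labels = phantom.labels["L"]
        rng = np.random.default_rng(0)
        vals = rng.standard_normal(labels.size)
        perm = rng.permutation(labels.size)
        a = subdivision_means(vals, labels)
        b = subdivision_means(vals[perm], labels[perm])
        pd.testing.assert_frame_equal(a, b)

    def test_random_mask_preserves_means(self, phantom):
        labels = phantom.labels["L"]
        rng = np.random.default_rng(1)
        vals = 2.0 + 0.1 * rng.standard_normal(labels.size)
        masked = vals.copy()
        masked[rng.uniform(size=labels.size) < 0.5] = np.nan
        a = subdivision_means(vals, labels)
        b = subdivision_means(masked, labels)
        np.testing.assert_allclose(a.mean_rtop, b.mean_rtop, atol=0.02)

    def test_empty_subdivision_named_in_error(self, phantom):
        labels = phantom.labels["L"].copy()
        labels[labels == "PI"] = "background"
        with pytest.raises(ValueError, match="PI"):
            subdivision_means(np.ones(labels.size), labels)


class TestLabelMerge:
    FINE = ["AVI", "MI", "FOP3", "AAIC", "PoI1", "PoI2", "Ig", "FOP2"]

    def test_tripartite_merge(self):
        fine = np.array(self.FINE * 3)
        out = merge_multimodal_labels(fine)
        assert set(out) == {"dAI", "vAI", "PI"}
        assert np.all(out[fine == "AAIC"] == "vAI")
        for name in ("AVI", "MI", "FOP3"):
            assert np.all(out[fine == name] == "dAI")
        for name in ("PoI1", "PoI2", "Ig", "FOP2"):
            assert np.all(out[fine == name] == "PI")

    def test_unlisted_label_becomes_background(self):
        fine = np.array(self.FINE + ["FOP4"])
        out = merge_multimodal_labels(fine)
        assert out[-1] == "background"

    def test_missing_required_label_listed(self):
        fine = np.array([l for l in self.FINE if l != "MI"])
        with pytest.raises(ValueError, match="MI"):
            merge_multimodal_labels(fine)


class TestAnova:
    def test_degrees_of_freedom_at_full_sample(self):
        """413 subjects x 3 subdivisions x 2 hemispheres gives the dfs
        (2, 824) for subdivision/interaction and (1, 412) for hemisphere."""
        table = make_parcel_table(413, seed=0)
        out = {a.effect: a for a in two_way_rm_anova(table)}
        assert (out["subdivision"].df_num, out["subdivision"].df_den) == (2, 824)
        assert (out["hemisphere"].df_num, out["hemisphere"].df_den) == (1, 412)
        assert (out["subdivision:hemisphere"].df_num,
                out["subdivision:hemisphere"].df_den) == (2, 824)

    def test_matches_pingouin_oracle(self):
        import pingouin as pg

        table = make_parcel_table(9, seed=5)
        mine = {a.effect: a for a in two_way_rm_anova(table)}
        ref = pg.rm_anova(data=table, dv="mean_rtop",
                          within=["subdivision", "hemisphere"],
                          subject="subject", detailed=True)
        ref = ref.set_index("Source")
        for effect, source in [("subdivision", "subdivision"),
                               ("hemisphere", "hemisphere"),
                               ("subdivision:hemisphere",
                                "subdivision * hemisphere")]:
            assert mine[effect].F == pytest.approx(ref.loc[source, "F"],
                                                   rel=1e-10)
            assert mine[effect].p == pytest.approx(ref.loc[source, "p_unc"],
                                                   rel=1e-8)

    def test_location_invariance(self):
        table = make_parcel_table(15, seed=2)
        shifted = table.assign(mean_rtop=table.mean_rtop + 17.3)
        f1 = [a.F for a in two_way_rm_anova(table)]
        f2 = [a.F for a in two_way_rm_anova(shifted)]
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_null_p_values_uniform(self):
        """With no planted effect, ANOVA p-values are uniform over
        replicates (Kolmogorov-Smirnov)."""
        rng = np.random.default_rng(7)
        pvals = []
        flat = np.ones((3, 2))
        for i in range(500):
            t = make_parcel_table(10, cell_means=flat, subject_sd=0.1,
                                  noise_sd=0.1, seed=10_000 + i)
            out = {a.effect: a for a in two_way_rm_anova(t)}
            pvals.append(out["subdivision"].p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_incomplete_table_names_subject(self):
        table = make_parcel_table(5, seed=0)
        broken = table[~((table.subject == 3) & (table.hemisphere == "R")
                         & (table.subdivision == "PI"))]
        with pytest.raises(ValueError, match="3"):
            two_way_rm_anova(broken)


class TestPosthoc:
    def test_planted_ordering_detected(self):
        """vAI < dAI < PI planted with n=100 -> all orderings significant."""
        table = make_parcel_table(100, seed=3)
        out = posthoc_paired_ttests(table)
        within = out[out.contrast.str.contains(":")
                     & out.contrast.str.startswith(("L", "R"))]
        assert (within.p_adjusted < 0.01).all()
        for _, row in out.iterrows():
            if "vAI vs dAI" in row.contrast or "dAI vs PI" in row.contrast:
                assert row.sign == -1  # listed first is the smaller

    def test_identical_columns_give_t0_p1(self):
        table = make_parcel_table(20, seed=4)
        # make hemispheres identical per subject: copy L into R
        wide = table.pivot_table(index="subject",
                                 columns=["subdivision", "hemisphere"],
                                 values="mean_rtop")
        for sub in ("vAI", "dAI", "PI"):
            wide[(sub, "R")] = wide[(sub, "L")]
        long = wide.stack([0, 1], future_stack=True).rename(
            "mean_rtop").reset_index()
        out = posthoc_paired_ttests(long)
        between = out[out.contrast.str.contains("L vs R")]
        assert (between.t == 0).all() and (between.p_adjusted == 1).all()

    def test_bonferroni_matches_definition(self):
        table = make_parcel_table(25, seed=5)
        out = posthoc_paired_ttests(table)
        m = len(out)
        np.testing.assert_allclose(out.p_adjusted,
                                   np.minimum(1.0, m * out.p_raw))

    def test_antisymmetric_under_contrast_swap(self):
        table = make_parcel_table(30, seed=6)
        out = posthoc_paired_ttests(table).set_index("contrast")
        relabel = {"vAI": "PI", "PI": "vAI", "dAI": "dAI"}
        swapped = posthoc_paired_ttests(
            table.assign(subdivision=table.subdivision.map(relabel))
        ).set_index("contrast")
        # swapping vAI<->PI flips the sign of the L: "PI vs vAI" contrast
        orig = out.loc["L: PI vs vAI"]
        flip = swapped.loc["L: PI vs vAI"]
        assert orig.t == pytest.approx(-flip.t)
        assert orig.sign == -flip.sign

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            posthoc_paired_ttests(make_parcel_table(2, seed=0))


class TestStability:
    def test_planted_unit_effect_stable_by_25(self):
        """A standardized paired difference of 1.0 reaches stable
        significance (p < 0.01 in >= 95% of subsamples) by N <= 25."""
        gap = 0.05 * np.sqrt(2)  # noise_sd 0.05 -> standardized diff 1.0
        means = np.array([[1.3, 1.3], [1.3 + gap, 1.3 + gap],
                          [1.3 + 2 * gap, 1.3 + 2 * gap]])
        table = make_parcel_table(200, cell_means=means, subject_sd=0.05,
                                  noise_sd=0.05, seed=8)
        out = stability_analysis(table, [10, 15, 20, 25], n_resamples=100,
                                 alpha=0.01, seed=1)
        within = out[out.contrast.str.contains("vs") &
                     out.contrast.str.startswith(("L", "R"))]
        assert (within.min_stable_n <= 25).all()

    def test_null_effect_never_stable(self):
        table = make_parcel_table(100, cell_means=np.ones((3, 2)),
                                  subject_sd=0.1, noise_sd=0.1, seed=9)
        out = stability_analysis(table, [10, 25, 50], n_resamples=50, seed=2)
        assert out.min_stable_n.isna().all()

    def test_seed_reproducibility(self):
        table = make_parcel_table(60, seed=10)
        a = stability_analysis(table, [10, 20], n_resamples=20, seed=3)
        b = stability_analysis(table, [10, 20], n_resamples=20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_fraction_monotone_in_n(self):
        table = make_parcel_table(120, seed=11)
        out = stability_analysis(table, [5, 10, 20, 40], n_resamples=200,
                                 seed=4)
        cols = [c for c in out.columns if c.startswith("frac_n")]
        fracs = out[cols].to_numpy()
        # monotone non-decreasing in expectation (small slack for resampling)
        assert np.all(np.diff(fracs, axis=1) >= -0.05)

    def test_validation_errors(self):
        table = make_parcel_table(20, seed=0)
        with pytest.raises(ValueError):
            stability_analysis(table, [10], n_resamples=5)
        with pytest.raises(ValueError):
            stability_analysis(table, [50], n_resamples=20)
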