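"""Segmentation, muscle discard, correlation images and group histograms."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import ftirct as ft
from ftirct.imaging import NORM_EPS, PatchError, SimilarityError
from ftirct.synth import CONNECTIVE, MUSCLE


@pytest.fixture(scope="module")
def clean_image():
    spec = ft.TissueImageSpec(rows=32, cols=32, n_fiber_seeds=4, seam_width=2,
                              degradation=ft.DegradationSpec(), seed=11)
    return ft.generate_tissue_image(spec)


@pytest.fixture(scope="module")
def clean_processed(clean_image):
    return ft.preprocess_pipeline(clean_image.cube, ft.SGParams()).data


@pytest.fixture(scope="module")
def oracle_patches(clean_image):
    return ft.patches_from_truth(clean_image.truth_labels, seed=3)


@pytest.fixture(scope="module")
def pure_processed_fp(clean_image):
    """Pure-component spectra preprocessed on the imaging grid."""
    axis = clean_image.cube.axis
    coll = ft.generate_pure_spectrum(ft.collagen_model(), axis)
    c4s = ft.generate_pure_spectrum(ft.c4s_model(), axis)
    labels = pd.DataFrame({"component": ["collagen_I", "C4S"]},
                          index=pd.Index(["coll", "c4s"], name="id"))
    sset = ft.SpectrumSet(axis, np.stack([coll.intensity, c4s.intensity]), labels)
    return ft.preprocess_pipeline(sset, ft.SGParams()).data


class TestCosineSimilarity:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, -1.0])
        assert ft.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert ft.cosine_similarity(np.array([1.0, 0.0]),
                                    np.array([0.0, 3.0])) == pytest.approx(0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=50)
        assert ft.cosine_similarity(u, 3.0 * u) == pytest.approx(1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(SimilarityError):
            ft.cosine_similarity(np.zeros(4), np.ones(4))


class TestSegmentation:
    def test_noiseless_image_perfect_accuracy(self, clean_image,
                                              clean_processed, oracle_patches):
        seg = ft.segment_tissue(clean_processed, oracle_patches)
        assert seg.accuracy(clean_image.truth_labels) == 1.0

    def test_segmentation_invariant_to_raw_scatter(self, clean_image,
                                                   oracle_patches):
        # per-pixel multiplicative scaling + quadratic baselines in raw
        # space must leave the label map unchanged once preprocessing runs
        clean = clean_image.cube
        deg_spec = ft.TissueImageSpec(rows=32, cols=32, n_fiber_seeds=4,
                                      seam_width=2,
                                      degradation=ft.DegradationSpec(
                                          mult_scale_sd=0.3,
                                          baseline_coeff_sd=(0.2, 0.1, 0.05)),
                                      seed=11)
        degraded = ft.generate_tissue_image(deg_spec)
        np.testing.assert_array_equal(degraded.truth_labels,
                                      clean_image.truth_labels)
        seg_clean = ft.segment_tissue(
            ft.preprocess_pipeline(clean, ft.SGParams()).data, oracle_patches)
        seg_deg = ft.segment_tissue(
            ft.preprocess_pipeline(degraded.cube, ft.SGParams()).data,
            oracle_patches)
        np.testing.assert_array_equal(seg_clean.labels, seg_deg.labels)

    def test_exact_tie_labels_muscle(self, fp_axis):
        # a cube whose every pixel equals both patch means ties exactly
        y = np.sin(fp_axis.values / 30.0) + 2.0
        cube = ft.HyperCube(fp_axis, np.tile(y, (4, 4, 1)))
        patches = ft.PatchSelection(
            muscle=(ft.Patch(0, 0, 1, 1),), connective=(ft.Patch(3, 3, 1, 1),))
        seg = ft.segment_tissue(cube, patches)
        assert (seg.labels == MUSCLE).all()
        assert (seg.margin == 0.0).all()

    def test_out_of_bounds_patch_rejected(self, clean_processed):
        patches = ft.PatchSelection(muscle=(ft.Patch(30, 30, 5, 5),),
                                    connective=(ft.Patch(0, 0, 2, 2),))
        with pytest.raises(PatchError):
            ft.segment_tissue(clean_processed, patches)

    def test_overlapping_class_patches_rejected(self, clean_processed):
        patches = ft.PatchSelection(muscle=(ft.Patch(0, 0, 3, 3),),
                                    connective=(ft.Patch(1, 1, 3, 3),))
        with pytest.raises(PatchError):
            ft.segment_tissue(clean_processed, patches)


class TestDiscardMuscle:
    def test_all_connective_truth_keeps_every_pixel(self, clean_processed):
        all_conn = np.full(clean_processed.shape, CONNECTIVE)
        seg = ft.SegmentationMap(all_conn, np.zeros(clean_processed.shape))
        out = ft.discard_muscle(clean_processed, seg)
        assert out.n == clean_processed.shape[0] * clean_processed.shape[1]

    def test_counts_match_truth_under_perfect_segmentation(
            self, clean_image, clean_processed, oracle_patches):
        seg = ft.segment_tissue(clean_processed, oracle_patches)
        out = ft.discard_muscle(clean_processed, seg)
        assert out.n == int((clean_image.truth_labels == CONNECTIVE).sum())

    def test_no_muscle_coordinates_leak_through(self, clean_processed,
                                                clean_image, oracle_patches):
        seg = ft.segment_tissue(clean_processed, oracle_patches)
        out = ft.discard_muscle(clean_processed, seg)
        for r, c in zip(out.labels["row"], out.labels["col"]):
            assert seg.labels[r, c] == CONNECTIVE

    def test_zero_connective_rejected(self, clean_processed):
        all_muscle = np.full(clean_processed.shape, MUSCLE)
        seg = ft.SegmentationMap(all_muscle, np.zeros(clean_processed.shape))
        with pytest.raises(ft.DataError):
            ft.discard_muscle(clean_processed, seg)


class TestCorrelationImages:
    def _connective(self, processed, truth):
        seg = ft.SegmentationMap(truth, np.zeros(truth.shape))
        return ft.discard_muscle(processed, seg)

    def test_pixel_equal_to_pure_correlates_one(self, pure_processed_fp):
        coll = pure_processed_fp.spectrum("coll")
        cube = ft.HyperCube(coll.axis, np.tile(coll.intensity, (2, 2, 1)))
        conn = self._connective(cube, np.full((2, 2), CONNECTIVE))
        img = ft.correlate_to_component(conn, coll, component="collagen_I")
        np.testing.assert_allclose(img.defined, 1.0, atol=1e-12)

    def test_affine_transform_invariance(self, pure_processed_fp):
        # Pearson is affine-invariant: 4x + offset correlates at exactly 1
        coll = pure_processed_fp.spectrum("coll")
        scaled = 4.0 * coll.intensity + 0.25
        cube = ft.HyperCube(coll.axis, np.tile(scaled, (2, 2, 1)))
        conn = self._connective(cube, np.full((2, 2), CONNECTIVE))
        img = ft.correlate_to_component(conn, coll, component="collagen_I")
        np.testing.assert_allclose(img.defined, 1.0, atol=1e-12)

    def test_correlation_increases_with_collagen_fraction(self, fp_axis):
        # noiseless connective pixels at fractions .6/.8/1.0: correlation to
        # the pure collagen derivative spectrum is strictly increasing
        fracs = [0.6, 0.8, 1.0]
        rows = np.stack([
            ft.connective_spectrum(f, fp_axis).intensity for f in fracs])
        cube = ft.HyperCube(fp_axis, rows.reshape(3, 1, -1))
        res = ft.preprocess_pipeline(cube, ft.SGParams()).data
        coll = ft.preprocess_pipeline(
            ft.HyperCube(fp_axis, ft.generate_pure_spectrum(
                ft.collagen_model(), fp_axis).intensity.reshape(1, 1, -1)),
            ft.SGParams()).data
        pure = ft.Spectrum(coll.axis, coll.cube[0, 0],
                           meta={"component": "collagen_I"})
        conn = self._connective(res, np.full((3, 1), CONNECTIVE))
        img = ft.correlate_to_component(conn, pure)
        vals = img.values[:, 0]
        assert vals[0] < vals[1] < vals[2]

    def test_spearman_against_truth_fraction(self, clean_image, clean_processed,
                                             pure_processed_fp):
        conn = self._connective(clean_processed, clean_image.truth_labels)
        img = ft.correlate_to_component(conn, pure_processed_fp.spectrum("coll"),
                                        component="collagen_I")
        rr = conn.labels["row"].to_numpy()
        cc = conn.labels["col"].to_numpy()
        rho = spearmanr(clean_image.collagen_fraction[rr, cc],
                        img.values[rr, cc]).statistic
        assert rho >= 0.99

    def test_constant_pixels_masked_and_counted(self, pure_processed_fp):
        coll = pure_processed_fp.spectrum("coll")
        cube_data = np.tile(coll.intensity, (2, 2, 1))
        cube_data[0, 0] = 0.7  # constant spectrum
        cube = ft.HyperCube(coll.axis, cube_data)
        conn = self._connective(cube, np.full((2, 2), CONNECTIVE))
        img = ft.correlate_to_component(conn, coll, component="collagen_I")
        assert img.n_masked_constant == 1
        assert not img.mask[0, 0]
        assert np.isnan(img.values[0, 0])
        assert img.mask.sum() == 3


class TestGroupComparison:
    def _image_from(self, values):
        vals = np.asarray(values, dtype=float)
        return ft.CorrelationImage(vals, np.isfinite(vals), "collagen_I",
                                   (800.0, 1800.0))

    def test_identical_groups_zero_difference(self):
        img = self._image_from([[0.5, 0.7], [np.nan, 0.9]])
        comp = ft.compare_groups({"LS": img, "HS": img}, bins=20)
        assert comp.mean_difference == 0.0

    def test_histogram_counts_conserve_pixels(self):
        rng = np.random.default_rng(6)
        ls = self._image_from(rng.uniform(-1, 1, size=(8, 8)))
        hs = self._image_from(rng.uniform(-1, 1, size=(5, 5)))
        comp = ft.compare_groups({"LS": ls, "HS": hs}, bins=50)
        assert comp.counts["LS"].sum() == comp.n_pixels["LS"] == 64
        assert comp.counts["HS"].sum() == comp.n_pixels["HS"] == 25
        np.testing.assert_array_equal(comp.bin_edges,
                                      np.linspace(-1, 1, 51))

    def test_diet_contrast_signs(self, pure_processed_fp):
        # HS seams are built collagen-richer than LS seams, so the mean
        # correlation difference HS-LS must be positive against collagen
        # and negative against C-4-S
        degr = ft.DegradationSpec(mult_scale_sd=0.2,
                                  baseline_coeff_sd=(0.1, 0.05, 0.02),
                                  noise_sd=0.005)
        images = {}
        for comp_name in ("collagen_I", "C4S"):
            images[comp_name] = {}
        for group, fcoll, seed in [("LS", 0.90, 21), ("HS", 0.93, 22)]:
            spec = ft.TissueImageSpec(rows=32, cols=32, n_fiber_seeds=4,
                                      seam_width=2, connective_composition=fcoll,
                                      group=group, degradation=degr, seed=seed)
            img = ft.generate_tissue_image(spec)
            proc = ft.preprocess_pipeline(img.cube, ft.SGParams()).data
            patches = ft.patches_from_truth(img.truth_labels, seed=5)
            seg = ft.segment_tissue(proc, patches)
            conn = ft.discard_muscle(proc, seg)
            for comp_name, rid in [("collagen_I", "coll"), ("C4S", "c4s")]:
                images[comp_name][group] = ft.correlate_to_component(
                    conn, pure_processed_fp.spectrum(rid), component=comp_name)
        coll_cmp = ft.compare_groups(images["collagen_I"])
        c4s_cmp = ft.compare_groups(images["C4S"])
        assert coll_cmp.mean_difference > 0
        assert c4s_cmp.mean_difference < 0

    def test_wrong_group_names_rejected(self):
        img = self._image_from([[0.1]])
        with pytest.raises(ft.ParameterError):
            ft.compare_groups({"A": img, "B": img})
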