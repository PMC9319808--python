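"""Generator contracts: determinism, class signal, bias injection,
slide-disjoint splits and label/source orthogonality."""

import numpy as np
import pytest
from scipy import ndimage, stats

from xbias import synthgen as sg

P64 = sg.GenParams(tile_size=64)


def test_tile_generation_is_deterministic_to_the_byte():
    a = sg.generate_tile("positive", "A", 1, {"nuclei_dense"}, seed=7, params=P64)
    b = sg.generate_tile("positive", "A", 1, {"nuclei_dense"}, seed=7, params=P64)
    assert np.array_equal(a.pixels, b.pixels)
    c = sg.generate_tile("positive", "A", 1, {"nuclei_dense"}, seed=8, params=P64)
    assert not np.array_equal(a.pixels, c.pixels)


def test_white_area_constraint_and_background_rejection():
    tile = sg.generate_tile("negative", "B", 3, {"nuclei_sparse", "collagen"},
                            seed=5, params=P64)
    assert sg.white_fraction(tile.pixels) <= 0.10
    with pytest.raises(sg.WhiteFractionError):
        sg.generate_tile("negative", "A", 1, {"background"}, seed=1, params=P64)


def test_unknown_stratum_and_empty_strata_rejected():
    with pytest.raises(sg.ConfigurationError):
        sg.generate_tile("positive", "A", 1, {"nope"}, seed=1, params=P64)
    with pytest.raises(sg.ConfigurationError):
        sg.generate_tile("positive", "A", 1, set(), seed=1, params=P64)


def test_positive_class_has_more_and_larger_nuclei():
    """Blob-count oracle: connected components on the generator's own
    nucleus mask, 200 tiles per class across many virtual slides."""
    counts = {"positive": [], "negative": []}
    sizes = {"positive": [], "negative": []}
    for label, stratum in (("positive", "nuclei_dense"),
                           ("negative", "nuclei_sparse")):
        for i in range(200):
            t = sg.generate_tile(label, "A", i % 25, {stratum}, seed=1000 + i,
                                 params=P64)
            _, n = ndimage.label(t.nucleus_mask)
            counts[label].append(n)
            if n:
                sizes[label].append(t.nucleus_mask.sum() / n)
    assert np.mean(counts["positive"]) > np.mean(counts["negative"])
    assert np.mean(sizes["positive"]) > np.mean(sizes["negative"])


def test_source_shift_is_affine_and_brightening():
    tile = sg.generate_tile("negative", "A", 2, {"nuclei_sparse"}, seed=3,
                            params=P64)
    ident = sg.apply_source_shift(tile.pixels, sg.SourceShift.identity())
    assert np.array_equal(ident, tile.pixels)
    plus20 = sg.apply_source_shift(tile.pixels,
                                   sg.SourceShift((1, 1, 1), (20, 20, 20)))
    expect = np.minimum(tile.pixels.astype(int) + 20, 255)
    assert np.array_equal(plus20, expect)
    shifted = sg.apply_source_shift(tile.pixels, sg.SourceShift.default())
    assert shifted.mean() > tile.pixels.mean()  # brighter regime
    assert shifted.std(axis=(0, 1)).mean() < tile.pixels.std(axis=(0, 1)).mean()


def test_marker_injection_exact_region_and_locality():
    tile = sg.generate_tile("positive", "A", 1, {"nuclei_dense"}, seed=9,
                            params=sg.GenParams(tile_size=96))
    marker = sg.MarkerSpec(size=8, offset=(4, 4), color=(255, 0, 0))
    out = sg.inject_marker(tile, marker)
    assert out.has_marker
    assert np.all(out.pixels[4:12, 4:12] == (255, 0, 0))
    mm = sg.marker_mask(96, marker)
    assert np.abs(out.pixels[~mm].astype(int)
                  - tile.pixels[~mm].astype(int)).sum() == 0
    # size-0 marker: identity, flag stays false
    none = sg.inject_marker(tile, sg.MarkerSpec(0, (4, 4)))
    assert not none.has_marker
    assert np.array_equal(none.pixels, tile.pixels)
    with pytest.raises(sg.ConfigurationError):
        sg.inject_marker(tile, sg.MarkerSpec(size=50, offset=(60, 60)))
    neg = sg.generate_tile("negative", "A", 1, {"nuclei_sparse"}, seed=9,
                           params=sg.GenParams(tile_size=96))
    with pytest.raises(sg.ConfigurationError):
        sg.inject_marker(neg, marker)


def test_splits_are_slide_disjoint_and_near_two_thirds():
    plan = sg.plan_dataset(sg.BiasConfig("none"), n_slides=30,
                           tiles_per_slide=4, seed=2)
    slides = {s: set(g["slide_id"]) for s, g in plan.groupby("split")}
    assert not slides["train"] & slides["val"]
    assert not slides["train"] & slides["test"]
    assert not slides["val"] & slides["test"]
    assert len(slides["train"]) == 20 and len(slides["val"]) == 5


def test_class_ratio_bias_yields_about_two_to_one():
    """600 candidate training tiles, halved positive admission."""
    plan = sg.plan_dataset(sg.BiasConfig("class_ratio", ratio_reduction=0.5),
                           n_slides=30, tiles_per_slide=30, seed=4)
    train = plan[plan.split == "train"]
    ratio = (train.label == "negative").sum() / (train.label == "positive").sum()
    assert 1.7 <= ratio <= 2.3
    # validation/test untouched: roughly balanced
    test = plan[plan.split == "test"]
    tr = (test.label == "negative").sum() / (test.label == "positive").sum()
    assert 0.6 <= tr <= 1.6


def test_class_correlated_markers_on_all_positives_only():
    plan = sg.plan_dataset(sg.BiasConfig("class_correlated"), 12, 10, seed=5)
    assert (plan[plan.label == "positive"].marker).all()
    assert (~plan[plan.label == "negative"].marker).all()


def test_sampling_bias_removes_stratum_from_train_negatives_only():
    plan = sg.plan_dataset(sg.BiasConfig("sampling"), 18, 30, seed=6)
    train_neg = plan[(plan.split == "train") & (plan.label == "negative")]
    assert not train_neg.strata.str.contains("collagen").any()
    test_neg = plan[(plan.split == "test") & (plan.label == "negative")]
    assert test_neg.strata.str.contains("collagen").sum() > 0


def test_measurement_bias_confounds_label_with_source_in_all_splits():
    plan = sg.plan_dataset(sg.BiasConfig("measurement"), 18, 6, seed=7)
    for _, row in plan.iterrows():
        assert row.source == ("A" if row.label == "positive" else "B")
    # both classes present in every split
    for s, g in plan.groupby("split"):
        assert set(g.label) == {"positive", "negative"}


def test_unbiased_label_independent_of_source_chi_square():
    """Label/source orthogonality under kind='none': chi-square p > 0.01
    in at least 19 of 20 seeds."""
    ok = 0
    for seed in range(20):
        plan = sg.plan_dataset(sg.BiasConfig("none"), 18, 20, seed=seed)
        ct = np.asarray(plan.groupby(["label", "source"]).size().unstack(fill_value=0))
        p = stats.chi2_contingency(ct).pvalue
        ok += p > 0.01
    assert ok >= 19


def test_dataset_build_and_roundtrip(tmp_path):
    ds = sg.build_dataset(sg.BiasConfig("class_correlated"), 6, 3, seed=8,
                          params=P64)
    assert len(ds.manifest) == len(ds.train) + len(ds.val) + len(ds.test)
    sg.save_dataset(ds, str(tmp_path))
    back = sg.load_dataset(str(tmp_path))
    assert len(back.train) == len(ds.train)
    orig = {t.tile_id: t for t in ds.test}
    for t in back.test:
        assert np.array_equal(t.pixels, orig[t.tile_id].pixels)
        assert t.label == orig[t.tile_id].label


def test_identical_config_and_seed_reproduce_identical_dataset():
    a = sg.build_dataset(sg.BiasConfig("measurement"), 6, 2, seed=9, params=P64)
    b = sg.build_dataset(sg.BiasConfig("measurement"), 6, 2, seed=9, params=P64)
    assert a.manifest.equals(b.manifest)
    for ta, tb in zip(a.train, b.train):
        assert np.array_equal(ta.pixels, tb.pixels)


def test_infeasible_configs_raise():
    with pytest.raises(sg.ConfigurationError):
        sg.BiasConfig("sprinkling")
    with pytest.raises(sg.ConfigurationError):
        sg.BiasConfig("class_ratio", ratio_reduction=1.5)
    with pytest.raises(sg.ConfigurationError):
        sg.plan_dataset(sg.BiasConfig("sampling", excluded_stratum="nuclei_sparse"),
                        12, 4, seed=0)
    with pytest.raises(sg.ConfigurationError):
        sg.plan_dataset(sg.BiasConfig("none"), n_slides=4, tiles_per_slide=4)
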