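"""Difference maps, per-pixel Wilcoxon statistics, hotspots, ranking."""

import numpy as np
import pandas as pd
import pytest

from pathcam.io import SampleAnnotations
from pathcam.key_pathways import (DifferenceMapSet, Hotspot, PixelTestResult,
                                  bonferroni_adjust, difference_maps,
                                  find_hotspots, identify_key_pathways,
                                  pixelwise_test, rank_pathways,
                                  wilcoxon_rank_sum)
from pathcam.xgradcam import ActivationMap


def _maps(raw, class_index, ids=None):
    raw = np.asarray(raw, float)
    n = raw.shape[0]
    ids = ids or [f"S{i}" for i in range(n)]
    lo = raw.min(axis=(1, 2), keepdims=True)
    hi = raw.max(axis=(1, 2), keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return ActivationMap(ids, class_index, np.zeros((n, 1)), raw,
                         np.where(hi - lo > 0, (raw - lo) / span, 0.0))


def _ann(labels):
    labels = np.asarray(labels, int)
    return SampleAnnotations([f"S{i}" for i in range(len(labels))], labels)


def test_equal_class_maps_give_zero_difference():
    raw = np.random.default_rng(0).random((4, 3, 2))
    d = difference_maps(_maps(raw, 1), _maps(raw, 0), _ann([0, 1, 0, 1]),
                        [f"p{i}" for i in range(3)], ["om"], 2)
    np.testing.assert_array_equal(d.maps, 0.0)


def test_difference_maps_bounded_and_partitioned():
    rng = np.random.default_rng(1)
    d = difference_maps(_maps(rng.random((6, 4, 2)), 1),
                        _maps(rng.random((6, 4, 2)), 0),
                        _ann([1, 0, 0, 1, 0, 0]),
                        [f"p{i}" for i in range(4)], ["om"], 2)
    assert d.maps.min() >= 0 and d.maps.max() <= 1
    assert d.group(1).shape[0] == 2 and d.group(0).shape[0] == 4


def test_hand_filled_pair_exact_absolute_difference():
    """With per-map normalization disabled scaling effects, a hand pair in
    [0,1] sharing min/max gives exactly |a - b|."""
    a = np.array([[[0.0, 1.0], [0.5, 0.25]]])
    b = np.array([[[1.0, 0.0], [0.5, 0.75]]])
    d = difference_maps(_maps(a, 1), _maps(b, 0), _ann([1]),
                        ["p0", "p1"], ["om"], 1, shared_scale=True)
    np.testing.assert_allclose(d.maps[0], np.abs(a - b)[0], atol=1e-12)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shapes differ"):
        difference_maps(_maps(np.zeros((2, 3, 2)), 1),
                        _maps(np.zeros((2, 4, 2)), 0), _ann([0, 1]),
                        ["p"] * 3, ["om"], 2)


def test_wilcoxon_exact_enumeration_small_sample():
    # all C(6,3)=20 rank splits; {1,2,3} vs {4,5,6} is one of the two
    # extreme tables -> two-sided p = 2/20 = 0.1
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_identical_groups_p_one():
    assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0


def test_wilcoxon_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        wilcoxon_rank_sum([], [1.0])


def test_wilcoxon_large_sample_matches_permutation_oracle():
    """The tie-corrected normal approximation must agree with a 20,000-draw
    permutation distribution of the rank-sum within 0.01."""
    rng = np.random.default_rng(42)
    x = rng.standard_normal(25) + 0.5
    y = rng.standard_normal(30)
    p_pkg = wilcoxon_rank_sum(x, y)

    from scipy.stats import rankdata
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    obs = ranks[:len(x)].sum()
    mu = len(x) * (len(combined) + 1) / 2
    count = 0
    draws = 20000
    for _ in range(draws):
        perm = rng.permutation(ranks)
        if abs(perm[:len(x)].sum() - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    assert p_pkg == pytest.approx(count / draws, abs=0.01)


def _diffset(maps, labels, q=1):
    maps = np.asarray(maps, float)
    P, W = maps.shape[1:]
    return DifferenceMapSet([f"S{i}" for i in range(maps.shape[0])], maps,
                            np.asarray(labels), [f"p{i}" for i in range(P)],
                            [f"om{c}" for c in range(W // q)], q)


def test_identical_maps_give_all_p_one():
    maps = np.tile(np.random.default_rng(2).random((1, 5, 2)), (20, 1, 1))
    res = pixelwise_test(_diffset(maps, [0, 1] * 10, q=2))
    np.testing.assert_array_equal(res.raw_p, 1.0)
    assert res.degenerate.all()


def test_planted_pixel_attains_minimum_p():
    rng = np.random.default_rng(3)
    labels = np.array([0] * 30 + [1] * 30)
    maps = rng.random((60, 8, 2))
    maps[labels == 1, 3, 1] += 2.0
    res = pixelwise_test(_diffset(maps, labels, q=2))
    assert np.unravel_index(res.raw_p.argmin(), res.raw_p.shape) == (3, 1)


def test_p_value_count_covers_full_grid():
    rng = np.random.default_rng(4)
    res = pixelwise_test(_diffset(rng.random((10, 6, 4)), [0, 1] * 5, q=2))
    assert res.raw_p.shape == (6, 4)
    assert res.n_tests == 24


def test_bonferroni_multiplication_and_cap():
    raw = np.array([[0.0002, 0.5]])
    np.testing.assert_allclose(bonferroni_adjust(raw, 100), [[0.02, 1.0]])
    assert bonferroni_adjust(np.array([0.5]), 10)[0] == 1.0


def test_bonferroni_is_order_preserving():
    """Monotone map: sorting then adjusting equals adjusting then sorting
    (the cap at 1 merges only the top of the ordering, never reorders)."""
    rng = np.random.default_rng(5)
    raw = rng.random(50)
    adj = bonferroni_adjust(raw, 50)
    np.testing.assert_array_equal(np.sort(adj),
                                  bonferroni_adjust(np.sort(raw), 50))


def test_hotspot_connectivity_hand_trace():
    """A 2x2 significant block plus one isolated pixel: with min_size=2
    only the block survives, as one 4-connected component of size 4."""
    adj = np.ones((6, 4))
    adj[1:3, 0:2] = 1e-5      # 2x2 block
    adj[5, 3] = 1e-5          # isolated pixel
    spots = find_hotspots(adj, alpha_sig=0.001, min_size=2, q=4)
    assert len(spots) == 1
    assert spots[0].size == 4
    assert sorted(spots[0].pixels) == [(1, 0), (1, 1), (2, 0), (2, 1)]


def test_hotspots_partition_significant_pixels():
    rng = np.random.default_rng(6)
    adj = np.where(rng.random((10, 4)) < 0.2, 1e-5, 1.0)
    spots = find_hotspots(adj, 0.001, 1, q=2)
    covered = sorted((h.omics_index * 2 + c_, r)
                     for h in spots for r, c_ in h.pixels)
    expected = sorted((c_, r) for r, c_ in zip(*np.nonzero(adj < 0.001)))
    assert len(covered) == int((adj < 0.001).sum())


def test_no_significant_pixels_no_hotspots_empty_table():
    res = PixelTestResult(np.ones((4, 2)), np.ones((4, 2)),
                          np.zeros((4, 2), bool), 8,
                          [f"p{i}" for i in range(4)], ["om"], 2)
    assert find_hotspots(res.adjusted_p, 0.001, 1, 2) == []
    assert rank_pathways(res).empty


def test_hotspots_do_not_cross_omics_channel_blocks():
    adj = np.ones((4, 4))
    adj[1, 1] = adj[1, 2] = 1e-6   # adjacent columns but different channels
    spots = find_hotspots(adj, 0.001, 1, q=2)
    assert len(spots) == 2
    assert {h.omics_index for h in spots} == {0, 1}


def test_rank_table_blank_rule_and_row_order():
    adj = np.ones((5, 4))
    adj[3, 0] = 0.0001   # om1 PC1
    adj[3, 1] = 0.0008   # om1 PC2
    adj[1, 3] = 0.0002   # om2 PC2 only
    res = PixelTestResult(adj.copy(), adj, np.zeros_like(adj, bool), 20,
                          [f"p{i}" for i in range(5)], ["om1", "om2"], 2)
    table = rank_pathways(res)
    assert list(table["row"]) == [2, 4]          # sorted by image row
    r4 = table[table["row"] == 4].iloc[0]
    assert r4["om1_PC1"] == pytest.approx(0.0001)
    assert r4["om1_PC2"] == pytest.approx(0.0008)
    assert pd.isna(r4["om2_PC1"]) and pd.isna(r4["om2_PC2"])
    r2 = table[table["row"] == 2].iloc[0]
    assert pd.isna(r2["om1_PC1"]) and r2["om2_PC2"] == pytest.approx(0.0002)


def test_null_calibration_family_wise_error(small_cohort, small_images,
                                            small_trained):
    """With labels permuted independently of the maps, Bonferroni keeps the
    family-wise rate of any significant pixel at alpha=0.05 conservative."""
    _, _, images = small_images
    diffs, _ = identify_key_pathways(small_trained, images,
                                     small_cohort.annotations)
    rng = np.random.default_rng(0)
    hits = 0
    reps = 200
    for _ in range(reps):
        perm = rng.permutation(diffs.labels)
        ds = DifferenceMapSet(diffs.sample_ids, diffs.maps, perm,
                              diffs.pathway_order, diffs.omics_names, diffs.q)
        res = pixelwise_test(ds)
        hits += bool((res.adjusted_p < 0.05).any())
    assert hits / reps <= 0.07


def test_planted_pathways_recovered_in_ranked_table(small_cohort,
                                                    small_images,
                                                    small_trained):
    """The planted pathways must own the smallest minimum adjusted p-values
    and appear in the ranked table."""
    cohort = small_cohort
    _, _, images = small_images
    _, res = identify_key_pathways(small_trained, images, cohort.annotations)
    planted_rows = {images.pathway_order.index(f"PATHWAY_{i:04d}")
                    for i in cohort.ground_truth["planted"]}
    minp = res.adjusted_p.min(axis=1)
    top = set(np.argsort(minp)[:len(planted_rows)].tolist())
    assert top == planted_rows
    table_rows = {r - 1 for r in res.table["row"]}
    assert planted_rows <= table_rows
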