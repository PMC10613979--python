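"""Patch library construction, splits and augmentation."""

import numpy as np
import pytest

from hsin.exceptions import (
    InsufficientCanopyError,
    InvalidParameterError,
)
from hsin.patches import (
    PatchSet,
    SplitSpec,
    augment_flip,
    augment_rotate,
    extract_patches,
    quadrant_split_array,
    split_dataset,
)


def make_patchset(n_per_class, classes=("HNHP", "HNLP", "LNHP", "LNLP"),
                  shape=(3, 3, 2), seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * len(classes)
    data = rng.random((n,) + shape).astype(np.float32)
    labels = np.repeat(classes, n_per_class)
    prov = [(f"scene-{i % 7}", i % 4, 0, 0, "") for i in range(n)]
    return PatchSet(data, labels, prov)


class TestQuadrantSplit:
    def test_even_dimensions(self):
        tiles = quadrant_split_array(np.zeros((30, 30, 5)))
        assert all(t.shape == (15, 15, 5) for t in tiles)

    def test_odd_dimensions_first_takes_extra(self):
        tiles = quadrant_split_array(np.zeros((31, 31)))
        assert [t.shape for t in tiles] == [(16, 16), (16, 15), (15, 16), (15, 15)]

    def test_reassembly_is_exact(self, rng):
        arr = rng.random((21, 33, 3))
        tl, tr, bl, br = quadrant_split_array(arr)
        top = np.concatenate([tl, tr], axis=1)
        bottom = np.concatenate([bl, br], axis=1)
        np.testing.assert_array_equal(np.concatenate([top, bottom], axis=0), arr)


class TestExtractPatches:
    def test_nonoverlapping_supply_and_relaxation(self, rng):
        """A full-canopy 60x60 segment holds 16 non-overlapping 15x15
        positions; requesting 20 errors, then succeeds with overlap."""
        seg = rng.random((60, 60, 4)).astype(np.float32)
        mask = np.ones((60, 60), bool)
        with pytest.raises(InsufficientCanopyError) as err:
            extract_patches(seg, mask, n_patches=20, rng=rng)
        assert err.value.n_valid == 16
        ps = extract_patches(seg, mask, n_patches=20, rng=rng, relax_overlap=True)
        assert len(ps) == 20
        assert all(p[4] == "overlap-relaxed" for p in ps.provenance)

    def test_all_background_errors_with_zero_count(self, rng):
        seg = rng.random((30, 30, 2)).astype(np.float32)
        with pytest.raises(InsufficientCanopyError) as err:
            extract_patches(seg, np.zeros((30, 30), bool), n_patches=5, rng=rng)
        assert err.value.n_valid == 0

    def test_patches_meet_plant_fraction(self, rng):
        mask = np.zeros((45, 45), bool)
        mask[:30, :] = True
        seg = np.broadcast_to(mask[..., None], (45, 45, 3)).astype(np.float32)
        ps = extract_patches(seg, mask, n_patches=3, min_plant_fraction=0.9,
                             rng=rng)
        assert (ps.data.reshape(3, -1, 3).mean(axis=(1, 2)) >= 0.9).all()

    def test_eighty_patches_per_scene(self, tiny_dataset):
        """20 patches x 4 quadrants = 80 patches from one scene."""
        from hsin.pipeline import PipelineConfig, scene_to_patches

        cfg = PipelineConfig(patches_per_quadrant=20)
        ps = scene_to_patches(tiny_dataset[0], cfg, np.random.default_rng(0))
        assert len(ps) == 80
        assert set(p[1] for p in ps.provenance) == {0, 1, 2, 3}


class TestSplitDataset:
    def test_table_arithmetic_2800_per_class(self):
        """2800 patches per class split 3:1 then 80:20 -> 1680/420/700."""
        ps = make_patchset(2800, shape=(1, 1, 1))
        tr, va, te = split_dataset(ps, SplitSpec(seed=0))
        for s, n in ((tr, 1680), (va, 420), (te, 700)):
            counts = s.class_counts()
            assert set(counts.values()) == {n}

    def test_small_class_floor_rounding(self):
        """8 per class: test=floor(8/4)=2, val=floor(6/5)=1, train=5."""
        ps = make_patchset(8)
        tr, va, te = split_dataset(ps, SplitSpec(seed=1))
        assert set(tr.class_counts().values()) == {5}
        assert set(va.class_counts().values()) == {1}
        assert set(te.class_counts().values()) == {2}

    def test_membership_disjoint_and_complete(self):
        ps = make_patchset(40)
        tr, va, te = split_dataset(ps, SplitSpec(seed=2))
        ids = [id_ for s in (tr, va, te) for id_ in
               (tuple(p) + (lbl,) for p, lbl in zip(s.provenance, s.labels))]
        assert len(tr) + len(va) + len(te) == len(ps)

    def test_deterministic_under_seed(self):
        ps = make_patchset(24)
        a = split_dataset(ps, SplitSpec(seed=9))
        b = split_dataset(ps, SplitSpec(seed=9))
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.data, s2.data)

    def test_scene_grouping_keeps_scenes_whole(self):
        ps = make_patchset(35)
        tr, va, te = split_dataset(ps, SplitSpec(seed=3, group_by_scene=True))
        for label in np.unique(ps.labels):
            sets = []
            for s in (tr, va, te):
                sets.append(
                    {p[0] for p, l in zip(s.provenance, s.labels) if l == label}
                )
            assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InvalidParameterError):
            SplitSpec(test_fraction=1.2)


class TestAugment:
    def test_rotation_count_arithmetic(self, rng):
        ps = make_patchset(250, classes=("a",), shape=(7, 7, 2))  # 250 patches
        out = augment_rotate(ps, fraction=0.4, rng=rng)
        assert len(out) == 350

    def test_fraction_zero_is_identity(self, rng):
        ps = make_patchset(10, classes=("a",))
        assert augment_rotate(ps, fraction=0.0, rng=rng) is ps

    def test_zero_angle_rotation_is_identity(self, rng):
        ps = make_patchset(5, classes=("a",), shape=(9, 9, 3))
        out = augment_rotate(ps, fraction=1.0, angle_range=(0.0, 0.0), rng=rng)
        orig, aug = out.data[:5], out.data[5:]
        # nearest-neighbour with angle 0 maps every pixel to itself
        order = [p[:4] for p in out.provenance[5:]]
        np.testing.assert_allclose(sorted(map(tuple, aug.reshape(5, -1))),
                                   sorted(map(tuple, orig.reshape(5, -1))))

    def test_labels_preserved_under_rotation(self, rng):
        ps = make_patchset(20, shape=(9, 9, 2))
        out = augment_rotate(ps, fraction=0.5, rng=rng)
        assert set(np.unique(out.labels)) == set(np.unique(ps.labels))

    def test_double_flip_is_identity(self, rng):
        ps = make_patchset(4, classes=("a",), shape=(6, 6, 2))
        once = np.flip(ps.data, axis=2)
        np.testing.assert_array_equal(np.flip(once, axis=2), ps.data)

    def test_flip_preserves_band_multisets(self, rng):
        ps = make_patchset(6, classes=("a",), shape=(5, 5, 3))
        out = augment_flip(ps, fraction=1.0, direction="horizontal", rng=rng)
        assert len(out) == 12
        # flipped copies are a permutation of the originals; per-band pixel
        # multisets over the flipped block match the original block exactly
        for b in range(3):
            np.testing.assert_array_equal(
                np.sort(ps.data[..., b].ravel()),
                np.sort(out.data[6:][..., b].ravel()),
            )

    def test_flip_both_adds_two_copies(self, rng):
        ps = make_patchset(10, classes=("a",))
        assert len(augment_flip(ps, fraction=1.0, direction="both", rng=rng)) == 30
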