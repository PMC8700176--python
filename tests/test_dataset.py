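"""Patch extraction arithmetic, normalization, and the phantom-level split."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prcpet.dataset import (PairedVolumes, extract_patch_grid,
                            grid_positions, make_splits, normalize_volume)
from conftest import make_image


def _pair(shape=(64, 64, 3), seed=0, scale=500.0):
    rng = np.random.default_rng(seed)
    ga = make_image(rng.random(shape) * scale, provenance="ga68", cid="a")
    gm = make_image(rng.random(shape) * scale, provenance="gamma", cid="a")
    return ga, gm


class TestNormalize:
    def test_max_becomes_one_and_scale_recorded(self):
        img = make_image(np.full((4, 4, 2), 125.0))
        out, scale = normalize_volume(img)
        assert scale == 125.0
        assert out.data.max() == 1.0

    def test_zero_image_unchanged(self):
        img = make_image(np.zeros((4, 4, 2)))
        out, scale = normalize_volume(img)
        assert scale == 1.0
        assert np.all(out.data == 0)

    def test_round_trip(self):
        img = make_image(np.random.default_rng(0).random((6, 6, 2)) * 77)
        out, scale = normalize_volume(img)
        assert np.allclose(out.data * scale, img.data, rtol=1e-6)


class TestPatchGrid:
    @pytest.mark.parametrize("extent,stride,expected", [
        (250, 14, 16), (250, 21, 11), (128, 14, 7), (32, 14, 1)])
    def test_position_counts_match_closed_form(self, extent, stride, expected):
        pos = grid_positions(extent, 32, stride)
        assert len(pos) == expected
        # brute-force enumeration oracle
        brute = [s for s in range(extent) if s % stride == 0
                 and s + 32 <= extent]
        assert list(pos) == brute

    @given(extent=st.integers(32, 300), stride=st.integers(1, 40))
    @settings(max_examples=60, deadline=None)
    def test_positions_always_fit(self, extent, stride):
        pos = grid_positions(extent, 32, stride)
        assert len(pos) == (extent - 32) // stride + 1
        assert pos[-1] + 32 <= extent

    @pytest.mark.parametrize("label_size,offset", [(20, 6), (18, 7)])
    def test_label_is_exact_center_crop(self, label_size, offset):
        ga, gm = _pair()
        pps = extract_patch_grid(ga, gm, stride=14, label_size=label_size,
                                 drop_empty=False)
        i = 3
        vol, z, r, c = pps.provenance[i]
        expect = gm.data[r + offset:r + offset + label_size,
                         c + offset:c + offset + label_size, z]
        assert np.array_equal(pps.labels[i], expect)
        assert np.array_equal(pps.inputs[i], ga.data[r:r + 32, c:c + 32, z])

    def test_empty_patches_dropped(self):
        ga, gm = _pair()
        ga.data[:32, :, :] = 0.0   # a fully dark strip
        full = extract_patch_grid(ga, gm, stride=32, label_size=18,
                                  drop_empty=False)
        kept = extract_patch_grid(ga, gm, stride=32, label_size=18,
                                  drop_empty=True)
        assert len(kept) < len(full)
        assert all(p.max() > 0 for p in kept.inputs)

    def test_small_image_rejected(self):
        ga, gm = _pair(shape=(20, 20, 1))
        with pytest.raises(ValueError):
            extract_patch_grid(ga, gm, stride=14, label_size=18)

    def test_reassembly_tiles_exactly_once(self):
        # stride == label size -> pasted label crops tile the valid region
        ga, gm = _pair(shape=(32 + 20 * 3, 32 + 20 * 3, 1))
        pps = extract_patch_grid(ga, gm, stride=20, label_size=20,
                                 drop_empty=False)
        H = ga.data.shape[0]
        canvas = np.zeros((H, H))
        hits = np.zeros((H, H))
        for patch, (vol, z, r, c) in zip(pps.labels, pps.provenance):
            canvas[r + 6:r + 26, c + 6:c + 26] = patch
            hits[r + 6:r + 26, c + 6:c + 26] += 1
        interior = hits[6:H - 6, 6:H - 6]
        assert np.all(interior == 1)
        assert np.array_equal(canvas[6:H - 6, 6:H - 6],
                              gm.data[6:H - 6, 6:H - 6, 0])


class TestSplits:
    def _volumes(self, n_brain=5):
        vols = []
        rng = np.random.default_rng(0)
        for i in range(n_brain):
            ga = make_image(rng.random((48, 48, 2)), provenance="ga68", cid=f"brain{i:02d}")
            gm = make_image(rng.random((48, 48, 2)), provenance="gamma", cid=f"brain{i:02d}")
            vols.append(PairedVolumes(f"brain{i:02d}", "brain", None, ga, gm))
        for tbr in (0, 2, 4, 5, 8, 10, 16, 20):
            cid = f"rod5_tbr{tbr}"
            ga = make_image(rng.random((48, 48, 2)), provenance="ga68", cid=cid)
            gm = make_image(rng.random((48, 48, 2)), provenance="gamma", cid=cid)
            vols.append(PairedVolumes(cid, "rod5", float(tbr), ga, gm))
        ga = make_image(rng.random((48, 48, 2)), provenance="ga68", cid="sphere1")
        gm = make_image(rng.random((48, 48, 2)), provenance="gamma", cid="sphere1")
        vols.append(PairedVolumes("sphere1", "sphere1", None, ga, gm))
        return vols

    def test_split_membership_and_strides(self):
        train, test = make_splits(self._volumes())
        assert train.split == "train" and train.stride == 14
        assert test.split == "test" and test.stride == 21
        assert set(train.config_ids) & set(test.config_ids) == set()
        train_tbrs = {c for c in train.config_ids if c.startswith("rod5")}
        assert train_tbrs == {"rod5_tbr0", "rod5_tbr4", "rod5_tbr5",
                              "rod5_tbr8"}
        test_tbrs = {c for c in test.config_ids if c.startswith("rod5")}
        assert test_tbrs == {"rod5_tbr2", "rod5_tbr10", "rod5_tbr16",
                             "rod5_tbr20"}
        # evaluation-only phantoms never patched
        assert "sphere1" not in train.config_ids + test.config_ids

    def test_patch_values_unit_interval(self):
        train, test = make_splits(self._volumes())
        for pps in (train, test):
            assert pps.inputs.min() >= 0 and pps.inputs.max() <= 1.0
            assert pps.labels.min() >= 0 and pps.labels.max() <= 1.0

    def test_deterministic(self):
        t1, _ = make_splits(self._volumes())
        t2, _ = make_splits(self._volumes())
        assert np.array_equal(t1.inputs, t2.inputs)
        assert np.array_equal(t1.provenance, t2.provenance)
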