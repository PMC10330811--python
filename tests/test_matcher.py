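import numpy as np
import pytest

from ceustrack.matcher import LearnedBackend, NCCBackend, get_backend
from ceustrack.nn import Backbone

from conftest import textured_frame


def brute_force_ncc(search, templ):
    """Independent oracle: zero-mean unit-norm correlation per placement."""
    th, tw = templ.shape
    t = templ - templ.mean()
    tn = np.sqrt((t**2).sum())
    H, W = search.shape
    out = np.zeros((H - th + 1, W - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            w = search[i : i + th, j : j + tw]
            wc = w - w.mean()
            wn = np.sqrt((wc**2).sum())
            out[i, j] = (t * wc).sum() / (tn * wn) if tn > 0 and wn > 0 else 0.0
    return out


class TestNCCBackend:
    def test_embed_is_identity_with_stride_one(self):
        be = NCCBackend()
        patch = textured_frame((20, 24), seed=1)
        feat = be.embed(patch)
        assert feat.stride == 1 and feat.offset == 0.0
        assert np.array_equal(feat.data[0], patch)

    def test_exact_copy_peaks_at_one(self):
        be = NCCBackend()
        search = textured_frame((60, 80), seed=2)
        templ = search[20:35, 30:49].copy()
        smap = be.correlate(be.embed(templ), be.embed(search))
        score, center = smap.peak()
        assert score == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(center, [30 + 9, 20 + 7])  # (x, y) of the copy center

    def test_flat_template_flagged(self):
        be = NCCBackend()
        smap = be.correlate(be.embed(np.full((9, 9), 0.3)), be.embed(textured_frame((30, 30))))
        assert smap.flat
        assert np.allclose(smap.values, 0.0)

    def test_template_larger_than_search_rejected(self):
        be = NCCBackend()
        with pytest.raises(ValueError):
            be.correlate(be.embed(np.zeros((20, 20))), be.embed(np.zeros((10, 10))))

    def test_matches_brute_force_oracle(self):
        be = NCCBackend()
        search = textured_frame((24, 28), seed=5)
        templ = textured_frame((9, 11), seed=6)
        smap = be.correlate(be.embed(templ), be.embed(search))
        assert np.allclose(smap.values, brute_force_ncc(search, templ), atol=1e-5)

    @pytest.mark.parametrize("x0,y0", [(0, 0), (13, 7), (26, 21), (40, 30)])
    def test_planted_patch_peak_maps_to_true_center(self, x0, y0):
        """Coordinate mapping is exact over a grid spanning the search region."""
        be = NCCBackend()
        rng = np.random.default_rng(9)
        templ = rng.random((15, 15))
        search = 0.5 + 0.01 * rng.random((60, 70))
        search[y0 : y0 + 15, x0 : x0 + 15] = templ
        smap = be.correlate(be.embed(templ), be.embed(search))
        _, center = smap.peak()
        true = np.array([x0 + 7, y0 + 7])
        assert np.linalg.norm(center - true) <= 0.5  # stride/2

    def test_translation_equivariance(self):
        be = NCCBackend()
        base = textured_frame((40, 50), seed=11)
        templ = base[10:25, 10:25].copy()
        sm1 = be.correlate(be.embed(templ), be.embed(base[:, :-1]))
        sm2 = be.correlate(be.embed(templ), be.embed(base[:, 1:]))
        p1 = np.unravel_index(np.argmax(sm1.values), sm1.values.shape)
        p2 = np.unravel_index(np.argmax(sm2.values), sm2.values.shape)
        assert p1[1] == p2[1] + 1  # shifting the search shifts the peak one cell
        assert p1[0] == p2[0]


class TestLearnedBackend:
    def test_embed_spatial_size_follows_layer_arithmetic(self):
        be = LearnedBackend(Backbone(seed=0))
        # apply the per-layer size arithmetic by hand for a 127 px input
        n = 127
        for k, s in [(11, 2), (2, 2), (5, 1), (2, 2), (3, 1), (3, 1), (3, 1)]:
            n = (n - k) // s + 1
        feat = be.embed(np.zeros((127, 127)))
        assert feat.spatial_shape == (n, n)
        assert be.stride == 8

    def test_channel_schedule(self):
        bb = Backbone(seed=0)
        convs = [s.out_channels for s in bb.specs if s.kind == "conv"]
        assert convs == [16, 32, 64, 128, 64]

    def test_identical_inputs_identical_outputs(self):
        be = LearnedBackend(Backbone(seed=0))
        patch = textured_frame((97, 97), seed=3)
        assert np.array_equal(be.embed(patch).data, be.embed(patch).data)

    def test_too_small_patch_reports_minimum(self):
        be = LearnedBackend(Backbone(seed=0))
        with pytest.raises(ValueError, match=str(be.backbone.min_input())):
            be.embed(np.zeros((32, 32)))

    def test_planted_copy_features_align_and_cosine_peak_maps_back(self):
        """Stride-aligned planted copy reproduces the template's feature
        block exactly, and the cosine-normalized correlation peak maps to
        the true center within stride/2."""
        be = LearnedBackend(Backbone(seed=1))
        rng = np.random.default_rng(4)
        from scipy import ndimage

        templ = ndimage.gaussian_filter(rng.random((97, 97)), 1.5)
        x0, y0 = 32, 16
        search = np.zeros((193, 193))
        search[y0 : y0 + 97, x0 : x0 + 97] = templ
        tf, sf = be.embed(templ), be.embed(search)
        smap = be.correlate(tf, sf)
        th, tw = tf.spatial_shape
        ci, cj = y0 // be.stride, x0 // be.stride
        assert np.allclose(sf.data[:, ci : ci + th, cj : cj + tw], tf.data, atol=1e-10)

        win = np.lib.stride_tricks.sliding_window_view(sf.data, (th, tw), axis=(1, 2))
        norms = np.sqrt(np.einsum("cijab,cijab->ij", win, win))
        raw = np.einsum("cijab,cab->ij", win, tf.data)
        cos = raw / np.maximum(norms * np.linalg.norm(tf.data), 1e-12)
        idx = np.unravel_index(np.argmax(cos), cos.shape)
        xs, ys = smap.candidate_coords()
        err = np.hypot(xs[idx[1]] - (x0 + 48), ys[idx[0]] - (y0 + 48))
        assert err <= be.stride / 2


class TestScoreMapUpsampling:
    def test_upsampled_grid_is_per_pixel_and_keeps_origin(self):
        be = LearnedBackend(Backbone(seed=0))
        templ = textured_frame((97, 97), seed=8)
        search = textured_frame((193, 193), seed=9)
        smap = be.correlate(be.embed(templ), be.embed(search))
        up = smap.upsampled()
        assert up.step == 1.0
        assert up.origin == smap.origin
        rows, cols = smap.values.shape
        assert up.values.shape == ((rows - 1) * 8 + 1, (cols - 1) * 8 + 1)
        # original cell values are preserved at the coarse grid nodes
        assert np.allclose(up.values[::8, ::8], smap.values, atol=1e-8)


def test_get_backend_dispatch():
    assert isinstance(get_backend("ncc"), NCCBackend)
    assert isinstance(get_backend("learned"), LearnedBackend)
    with pytest.raises(ValueError):
        get_backend("nope")
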