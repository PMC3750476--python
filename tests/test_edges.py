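import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from mamle import directional_edge, fuzzy_edge_image, structuring_element

DIRECTION_STEPS = {1: (0, 1), 2: (1, 0), 3: (1, 1), 4: (1, -1)}


def edge_brute_force(img, s, d):
    """Per-pixel double loop: p is marked iff no probed neighbor at
    distance s along d is darker (out-of-image probes count as +inf)."""
    h, w = img.shape
    dr, dc = DIRECTION_STEPS[d]
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            vals = []
            for sign in (-1, 1):
                rr, cc = r + sign * s * dr, c + sign * s * dc
                if 0 <= rr < h and 0 <= cc < w:
                    vals.append(img[rr, cc])
            out[r, c] = img[r, c] <= min(vals, default=np.inf)
    return out


def fuzzy_brute_force(img, max_scale):
    votes = np.zeros(img.shape, dtype=int)
    for s in range(1, max_scale + 1):
        marked = np.zeros(img.shape, dtype=bool)
        for d in (1, 2, 3, 4):
            marked |= edge_brute_force(img, s, d)
        votes += marked
    return votes


class TestStructuringElement:
    @pytest.mark.parametrize(
        "s,d,expected",
        [
            (1, 1, ((0, -1), (0, 1))),
            (2, 2, ((-2, 0), (2, 0))),
            (1, 3, ((-1, -1), (1, 1))),
            (1, 4, ((-1, 1), (1, -1))),
        ],
    )
    def test_probe_offsets(self, s, d, expected):
        elem = structuring_element(s, d)
        assert elem.offsets == expected

    @pytest.mark.parametrize("s,d", [(s, d) for s in (1, 2, 3) for d in (1, 2, 3, 4)])
    def test_support_has_exactly_two_endpoints_origin_excluded(self, s, d):
        elem = structuring_element(s, d)
        assert elem.support.sum() == 2
        assert not elem.support[elem.origin]

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            structuring_element(1, 5)


class TestDirectionalEdge:
    def test_constant_image_all_marked(self):
        img = np.full((16, 16), 9.0)
        for s in (1, 2, 3):
            for d in (1, 2, 3, 4):
                assert directional_edge(img, s, d).all()

    def test_ramp_row_only_minimum_end(self):
        img = np.full((16, 16), 100.0)
        img[8, 5:10] = [1, 2, 3, 4, 5]
        marked = directional_edge(img, 1, 1)
        # strictly increasing run: only the left end is a directional minimum
        assert marked[8, 5]
        assert not marked[8, 6:10].any()

    @pytest.mark.parametrize("s", [1, 2, 3, 4])
    @pytest.mark.parametrize("d", [1, 2, 3, 4])
    def test_matches_brute_force(self, s, d):
        rng = np.random.default_rng(100 * s + d)
        img = rng.integers(0, 32, (16, 16)).astype(float)
        np.testing.assert_array_equal(
            directional_edge(img, s, d), edge_brute_force(img, s, d)
        )


class TestFuzzyEdgeImage:
    def test_constant_in_roi_saturates(self):
        img = np.full((20, 20), 5.0)
        roi = np.zeros((20, 20), dtype=bool)
        roi[5:15, 5:15] = True
        votes = fuzzy_edge_image(img, 4, roi)
        assert (votes[roi] == 4).all()
        assert (votes[~roi] == 0).all()

    def test_dark_line_gets_full_votes(self):
        # textured bright background so flat-tie votes do not saturate
        rng = np.random.default_rng(8)
        img = rng.integers(150, 250, (24, 24)).astype(float)
        img[:, 12] = 50.0
        votes = fuzzy_edge_image(img, 2)
        assert (votes[:, 12] == 2).all()
        off_line = np.delete(votes, 12, axis=1)
        # background votes are scattered, never the unanimous line signal
        assert (off_line < 2).mean() > 0.3

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 64, (32, 32)).astype(float)
        np.testing.assert_array_equal(fuzzy_edge_image(img, 3), fuzzy_brute_force(img, 3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 20)),
        st.integers(1, 3),
    )
    def test_brute_force_property(self, img, max_scale):
        img = img.astype(float)
        np.testing.assert_array_equal(
            fuzzy_edge_image(img, max_scale), fuzzy_brute_force(img, max_scale)
        )

    def test_monotone_in_scale_count(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 64, (24, 24)).astype(float)
        v3 = fuzzy_edge_image(img, 3)
        v4 = fuzzy_edge_image(img, 4)
        assert (v3 <= v4).all()

    def test_isotropy_under_quarter_turn(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 64, (20, 20)).astype(float)
        votes = fuzzy_edge_image(img, 3)
        rotated_votes = fuzzy_edge_image(np.rot90(img), 3)
        np.testing.assert_array_equal(np.rot90(votes), rotated_votes)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            fuzzy_edge_image(np.zeros((16, 16)), 0)
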