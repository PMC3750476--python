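import itertools

import numpy as np
import pytest

from mamle import (
    apply_selection,
    best_binary_split,
    build_candidate_set,
    generate_hypotheses,
    merge_fragments,
    recursive_split,
    select_split_candidates,
    solve_selection,
)
from mamle.shape import features_of_coords, mahalanobis_D
from mamle.split_merge import _exact_cover_best
from mamle.synthetic import _cell_mask


def paint(shapes, canvas_shape=(80, 80)):
    """Paint boolean crops at offsets into a label mask."""
    mask = np.zeros(canvas_shape, dtype=np.int32)
    for label, (crop, (r0, c0)) in enumerate(shapes, start=1):
        rr, cc = np.nonzero(crop)
        mask[rr + r0, cc + c0] = label
    return mask


def fused_rods(theta=0.0, length=30, width=9, canvas=(80, 80)):
    """One object made of two identical rods fused end to end."""
    rod = _cell_mask(length, width, theta, "rod")
    mask = np.zeros(canvas, dtype=bool)
    ext = rod.shape[0] // 2
    cy, cx = canvas[0] // 2, canvas[1] // 2
    step = int(round((length - 1) * np.cos(theta))), int(round((length - 1) * np.sin(theta)))
    for k in (0, 1):
        r0 = cy - ext + k * step[1]
        c0 = cx - ext - length // 2 + k * step[0]
        rr, cc = np.nonzero(rod)
        mask[rr + r0, cc + c0] = True
    return mask


class TestSplit:
    def test_candidates_are_strictly_larger_than_mean(self, rod_model):
        area = int(rod_model.mean_area)
        side = int(np.sqrt(area))
        sq = np.ones((side, side), bool)
        big = np.ones((side, 2 * side), bool)
        mask = paint([(sq, (5, 5)), (big, (40, 5))], (80, 80))
        cands = select_split_candidates(mask, rod_model)
        assert cands == [2]

    def test_fused_rods_cut_near_junction(self, rod_model):
        obj = fused_rods(theta=0.0)
        cut = best_binary_split(obj, rod_model, max_cell_area=450)
        assert cut is not None
        rows, cols = np.nonzero(obj)
        junction_col = (cols.min() + cols.max()) / 2.0
        # the two parts separate close to the geometric junction
        p1_max = cut.part1[1].max()
        p1_min = cut.part1[1].min()
        boundary = p1_max if p1_min < junction_col else p1_min
        assert abs(boundary - junction_col) <= 2.5
        whole = features_of_coords(rows.astype(float), cols.astype(float))
        assert cut.d_part1 < mahalanobis_D(whole, rod_model)

    def test_well_shaped_cell_not_cut(self, rod_model):
        rod = _cell_mask(30, 9, 0.3, "rod")
        assert best_binary_split(rod, rod_model, max_cell_area=450) is None

    def test_l_shaped_fusion_separated(self, rod_model):
        a = _cell_mask(32, 9, 0.0, "rod")
        b = _cell_mask(32, 9, np.pi / 2, "rod")
        canvas = np.zeros((80, 80), bool)
        rr, cc = np.nonzero(a)
        canvas[rr + 30, cc + 20] = True
        rr, cc = np.nonzero(b)
        canvas[rr + 40, cc + 28] = True
        if not _is_connected(canvas):
            pytest.skip("construction produced a disconnected L")
        cut = best_binary_split(canvas, rod_model, max_cell_area=450)
        assert cut is not None
        whole = features_of_coords(*[x.astype(float) for x in np.nonzero(canvas)])
        assert cut.d_part1 < mahalanobis_D(whole, rod_model)

    def test_chain_of_three_recovered(self, rod_model):
        rod = _cell_mask(30, 9, 0.0, "rod")
        mask = np.zeros((60, 140), dtype=np.int32)
        rr, cc = np.nonzero(rod)
        for k in range(3):
            mask[rr + 15, cc + 20 + k * 29] = 1
        from scipy import ndimage

        assert ndimage.label(mask > 0)[1] == 1  # genuinely one fused object
        out = recursive_split(mask, rod_model, max_cell_area=450)
        assert out.max() == 3

    def test_no_candidates_is_identity(self, rod_model):
        rod = _cell_mask(24, 8, 0.0, "rod")
        mask = paint([(rod, (10, 10))], (60, 60))
        out = recursive_split(mask, rod_model, max_cell_area=450)
        np.testing.assert_array_equal(out > 0, mask > 0)
        assert out.max() == 1

    def test_ring_terminates(self, rod_model):
        yy, xx = np.mgrid[-20:21, -20:21]
        r2 = yy**2 + xx**2
        ring = (r2 <= 400) & (r2 >= 196)
        mask = np.zeros((60, 60), dtype=np.int32)
        rr, cc = np.nonzero(ring)
        mask[rr + 8, cc + 8] = 1
        out = recursive_split(mask, rod_model, max_cell_area=300)
        assert out.max() >= 1  # completed without hanging

    def test_pixel_conservation(self, rod_model):
        obj = fused_rods(theta=0.4)
        mask = obj.astype(np.int32)
        out = recursive_split(mask, rod_model, max_cell_area=450)
        np.testing.assert_array_equal(out > 0, mask > 0)


def _is_connected(mask):
    from scipy import ndimage

    return ndimage.label(mask)[1] == 1


def overlapping_rod_fragments(rod_model, n_frag=2):
    """An over-split rod: fragments of one rod, plus their mask."""
    rod = _cell_mask(34, 9, 0.0, "rod")
    rr, cc = np.nonzero(rod)
    cut = (cc.min() + cc.max()) // 2
    mask = np.zeros((50, 60), dtype=np.int32)
    if n_frag == 2:
        mask[rr[cc <= cut] + 10, cc[cc <= cut] + 10] = 1
        mask[rr[cc > cut] + 10, cc[cc > cut] + 10] = 2
    else:
        t1, t2 = cc.min() + (cc.max() - cc.min()) // 3, cc.min() + 2 * (cc.max() - cc.min()) // 3
        mask[rr[cc <= t1] + 10, cc[cc <= t1] + 10] = 1
        sel = (cc > t1) & (cc <= t2)
        mask[rr[sel] + 10, cc[sel] + 10] = 2
        mask[rr[cc > t2] + 10, cc[cc > t2] + 10] = 3
    return mask


class TestCandidatesAndHypotheses:
    def test_over_split_halves_are_candidates(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 2)
        cands, pairs = build_candidate_set(mask, rod_model)
        assert cands == [1, 2]
        assert (1, 2) in pairs

    def test_separated_cells_not_candidates(self, rod_model):
        rod = _cell_mask(30, 9, 0.0, "rod")
        mask = paint([(rod, (5, 5)), (rod, (40, 5))], (80, 60))
        cands, _ = build_candidate_set(mask, rod_model)
        assert cands == []

    def test_single_object_no_candidates(self, rod_model):
        rod = _cell_mask(30, 9, 0.0, "rod")
        mask = paint([(rod, (5, 5))], (60, 60))
        assert build_candidate_set(mask, rod_model)[0] == []

    def test_pair_hypothesis_structure(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 2)
        hyp = generate_hypotheses(mask, rod_model)
        assert hyp.H.shape == (3, 2)
        np.testing.assert_array_equal(hyp.H[:2], np.eye(2, dtype=np.int8))
        np.testing.assert_array_equal(hyp.H[2], [1, 1])
        assert hyp.levels.tolist() == [1, 1, 2]
        # the pair score is -D of the exact pixel union
        rr, cc = np.nonzero(mask > 0)
        d_union = mahalanobis_D(
            features_of_coords(rr.astype(float), cc.astype(float)), rod_model
        )
        assert hyp.L[2] == pytest.approx(-d_union)

    def test_triple_hypothesis_wins(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 3)
        hyp = generate_hypotheses(mask, rod_model)
        triple_rows = np.nonzero(hyp.levels == 3)[0]
        assert triple_rows.size == 1
        x = solve_selection(hyp.H, hyp.L)
        assert x[triple_rows[0]] == 1
        out = apply_selection(mask, hyp, x)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, mask > 0)


def enumerate_partitions_best(H, L):
    """Independent oracle: try every set partition of the candidates whose
    blocks all exist as hypothesis rows; return (best score, best n_rows)."""
    m, n = H.shape
    row_of = {}  # best score per distinct block of candidates
    for r in range(m):
        key = frozenset(np.flatnonzero(H[r]))
        row_of[key] = max(L[r], row_of.get(key, -np.inf))

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {first}] + part[i + 1:]
            yield part + [{first}]

    best = None
    for part in partitions(list(range(n))):
        blocks = [frozenset(b) for b in part]
        if not all(b in row_of for b in blocks):
            continue
        score = sum(row_of[b] for b in blocks)
        key = (score, len(blocks))
        if best is None or key > best:
            best = key
    return best


class TestSelection:
    def test_identity_only_selects_everything(self):
        H = np.eye(4, dtype=np.int8)
        L = -np.arange(4.0)
        x = solve_selection(H, L)
        np.testing.assert_array_equal(x, np.ones(4, dtype=np.int8))

    def test_pair_beats_identities(self):
        H = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        L = np.array([-10.0, -12.0, -3.0])
        x = solve_selection(H, L)
        np.testing.assert_array_equal(x, [0, 0, 1])

    def test_cover_is_exact(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 3)
        hyp = generate_hypotheses(mask, rod_model)
        x = solve_selection(hyp.H, hyp.L)
        np.testing.assert_array_equal(hyp.H.T @ x, np.ones(hyp.H.shape[1]))

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_partition_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 7))
        rows = [tuple(1 if j == i else 0 for j in range(n)) for i in range(n)]
        for size in (2, 3):
            for combo in itertools.combinations(range(n), size):
                if rng.random() < 0.4:
                    rows.append(tuple(1 if j in combo else 0 for j in range(n)))
        H = np.array(rows, dtype=np.int8)
        L = rng.normal(scale=5.0, size=H.shape[0])
        x = solve_selection(H, L)
        score = float(L @ x)
        np.testing.assert_array_equal(H.T @ x, np.ones(n))
        best_score, best_rows = enumerate_partitions_best(H, L)
        assert score == pytest.approx(best_score, abs=1e-9)
        assert int(x.sum()) == best_rows

    def test_branch_and_bound_matches_enumeration(self):
        """The MILP path and the exhaustive path agree on the same instance."""
        from mamle.split_merge import _milp_cover

        rng = np.random.default_rng(123)
        n = 6
        rows = [tuple(1 if j == i else 0 for j in range(n)) for i in range(n)]
        for combo in itertools.combinations(range(n), 2):
            rows.append(tuple(1 if j in combo else 0 for j in range(n)))
        H = np.array(rows, dtype=np.int8)
        L = rng.normal(scale=5.0, size=H.shape[0])
        x_exact = _exact_cover_best(H, L)
        x_milp = _milp_cover(H, L)
        assert L @ x_exact == pytest.approx(L @ x_milp, abs=1e-6)

    def test_likelihood_never_below_identity(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 3)
        hyp = generate_hypotheses(mask, rod_model)
        x = solve_selection(hyp.H, hyp.L)
        identity_score = hyp.L[hyp.levels == 1].sum()
        assert float(hyp.L @ x) >= identity_score - 1e-9


class TestApplyAndMerge:
    def test_all_identity_keeps_mask(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 2)
        hyp = generate_hypotheses(mask, rod_model)
        x = np.zeros(hyp.H.shape[0], dtype=np.int8)
        x[:2] = 1
        out = apply_selection(mask, hyp, x)
        np.testing.assert_array_equal(out, mask)

    def test_merge_restores_over_split_rod(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 2)
        out = merge_fragments(mask, rod_model)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, mask > 0)

    def test_pixel_conservation_through_merge(self, rod_model):
        mask = overlapping_rod_fragments(rod_model, 3)
        out = merge_fragments(mask, rod_model)
        np.testing.assert_array_equal(out > 0, mask > 0)
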