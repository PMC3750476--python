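"""Likelihood-guided correction of the initial segmentation.

Two passes run over the initial label mask, both scored by the Mahalanobis
distance ``D`` under the learned Gaussian shape model:

* **Binary split** (under-segmentation repair): every object larger than
  the model's mean area is a split candidate.  Candidate cuts are straight
  lines perpendicular to the object's local medial-axis orientation,
  anchored at medial-axis points; each cut partitions the object into a
  connected part and a remainder.  The cut minimizing ``D`` of one part
  (maximizing that part's likelihood, disregarding the other) is applied,
  and the remainder re-enters the queue while it is larger than the mean
  cell area.  A no-improvement guard keeps large-but-well-shaped cells
  intact: if no cut beats the whole object's ``D`` and the object does not
  exceed the maximum cell area, it is left alone.

* **Maximum-likelihood merge** (over-segmentation repair): fragments whose
  union with an adjacent fragment is at least as likely as the two apart
  form the candidate set; keep/pair/triple hypotheses are enumerated with
  their log-likelihood scores and the best exactly-once cover of the
  candidates is selected by binary integer programming (exhaustive
  enumeration on small clusters, LP-based branch-and-bound otherwise).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.optimize import LinearConstraint, milp
from skimage.morphology import medial_axis

from .shape import (
    MIN_REGION_PIXELS,
    FeatureVector,
    ShapeModel,
    features_of_coords,
    mahalanobis_D,
)

__all__ = [
    "SplitCut",
    "HypothesisSet",
    "select_split_candidates",
    "best_binary_split",
    "recursive_split",
    "build_candidate_set",
    "generate_hypotheses",
    "solve_selection",
    "apply_selection",
    "merge_fragments",
]

#: medial-axis anchors are sampled at this stride
ANCHOR_STRIDE = 2
#: radius (px) of the skeleton neighborhood used to estimate local orientation
ORIENTATION_RADIUS = 5
#: objects whose boundaries lie within this many pixels are merge-adjacent
ADJACENCY_PX = 2
#: clusters with at most this many hypothesis rows are solved by enumeration
EXACT_SOLVE_ROWS = 20
#: Mahalanobis distance assigned to regions too small to have features;
#: finite so the selection stays well-posed, large so debris prefers merging
UNDEFINED_D = 1e9
#: 95% quantile of chi^2 with 3 dof: objects below this Mahalanobis
#: distance are plausible single cells and are not cut unless oversized
SPLIT_D_THRESHOLD = 7.81


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitCut:
    """A binary split of one object: a connected part and the remainder."""

    label: int
    anchor: tuple[float, float]
    orientation: float  # tangent angle (radians) the cut is perpendicular to
    part1: tuple[np.ndarray, np.ndarray]  # (rows, cols), global coordinates
    remainder: tuple[np.ndarray, np.ndarray]
    d_part1: float


def select_split_candidates(mask: np.ndarray, model: ShapeModel) -> list[int]:
    """Labels whose area exceeds the model's mean cell area."""
    areas = np.bincount(np.asarray(mask).ravel())
    return [int(l) for l in range(1, areas.size) if areas[l] > model.mean_area]


def _safe_features(rows: np.ndarray, cols: np.ndarray) -> FeatureVector | None:
    if rows.size < MIN_REGION_PIXELS:
        return None
    return features_of_coords(rows.astype(np.float64), cols.astype(np.float64))


def best_binary_split(
    obj_mask: np.ndarray,
    model: ShapeModel,
    max_cell_area: float,
    offset: tuple[int, int] = (0, 0),
    label: int = 0,
) -> SplitCut | None:
    """Search straight normal cuts for the one maximizing a part's likelihood.

    ``obj_mask`` is a boolean crop of a single object; ``offset`` places the
    crop in the full image.  Returns ``None`` when the object is too thin to
    cut, or when no cut improves on the whole object and the object is not
    oversized.
    """
    obj_mask = np.asarray(obj_mask, dtype=bool)
    rows_all, cols_all = np.nonzero(obj_mask)
    area = rows_all.size
    whole = _safe_features(rows_all, cols_all)
    if whole is None:
        return None
    d_whole = mahalanobis_D(whole, model)
    if area <= max_cell_area and d_whole <= SPLIT_D_THRESHOLD:
        # plausible single cell: never worth cutting
        return None

    skel = medial_axis(obj_mask, rng=0)  # fixed rng: deterministic skeleton
    sk_r, sk_c = np.nonzero(skel)
    if sk_r.size == 0:
        return None
    order = np.lexsort((sk_c, sk_r))
    anchors = order[::ANCHOR_STRIDE]
    sk_pts = np.column_stack([sk_r, sk_c]).astype(np.float64)
    pts = np.column_stack([rows_all, cols_all]).astype(np.float64)

    best: tuple[float, np.ndarray, tuple[float, float], float] | None = None
    structure = ndimage.generate_binary_structure(2, 2)
    for idx in anchors:
        anchor = sk_pts[idx]
        near = sk_pts[np.max(np.abs(sk_pts - anchor), axis=1) <= ORIENTATION_RADIUS]
        if near.shape[0] < 2:
            continue
        centered = near - near.mean(axis=0)
        # leading eigenvector of the 2x2 scatter = local tangent direction
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        tangent = v[:, np.argmax(w)]
        proj = (pts - anchor) @ tangent
        for side_mask in (proj < 0, proj >= 0):
            n_side = int(side_mask.sum())
            if n_side < MIN_REGION_PIXELS or area - n_side < MIN_REGION_PIXELS:
                continue
            side = np.zeros(obj_mask.shape, dtype=bool)
            side[rows_all[side_mask], cols_all[side_mask]] = True
            comp, n_comp = ndimage.label(side, structure=structure)
            if n_comp > 1:
                # keep the largest connected piece as the evaluated part
                sizes = np.bincount(comp.ravel())[1:]
                side = comp == (int(np.argmax(sizes)) + 1)
                if side.sum() < MIN_REGION_PIXELS or area - side.sum() < MIN_REGION_PIXELS:
                    continue
            pr, pc = np.nonzero(side)
            feat = _safe_features(pr, pc)
            if feat is None:
                continue
            d = mahalanobis_D(feat, model)
            if best is None or d < best[0]:
                angle = float(np.arctan2(tangent[0], tangent[1]))
                best = (d, side.copy(), (float(anchor[0]), float(anchor[1])), angle)
    if best is None:
        return None
    d_best, side, anchor_pt, angle = best
    if d_best >= d_whole and area <= max_cell_area:
        return None
    rem = obj_mask & ~side
    r0, c0 = offset
    pr, pc = np.nonzero(side)
    rr, rc = np.nonzero(rem)
    return SplitCut(
        label=label,
        anchor=(anchor_pt[0] + r0, anchor_pt[1] + c0),
        orientation=angle,
        part1=(pr + r0, pc + c0),
        remainder=(rr + r0, rc + c0),
        d_part1=d_best,
    )


def recursive_split(
    mask: np.ndarray,
    model: ShapeModel,
    max_cell_area: float,
    connectivity: int = 4,
) -> np.ndarray:
    """Apply the binary split recursively until no candidate remains."""
    out = np.asarray(mask).copy()
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    queue = select_split_candidates(out, model)
    next_label = int(out.max()) + 1
    while queue:
        label = queue.pop()
        rows, cols = np.nonzero(out == label)
        if rows.size == 0:
            continue
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        crop = out[r0:r1, c0:c1] == label
        cut = best_binary_split(crop, model, max_cell_area, offset=(r0, c0), label=label)
        if cut is None:
            continue
        out[cut.part1] = next_label
        next_label += 1
        # the remainder may have disconnected; each piece gets its own label
        rem = np.zeros_like(crop)
        rem[cut.remainder[0] - r0, cut.remainder[1] - c0] = True
        comp, n_comp = ndimage.label(rem, structure=structure)
        for k in range(1, n_comp + 1):
            piece = comp == k
            piece_label = label if k == 1 else next_label
            if k > 1:
                next_label += 1
            view = out[r0:r1, c0:c1]
            view[piece] = piece_label
            if piece.sum() > model.mean_area:
                queue.append(piece_label)
    return _relabel(out)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HypothesisSet:
    """Keep/pair/triple merge hypotheses over the candidate objects.

    ``H`` is the m x n binary hypothesis matrix (n = number of candidates),
    ``L`` the m-vector of log-likelihood scores (−D of the hypothesized
    object), ``levels`` the number of objects each row merges.
    """

    H: np.ndarray
    L: np.ndarray
    levels: np.ndarray
    candidates: list[int]


def _adjacency_pairs(mask: np.ndarray, reach: int = ADJACENCY_PX) -> set[tuple[int, int]]:
    """Pairs of labels whose pixel sets lie within ``reach`` (Chebyshev) px."""
    mask = np.asarray(mask)
    pairs: set[tuple[int, int]] = set()
    structure = ndimage.generate_binary_structure(2, 2)
    for label, sl in enumerate(ndimage.find_objects(mask), start=1):
        if sl is None:
            continue
        r0 = max(sl[0].start - reach, 0)
        r1 = min(sl[0].stop + reach, mask.shape[0])
        c0 = max(sl[1].start - reach, 0)
        c1 = min(sl[1].stop + reach, mask.shape[1])
        crop = mask[r0:r1, c0:c1]
        grown = ndimage.binary_dilation(crop == label, structure=structure, iterations=reach)
        for other in np.unique(crop[grown]):
            if other > label:
                pairs.add((label, int(other)))
    return pairs


class _UnionFeatures:
    """Caches features / D of unions of labeled objects."""

    def __init__(self, mask: np.ndarray, model: ShapeModel):
        self.mask = np.asarray(mask)
        self.model = model
        self._coords: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._d: dict[frozenset[int], float] = {}

    def coords(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        if label not in self._coords:
            self._coords[label] = np.nonzero(self.mask == label)
        return self._coords[label]

    def d(self, labels: frozenset[int]) -> float:
        if labels not in self._d:
            rows = np.concatenate([self.coords(l)[0] for l in labels])
            cols = np.concatenate([self.coords(l)[1] for l in labels])
            feat = _safe_features(rows, cols)
            self._d[labels] = UNDEFINED_D if feat is None else mahalanobis_D(feat, self.model)
        return self._d[labels]


def build_candidate_set(
    mask: np.ndarray, model: ShapeModel, _cache: _UnionFeatures | None = None
) -> tuple[list[int], set[tuple[int, int]]]:
    """Candidate fragments for merging.

    A label joins the candidate set when some adjacent label exists whose
    union with it is at least as likely as the two objects separately,
    i.e. ``D(i) + D(j) >= D(i u j)``.  Returns the candidate list and the
    adjacency pairs among them.
    """
    cache = _cache or _UnionFeatures(mask, model)
    pairs = _adjacency_pairs(mask)
    candidates: set[int] = set()
    good_pairs: set[tuple[int, int]] = set()
    for i, j in pairs:
        di = cache.d(frozenset([i]))
        dj = cache.d(frozenset([j]))
        dij = cache.d(frozenset([i, j]))
        if di + dj >= dij:
            candidates.update((i, j))
            good_pairs.add((i, j))
    kept = sorted(candidates)
    pairs_in = {(i, j) for i, j in pairs if i in candidates and j in candidates}
    return kept, pairs_in


def generate_hypotheses(
    mask: np.ndarray,
    model: ShapeModel,
    candidates: list[int] | None = None,
    pairs: set[tuple[int, int]] | None = None,
) -> HypothesisSet:
    """Build the hypothesis matrix and log-likelihood vector.

    Rows: one identity row per candidate; one row per adjacent pair whose
    merge is at least as likely as its parts; one row per connected triple
    satisfying the analogous constraint.  Hypotheses stop at level three.
    """
    cache = _UnionFeatures(mask, model)
    if candidates is None or pairs is None:
        candidates, pairs = build_candidate_set(mask, model, _cache=cache)
    if not candidates:
        return HypothesisSet(
            H=np.zeros((0, 0), dtype=np.int8),
            L=np.zeros(0),
            levels=np.zeros(0, dtype=int),
            candidates=[],
        )
    index = {label: k for k, label in enumerate(candidates)}
    n = len(candidates)
    rows: list[np.ndarray] = []
    scores: list[float] = []
    levels: list[int] = []
    for label in candidates:
        row = np.zeros(n, dtype=np.int8)
        row[index[label]] = 1
        rows.append(row)
        scores.append(-cache.d(frozenset([label])))
        levels.append(1)
    for i, j in sorted(pairs):
        di, dj = cache.d(frozenset([i])), cache.d(frozenset([j]))
        dij = cache.d(frozenset([i, j]))
        if di + dj >= dij:
            row = np.zeros(n, dtype=np.int8)
            row[index[i]] = row[index[j]] = 1
            rows.append(row)
            scores.append(-dij)
            levels.append(2)
    # triples: unions over adjacency-connected triples of candidates
    neighbors: dict[int, set[int]] = {c: set() for c in candidates}
    for i, j in pairs:
        neighbors[i].add(j)
        neighbors[j].add(i)
    seen: set[frozenset[int]] = set()
    for i, j in sorted(pairs):
        for k in sorted(neighbors[i] | neighbors[j]):
            trip = frozenset([i, j, k])
            if len(trip) < 3 or trip in seen:
                continue
            seen.add(trip)
            d_sum = sum(cache.d(frozenset([c])) for c in trip)
            d_union = cache.d(trip)
            if d_sum >= d_union:
                row = np.zeros(n, dtype=np.int8)
                for c in trip:
                    row[index[c]] = 1
                rows.append(row)
                scores.append(-d_union)
                levels.append(3)
    return HypothesisSet(
        H=np.array(rows, dtype=np.int8),
        L=np.array(scores, dtype=np.float64),
        levels=np.array(levels, dtype=int),
        candidates=list(candidates),
    )


def _exact_cover_best(H: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Enumerate exact covers by depth-first search; return the best.

    Maximizes total score; ties broken toward more rows (fewer merges).
    """
    m, n = H.shape
    row_sets = [frozenset(np.flatnonzero(H[r])) for r in range(m)]
    rows_for: list[list[int]] = [[] for _ in range(n)]
    for r, s in enumerate(row_sets):
        for c in s:
            rows_for[c].append(r)
    best: tuple[float, int, list[int]] | None = None

    def search(covered: frozenset[int], chosen: list[int], score: float) -> None:
        nonlocal best
        if len(covered) == n:
            key = (score, len(chosen))
            if best is None or key > (best[0], best[1]):
                best = (score, len(chosen), list(chosen))
            return
        first = min(c for c in range(n) if c not in covered)
        for r in rows_for[first]:
            if row_sets[r] & covered:
                continue
            chosen.append(r)
            search(covered | row_sets[r], chosen, score + L[r])
            chosen.pop()

    search(frozenset(), [], 0.0)
    x = np.zeros(m, dtype=np.int8)
    if best is not None:
        x[best[2]] = 1
    return x


def _milp_cover(H: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Exactly-once cover by LP-based branch-and-bound (HiGHS).

    A tiny per-row bonus steers ties toward selections with more rows
    (fewer merges) without affecting the optimum.
    """
    m = H.shape[0]
    scale = max(1.0, float(np.max(np.abs(L)))) if m else 1.0
    eps = 1e-7 * scale
    res = milp(
        c=-(L + eps),  # milp minimizes
        constraints=LinearConstraint(H.T.astype(float), lb=1, ub=1),
        integrality=np.ones(m),
        bounds=None,
    )
    if not res.success:
        raise RuntimeError(f"hypothesis selection infeasible: {res.message}")
    return (res.x > 0.5).astype(np.int8)


def solve_selection(H: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Select the maximum-likelihood exactly-once cover of the candidates.

    max L^T x  s.t.  H^T x = 1.  Candidate clusters that share no
    hypothesis row are independent and solved separately: exhaustively for
    small clusters, by branch-and-bound otherwise.
    """
    H = np.asarray(H)
    L = np.asarray(L, dtype=np.float64)
    m, n = H.shape
    if m == 0:
        return np.zeros(0, dtype=np.int8)
    if L.shape != (m,):
        raise ValueError("H and L are inconsistent")
    if not np.all(H.sum(axis=0) >= 1):
        raise ValueError("some candidate is covered by no hypothesis")
    # cluster candidates connected through shared rows
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for r in range(m):
        cols = np.flatnonzero(H[r])
        for c in cols[1:]:
            ra, rb = find(int(cols[0])), find(int(c))
            if ra != rb:
                parent[rb] = ra
    clusters: dict[int, list[int]] = {}
    for c in range(n):
        clusters.setdefault(find(c), []).append(c)
    x = np.zeros(m, dtype=np.int8)
    for cols in clusters.values():
        col_set = set(cols)
        row_ids = [r for r in range(m) if set(np.flatnonzero(H[r])) & col_set]
        sub_h = H[np.ix_(row_ids, cols)]
        sub_l = L[row_ids]
        if len(row_ids) <= EXACT_SOLVE_ROWS:
            sub_x = _exact_cover_best(sub_h, sub_l)
        else:
            sub_x = _milp_cover(sub_h, sub_l)
        x[row_ids] = sub_x
    return x


def apply_selection(mask: np.ndarray, hyp: HypothesisSet, x: np.ndarray) -> np.ndarray:
    """Merge the objects covered by each accepted multi-object hypothesis."""
    out = np.asarray(mask).copy()
    for r in np.flatnonzero(np.asarray(x)):
        members = [hyp.candidates[c] for c in np.flatnonzero(hyp.H[r])]
        if len(members) > 1:
            target = min(members)
            for label in members:
                if label != target:
                    out[out == label] = target
    return _relabel(out)


def merge_fragments(mask: np.ndarray, model: ShapeModel) -> np.ndarray:
    """Full merge pass: candidates, hypotheses, selection, application."""
    hyp = generate_hypotheses(mask, model)
    if not hyp.candidates:
        return _relabel(np.asarray(mask).copy())
    x = solve_selection(hyp.H, hyp.L)
    return apply_selection(mask, hyp, x)


def _relabel(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=labels.dtype)
    lut[present] = np.arange(1, present.size + 1, dtype=labels.dtype)
    return lut[labels]
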