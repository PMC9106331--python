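"""Segmentation fusion, convex decomposition, LAP cost matrix and solver,
and chain assembly — including the brute-force assignment oracle."""

import itertools
import math

import numpy as np
import pytest

from pgcolony.linking import (
    CostMatrix,
    LinkParams,
    SliceMask,
    build_chains,
    build_cost_matrix,
    convex_decompose,
    fuse_segmentations,
    link_cost,
    link_stack,
    masks_from_labels,
    solve_linking,
)


def disc_mask(shape, center, radius, label=1):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2) * label


def mask_from_bool(m, z=0, label=1):
    return SliceMask(pixels=np.argwhere(m), slice_index=z, label=label, width=m.shape[1])


def brute_force_total(A: np.ndarray, alt: float) -> float:
    """Minimum block-LAP objective over all partial matchings: each link
    (i, j) costs 2*A(i, j) (the mirrored lower-right block doubles it),
    each unmatched row/column costs the alternative cost once."""
    n, m = A.shape
    best = math.inf
    rows = list(range(n))
    for k in range(0, min(n, m) + 1):
        for row_sub in itertools.combinations(rows, k):
            for col_perm in itertools.permutations(range(m), k):
                cost = sum(A[i, j] for i, j in zip(row_sub, col_perm))
                if not math.isfinite(cost):
                    continue
                total = 2 * cost + alt * (n - k) + alt * (m - k)
                best = min(best, total)
    return min(best, alt * (n + m))


def random_instance(rng, n, m, shape=(40, 40)):
    """Random overlapping-square masks in two adjacent slices."""
    def masks(count, z):
        out = []
        for i in range(count):
            r0, c0 = rng.integers(2, shape[0] - 8, size=2)
            h, w = rng.integers(3, 7, size=2)
            mm = np.zeros(shape, bool)
            mm[r0 : r0 + h, c0 : c0 + w] = True
            out.append(mask_from_bool(mm, z=z, label=i + 1))
        return out

    return masks(n, 0), masks(m, 1)


class TestFuseSegmentations:
    def test_empty_fallback_returns_primary(self):
        primary = disc_mask((40, 40), (20, 20), 6)
        fused = fuse_segmentations(primary, np.zeros_like(primary))
        assert np.array_equal(fused, primary)

    def test_empty_primary_passes_fallback_through(self):
        fb = disc_mask((60, 60), (15, 15), 7) + disc_mask((60, 60), (45, 45), 7, label=2)
        fused = fuse_segmentations(np.zeros_like(fb), fb, opening_radius=1, min_area=10)
        labels = np.setdiff1d(np.unique(fused), [0])
        assert len(labels) == 2
        # opening erodes at most a thin boundary ring
        assert (fused > 0).sum() >= 0.8 * (fb > 0).sum()

    def test_fallback_only_nucleus_recovered(self):
        # primary covers nucleus A; fallback covers A and a disjoint B
        a = disc_mask((80, 80), (20, 20), 8)
        b = disc_mask((80, 80), (60, 60), 8, label=2)
        primary = a.copy()
        fallback = ((a + b) > 0).astype(np.int32)
        fused = fuse_segmentations(primary, fallback, min_area=20)
        # A kept unchanged with its primary label
        assert np.array_equal(fused == 1, a > 0)
        # B present under a new label, nearly complete
        b_label = np.setdiff1d(np.unique(fused), [0, 1])
        assert len(b_label) == 1
        assert (fused == b_label[0]).sum() >= 0.8 * (b > 0).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_segmentations(np.zeros((4, 4), np.int32), np.zeros((5, 5), np.int32))


class TestConvexDecompose:
    def test_convex_disc_unchanged(self):
        m = disc_mask((40, 40), (20, 20), 10) > 0
        parts = convex_decompose(m)
        assert len(parts) == 1
        assert np.array_equal(parts[0], m)

    def test_figure_eight_split_preserves_centers(self):
        m = (disc_mask((50, 80), (25, 25), 13) + disc_mask((50, 80), (25, 50), 13)) > 0
        parts = convex_decompose(m, solidity_min=0.9)
        assert len(parts) == 2
        # conservation and disjointness
        union = np.zeros_like(m)
        total = 0
        for p in parts:
            assert not (union & p).any()
            union |= p
            total += p.sum()
        assert np.array_equal(union, m)
        assert total == m.sum()
        # each part contains exactly one of the two disc centers
        owners = {tuple(sorted(p[25, 25] for p in parts)), tuple(sorted(p[25, 50] for p in parts))}
        for p in parts:
            assert p[25, 25] != p[25, 50]

    def test_split_parts_are_near_convex(self):
        m = (disc_mask((50, 80), (25, 24), 13) + disc_mask((50, 80), (25, 46), 13)) > 0
        from pgcolony.linking import _solidity

        for p in convex_decompose(m, solidity_min=0.9):
            assert _solidity(p) >= 0.85


class TestLinkCost:
    params = LinkParams(dmax=10.0, iou_min=0.25)

    def test_identical_masks_cost_one(self):
        m = np.zeros((20, 20), bool)
        m[5:9, 5:9] = True
        a, b = mask_from_bool(m, 0), mask_from_bool(m, 1)
        assert link_cost(a, b, self.params) == 1.0

    def test_printed_formula_example(self):
        # |N_a| = 8, |N_b| = 10, overlap 4 -> cost min(8,10)/4 = 2.0
        a_m = np.zeros((20, 20), bool)
        a_m[0:2, 0:4] = True  # 8 px
        b_m = np.zeros((20, 20), bool)
        b_m[1:3, 0:5] = True  # 10 px, overlap = row 1, cols 0..3 = 4 px
        a, b = mask_from_bool(a_m, 0), mask_from_bool(b_m, 1)
        assert a.area == 8 and b.area == 10 and a.overlap(b) == 4
        assert link_cost(a, b, self.params) == pytest.approx(2.0)

    def test_distance_beyond_dmax_is_unlinkable(self):
        m1 = np.zeros((40, 40), bool)
        m1[0:4, 0:4] = True
        m2 = np.zeros((40, 40), bool)
        m2[30:34, 30:34] = True
        a, b = mask_from_bool(m1, 0), mask_from_bool(m2, 1)
        assert math.isinf(link_cost(a, b, self.params))

    def test_zero_overlap_is_unlinkable(self):
        m1 = np.zeros((20, 20), bool)
        m1[5:8, 2:5] = True
        m2 = np.zeros((20, 20), bool)
        m2[5:8, 6:9] = True  # nearby but disjoint
        a, b = mask_from_bool(m1, 0), mask_from_bool(m2, 1)
        assert math.isinf(link_cost(a, b, LinkParams(dmax=50.0)))


class TestLinkCostProperties:
    """Invariants of the link cost over arbitrary rectangular masks."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    rect = st.tuples(
        st.integers(0, 24), st.integers(0, 24), st.integers(2, 8), st.integers(2, 8)
    )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=rect, b=rect)
    def test_cost_symmetric_and_bounded_below(self, a, b):
        params = LinkParams(dmax=100.0)
        ma = np.zeros((40, 40), bool)
        ma[a[0] : a[0] + a[2], a[1] : a[1] + a[3]] = True
        mb = np.zeros((40, 40), bool)
        mb[b[0] : b[0] + b[2], b[1] : b[1] + b[3]] = True
        sa, sb = mask_from_bool(ma, 0), mask_from_bool(mb, 1)
        c_ab = link_cost(sa, sb, params)
        c_ba = link_cost(sb, sa.__class__(sa.pixels, 1, sa.label, sa.width), params)
        # symmetric in its arguments and never below 1 (overlap <= min area)
        assert c_ab == c_ba
        assert c_ab >= 1.0
        # identical masks achieve the lower bound
        if np.array_equal(ma, mb):
            assert c_ab == 1.0


class TestCostMatrix:
    def test_one_vs_one_overlapping(self):
        m = np.zeros((20, 20), bool)
        m[5:9, 5:9] = True
        cm = build_cost_matrix([mask_from_bool(m, 0)], [mask_from_bool(m, 1)], LinkParams())
        assert cm.A[0, 0] == 1.0
        assert cm.matrix[0, 1] == cm.alternative_cost  # B diagonal
        assert cm.matrix[1, 0] == cm.alternative_cost  # C diagonal
        assert cm.matrix[1, 1] == cm.A[0, 0]           # A^T block

    def test_knn_candidate_exclusion(self, rng):
        # 5 vs 5 masks: with k_neighbors=3 each row of A has >= 2 sentinel
        # (non-candidate) entries
        a, b = random_instance(rng, 5, 5)
        cm = build_cost_matrix(a, b, LinkParams(dmax=100.0, k_neighbors=3))
        for i in range(5):
            assert (cm.A[i] >= 0.5 * cm.sentinel).sum() >= 2

    def test_degenerate_empty_slices(self):
        cm = build_cost_matrix([], [], LinkParams())
        assert solve_linking(cm) == []
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        cm = build_cost_matrix([mask_from_bool(m, 0)], [], LinkParams())
        assert solve_linking(cm) == []


class TestSolveLinking:
    def test_single_pair_linked_when_cheaper_than_alternative(self):
        m = np.zeros((20, 20), bool)
        m[5:9, 5:9] = True
        cm = build_cost_matrix([mask_from_bool(m, 0)], [mask_from_bool(m, 1)], LinkParams(iou_min=0.25))
        assert solve_linking(cm) == [(0, 0)]

    def test_all_sentinel_rows_give_no_links(self):
        m1 = np.zeros((60, 60), bool)
        m1[0:4, 0:4] = True
        m2 = np.zeros((60, 60), bool)
        m2[50:54, 50:54] = True
        cm = build_cost_matrix([mask_from_bool(m1, 0)], [mask_from_bool(m2, 1)], LinkParams(dmax=5.0))
        assert solve_linking(cm) == []

    def test_greedy_suboptimal_instance_solved_optimally(self):
        # handcrafted 2x2 where greedy row-wise choice is suboptimal:
        # A = [[1.0, 1.1], [1.2, 3.0]]; greedy links (0,0)+(1,1)=4.0,
        # optimum links (0,1)+(1,0)=2.3
        alt = 4.0
        A = np.array([[1.0, 1.1], [1.2, 3.0]])
        sent = 1e6 * alt
        full = np.full((4, 4), sent)
        full[:2, :2] = A
        full[2:, 2:] = A.T
        np.fill_diagonal(full[:2, 2:], alt)
        np.fill_diagonal(full[2:, :2], alt)
        cm = CostMatrix(full, 2, 2, alt, sent)
        links = solve_linking(cm)
        assert sorted(links) == [(0, 1), (1, 0)]

    @pytest.mark.parametrize("seed", range(25))
    def test_solver_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 6, size=2)
        a, b = random_instance(rng, int(n), int(m))
        params = LinkParams(dmax=15.0, iou_min=0.25)
        cm = build_cost_matrix(a, b, params)
        rows, cols = __import__("scipy.optimize", fromlist=["linear_sum_assignment"]).linear_sum_assignment(cm.matrix)
        solver_total = cm.matrix[rows, cols].sum()
        A = np.where(cm.A >= 0.5 * cm.sentinel, np.inf, cm.A)
        assert solver_total == pytest.approx(brute_force_total(A, cm.alternative_cost))

    def test_lowering_iou_min_never_decreases_links(self, rng):
        a, b = random_instance(rng, 5, 5)
        counts = []
        for iou in (0.9, 0.5, 0.25, 0.1):
            cm = build_cost_matrix(a, b, LinkParams(dmax=20.0, iou_min=iou))
            counts.append(len(solve_linking(cm)))
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_links_invariant_under_mask_order_permutation(self, rng):
        a, b = random_instance(rng, 5, 5)
        params = LinkParams(dmax=20.0)
        links = set(solve_linking(build_cost_matrix(a, b, params)))
        perm_a = [4, 2, 0, 3, 1]
        perm_b = [1, 3, 4, 0, 2]
        a2 = [a[i] for i in perm_a]
        b2 = [b[j] for j in perm_b]
        links2 = set(solve_linking(build_cost_matrix(a2, b2, params)))
        remapped = {(perm_a[i], perm_b[j]) for i, j in links2}
        assert remapped == links


class TestBuildChains:
    @staticmethod
    def chain_masks(areas, col_offset=0):
        """A vertical stack of square-ish masks with the given areas."""
        masks = []
        for z, area in enumerate(areas):
            side = int(np.ceil(np.sqrt(area)))
            m = np.zeros((40, 40), bool)
            filled = 0
            for r in range(side):
                for c in range(side):
                    if filled < area:
                        m[10 + r, 10 + col_offset + c] = True
                        filled += 1
            masks.append(mask_from_bool(m, z=z))
        return masks

    def test_short_chain_kept_whole(self):
        masks = self.chain_masks([10, 12, 11])
        links = [[(0, 0)], [(0, 0)]]
        nuclei = build_chains(links, [[m] for m in masks], LinkParams(max_slices=4))
        assert len(nuclei) == 1
        assert nuclei[0].z_extent == 3

    def test_chain_split_at_area_minimum(self):
        # areas [12, 15, 5, 14, 13] with max_slices=4: split at the area-5
        # slice; the minimum-area slice joins the earlier chain
        masks = self.chain_masks([12, 15, 5, 14, 13])
        links = [[(0, 0)]] * 4
        nuclei = build_chains(links, [[m] for m in masks], LinkParams(max_slices=4))
        assert len(nuclei) == 2
        extents = sorted(n.z_extent for n in nuclei)
        assert extents == [2, 3]
        first = min(nuclei, key=lambda n: n.slice_indices[0])
        assert [m.area for m in first.chain] == [12, 15, 5]

    def test_unlinked_masks_become_singletons(self):
        masks0 = self.chain_masks([10])
        masks1 = self.chain_masks([10], col_offset=20)
        nuclei = build_chains([[]], [masks0, [masks1[0].__class__(masks1[0].pixels, 1, 1, masks1[0].width)]],
                              LinkParams(max_slices=4))
        assert len(nuclei) == 2
        assert all(n.z_extent == 1 for n in nuclei)

    def test_every_mask_in_exactly_one_nucleus(self, rng):
        # conservation on a random linked stack
        from pgcolony.synthetic import ColonySpec, generate_colony

        spec = ColonySpec(diameter=100.0, n_cells=40, n_slices=6, pixel_size=1.0, seed=21)
        _, truth = generate_colony(spec)
        lp = LinkParams.from_geometry(8.0, spec.z_spacing, spec.pixel_size)
        nuclei = link_stack(truth.label_stack, lp)
        n_masks = sum(
            len(masks_from_labels(truth.label_stack[z], z))
            for z in range(truth.label_stack.shape[0])
        )
        assert sum(n.z_extent for n in nuclei) == n_masks


class TestPerfectRecovery:
    def test_clean_colony_reconstructed_one_to_one(self, clean_colony, link_params):
        image, truth = clean_colony
        nuclei = link_stack(
            truth.label_stack, link_params,
            pixel_size=truth.spec.pixel_size, z_spacing=truth.spec.z_spacing,
        )
        gt = truth.label_stack
        per_gt_chains: dict[int, int] = {}
        merges = 0
        for nuc in nuclei:
            ids = set()
            for m in nuc.chain:
                ids |= set(np.unique(gt[m.slice_index].ravel()[m.lin]))
            ids.discard(0)
            if len(ids) > 1:
                merges += 1
            else:
                (gid,) = ids
                per_gt_chains[gid] = per_gt_chains.get(gid, 0) + 1
        assert merges == 0
        exact = sum(1 for v in per_gt_chains.values() if v == 1)
        assert exact / len(truth) >= 0.98
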