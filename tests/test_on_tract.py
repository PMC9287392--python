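"""Candidate generation, scoring/selection, cleaning and the central fiber."""

import numpy as np
import pytest

from ondti.dwi_core import ROISphere
from ondti.errors import DegenerateBundleError, PreconditionError
from ondti.on_tract import (
    FiberBundle,
    Streamline,
    central_fiber,
    clean_outliers,
    generate_candidates,
    resample_equidistant,
    save_bundle_csv,
    save_bundle_tck,
    score_and_select,
)


def straight_fiber(offset=(0.0, 0.0), y0=8.0, y1=32.0, n=25, score=None):
    y = np.linspace(y0, y1, n)
    pts = np.column_stack([np.full(n, 19.0 + offset[0]), y, np.full(n, 15.0 + offset[1])])
    return Streamline(points=pts, score=score)


def brute_force_core_distance(P):
    """Independent fiber-averaged Mahalanobis oracle (pure numpy loops)."""
    F, N, _ = P.shape
    core = P.mean(axis=0)
    out = np.zeros(F)
    for f in range(F):
        acc = 0.0
        for j in range(N):
            dev = P[:, j, :] - core[j]
            cov = dev.T @ dev / F
            inv = np.linalg.pinv(cov + 1e-12 * max(np.trace(cov), 1.0) * np.eye(3))
            d = P[f, j] - core[j]
            acc += np.sqrt(max(d @ inv @ d, 0.0))
        out[f] = acc / N
    return out


class TestResample:
    def test_uniform_spacing_on_straight_line(self):
        s = Streamline(points=np.column_stack([np.zeros(5), np.linspace(0, 19, 5), np.zeros(5)]))
        r = resample_equidistant(s, 20)
        seg = np.linalg.norm(np.diff(r.points, axis=0), axis=1)
        assert np.allclose(seg, 1.0, atol=1e-12)

    def test_endpoints_only(self):
        s = straight_fiber()
        r = resample_equidistant(s, 2)
        assert np.allclose(r.points[0], s.points[0])
        assert np.allclose(r.points[-1], s.points[-1])

    def test_length_preserved_on_smooth_curve(self):
        t = np.linspace(0, np.pi, 400)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)]) * 10
        s = Streamline(points=pts)
        r = resample_equidistant(s, 20)
        assert abs(r.arc_length - s.arc_length) / s.arc_length < 0.005

    def test_min_nodes(self):
        with pytest.raises(PreconditionError):
            resample_equidistant(straight_fiber(), 1)


class TestGeneration:
    def test_exact_candidate_count(self, straight_tf, straight_bundle):
        bundle = generate_candidates(straight_tf, *straight_bundle.rois, n=200, seed=1)
        assert len(bundle) == 200
        assert bundle.provenance == "candidates"

    def test_lengths_bounded_by_geometry(self, straight_tf, straight_bundle):
        r1, r2 = straight_bundle.rois
        bundle = generate_candidates(straight_tf, r1, r2, n=200, seed=2)
        D = np.linalg.norm(np.asarray(r2.center) - np.asarray(r1.center))
        L = bundle.lengths()
        assert np.all(L >= D - r1.radius - r2.radius - 1e-9)
        assert np.all(L <= 2 * D + 1e-9)
        assert abs(np.median(L) - D) / D < 0.10

    def test_roi_outside_grid_rejected(self, straight_tf, straight_bundle):
        bad = ROISphere((500.0, 500.0, 500.0), 3.0)
        with pytest.raises(PreconditionError):
            generate_candidates(straight_tf, straight_bundle.rois[0], bad, n=10, seed=0)

    def test_seed_determinism(self, straight_tf, straight_bundle):
        a = generate_candidates(straight_tf, *straight_bundle.rois, n=50, seed=9)
        b = generate_candidates(straight_tf, *straight_bundle.rois, n=50, seed=9)
        for s1, s2 in zip(a.streamlines, b.streamlines):
            assert np.array_equal(s1.points, s2.points)

    def test_orientation_toward_roi1(self, straight_tf, straight_bundle):
        r1 = straight_bundle.rois[0]
        bundle = generate_candidates(straight_tf, *straight_bundle.rois, n=50, seed=3)
        c1 = np.asarray(r1.center)
        for s in bundle.streamlines:
            assert np.linalg.norm(s.points[0] - c1) < np.linalg.norm(s.points[-1] - c1)


class TestSelection:
    def test_top_fraction_count(self, straight_tf, straight_bundle):
        bundle = generate_candidates(straight_tf, *straight_bundle.rois, n=200, seed=4)
        sel = score_and_select(bundle, straight_tf, keep_frac=0.10)
        assert len(sel) == 20
        assert sel.provenance == "selected"
        scores = [s.score for s in sel.streamlines]
        assert scores == sorted(scores, reverse=True)

    def test_keep_all_is_identity_on_membership(self, straight_tf, straight_bundle):
        bundle = generate_candidates(straight_tf, *straight_bundle.rois, n=50, seed=5)
        sel = score_and_select(bundle, straight_tf, keep_frac=1.0)
        assert len(sel) == 50
        ids = {id(s) for s in bundle.streamlines}
        assert {id(s) for s in sel.streamlines} == ids

    def test_permutation_invariant_membership(self, straight_tf, straight_bundle):
        bundle = generate_candidates(straight_tf, *straight_bundle.rois, n=100, seed=6)
        sel1 = score_and_select(bundle, straight_tf, keep_frac=0.2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(bundle))
        shuffled = FiberBundle(
            streamlines=[bundle.streamlines[i] for i in perm], provenance="candidates"
        )
        sel2 = score_and_select(shuffled, straight_tf, keep_frac=0.2)
        pts1 = sorted(tuple(s.points[0]) + tuple(s.points[-1]) for s in sel1.streamlines)
        pts2 = sorted(tuple(s.points[0]) + tuple(s.points[-1]) for s in sel2.streamlines)
        assert np.allclose(pts1, pts2)

    def test_in_tube_fiber_outscores_background(self, straight_tf):
        """A fiber running along the tube must score higher than a parallel
        fiber through isotropic background."""
        in_tube = straight_fiber()
        outside = straight_fiber(offset=(14.0, 0.0))
        bundle = FiberBundle(streamlines=[in_tube, outside], provenance="candidates")
        sel = score_and_select(bundle, straight_tf, keep_frac=1.0)
        assert in_tube.score > outside.score

    def test_invalid_fraction(self, straight_tf):
        bundle = FiberBundle(streamlines=[straight_fiber()], provenance="candidates")
        with pytest.raises(PreconditionError):
            score_and_select(bundle, straight_tf, keep_frac=0.0)


class TestCleaning:
    def test_identical_fibers_nothing_removed(self):
        fibers = [straight_fiber() for _ in range(10)]
        bundle = FiberBundle(streamlines=fibers, provenance="selected")
        out = clean_outliers(bundle)
        assert len(out) == 10
        assert out.provenance == "cleaned"

    def test_planted_detour_removed(self):
        rng = np.random.default_rng(8)
        fibers = []
        for _ in range(19):
            off = rng.normal(0, 0.1, size=2)
            fibers.append(straight_fiber(offset=tuple(off)))
        detour = straight_fiber().points.copy()
        detour[10:15, 0] += 6.0  # 6 mm excursion mid-path
        fibers.append(Streamline(points=detour))
        P = np.stack([resample_equidistant(f, 20).points for f in fibers])
        cd = brute_force_core_distance(P)
        assert cd[-1] > cd.mean() + 2.6 * cd.std()  # oracle confirms outlier
        bundle = FiberBundle(streamlines=fibers, provenance="selected")
        out = clean_outliers(bundle)
        assert len(out) == 19
        assert all(s is not fibers[-1] for s in out.streamlines)

    def test_overlong_fiber_removed(self):
        rng = np.random.default_rng(9)
        fibers = [straight_fiber(offset=tuple(rng.normal(0, 0.05, 2))) for _ in range(20)]
        zig = straight_fiber().points.copy()
        # add a long zigzag that stays near the core laterally
        zig = np.repeat(zig, 2, axis=0)
        zig[1::2, 2] += 2.0
        zig = zig[:-1]
        fibers.append(Streamline(points=zig))
        bundle = FiberBundle(streamlines=fibers, provenance="selected")
        out = clean_outliers(bundle)
        assert len(out) == 20

    def test_minimum_bundle_size(self):
        bundle = FiberBundle(streamlines=[straight_fiber()] * 4, provenance="selected")
        with pytest.raises(PreconditionError):
            clean_outliers(bundle)

    def test_idempotent_after_convergence(self, straight_tf, straight_bundle):
        cand = generate_candidates(straight_tf, *straight_bundle.rois, n=100, seed=10)
        sel = score_and_select(cand, straight_tf, keep_frac=0.5)
        once = clean_outliers(sel)
        twice = clean_outliers(once)
        assert len(twice) == len(once)


class TestCentralFiber:
    def test_mean_of_identical_fibers(self):
        fibers = [straight_fiber() for _ in range(6)]
        bundle = FiberBundle(streamlines=fibers, provenance="cleaned")
        r1 = ROISphere((19.0, 9.0, 15.0), 3.0)
        r2 = ROISphere((19.0, 31.0, 15.0), 3.0)
        cf = central_fiber(bundle, r1, r2)
        assert len(cf.points) == 20
        assert np.allclose(cf.points[:, 0], 19.0, atol=1e-6)
        assert np.allclose(cf.points[:, 2], 15.0, atol=1e-6)

    def test_symmetric_pair_averages_to_axis(self):
        a = straight_fiber(offset=(1.0, 0.0))
        b = straight_fiber(offset=(-1.0, 0.0))
        bundle = FiberBundle(streamlines=[a, b], provenance="cleaned")
        r1 = ROISphere((19.0, 9.0, 15.0), 3.0)
        r2 = ROISphere((19.0, 31.0, 15.0), 3.0)
        cf = central_fiber(bundle, r1, r2)
        assert np.allclose(cf.points[:, 0], 19.0, atol=1e-9)

    def test_node1_at_nerve_head_end(self, straight_tf, straight_bundle):
        cand = generate_candidates(straight_tf, *straight_bundle.rois, n=100, seed=11)
        sel = score_and_select(cand, straight_tf)
        cleaned = clean_outliers(sel)
        r1, r2 = straight_bundle.rois
        cf = central_fiber(cleaned, r1, r2)
        c1 = np.asarray(r1.center)
        assert np.linalg.norm(cf.points[0] - c1) < np.linalg.norm(cf.points[-1] - c1)

    def test_tracks_true_centerline(self, straight_tf, straight_bundle):
        from scipy.spatial import cKDTree

        cand = generate_candidates(straight_tf, *straight_bundle.rois, n=500, seed=12)
        sel = score_and_select(cand, straight_tf)
        cleaned = clean_outliers(sel)
        cf = central_fiber(cleaned, *straight_bundle.rois)
        d, _ = cKDTree(straight_bundle.centerline).query(cf.points)
        assert d.max() < 2.0  # within one voxel of ground truth

    def test_keep_frac_sharpens_individual_fibers(self, straight_tf, straight_bundle):
        """Selecting a smaller top fraction keeps fibers that individually
        hug the true centerline more tightly (averaged over seeds)."""
        from scipy.spatial import cKDTree

        tree = cKDTree(straight_bundle.centerline)

        def mean_fiber_rms(keep, seed):
            cand = generate_candidates(
                straight_tf, *straight_bundle.rois, n=300, seed=seed
            )
            sel = score_and_select(cand, straight_tf, keep_frac=keep)
            vals = []
            for s in sel.streamlines:
                d, _ = tree.query(s.points)
                vals.append(np.sqrt(np.mean(d**2)))
            return float(np.mean(vals))

        seeds = (21, 22, 23)
        by_keep = [
            np.mean([mean_fiber_rms(k, s) for s in seeds]) for k in (1.0, 0.5, 0.1)
        ]
        assert by_keep[2] < by_keep[1] < by_keep[0]


class TestExport:
    def test_tck_and_csv_round_trip(self, tmp_path):
        bundle = FiberBundle(
            streamlines=[straight_fiber(), straight_fiber(offset=(1.0, 0.5))],
            provenance="cleaned",
        )
        tck = save_bundle_tck(bundle, tmp_path / "b.tck")
        import nibabel.streamlines as nibs

        back = nibs.load(str(tck))
        assert len(back.streamlines) == 2
        assert np.allclose(back.streamlines[0], bundle.streamlines[0].points, atol=1e-4)
        csv_path = save_bundle_csv(bundle, tmp_path / "b.csv")
        lines = csv_path.read_text().strip().splitlines()
        assert lines[0] == "fiber_id,node,x,y,z"
        assert len(lines) == 1 + sum(len(s.points) for s in bundle.streamlines)
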