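"""ROI-to-ROI probabilistic tractography of the optic nerve.

Candidate streamlines are random walks whose step directions are drawn from
a Watson angular distribution aligned with the local principal diffusion
axis, with concentration proportional to local FA (kappa = kappa_max * FA).
The same density scores each candidate, the top fraction is kept, outliers
are removed by fiber-core Mahalanobis and length rules, and the surviving
bundle is averaged into a single central fiber resampled to 20 equidistant
nodes. Node 1 is always the nerve-head (ROI 1) end.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import hyp1f1

from .dwi_core import ROISphere
from .errors import DegenerateBundleError, PreconditionError, TrackingError
from .tensor_fit import TensorField

__all__ = [
    "Streamline",
    "FiberBundle",
    "CentralFiber",
    "generate_candidates",
    "score_and_select",
    "clean_outliers",
    "central_fiber",
    "resample_equidistant",
    "save_bundle_tck",
    "save_bundle_csv",
    "watson_logpdf",
]

DEFAULT_KAPPA_MAX = 30.0


@dataclass(eq=False)
class Streamline:
    """An ordered polyline in RAS+ mm with an optional log-likelihood score."""

    points: np.ndarray
    score: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise PreconditionError("points must be (n, 3)")
        if len(self.points) < 2:
            raise PreconditionError("a streamline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise PreconditionError("consecutive streamline points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


class CentralFiber(Streamline):
    """A streamline with exactly ``n_nodes`` equidistant-arc nodes;
    node 1 (index 0) is the nerve-head end."""

    def __post_init__(self) -> None:
        super().__post_init__()
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if seg.max() - seg.min() > 1e-6 * max(seg.mean(), 1e-12):
            raise PreconditionError("central fiber nodes must be equidistant in arc")


@dataclass(eq=False)
class FiberBundle:
    """A set of streamlines with a provenance tag
    (candidates -> selected -> cleaned)."""

    streamlines: list[Streamline]
    provenance: str = "candidates"
    core_mean: np.ndarray | None = None
    core_cov: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([s.arc_length for s in self.streamlines])


# ---------------------------------------------------------------------------
# geometry helpers


def resample_equidistant(s: Streamline, n: int = 20) -> Streamline:
    """Resample to ``n`` points at equal arc-length fractions (linear
    interpolation along segments, endpoints preserved exactly)."""
    if n < 2:
        raise PreconditionError("n must be >= 2")
    pts = s.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cs = np.concatenate([[0.0], np.cumsum(seg)])
    if cs[-1] <= 0:
        raise PreconditionError("zero arc length")
    targets = np.linspace(0.0, cs[-1], n)
    out = np.column_stack([np.interp(targets, cs, pts[:, k]) for k in range(3)])
    out[0], out[-1] = pts[0], pts[-1]
    return Streamline(points=out, score=s.score)


def _orient_bundle(streamlines: list[Streamline], roi1: ROISphere) -> list[Streamline]:
    """Flip streamlines so the first point is the one nearer ROI 1."""
    c = np.asarray(roi1.center)
    out = []
    for s in streamlines:
        if np.linalg.norm(s.points[0] - c) <= np.linalg.norm(s.points[-1] - c):
            out.append(s)
        else:
            out.append(Streamline(points=s.points[::-1].copy(), score=s.score))
    return out


# ---------------------------------------------------------------------------
# Watson angular model


def watson_logpdf(t2: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Log density of the (axial) Watson distribution on the sphere,
    evaluated at squared cosine ``t2`` of the angle to the axis."""
    norm = np.log(4.0 * math.pi) + np.log(hyp1f1(0.5, 1.5, kappa))
    return kappa * t2 - norm


def _sample_watson_t(rng: np.random.Generator, kappa: np.ndarray, max_rounds: int = 300) -> np.ndarray:
    """Sample cos(angle-to-axis) for per-walker concentrations by rejection
    from the uniform proposal (accept with exp(kappa (t^2 - 1)))."""
    k = len(kappa)
    t = np.zeros(k)
    todo = np.ones(k, dtype=bool)
    for _ in range(max_rounds):
        m = int(todo.sum())
        if m == 0:
            break
        prop = rng.uniform(-1.0, 1.0, size=m)
        u = rng.uniform(size=m)
        acc = u < np.exp(kappa[todo] * (prop**2 - 1.0))
        idx = np.flatnonzero(todo)
        t[idx[acc]] = prop[acc]
        todo[idx[acc]] = False
    if np.any(todo):  # astronomically rare at kappa <= kappa_max
        t[todo] = rng.choice([-1.0, 1.0], size=int(todo.sum()))
    return t


def _perp_basis(mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing each row of ``mu`` to an orthonormal frame."""
    a = np.zeros_like(mu)
    smallest = np.argmin(np.abs(mu), axis=1)
    a[np.arange(len(mu)), smallest] = 1.0
    p1 = np.cross(mu, a)
    p1 /= np.linalg.norm(p1, axis=1, keepdims=True)
    p2 = np.cross(mu, p1)
    return p1, p2


def _sample_directions(
    rng: np.random.Generator,
    mu: np.ndarray,
    kappa: np.ndarray,
    prev: np.ndarray,
    cos_max: float,
    max_tries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one Watson direction per walker, antipodally aligned with the
    previous direction and respecting the turning-angle cap.

    Returns (directions, ok); walkers still failing after ``max_tries``
    resampling rounds get ok=False (they terminate).
    """
    n = len(mu)
    d = np.zeros((n, 3))
    ok = np.zeros(n, dtype=bool)
    todo = np.ones(n, dtype=bool)
    p1, p2 = _perp_basis(mu)
    for _ in range(max_tries):
        m = int(todo.sum())
        if m == 0:
            break
        idx = np.flatnonzero(todo)
        t = _sample_watson_t(rng, kappa[idx])
        phi = rng.uniform(0.0, 2.0 * math.pi, size=m)
        sin_t = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
        cand = (
            t[:, None] * mu[idx]
            + sin_t[:, None] * (np.cos(phi)[:, None] * p1[idx] + np.sin(phi)[:, None] * p2[idx])
        )
        # axial symmetry: pick the hemisphere continuing the walk
        dots = np.sum(cand * prev[idx], axis=1)
        cand[dots < 0] *= -1.0
        dots = np.abs(dots)
        good = dots >= cos_max
        d[idx[good]] = cand[good]
        ok[idx[good]] = True
        todo[idx[good]] = False
    return d, ok


# ---------------------------------------------------------------------------
# candidate generation


class _FieldLookup:
    """Nearest-voxel FA and principal-axis lookup over a tensor field."""

    def __init__(self, tf: TensorField, kappa_max: float):
        ev = tf.eigenvalues
        e1 = tf.principal_axis
        md = ev.mean(axis=-1, keepdims=True)
        lc = np.clip(ev, 0.0, None)
        mbar = lc.mean(axis=-1, keepdims=True)
        den = np.sum(lc**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * np.sum((lc - mbar) ** 2, axis=-1) / den)
        fa = np.where(den > 0, fa, 0.0)
        fa = np.where(tf.mask, fa, 0.0)
        self.fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)
        self.e1 = e1
        self.kappa_max = kappa_max
        self.shape = np.asarray(tf.shape)
        self.inv = np.linalg.inv(tf.affine)

    def voxel_index(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(indices, inside) for mm positions; indices rounded to nearest."""
        v = pos @ self.inv[:3, :3].T + self.inv[:3, 3]
        idx = np.rint(v).astype(int)
        inside = np.all((idx >= 0) & (idx < self.shape), axis=-1)
        return idx, inside

    def lookup(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
        mu = self.e1[i, j, k]
        kappa = self.kappa_max * self.fa[i, j, k]
        return mu, kappa


def _uniform_in_sphere(rng: np.random.Generator, roi: ROISphere, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = roi.radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(roi.center) + r * v


def generate_candidates(
    tf: TensorField,
    roi1: ROISphere,
    roi2: ROISphere,
    n: int = 1000,
    seed: int = 0,
    step_mm: float = 1.0,
    max_angle_deg: float = 45.0,
    kappa_max: float = DEFAULT_KAPPA_MAX,
    max_attempt_factor: int = 100,
) -> FiberBundle:
    """Generate ``n`` accepted candidate pathways from ROI 1 to ROI 2.

    Walkers are seeded uniformly in ROI 1, take ``step_mm`` steps along
    Watson-sampled directions (turning angle capped at ``max_angle_deg``),
    and are accepted on entering ROI 2 within a length cap of twice the
    straight-line ROI distance. Generation stops at ``n`` accepted walkers
    or ``max_attempt_factor * n`` attempts, whichever comes first; zero
    acceptances raise :class:`TrackingError`.
    """
    if n < 1:
        raise PreconditionError("n must be >= 1")
    field_lu = _FieldLookup(tf, kappa_max)
    for name, roi in (("roi1", roi1), ("roi2", roi2)):
        _, inside = field_lu.voxel_index(np.asarray(roi.center)[None, :])
        if not inside[0]:
            raise PreconditionError(f"{name} centre lies outside the image grid")
    rng = np.random.default_rng(seed)
    cos_max = math.cos(math.radians(max_angle_deg))
    c2 = np.asarray(roi2.center)
    cap_len = 2.0 * float(np.linalg.norm(c2 - np.asarray(roi1.center)))
    max_steps = max(2, int(math.ceil(cap_len / step_mm)))

    accepted: list[Streamline] = []
    attempts = 0
    max_attempts = max_attempt_factor * n
    batch = min(1024, max_attempts)
    while len(accepted) < n and attempts < max_attempts:
        k = min(batch, max_attempts - attempts)
        attempts += k
        pos = _uniform_in_sphere(rng, roi1, k)
        prev = c2 - pos
        prev /= np.linalg.norm(prev, axis=1, keepdims=True)
        paths = np.zeros((k, max_steps + 1, 3))
        paths[:, 0] = pos
        npts = np.ones(k, dtype=int)
        alive = np.ones(k, dtype=bool)
        finished = np.zeros(k, dtype=bool)
        for _ in range(max_steps):
            act = np.flatnonzero(alive)
            if len(act) == 0:
                break
            idx, inside = field_lu.voxel_index(pos[act])
            alive[act[~inside]] = False
            act = act[inside]
            if len(act) == 0:
                break
            mu, kappa = field_lu.lookup(idx[inside])
            d, ok = _sample_directions(rng, mu, kappa, prev[act], cos_max)
            alive[act[~ok]] = False
            act = act[ok]
            if len(act) == 0:
                break
            pos[act] = pos[act] + step_mm * d[ok]
            prev[act] = d[ok]
            paths[act, npts[act]] = pos[act]
            npts[act] += 1
            hit = np.linalg.norm(pos[act] - c2, axis=1) <= roi2.radius
            finished[act[hit]] = True
            alive[act[hit]] = False
        for i in np.flatnonzero(finished):
            accepted.append(Streamline(points=paths[i, : npts[i]].copy()))
            if len(accepted) == n:
                break
    if not accepted:
        raise TrackingError(
            f"no pathway reached ROI 2 from ROI 1 within {max_attempts} attempts"
        )
    return FiberBundle(streamlines=accepted[:n], provenance="candidates")


# ---------------------------------------------------------------------------
# scoring, selection, cleaning


def score_and_select(
    bundle: FiberBundle,
    tf: TensorField,
    keep_frac: float = 0.10,
    kappa_max: float = DEFAULT_KAPPA_MAX,
) -> FiberBundle:
    """Score candidates by the mean Watson step log-likelihood and keep the
    top ``ceil(keep_frac * n)``, ties broken by shorter arc length then by
    creation index. The output is sorted by score descending."""
    if not 0.0 < keep_frac <= 1.0:
        raise PreconditionError("keep_frac must be in (0, 1]")
    if len(bundle) == 0:
        raise PreconditionError("empty bundle")
    if bundle.provenance != "candidates":
        raise PreconditionError("score_and_select expects a candidates bundle")
    field_lu = _FieldLookup(tf, kappa_max)
    scores = np.empty(len(bundle))
    for i, s in enumerate(bundle.streamlines):
        steps = np.diff(s.points, axis=0)
        norms = np.linalg.norm(steps, axis=1, keepdims=True)
        d = steps / norms
        mid = 0.5 * (s.points[:-1] + s.points[1:])
        idx, inside = field_lu.voxel_index(mid)
        idx = np.clip(idx, 0, field_lu.shape - 1)
        mu, kappa = field_lu.lookup(idx)
        t2 = np.sum(d * mu, axis=1) ** 2
        lp = watson_logpdf(t2, kappa)
        lp = np.where(inside, lp, -np.inf)
        scores[i] = float(np.mean(lp))
        s.score = scores[i]
    lengths = bundle.lengths()
    order = np.lexsort((np.arange(len(bundle)), lengths, -scores))
    n_keep = int(math.ceil(keep_frac * len(bundle)))
    kept = [bundle.streamlines[i] for i in order[:n_keep]]
    return FiberBundle(streamlines=kept, provenance="selected")


def _core_distances(P: np.ndarray) -> np.ndarray:
    """Fiber-averaged Mahalanobis distance of each fiber to the node-wise
    bundle core. P is (fibers, nodes, 3)."""
    core = P.mean(axis=0)
    dev = P - core  # (f, n, 3)
    n_nodes = P.shape[1]
    dists = np.zeros((P.shape[0], n_nodes))
    for j in range(n_nodes):
        cov = np.cov(P[:, j, :].T, ddof=0)
        cov = np.atleast_2d(cov)
        tr = np.trace(cov)
        inv = np.linalg.pinv(cov + 1e-12 * max(tr, 1.0) * np.eye(3))
        d = dev[:, j, :]
        dists[:, j] = np.sqrt(np.maximum(np.einsum("fi,ij,fj->f", d, inv, d), 0.0))
    return dists.mean(axis=1)


def clean_outliers(
    bundle: FiberBundle,
    core_sd: float = 2.6,
    len_sd: float = 3.0,
    n_nodes: int = 20,
    max_rounds: int = 5,
) -> FiberBundle:
    """Iteratively remove fibers that stray from the bundle core or are
    abnormally long.

    A fiber is removed when its fiber-averaged Mahalanobis distance to the
    node-wise core exceeds the bundle mean by more than ``core_sd`` standard
    deviations, or its arc length exceeds the mean by more than ``len_sd``
    standard deviations. Zero-variance bundles (identical fibers) have no
    outliers. Rules iterate to convergence, at most ``max_rounds`` times.
    """
    if len(bundle) < 5:
        raise PreconditionError("need at least 5 streamlines to clean")
    if bundle.provenance not in ("selected", "cleaned"):
        raise PreconditionError("clean_outliers expects a selected bundle")
    fibers = list(bundle.streamlines)
    core_mean = core_cov = None
    for _ in range(max_rounds):
        P = np.stack([resample_equidistant(s, n_nodes).points for s in fibers])
        cd = _core_distances(P)
        sd_cd = cd.std(ddof=0)
        keep = np.ones(len(fibers), dtype=bool)
        if sd_cd > 0:
            keep &= cd <= cd.mean() + core_sd * sd_cd
        lengths = np.array([s.arc_length for s in fibers])
        sd_len = lengths.std(ddof=0)
        if sd_len > 0:
            keep &= lengths <= lengths.mean() + len_sd * sd_len
        if not np.any(keep):
            raise DegenerateBundleError("outlier rules removed every fiber")
        core_mean = P.mean(axis=0)
        core_cov = np.stack(
            [np.atleast_2d(np.cov(P[:, j, :].T, ddof=0)) for j in range(n_nodes)]
        )
        if np.all(keep):
            break
        fibers = [f for f, k in zip(fibers, keep) if k]
    return FiberBundle(
        streamlines=fibers, provenance="cleaned",
        core_mean=core_mean, core_cov=core_cov,
    )


def central_fiber(
    bundle: FiberBundle,
    roi1: ROISphere,
    roi2: ROISphere,
    n_nodes: int = 20,
) -> CentralFiber:
    """Average the cleaned bundle into one central fiber.

    Fibers are oriented nerve-head-first, resampled to ``n_nodes``, averaged
    node-wise; endpoints falling outside their ROI sphere are projected onto
    it, and the result is re-resampled to exactly ``n_nodes`` equidistant-arc
    nodes (node 1 at the ROI-1 end).
    """
    if len(bundle) < 1:
        raise PreconditionError("empty bundle")
    oriented = _orient_bundle(bundle.streamlines, roi1)
    P = np.stack([resample_equidistant(s, n_nodes).points for s in oriented])
    mean = P.mean(axis=0)
    for end, roi in ((0, roi1), (-1, roi2)):
        c = np.asarray(roi.center)
        v = mean[end] - c
        r = np.linalg.norm(v)
        if r > roi.radius:
            mean[end] = c + v * (roi.radius / r)
    out = Streamline(points=mean)
    # iterate to a fixed point so consecutive-node spacing is equal along
    # the fiber's own polyline, not just along its parent curve
    for _ in range(50):
        out = resample_equidistant(out, n_nodes)
        seg = np.linalg.norm(np.diff(out.points, axis=0), axis=1)
        if seg.max() - seg.min() <= 1e-9 * seg.mean():
            break
    return CentralFiber(points=out.points)


# ---------------------------------------------------------------------------
# export


def save_bundle_tck(bundle: FiberBundle, path: str | Path) -> Path:
    """Write the bundle as a TCK file (RAS+ mm)."""
    import nibabel.streamlines as nibs

    tractogram = nibs.Tractogram(
        [s.points for s in bundle.streamlines], affine_to_rasmm=np.eye(4)
    )
    nibs.save(tractogram, str(path))
    return Path(path)


def save_bundle_csv(bundle: FiberBundle, path: str | Path) -> Path:
    """Plain-text export: one row per (fiber_id, node, x, y, z)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fiber_id", "node", "x", "y", "z"])
        for i, s in enumerate(bundle.streamlines):
            for j, p in enumerate(s.points):
                w.writerow([i, j, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}"])
    return Path(path)
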