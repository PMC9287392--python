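"""Synthetic orbital DWI phantoms with a curved tubular optic nerve.

The generator emulates a 2 mm-isotropic whole-orbit acquisition: 48
diffusion directions at b = 2000 s/mm^2 plus two opposed-phase b0 volumes.
The nerve is a ~25 mm gentle S-curve tube of ~4 mm diameter whose voxels
carry an axially symmetric tensor (eigenvalues AD, RD, RD along the local
tangent); the surround is CSF-like isotropic. Signal follows the
monoexponential tensor model with Rician noise, and a cohort builder links
per-nerve ground-truth FA to RNFL thickness so the downstream statistics
have a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import reference
from .dwi_core import DWIDataset, GradientTable, ROISphere
from .errors import PreconditionError
from .tensor_fit import TensorField

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "NervePhantom",
    "PhantomBundle",
    "make_centerline",
    "ground_truth_tensors",
    "simulate_signal",
    "place_rois",
    "make_phantom",
    "make_cohort",
    "acquisition_scheme",
    "electrostatic_directions",
    "axially_symmetric_fa",
    "save_ground_truth",
]

_CENTERLINE_STEP_MM = 0.5


def axially_symmetric_fa(ad: float, rd: float) -> float:
    """Closed-form FA of an axially symmetric tensor (ad, rd, rd)."""
    return float((ad - rd) / math.sqrt(ad**2 + 2 * rd**2))


def electrostatic_directions(n: int, seed: int = 20, n_iter: int = 200, step: float = 0.05) -> np.ndarray:
    """n unit vectors spread by antipodally symmetric Coulomb repulsion.

    Deterministic for a given seed; the default scheme is frozen and serves
    as the package's acquisition fixture.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sign in (1.0, -1.0):
            diff = v[:, None, :] - sign * v[None, :, :]  # (n, n, 3)
            d2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            d2 = np.maximum(d2, 1e-9)
            force += np.sum(diff / d2[..., None] ** 1.5, axis=1)
        # project onto tangent plane and take a damped step
        force -= np.sum(force * v, axis=1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        v = v + step * force / np.maximum(norm.max(), 1e-9)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def acquisition_scheme(n_dirs: int = 48, bval: float = 2000.0) -> GradientTable:
    """Default gradient table: AP b0, PA b0, then ``n_dirs`` DWI volumes."""
    dirs = electrostatic_directions(n_dirs)
    bvals = np.concatenate([[0.0, 0.0], np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((2, 3)), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs, b0_phase=("AP", "PA"))


def _default_ctrl_points(grid_shape, voxel_size, length_mm=25.0, amplitude_mm=3.0):
    """Gentle S-curve along +y through the grid centre, in the x-y plane."""
    nx, ny, nz = grid_shape
    c = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0]) * voxel_size
    ys = np.linspace(-length_mm / 2.0, length_mm / 2.0, 5)
    pts = []
    for y in ys:
        x = amplitude_mm * math.sin(math.pi * (y + length_mm / 2.0) / length_mm - math.pi / 2.0)
        pts.append((c[0] + x, c[1] + y, c[2]))
    return tuple(pts)


@dataclass(eq=False)
class PhantomSpec:
    """Geometry, tissue parameters and acquisition of one nerve phantom.

    Diffusivities are on the printed clinical scale (1e-3 mm^2/s): the
    healthy default profile is AD 0.955 / RD 0.510 and the surround is
    CSF-like isotropic MD 3.0. ``snr`` is the ratio of the b0 signal S0 to
    the Gaussian noise sigma of each quadrature channel; ``np.inf`` disables
    noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 33)
    voxel_size: float = 2.0
    centerline_ctrl_points: tuple[tuple[float, float, float], ...] | None = None
    tube_radius: float = 2.0
    nerve_ad: float = 0.955
    nerve_rd: float = 0.510
    background_md: float = 3.0
    s0: float = 1000.0
    snr: float = 20.0
    seed: int = 0
    n_dirs: int = 48
    bval: float = 2000.0
    noise_model: str = "rician"
    partial_volume: bool = False

    def __post_init__(self) -> None:
        if not (self.nerve_ad >= self.nerve_rd > 0):
            raise PreconditionError("need nerve_AD >= nerve_RD > 0")
        if not self.tube_radius > 0:
            raise PreconditionError("tube_radius must be > 0")
        if not self.snr > 0:
            raise PreconditionError("snr must be > 0")
        if self.s0 < 0:
            raise PreconditionError("S0 must be non-negative")
        if self.noise_model not in ("rician", "gaussian"):
            raise PreconditionError("noise_model must be 'rician' or 'gaussian'")
        if self.centerline_ctrl_points is None:
            self.centerline_ctrl_points = _default_ctrl_points(
                self.grid_shape, self.voxel_size
            )
        self.centerline_ctrl_points = tuple(
            tuple(float(x) for x in p) for p in self.centerline_ctrl_points
        )

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size
        return a

    @property
    def fa_truth(self) -> float:
        return axially_symmetric_fa(self.nerve_ad, self.nerve_rd)


def _bounds_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Volume edges in mm (voxel centres at integer indices)."""
    h = spec.voxel_size
    lo = np.full(3, -h / 2.0)
    hi = (np.asarray(spec.grid_shape) - 0.5) * h
    return lo, hi


def _catmull_rom(ctrl: np.ndarray, samples_per_seg: int = 200) -> np.ndarray:
    """Centripetal-flavoured Catmull-Rom: C1 curve through the control points."""
    if len(ctrl) == 2:
        t = np.linspace(0.0, 1.0, samples_per_seg)[:, None]
        return ctrl[0] + t * (ctrl[1] - ctrl[0])
    padded = np.vstack([2 * ctrl[0] - ctrl[1], ctrl, 2 * ctrl[-1] - ctrl[-2]])
    out = []
    for i in range(len(ctrl) - 1):
        p0, p1, p2, p3 = padded[i : i + 4]
        t = np.linspace(0.0, 1.0, samples_per_seg, endpoint=(i == len(ctrl) - 2))[:, None]
        a = 2 * p1
        b = p2 - p0
        c = 2 * p0 - 5 * p1 + 4 * p2 - p3
        d = -p0 + 3 * p1 - 3 * p2 + p3
        out.append(0.5 * (a + b * t + c * t**2 + d * t**3))
    return np.vstack(out)


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def make_centerline(spec: PhantomSpec) -> np.ndarray:
    """Smooth nerve centerline resampled at 0.5 mm arc-length steps (mm points)."""
    ctrl = np.asarray(spec.centerline_ctrl_points, dtype=float)
    if len(ctrl) < 2:
        raise PreconditionError("need at least 2 control points")
    dense = _catmull_rom(ctrl)
    s = _arc_lengths(dense)
    total = s[-1]
    if total <= 0:
        raise PreconditionError("degenerate centerline")
    n_steps = max(2, int(math.floor(total / _CENTERLINE_STEP_MM)) + 1)
    targets = np.arange(n_steps) * _CENTERLINE_STEP_MM
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    line = np.column_stack([np.interp(targets, s, dense[:, k]) for k in range(3)])
    lo, hi = _bounds_mm(spec)
    r = spec.tube_radius
    if np.any(line < lo + r) or np.any(line > hi - r):
        raise PreconditionError(
            "centerline does not keep a tube_radius margin inside the grid"
        )
    return line


def _voxel_centers_mm(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    return np.stack([ii, jj, kk], axis=-1) * spec.voxel_size


def _nearest_on_polyline(points: np.ndarray, line: np.ndarray):
    """Distance to and tangent at the nearest point of a dense polyline."""
    from scipy.spatial import cKDTree

    tree = cKDTree(line)
    dist, idx = tree.query(points.reshape(-1, 3))
    tangents = np.gradient(line, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    return dist, tangents[idx]


def ground_truth_tensors(spec: PhantomSpec, centerline: np.ndarray) -> TensorField:
    """Known tensor field: axially symmetric along the local tangent inside
    the tube, isotropic ``background_MD`` outside.

    With ``spec.partial_volume`` each voxel is the average of a 3x3x3
    sub-voxel sampling of the same rule, mimicking partial-volume mixing at
    the tube boundary.
    """
    centers = _voxel_centers_mm(spec)
    shape = spec.grid_shape

    def tensor_at(points: np.ndarray) -> np.ndarray:
        dist, tang = _nearest_on_polyline(points, centerline)
        n = len(points.reshape(-1, 3))
        t = np.empty((n, 3, 3))
        iso = spec.background_md * np.eye(3)
        t[:] = iso
        inside = dist <= spec.tube_radius
        if np.any(inside):
            tt = tang[inside]
            outer = tt[:, :, None] * tt[:, None, :]
            t[inside] = spec.nerve_rd * np.eye(3) + (spec.nerve_ad - spec.nerve_rd) * outer
        return t

    flat = centers.reshape(-1, 3)
    if spec.partial_volume:
        h = spec.voxel_size
        offsets = np.array(
            [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
        ) * (h / 3.0)
        acc = np.zeros((len(flat), 3, 3))
        for off in offsets:
            acc += tensor_at(flat + off)
        tensors = (acc / len(offsets)).reshape(shape + (3, 3))
    else:
        tensors = tensor_at(flat).reshape(shape + (3, 3))
    mask = np.ones(shape, dtype=bool)
    return TensorField(tensors=tensors, mask=mask, affine=spec.affine)


def tube_mask(spec: PhantomSpec, centerline: np.ndarray) -> np.ndarray:
    """Boolean grid of voxels whose centre lies within the tube radius."""
    centers = _voxel_centers_mm(spec).reshape(-1, 3)
    dist, _ = _nearest_on_polyline(centers, centerline)
    return (dist <= spec.tube_radius).reshape(spec.grid_shape)


def simulate_signal(
    tensors: TensorField,
    gradients: GradientTable,
    s0: float = 1000.0,
    snr: float = 20.0,
    seed: int = 0,
    noise_model: str = "rician",
) -> DWIDataset:
    """Monoexponential tensor-model signal with Rician (or Gaussian) noise.

    S = S0 exp(-b g^T D g) with b in s/mm^2 and D converted from printed
    units to mm^2/s; Rician noise is |S + e1 + i e2| with independent
    Gaussian channels of sigma = S0 / snr. ``snr=np.inf`` gives the
    noiseless signal.
    """
    if s0 < 0:
        raise PreconditionError("S0 must be non-negative")
    if not snr > 0:
        raise PreconditionError("snr must be > 0")
    g = gradients.bvecs
    b = gradients.bvals * 1e-3  # pairs with printed-scale D
    gg = np.einsum("ni,nj->nij", g, g).reshape(len(g), 9)
    D9 = tensors.tensors.reshape(-1, 9)
    quad = D9 @ gg.T  # (n_vox, n_vol)
    S = s0 * np.exp(-b[None, :] * quad)
    if np.isfinite(snr):
        sigma = s0 / snr
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            e1 = rng.normal(0.0, sigma, size=S.shape)
            e2 = rng.normal(0.0, sigma, size=S.shape)
            S = np.sqrt((S + e1) ** 2 + e2**2)
        elif noise_model == "gaussian":
            S = np.abs(S + rng.normal(0.0, sigma, size=S.shape))
        else:
            raise PreconditionError(f"unknown noise model {noise_model!r}")
    S = S.reshape(tensors.shape + (len(g),))
    return DWIDataset(signal=S, affine=tensors.affine, gradients=gradients)


def place_rois(centerline: np.ndarray, radius: float = 3.0) -> tuple[ROISphere, ROISphere]:
    """Two 3 mm spheres at 5% (retrobulbar / nerve-head end) and 95%
    (orbital apex end) of the centerline arc length."""
    s = _arc_lengths(centerline)
    if s[-1] <= 10.0:
        raise PreconditionError("centerline must be longer than 10 mm")
    centers = []
    for frac in (0.05, 0.95):
        target = frac * s[-1]
        centers.append([np.interp(target, s, centerline[:, k]) for k in range(3)])
    return ROISphere(tuple(centers[0]), radius), ROISphere(tuple(centers[1]), radius)


@dataclass(eq=False)
class PhantomBundle:
    """One materialised nerve phantom: data plus every ground-truth object."""

    spec: PhantomSpec
    dataset: DWIDataset
    centerline: np.ndarray
    rois: tuple[ROISphere, ROISphere]
    truth: TensorField
    tube: np.ndarray


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build centerline, ground-truth tensors, ROIs and the simulated scan."""
    line = make_centerline(spec)
    truth = ground_truth_tensors(spec, line)
    gtab = acquisition_scheme(spec.n_dirs, spec.bval)
    ds = simulate_signal(
        truth, gtab, s0=spec.s0, snr=spec.snr, seed=spec.seed,
        noise_model=spec.noise_model,
    )
    return PhantomBundle(
        spec=spec, dataset=ds, centerline=line,
        rois=place_rois(line), truth=truth, tube=tube_mask(spec, line),
    )


def save_ground_truth(truth: TensorField, path: str | Path) -> Path:
    """Write a 5-volume NIfTI: lambda1..3 plus the polar angles (theta, phi)
    of the principal axis, for oracle tests against fitted maps."""
    ev = truth.eigenvalues
    e1 = truth.principal_axis
    theta = np.arccos(np.clip(np.abs(e1[..., 2]), 0.0, 1.0))
    phi = np.arctan2(e1[..., 1], e1[..., 0])
    vols = np.stack([ev[..., 0], ev[..., 1], ev[..., 2], theta, phi], axis=-1)
    nib.save(nib.Nifti1Image(vols.astype(np.float32), truth.affine), str(path))
    return Path(path)


def _derived_rnfl_link() -> tuple[float, float, float]:
    """(intercept, slope, noise SD) of the RNFL <- FA link, anchored to the
    published group means: the line passes through the two patient-group
    (ground-truth FA, mean RNFL) points, and the noise SD reproduces the
    reported FA-RNFL R^2 given the between-group FA spread."""
    fa_a = axially_symmetric_fa(
        reference.GROUP_MEANS["atrophic"]["AD"], reference.GROUP_MEANS["atrophic"]["RD"]
    )
    fa_n = axially_symmetric_fa(
        reference.GROUP_MEANS["non_affected"]["AD"],
        reference.GROUP_MEANS["non_affected"]["RD"],
    )
    rnfl_a = float(np.mean(reference.RNFL_AFFECTED_UM))
    rnfl_n = float(np.mean(reference.RNFL_NON_AFFECTED_UM))
    slope = (rnfl_n - rnfl_a) / (fa_n - fa_a)
    intercept = rnfl_a - slope * fa_a
    half_gap = (fa_n - fa_a) / 2.0
    noise_sd = abs(slope) * half_gap * math.sqrt(1.0 / reference.FA_RNFL_R2 - 1.0)
    return intercept, slope, noise_sd


@dataclass(eq=False)
class CohortSpec:
    """Study design of the synthetic cohort.

    Six patients contribute one atrophic and one non-affected nerve each;
    eleven controls contribute two control nerves. Per-nerve (AD, RD) are
    the group profile plus correlated Gaussian jitter (printed group SDs,
    correlation ``jitter_corr``, a ``subject_share`` fraction of the
    variance shared between a subject's two eyes). RNFL thickness is a
    linear function of ground-truth FA plus Gaussian noise; the default
    link is anchored to the published group means and R^2.
    """

    n_patients: int = reference.N_PATIENTS
    n_controls: int = reference.N_CONTROLS
    profiles: dict = field(default_factory=lambda: {
        g: (reference.GROUP_MEANS[g]["AD"], reference.GROUP_MEANS[g]["RD"])
        for g in ("atrophic", "non_affected", "control")
    })
    jitter_sds: dict = field(default_factory=lambda: {
        g: (reference.GROUP_SDS[g]["AD"], reference.GROUP_SDS[g]["RD"])
        for g in ("atrophic", "non_affected", "control")
    })
    jitter_corr: float = 0.9
    subject_share: float = 0.5
    rnfl_intercept: float | None = None
    rnfl_slope: float | None = None
    rnfl_noise_sd: float | None = None
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise PreconditionError("need at least one patient and one control")
        if not 0.0 <= self.subject_share <= 1.0:
            raise PreconditionError("subject_share must be in [0, 1]")
        if not -1.0 < self.jitter_corr < 1.0:
            raise PreconditionError("jitter_corr must be in (-1, 1)")
        intercept, slope, noise = _derived_rnfl_link()
        if self.rnfl_intercept is None:
            self.rnfl_intercept = intercept
        if self.rnfl_slope is None:
            self.rnfl_slope = slope
        if self.rnfl_noise_sd is None:
            self.rnfl_noise_sd = noise
        if self.rnfl_noise_sd < 0:
            raise PreconditionError("rnfl_noise_sd must be >= 0")


@dataclass(eq=False)
class NervePhantom:
    """One nerve of the cohort: identity, ground-truth parameters and the
    fully specified phantom (materialise it with :meth:`build`)."""

    subject_id: str
    eye: str
    group: str
    ad: float
    rd: float
    fa_truth: float
    rnfl_um: float
    spec: PhantomSpec

    def build(self) -> PhantomBundle:
        return make_phantom(self.spec)


def make_cohort(cspec: CohortSpec) -> tuple[list[NervePhantom], pd.DataFrame]:
    """Draw the cohort: per-nerve diffusivities, RNFL values and specs.

    Returns the list of nerve phantoms and the cohort metadata table
    (subject_id, eye, group, rnfl_um, ground-truth AD/RD/FA, per-nerve seed).
    All randomness derives from ``cspec.seed``.
    """
    rng = np.random.default_rng(cspec.seed)
    rho = cspec.jitter_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))

    def draw_pair(z_subj: np.ndarray) -> np.ndarray:
        z_eye = chol @ rng.standard_normal(2)
        f = cspec.subject_share
        return math.sqrt(f) * z_subj + math.sqrt(1.0 - f) * z_eye

    def nerve_params(group: str, z_subj: np.ndarray) -> tuple[float, float]:
        mean_ad, mean_rd = cspec.profiles[group]
        sd_ad, sd_rd = cspec.jitter_sds[group]
        z = draw_pair(z_subj)
        ad = mean_ad + sd_ad * z[0]
        rd = mean_rd + sd_rd * z[1]
        ad = max(ad, 0.05)
        rd = float(np.clip(rd, 0.02, 0.98 * ad))
        return float(ad), rd

    nerves: list[NervePhantom] = []
    rows = []
    subjects = [("P%02d" % (i + 1), ("atrophic", "non_affected")) for i in range(cspec.n_patients)]
    subjects += [("C%02d" % (i + 1), ("control", "control")) for i in range(cspec.n_controls)]
    for subject_id, groups in subjects:
        z_subj = chol @ rng.standard_normal(2)
        for eye, group in zip(("OD", "OS"), groups):
            ad, rd = nerve_params(group, z_subj)
            fa = axially_symmetric_fa(ad, rd)
            rnfl = (
                cspec.rnfl_intercept
                + cspec.rnfl_slope * fa
                + rng.normal(0.0, cspec.rnfl_noise_sd)
            )
            nerve_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                cspec.phantom, nerve_ad=ad, nerve_rd=rd, seed=nerve_seed,
                centerline_ctrl_points=cspec.phantom.centerline_ctrl_points,
            )
            nerves.append(
                NervePhantom(
                    subject_id=subject_id, eye=eye, group=group, ad=ad, rd=rd,
                    fa_truth=fa, rnfl_um=float(rnfl), spec=spec,
                )
            )
            rows.append(
                dict(
                    subject_id=subject_id, eye=eye, group=group,
                    rnfl_um=float(rnfl), ad_truth=ad, rd_truth=rd,
                    fa_truth=fa, seed=nerve_seed,
                )
            )
    return nerves, pd.DataFrame(rows)
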