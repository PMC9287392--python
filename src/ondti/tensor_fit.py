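"""Per-voxel diffusion tensor estimation and scalar maps.

The tensor is fit by log-linear ordinary least squares on
``ln S_i = ln S0 - b_i g_i^T D g_i`` with the six unique tensor components
plus ``ln S0`` as unknowns, optionally followed by a residual bootstrap that
yields per-measure uncertainty maps. Diffusivities are handled on the
printed clinical scale (units of 1e-3 mm^2/s): the design matrix absorbs the
1e-3 so that recovered components are numerically ~0.5-3.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .dwi_core import DWIDataset
from .errors import PreconditionError

__all__ = [
    "TensorField",
    "ScalarMaps",
    "design_matrix",
    "fit_tensor_lls",
    "bootstrap_tensor",
    "eigensystem",
    "scalar_maps",
    "save_scalar_maps",
    "DIFFUSIVITY_SCALE",
]

log = logging.getLogger(__name__)

#: printed diffusivity unit -> mm^2/s
DIFFUSIVITY_SCALE = 1e-3

# order of the unique components in the design matrix / coefficient vector
_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass(eq=False)
class TensorField:
    """Per-voxel symmetric diffusion tensors over a mask.

    ``tensors`` is (x, y, z, 3, 3) in printed diffusivity units; voxels
    outside ``mask`` are zero. Eigensystems are computed lazily and cached.
    """

    tensors: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    _evals: np.ndarray | None = field(default=None, repr=False)
    _evecs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise PreconditionError("tensors must be (..., 3, 3)")
        if self.tensors.shape[:3] != self.mask.shape:
            raise PreconditionError("mask shape does not match tensor grid")
        if not np.all(np.isfinite(self.tensors[self.mask])):
            raise PreconditionError("non-finite tensor inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def _decompose(self) -> None:
        if self._evals is not None:
            return
        w, v = np.linalg.eigh(self.tensors)  # ascending
        self._evals = w[..., ::-1]
        self._evecs = v[..., :, ::-1]  # columns are eigenvectors, descending

    @property
    def eigenvalues(self) -> np.ndarray:
        """(x, y, z, 3) eigenvalues sorted descending (lambda1 first)."""
        self._decompose()
        return self._evals

    @property
    def principal_axis(self) -> np.ndarray:
        """(x, y, z, 3) unit eigenvector of the largest eigenvalue."""
        self._decompose()
        return self._evecs[..., :, 0]


@dataclass(eq=False)
class ScalarMaps:
    """FA/MD/AD/RD volumes (NaN outside the mask) sharing one affine.

    ``sd`` optionally holds bootstrap standard-deviation maps keyed
    ``fa``, ``md``, ``ad``, ``rd``.
    """

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    sd: dict[str, np.ndarray] | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"fa": self.fa, "md": self.md, "ad": self.ad, "rd": self.rd}


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(n, 7) log-linear design: columns for Dxx..Dyz (printed units) + ln S0."""
    b = np.asarray(bvals, dtype=float) * DIFFUSIVITY_SCALE
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
            np.ones(len(b)),
        ]
    )


def _coeffs_to_tensors(beta: np.ndarray) -> np.ndarray:
    """Map (..., >=6) LLS coefficients to (..., 3, 3) symmetric tensors."""
    t = np.empty(beta.shape[:-1] + (3, 3), dtype=float)
    t[..., 0, 0] = beta[..., 0]
    t[..., 1, 1] = beta[..., 1]
    t[..., 2, 2] = beta[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = beta[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = beta[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = beta[..., 5]
    return t


def _check_design(X: np.ndarray) -> None:
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise PreconditionError(
            "rank-deficient design: need >=6 non-collinear DWI directions and >=1 b0"
        )


def _prepare(ds: DWIDataset, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    if mask is None:
        mask = np.ones(ds.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ds.shape:
        raise PreconditionError("mask shape does not match dataset grid")
    X = design_matrix(ds.gradients.bvals, ds.gradients.bvecs)
    _check_design(X)
    return mask, X


def fit_tensor_lls(ds: DWIDataset, mask: np.ndarray | None = None) -> TensorField:
    """Ordinary least squares fit of the log signal per masked voxel.

    Measurements with non-positive signal are dropped per voxel (a log of
    zero would be undefined); a voxel with fewer than 7 usable measurements
    is removed from the output mask, with the count reported via logging.
    """
    mask, X = _prepare(ds, mask)
    S = ds.signal[mask]  # (n_vox, n_meas)
    n_vox = S.shape[0]
    tensors = np.zeros(ds.shape + (3, 3), dtype=float)
    out_mask = mask.copy()
    if n_vox == 0:
        return TensorField(tensors=tensors, mask=out_mask, affine=ds.affine)

    good = S > 0
    all_good = good.all(axis=1)
    beta = np.full((n_vox, 7), np.nan)
    if np.any(all_good):
        pinv = np.linalg.pinv(X)
        beta[all_good] = np.log(S[all_good]) @ pinv.T
    n_dropped_voxels = 0
    for i in np.flatnonzero(~all_good):
        keep = good[i]
        if keep.sum() < 7 or np.linalg.matrix_rank(X[keep]) < 7:
            n_dropped_voxels += 1
            continue
        beta[i], *_ = np.linalg.lstsq(X[keep], np.log(S[i, keep]), rcond=None)
    if n_dropped_voxels:
        log.warning("excluded %d voxel(s) with <7 positive measurements", n_dropped_voxels)

    ok = np.all(np.isfinite(beta), axis=1)
    idx = np.argwhere(mask)
    bad_idx = idx[~ok]
    out_mask[tuple(bad_idx.T)] = False
    tensors[mask] = np.where(ok[:, None, None], _coeffs_to_tensors(beta), 0.0)
    return TensorField(tensors=tensors, mask=out_mask, affine=ds.affine)


def bootstrap_tensor(
    ds: DWIDataset,
    mask: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[TensorField, dict[str, np.ndarray]]:
    """Residual bootstrap of the log-linear fit.

    Whole-model residuals are resampled with replacement per voxel, the fit
    repeated ``n_boot`` times, and the mean tensor plus the standard
    deviation of FA/MD/AD/RD over replicates returned. Voxels with any
    non-positive measurement are excluded from the bootstrap mask.
    """
    if n_boot < 2:
        raise PreconditionError("n_boot must be >= 2")
    mask, X = _prepare(ds, mask)
    good_vox = mask & np.all(ds.signal > 0, axis=3)
    n_excl = int(mask.sum() - good_vox.sum())
    if n_excl:
        log.warning("bootstrap: excluded %d voxel(s) with non-positive signal", n_excl)
    S = ds.signal[good_vox]
    n_vox, n_meas = S.shape
    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(X)

    Y = np.log(S)
    beta0 = Y @ pinv.T
    fitted = beta0 @ X.T
    resid = Y - fitted

    # accumulate replicate measures as deviations from the point fit so the
    # variance does not lose precision when residuals are ~0
    base_ev = np.linalg.eigvalsh(_coeffs_to_tensors(beta0))[..., ::-1]
    base = _measures_from_evals(base_ev)
    sum_t = np.zeros((n_vox, 3, 3))
    meas_sums = {k: np.zeros(n_vox) for k in ("fa", "md", "ad", "rd")}
    meas_sq = {k: np.zeros(n_vox) for k in ("fa", "md", "ad", "rd")}
    chunk = max(1, min(n_boot, int(5e7 // max(1, n_vox * n_meas))))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n_meas, size=(m, n_vox, n_meas))
        Ystar = fitted[None] + np.take_along_axis(resid[None].repeat(m, 0), idx, axis=2)
        bstar = Ystar @ pinv.T  # (m, n_vox, 7)
        tstar = _coeffs_to_tensors(bstar)
        sum_t += tstar.sum(axis=0)
        ev = np.linalg.eigvalsh(tstar)[..., ::-1]
        vals = _measures_from_evals(ev)
        for k in meas_sums:
            dev = vals[k] - base[k][None, :]
            meas_sums[k] += dev.sum(axis=0)
            meas_sq[k] += (dev**2).sum(axis=0)
        done += m

    tensors = np.zeros(ds.shape + (3, 3))
    tensors[good_vox] = sum_t / n_boot
    mean_tf = TensorField(tensors=tensors, mask=good_vox, affine=ds.affine)
    sd_maps: dict[str, np.ndarray] = {}
    for k in meas_sums:
        var = meas_sq[k] / n_boot - (meas_sums[k] / n_boot) ** 2
        vol = np.full(ds.shape, np.nan)
        vol[good_vox] = np.sqrt(np.clip(var, 0.0, None))
        sd_maps[k] = vol
    return mean_tf, sd_maps


def eigensystem(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of one symmetric 3x3 tensor.

    Returns eigenvalues sorted descending and the matching unit eigenvectors
    as rows ``(e1, e2, e3)``, each sign-fixed so its largest-magnitude
    component is positive.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise PreconditionError("tensor must be 3x3")
    if not np.all(np.isfinite(tensor)):
        raise PreconditionError("non-finite tensor")
    if not np.allclose(tensor, tensor.T, atol=1e-10):
        raise PreconditionError("tensor must be symmetric")
    w, v = np.linalg.eigh(tensor)
    order = np.argsort(w)[::-1]
    w = w[order]
    vecs = v[:, order].T
    for i in range(3):
        j = np.argmax(np.abs(vecs[i]))
        if vecs[i, j] < 0:
            vecs[i] = -vecs[i]
    return w, vecs


def _measures_from_evals(ev: np.ndarray) -> dict[str, np.ndarray]:
    """FA/MD/AD/RD from descending eigenvalues (..., 3).

    Negative eigenvalues are clamped to zero for FA only; MD/AD/RD use the
    raw values so that MD == (AD + 2 RD) / 3 holds exactly.
    """
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = 0.5 * (ev[..., 1] + ev[..., 2])
    lc = np.clip(ev, 0.0, None)
    mbar = lc.mean(axis=-1, keepdims=True)
    num = np.sum((lc - mbar) ** 2, axis=-1)
    den = np.sum(lc**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return {"fa": fa, "md": md, "ad": ad, "rd": rd}


def scalar_maps(tf: TensorField, sd: dict[str, np.ndarray] | None = None) -> ScalarMaps:
    """Compute the four tensor-derived measures over the field's mask.

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda|| (clamped eigenvalues),
    MD = mean eigenvalue, AD = lambda1, RD = (lambda2 + lambda3) / 2.
    Voxels outside the mask are NaN. A count of clamped (negative)
    eigenvalues is reported via logging.
    """
    ev = tf.eigenvalues[tf.mask]
    n_neg = int(np.sum(ev < 0))
    if n_neg:
        log.info("clamped %d negative eigenvalue(s) for FA", n_neg)
    vals = _measures_from_evals(ev)
    vols = {}
    for k, v in vals.items():
        vol = np.full(tf.shape, np.nan)
        vol[tf.mask] = v
        vols[k] = vol
    return ScalarMaps(
        fa=vols["fa"], md=vols["md"], ad=vols["ad"], rd=vols["rd"],
        affine=tf.affine, mask=tf.mask.copy(), sd=sd,
    )


def save_scalar_maps(maps: ScalarMaps, out_dir: str | Path) -> list[Path]:
    """Write fa/md/ad/rd (and any bootstrap SDs) as NIfTI volumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.as_dict().items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), maps.affine), str(p))
        written.append(p)
    for name, vol in (maps.sd or {}).items():
        p = out_dir / f"{name}_sd.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), maps.affine), str(p))
        written.append(p)
    return written
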