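"""Data model and I/O for diffusion-weighted volumes and gradient tables.

Conventions used by every module in this package:

* world coordinates are RAS+ millimetres;
* voxel indices are 0-based and voxel *centres* sit at integer indices, so
  the affine maps index ``(i, j, k)`` to the centre of that voxel in mm;
* b-values are in s/mm^2; diffusivities are stored on the printed clinical
  scale (numerically ~0.5-3.0, units of 1e-3 mm^2/s) and converted by 1e-3
  only inside the signal model and the tensor fit;
* the bval/bvec text dialect is FSL's (one whitespace-separated row of
  b-values; three rows of x, y, z components), with b0 phase-encoding tags
  carried in a JSON sidecar ``{"b0_phase": ["AP", "PA"]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, PreconditionError

__all__ = [
    "GradientTable",
    "DWIDataset",
    "ROISphere",
    "load_dwi",
    "save_dwi",
    "merge_b0_pairs",
    "sidecar_path_for",
]

B0_PHASES = ("AP", "PA", "none")


@dataclass(eq=False)
class GradientTable:
    """Per-volume diffusion weighting: b-values, unit gradient directions and
    the phase-encoding tag of each b0 volume (in acquisition order)."""

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_phase: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"{len(self.bvals)} b-values vs {len(self.bvecs)} b-vectors"
            )
        if np.any(self.bvals < 0):
            raise FormatError("negative b-value")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-6):
            raise FormatError("non-unit b-vector at b > 0")
        if np.any(norms[~dwi] > 1e-12):
            raise FormatError("b0 volume with a nonzero b-vector")
        self.b0_phase = tuple(self.b0_phase)
        for tag in self.b0_phase:
            if tag not in B0_PHASES:
                raise FormatError(f"unknown phase tag {tag!r}")
        if self.b0_phase and len(self.b0_phase) != int(np.sum(~dwi)):
            raise FormatError(
                f"{len(self.b0_phase)} phase tags for {int(np.sum(~dwi))} b0 volumes"
            )

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def n_dwi(self) -> int:
        return int(np.sum(self.dwi_mask))


@dataclass(eq=False)
class DWIDataset:
    """A 4-D diffusion acquisition: signal (x, y, z, volume), RAS+ affine and
    the matching gradient table."""

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] == 0:
            raise FormatError("dataset with 0 volumes")
        if self.signal.shape[3] != self.gradients.n_volumes:
            raise FormatError(
                f"{self.signal.shape[3]} volumes vs "
                f"{self.gradients.n_volumes} gradient entries"
            )
        if np.any(self.signal < 0):
            raise FormatError("negative signal values")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("non-invertible affine")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass(frozen=True)
class ROISphere:
    """A spherical region of interest in RAS+ mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise PreconditionError("ROI radius must be > 0")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.linalg.norm(points - np.asarray(self.center), axis=-1) <= self.radius


def sidecar_path_for(nifti_path: str | Path) -> Path:
    """JSON sidecar path conventionally paired with a NIfTI file."""
    p = Path(nifti_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def load_dwi(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> DWIDataset:
    """Read a 4-D NIfTI plus FSL-style bval/bvec files into a DWIDataset.

    b-vectors of diffusion-weighted volumes are re-normalized to unit length
    when within 1e-3 of unit norm; larger deviations are a format error.
    Phase-encoding tags for the b0 volumes are read from the JSON sidecar if
    one is present (default: same stem with a ``.json`` suffix), otherwise
    every b0 is tagged ``none``.
    """
    for p in (nifti_path, bval_path, bvec_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.dataobj, dtype=float)
    if signal.ndim == 3:
        signal = signal[..., None]
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL dialect: rows are x, y, z
    if len(bvals) != signal.shape[3] or len(bvecs) != signal.shape[3]:
        raise FormatError(
            f"volume count mismatch: {signal.shape[3]} volumes, "
            f"{len(bvals)} b-values, {len(bvecs)} b-vectors"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi = bvals > 0
    bad = dwi & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        raise FormatError(
            f"{int(bad.sum())} b-vector(s) deviate from unit norm by more than 1e-3"
        )
    bvecs = bvecs.copy()
    bvecs[dwi] /= norms[dwi, None]
    bvecs[~dwi] = 0.0

    if sidecar_path is None:
        sidecar_path = sidecar_path_for(nifti_path)
    b0_phase: tuple[str, ...]
    if Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
        b0_phase = tuple(meta.get("b0_phase", ()))
    else:
        b0_phase = ("none",) * int(np.sum(~dwi))

    gtab = GradientTable(bvals=bvals, bvecs=bvecs, b0_phase=b0_phase)
    return DWIDataset(signal=signal, affine=np.asarray(img.affine), gradients=gtab)


def save_dwi(
    ds: DWIDataset,
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> tuple[Path, Path, Path, Path]:
    """Write a DWIDataset as NIfTI (float32) + bval/bvec text + JSON sidecar.

    Round trip contract: ``load_dwi`` on the written files reproduces the
    gradient table bit-identically (full-precision text) and the signal
    within float32 rounding.
    """
    nifti_path, bval_path, bvec_path = Path(nifti_path), Path(bval_path), Path(bvec_path)
    img = nib.Nifti1Image(ds.signal.astype(np.float32), ds.affine)
    nib.save(img, str(nifti_path))
    fmt = "%.17g"
    np.savetxt(bval_path, ds.gradients.bvals[None, :], fmt=fmt)
    np.savetxt(bvec_path, ds.gradients.bvecs.T, fmt=fmt)
    if sidecar_path is None:
        sidecar_path = sidecar_path_for(nifti_path)
    Path(sidecar_path).write_text(
        json.dumps({"b0_phase": list(ds.gradients.b0_phase)}, indent=1)
    )
    return nifti_path, bval_path, bvec_path, Path(sidecar_path)


def merge_b0_pairs(ds: DWIDataset) -> DWIDataset:
    """Replace all b0 volumes by their voxel-wise arithmetic mean, placed first.

    Emulates the "one corrected b0" stage of opposed-phase distortion
    correction for distortion-free data: requires at least one AP- and one
    PA-tagged b0, averages every b0 volume, and leaves the diffusion-weighted
    volumes untouched, so the output has (#DWI volumes) + 1 volumes.
    """
    g = ds.gradients
    phases = g.b0_phase
    if "AP" not in phases or "PA" not in phases:
        raise PreconditionError(
            f"need at least one AP- and one PA-tagged b0; got tags {phases}"
        )
    b0 = ds.signal[..., g.b0_mask]
    merged = b0.mean(axis=3, keepdims=True)
    dwi = ds.signal[..., g.dwi_mask]
    signal = np.concatenate([merged, dwi], axis=3)
    gtab = GradientTable(
        bvals=np.concatenate([[0.0], g.bvals[g.dwi_mask]]),
        bvecs=np.vstack([np.zeros(3), g.bvecs[g.dwi_mask]]),
        b0_phase=("none",),
    )
    return DWIDataset(signal=signal, affine=ds.affine.copy(), gradients=gtab)
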