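"""Sample scalar maps along the central fiber and summarize per nerve.

The central fiber's nodes (node 1 = nerve-head end) are interpolated into
the FA/MD/AD/RD volumes; the ``k`` nodes nearest the nerve head are excluded
(default 5 of 20, i.e. the posterior 75% is kept) and the remaining nodes
averaged into a per-nerve summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import PreconditionError
from .on_tract import CentralFiber
from .tensor_fit import ScalarMaps

__all__ = [
    "TractProfile",
    "NerveSummary",
    "sample_profile",
    "exclude_onh_nodes",
    "summarize",
    "profiles_to_frame",
    "summaries_to_frame",
]


@dataclass(eq=False)
class TractProfile:
    """Per-node diffusion measures along one nerve's central fiber."""

    nodes: np.ndarray  # (n, 3) mm
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    included: np.ndarray  # boolean per node; False = excluded from summary
    nerve_id: str = ""
    subject_id: str = ""
    eye: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for name in ("fa", "md", "ad", "rd", "included"):
            if len(getattr(self, name)) != n:
                raise PreconditionError(f"{name} length does not match node count")
        self.included = np.asarray(self.included, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass(frozen=True)
class NerveSummary:
    """Unweighted means of the four measures over the included nodes."""

    fa: float
    md: float
    ad: float
    rd: float
    n_nodes: int


def _voxel_coords(maps: ScalarMaps, points_mm: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(maps.affine)
    return points_mm @ inv[:3, :3].T + inv[:3, 3]


def sample_profile(
    cf: CentralFiber,
    maps: ScalarMaps,
    mode: str = "trilinear",
    nerve_id: str = "",
    subject_id: str = "",
    eye: str = "",
    group: str = "",
) -> TractProfile:
    """Interpolate each scalar map at the fiber's node positions.

    ``mode`` is ``"trilinear"`` (default) or ``"nearest"`` (the single-voxel
    sub-sampling variant). All nodes must fall inside the image grid;
    an offending node is named in the error. No exclusion is applied yet.
    """
    if mode not in ("trilinear", "nearest"):
        raise PreconditionError("mode must be 'trilinear' or 'nearest'")
    vox = _voxel_coords(maps, cf.points)
    shape = np.asarray(maps.fa.shape)
    outside = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    if np.any(outside):
        raise PreconditionError(
            f"node {int(np.flatnonzero(outside)[0])} lies outside the image grid"
        )
    order = 1 if mode == "trilinear" else 0
    values = {}
    for name, vol in maps.as_dict().items():
        values[name] = map_coordinates(
            vol, vox.T, order=order, mode="nearest", cval=np.nan
        )
    return TractProfile(
        nodes=cf.points.copy(),
        fa=values["fa"], md=values["md"], ad=values["ad"], rd=values["rd"],
        included=np.ones(len(vox), dtype=bool),
        nerve_id=nerve_id, subject_id=subject_id, eye=eye, group=group,
    )


def exclude_onh_nodes(p: TractProfile, k: int = 5) -> TractProfile:
    """Mask the ``k`` nodes nearest the nerve head (node 1 end)."""
    if not 0 <= k < p.n_nodes:
        raise PreconditionError(f"k must be in [0, {p.n_nodes - 1}]")
    included = np.ones(p.n_nodes, dtype=bool)
    included[:k] = False
    return replace(p, included=included & p.included)


def summarize(p: TractProfile) -> NerveSummary:
    """Arithmetic mean of each measure over the included nodes."""
    if p.n_included == 0:
        raise PreconditionError("no included nodes to summarize")
    m = p.included
    return NerveSummary(
        fa=float(np.mean(p.fa[m])),
        md=float(np.mean(p.md[m])),
        ad=float(np.mean(p.ad[m])),
        rd=float(np.mean(p.rd[m])),
        n_nodes=p.n_included,
    )


def profiles_to_frame(profiles: list[TractProfile]) -> pd.DataFrame:
    """Tidy table: one row per (nerve, node)."""
    rows = []
    for p in profiles:
        for i in range(p.n_nodes):
            rows.append(
                dict(
                    nerve_id=p.nerve_id, subject_id=p.subject_id, eye=p.eye,
                    group=p.group, node=i + 1, included=bool(p.included[i]),
                    x=p.nodes[i, 0], y=p.nodes[i, 1], z=p.nodes[i, 2],
                    FA=p.fa[i], MD=p.md[i], AD=p.ad[i], RD=p.rd[i],
                )
            )
    return pd.DataFrame(rows)


def summaries_to_frame(
    items: list[tuple[TractProfile, NerveSummary]]
) -> pd.DataFrame:
    """Tidy table: one row per nerve."""
    rows = []
    for p, s in items:
        rows.append(
            dict(
                nerve_id=p.nerve_id, subject_id=p.subject_id, eye=p.eye,
                group=p.group, n_nodes=s.n_nodes,
                FA=s.fa, MD=s.md, AD=s.ad, RD=s.rd,
            )
        )
    return pd.DataFrame(rows)
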