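"""Seed-based connectivity: seed signals, correlation maps, Fisher r-to-z."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSeedError, EmptySeedError, InvalidConfigError
from .types import BoldTimeSeries

R_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class SeedDefinition:
    """A seed is a set of node indices (ROI mode) or an MNI sphere (volume
    mode, resolved to nodes/voxels before use)."""

    label: str
    node_indices: tuple[int, ...] = ()
    mni_center: tuple[float, float, float] | None = None
    radius: float = 0.0

    def __post_init__(self):
        if not self.node_indices and self.mni_center is None:
            raise EmptySeedError(f"seed {self.label!r} has no nodes and no center")
        if self.mni_center is not None and not self.radius > 0:
            raise InvalidConfigError(f"seed {self.label!r}: radius must be > 0")


def seed_from_labels(label: str, node_labels: list[str],
                     members: list[str] | None = None) -> SeedDefinition:
    members = members if members is not None else [label]
    idx = tuple(node_labels.index(m) for m in members)
    return SeedDefinition(label=label, node_indices=idx)


@dataclass
class ConnectivityMap:
    subject_id: str
    seed_label: str
    node_labels: list[str]
    r_values: np.ndarray  # NaN sentinel on seed / zero-variance nodes
    z_values: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_label": self.node_labels,
            "r": self.r_values,
            "z": self.z_values,
        })


def seed_signal(ts: BoldTimeSeries, seed: SeedDefinition) -> np.ndarray:
    """Arithmetic mean of the seed's node columns at each time point."""
    if not seed.node_indices:
        raise EmptySeedError(f"seed {seed.label!r} resolves to no nodes")
    idx = np.asarray(seed.node_indices)
    if idx.max() >= ts.n_nodes or idx.min() < 0:
        raise EmptySeedError(f"seed {seed.label!r} indexes outside the node set")
    return ts.values[:, idx].mean(axis=1)


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r), clipped near |r| = 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValueError("|r| must be <= 1")
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def rsfc_map(ts: BoldTimeSeries, seed: SeedDefinition,
             subject_id: str = "") -> ConnectivityMap:
    """Pearson correlation of the seed signal with every node, plus Fisher z.

    Seed member nodes and zero-variance nodes carry a NaN sentinel so vector
    lengths stay aligned with the node list.
    """
    sig = seed_signal(ts, seed)
    sig_c = sig - sig.mean()
    sig_ss = float(sig_c @ sig_c)
    if sig_ss == 0.0 or np.ptp(sig) == 0.0:
        raise DegenerateSeedError(f"seed {seed.label!r} signal has zero variance")
    x = ts.values - ts.values.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", x, x)
    degenerate = (ss == 0.0) | (np.ptp(ts.values, axis=0) == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (sig_c @ x) / np.sqrt(sig_ss * ss)
    r[degenerate] = np.nan
    r = np.where(np.isnan(r), np.nan, np.clip(r, -1.0, 1.0))
    r[list(seed.node_indices)] = np.nan
    with np.errstate(invalid="ignore"):
        z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return ConnectivityMap(subject_id=subject_id, seed_label=seed.label,
                           node_labels=list(ts.node_labels), r_values=r,
                           z_values=z)


# ---------------------------------------------------------------------------
# volume-mode adapter: sphere around an MNI center on a voxel grid


def sphere_voxel_indices(shape, affine, center_mm, radius_mm) -> np.ndarray:
    """Voxel coordinates (k x 3 int array) within a sphere in world space."""
    affine = np.asarray(affine, dtype=float)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = vox @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(world - np.asarray(center_mm, dtype=float), axis=1)
    inside = vox[dist <= radius_mm]
    if inside.size == 0:
        raise EmptySeedError("sphere contains no voxels on this grid")
    return inside


def volume_seed_signal(img, center_mm, radius_mm) -> np.ndarray:
    """Mean time series of a spherical seed from a 4-D NIfTI image."""
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InvalidConfigError("expected a 4-D image")
    vox = sphere_voxel_indices(data.shape[:3], img.affine, center_mm, radius_mm)
    return data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
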