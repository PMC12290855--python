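"""Seed-to-voxel functional connectivity and winner-take-all mapping.

Spinal seeds (segmental gray-matter masks) are averaged into mean time
series on *unsmoothed* denoised data; Pearson correlation with every
brain voxel gives per-seed FC maps, which are Fisher z-transformed,
averaged across subjects, and resolved into a somatotopic label map by
assigning each voxel the seed with the strongest connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .types import BoldImage, LabelMap, as_mask

__all__ = [
    "SeedSet",
    "FCMap",
    "WTAMap",
    "seeds_from_labelmap",
    "seeds_from_icap_maps",
    "extract_seed_series",
    "seed_to_voxel_fc",
    "fisher_z",
    "group_average",
    "winner_take_all",
    "wta_subject_counts",
]

#: clamp applied before atanh so |r| = 1 stays finite
FISHER_CLAMP = 1.0 - 1e-7


@dataclass
class SeedSet:
    """S labelled seed regions on the cord grid (labels 1..S)."""

    labels: LabelMap
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        present = self.labels.labels
        if len(present) < 1:
            raise ContractError("SeedSet has no labels")
        expected = np.arange(1, len(present) + 1)
        if not np.array_equal(present, expected):
            raise ContractError(f"seed labels must be 1..S, got {present.tolist()}")
        if not self.names:
            self.names = [f"C{i}" for i in expected]
        if len(self.names) != len(present):
            raise ContractError("names length must equal number of seeds")

    @property
    def n_seeds(self) -> int:
        return len(self.labels.labels)

    def voxel_counts(self) -> dict[int, int]:
        return self.labels.counts()


def seeds_from_labelmap(labels: LabelMap, names: list[str] | None = None) -> SeedSet:
    """Seeds directly from an atlas / ground-truth label map."""
    return SeedSet(labels, names or [])


def seeds_from_icap_maps(
    maps: np.ndarray, mask: np.ndarray, affine: np.ndarray, z_threshold: float = 1.5
) -> SeedSet:
    """Seeds from K z-scored iCAP maps: threshold, binarize, and let each
    voxel join the map with its highest suprathreshold z (disjoint seeds).
    """
    n_vox, K = maps.shape
    mask = np.asarray(mask, bool)
    if mask.sum() != n_vox:
        raise ContractError("maps row count must equal mask size")
    winner = np.argmax(maps, axis=1)
    above = maps[np.arange(n_vox), winner] >= z_threshold
    labels = np.zeros(mask.shape, dtype=np.int32)
    vals = np.where(above, winner + 1, 0)
    labels[mask] = vals
    lm = LabelMap(labels, affine)
    present = lm.labels
    if len(present) < K:
        # compress to consecutive labels
        remap = {old: new for new, old in enumerate(present, start=1)}
        data = np.zeros_like(labels)
        for old, new in remap.items():
            data[labels == old] = new
        lm = LabelMap(data, affine)
    return SeedSet(lm)


def extract_seed_series(
    img_unsmoothed_denoised: BoldImage, seeds: SeedSet
) -> np.ndarray:
    """Unweighted mean time series per seed, shape (S, T)."""
    img = img_unsmoothed_denoised
    if seeds.labels.data.shape != img.grid:
        raise ContractError("seeds are not on the image grid")
    out = np.empty((seeds.n_seeds, img.n_volumes))
    for s in range(1, seeds.n_seeds + 1):
        vox = seeds.labels.data == s
        if not vox.any():
            raise ContractError(f"seed {s} is empty")
        out[s - 1] = img.data[vox].mean(axis=0)
    return out


@dataclass
class FCMap:
    """Per-seed 3D connectivity map restricted to a target mask."""

    values: np.ndarray  # 3D, NaN outside mask
    mask: np.ndarray
    seed_label: int
    subject: str = "group"
    n_degenerate: int = 0

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of X (V, T) against y (T,); constant rows -> 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum())
    degenerate = (xs == 0) | (ys == 0)
    denom = np.where(degenerate, 1.0, xs * ys)
    r = (Xc @ yc) / denom
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), degenerate


def seed_to_voxel_fc(
    seed_series: np.ndarray,
    img: BoldImage,
    target_mask: np.ndarray,
    seed_label: int = 1,
    subject: str = "group",
) -> FCMap:
    """Pearson correlation of one seed series with every target voxel."""
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.shape != (img.n_volumes,):
        raise ContractError(
            f"seed series length {seed_series.shape} != n_volumes {img.n_volumes}"
        )
    target_mask = as_mask(target_mask, img.grid)
    r, degenerate = _pearson_rows(img.data[target_mask], seed_series)
    values = np.full(img.grid, np.nan)
    values[target_mask] = r
    return FCMap(values, target_mask, seed_label, subject,
                 n_degenerate=int(degenerate.sum()))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher's variance-stabilizing r-to-z transform, atanh with clamp."""
    arr = np.asarray(r, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (np.abs(finite) > 1).any():
        raise ContractError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(arr, -FISHER_CLAMP, FISHER_CLAMP))
    out = np.where(np.isfinite(arr), z, arr)
    return float(out) if np.ndim(r) == 0 else out


def fc_z_map(fc: FCMap) -> FCMap:
    """Fisher z version of an FC map (NaN outside mask preserved)."""
    return FCMap(fisher_z(fc.values), fc.mask, fc.seed_label, fc.subject,
                 fc.n_degenerate)


def group_average(maps: list[FCMap]) -> FCMap:
    """Voxelwise arithmetic mean of per-subject z maps."""
    if not maps:
        raise ContractError("need at least one subject map")
    ref = maps[0]
    for m in maps[1:]:
        if m.values.shape != ref.values.shape or not np.array_equal(m.mask, ref.mask):
            raise ContractError("FC maps have mismatched grids/masks")
        if m.seed_label != ref.seed_label:
            raise ContractError("FC maps belong to different seeds")
    stacked = np.stack([m.values for m in maps])
    return FCMap(stacked.mean(axis=0), ref.mask, ref.seed_label, "group")


@dataclass
class WTAMap:
    """Winner-take-all labelling of a target mask by strongest FC."""

    labels: LabelMap
    counts: dict[int, int]
    n_ties: int
    n_unassigned: int = 0

    @property
    def mask(self) -> np.ndarray:
        return self.labels.data != 0


def winner_take_all(
    maps: list[FCMap] | np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    positive_only: bool = False,
) -> WTAMap:
    """Label every in-mask voxel with the seed of its strongest FC.

    ``maps`` is a list of S FCMaps (S >= 2) on the same mask, or an
    (n_vox, S) array aligned with the mask.  Ties go to the lowest seed
    index and are counted.  With ``positive_only``, voxels whose maximum
    value is <= 0 are left unassigned (label 0).  NaN inside the mask is
    a contract violation.
    """
    if isinstance(maps, np.ndarray):
        values = maps
        if affine is None:
            affine = np.eye(4)
    else:
        if len(maps) < 2:
            raise ContractError("winner-take-all needs at least 2 seed maps")
        values = np.column_stack([m.in_mask() for m in maps])
        affine = affine if affine is not None else np.eye(4)
    mask = as_mask(mask, np.asarray(mask).shape)
    if values.shape[0] != int(mask.sum()):
        raise ContractError("map rows must equal mask voxel count")
    if values.shape[1] < 2:
        raise ContractError("winner-take-all needs at least 2 seed maps")
    if np.isnan(values).any():
        raise ContractError("NaN inside target mask")
    winner = np.argmax(values, axis=1)  # ties -> lowest index
    best = values[np.arange(len(winner)), winner]
    is_tie = (values == best[:, None]).sum(axis=1) > 1
    labels_in = winner + 1
    n_unassigned = 0
    if positive_only:
        unassigned = best <= 0
        labels_in = np.where(unassigned, 0, labels_in)
        n_unassigned = int(unassigned.sum())
    data = np.zeros(mask.shape, dtype=np.int32)
    data[mask] = labels_in
    lm = LabelMap(data, affine)
    counts = {int(s): int((labels_in == s).sum())
              for s in range(1, values.shape[1] + 1)}
    return WTAMap(lm, counts, int(is_tie.sum()), n_unassigned)


def wta_subject_counts(
    subject_maps: dict[str, WTAMap], group_map: WTAMap
) -> pd.DataFrame:
    """Reproducibility table: per group-level winner mask and subject,
    the number of voxels assigned to each spinal level.

    Columns: ``group_mask_label, subject, assigned_label, n_voxels``.
    Row sums over ``assigned_label`` equal the group mask size for every
    subject (conservation).
    """
    group_labels = group_map.labels.data
    all_labels = sorted(group_map.counts)
    records = []
    for subject, wta in subject_maps.items():
        if wta.labels.data.shape != group_labels.shape:
            raise ContractError("subject/group WTA grids differ")
        if sorted(wta.counts) != all_labels:
            raise ContractError("subject/group WTA label ranges differ")
        for g in all_labels:
            in_mask = group_labels == g
            sub_labels = wta.labels.data[in_mask]
            for s in all_labels:
                records.append(
                    {"group_mask_label": g, "subject": subject,
                     "assigned_label": s, "n_voxels": int((sub_labels == s).sum())}
                )
    return pd.DataFrame.from_records(records)
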