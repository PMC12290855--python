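"""Core in-memory containers shared by every pipeline stage.

All spatial data live on fixed voxel grids; world coordinates are
carried by a 4x4 affine only.  Voxel indexing is 0-based throughout.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "BoldImage",
    "LabelMap",
    "NuisanceDesign",
    "PhysioTrace",
    "MotionParams",
    "QCReport",
    "as_mask",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ContractError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ContractError("affine is singular")
    return affine


def as_mask(mask: np.ndarray, shape: tuple[int, ...], *, nonempty: bool = True) -> np.ndarray:
    """Validate a boolean voxel mask against a spatial grid shape."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ContractError("mask must be boolean or 0/1 valued")
        mask = mask.astype(bool)
    if mask.shape != tuple(shape):
        raise ContractError(f"mask shape {mask.shape} does not match grid {tuple(shape)}")
    if nonempty and not mask.any():
        raise ContractError("mask is empty")
    return mask


@dataclass
class BoldImage:
    """A 4D BOLD time series (i, j, k, t) with repetition time and affine.

    Parameters
    ----------
    data : ndarray, shape (i, j, k, t)
        Signal in arbitrary units; must be finite with t >= 2.
    tr_seconds : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (invertible).
    organ : {"brain", "cord"}
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    organ: str = "brain"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ContractError(f"BOLD data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[3] < 2:
            raise ContractError("BOLD data needs at least 2 volumes")
        if not np.isfinite(self.data).all():
            raise ContractError("BOLD data contains non-finite values")
        if not self.tr_seconds > 0:
            raise ContractError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)
        if self.organ not in ("brain", "cord"):
            raise ContractError(f"organ must be 'brain' or 'cord', got {self.organ!r}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_seconds

    def with_data(self, data: np.ndarray) -> "BoldImage":
        return BoldImage(data, self.tr_seconds, self.affine, self.organ)


@dataclass
class LabelMap:
    """An integer-labelled 3D volume (0 = background)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ContractError(f"LabelMap must be 3D, got ndim={data.ndim}")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.all(np.mod(data, 1) == 0):
                raise ContractError("LabelMap values must be integers")
            data = data.astype(np.int32)
        self.data = data
        self.affine = _check_affine(self.affine)

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        u = np.unique(self.data)
        return u[u != 0]

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all nonzero voxels."""
        if label is None:
            return self.data != 0
        return self.data == label

    def counts(self) -> dict[int, int]:
        return {int(l): int((self.data == l).sum()) for l in self.labels}


#: allowed provenance tags for nuisance regressors
PROVENANCE_TAGS = ("retroicor", "compcor", "dct", "motion", "other")


@dataclass
class NuisanceDesign:
    """A time-by-regressor matrix with labelled, provenance-tagged columns."""

    matrix: np.ndarray
    names: list[str]
    provenance: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2:
            raise ContractError("design matrix must be 2D")
        if not np.isfinite(self.matrix).all():
            raise ContractError("design matrix contains non-finite values")
        n_col = self.matrix.shape[1]
        if len(self.names) != n_col or len(self.provenance) != n_col:
            raise ContractError("names/provenance length must match column count")
        for tag in self.provenance:
            if tag not in PROVENANCE_TAGS:
                raise ContractError(f"unknown provenance tag {tag!r}")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def degenerate_columns(self) -> list[str]:
        """Names of columns with (numerically) zero temporal variance."""
        sd = self.matrix.std(axis=0)
        return [n for n, s in zip(self.names, sd) if s < 1e-12]

    @classmethod
    def concat(cls, designs: "list[NuisanceDesign]") -> "NuisanceDesign":
        designs = [d for d in designs if d.n_regressors > 0]
        if not designs:
            raise ContractError("no designs to concatenate")
        rows = {d.n_volumes for d in designs}
        if len(rows) > 1:
            raise ContractError(f"designs have differing row counts: {sorted(rows)}")
        return cls(
            np.hstack([d.matrix for d in designs]),
            [n for d in designs for n in d.names],
            [p for d in designs for p in d.provenance],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class PhysioTrace:
    """A peripheral physiological recording (pulse or respiration belt)."""

    samples: np.ndarray
    sampling_rate_hz: float
    modality: str
    peak_times_seconds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ContractError("physio samples must be a 1D sequence")
        if not self.sampling_rate_hz > 0:
            raise ContractError("sampling_rate_hz must be positive")
        if self.modality not in ("cardiac", "respiratory"):
            raise ContractError(f"modality must be cardiac/respiratory, got {self.modality!r}")
        if self.peak_times_seconds is not None:
            pk = np.asarray(self.peak_times_seconds, dtype=float)
            if pk.ndim != 1 or (len(pk) > 1 and not (np.diff(pk) > 0).all()):
                raise ContractError("peak_times_seconds must be strictly increasing")
            self.peak_times_seconds = pk

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate_hz


@dataclass
class MotionParams:
    """Realignment parameters: 6 columns for the brain (3 translations in
    mm, 3 rotations in rad), 2 for the cord (in-plane translations in mm)."""

    table: pd.DataFrame

    BRAIN_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
    CORD_COLUMNS = ("trans_x", "trans_y")

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            raise ContractError("motion table must be a pandas DataFrame")
        if not np.isfinite(self.table.to_numpy(dtype=float)).all():
            raise ContractError("motion parameters contain non-finite values")

    @classmethod
    def from_array(cls, values: np.ndarray, organ: str) -> "MotionParams":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        cols = cls.BRAIN_COLUMNS if organ == "brain" else cls.CORD_COLUMNS
        if values.shape[1] != len(cols):
            raise ContractError(
                f"{organ} motion needs {len(cols)} columns, got {values.shape[1]}"
            )
        return cls(pd.DataFrame(values, columns=list(cols)))

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def n_volumes(self) -> int:
        return len(self.table)


@dataclass
class QCReport:
    """Motion and signal-quality summary for one run."""

    fd_series: np.ndarray
    fd_mean: float
    tsnr_map: np.ndarray
    tsnr_mean: float
    excess_motion: bool
    n_degenerate_voxels: int = 0

    def to_dict(self) -> dict:
        return {
            "fd_mean": float(self.fd_mean),
            "tsnr_mean": float(self.tsnr_mean),
            "excess_motion": bool(self.excess_motion),
            "n_degenerate_voxels": int(self.n_degenerate_voxels),
            "fd_series": [float(v) for v in self.fd_series],
        }


def replace(obj, **changes):
    """dataclasses.replace passthrough (convenience re-export)."""
    return dataclasses.replace(obj, **changes)
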