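"""Quality-control metrics: framewise displacement and temporal SNR."""
from __future__ import annotations

import numpy as np

from .errors import ContractError
from .types import BoldImage, MotionParams, QCReport, as_mask

__all__ = ["framewise_displacement", "tsnr", "qc_report", "FD_EXCESS_THRESHOLD_MM"]

#: mean-FD threshold flagging excessive motion (mm)
FD_EXCESS_THRESHOLD_MM = 0.3


def framewise_displacement(
    motion: MotionParams | np.ndarray,
    organ: str,
    rotation_radius_mm: float = 50.0,
) -> tuple[np.ndarray, float, bool]:
    """Per-volume framewise displacement from realignment parameters.

    Brain (6 columns, Power's convention): ``FD_t = sum |d trans| +
    radius * sum |d rot|`` with rotations in radians converted to arc
    length on a ``rotation_radius_mm`` sphere.  Cord (2 columns):
    ``FD_t = mean(|dx|, |dy|)``.  The first entry is 0 by convention.

    Returns ``(fd_series, fd_mean, excess_flag)`` with the flag raised
    when mean FD exceeds 0.3 mm.
    """
    if isinstance(motion, MotionParams):
        values = motion.values
    else:
        values = np.atleast_2d(np.asarray(motion, dtype=float))
    expected = {"brain": 6, "cord": 2}
    if organ not in expected:
        raise ContractError(f"organ must be brain/cord, got {organ!r}")
    if values.shape[1] != expected[organ]:
        raise ContractError(
            f"{organ} motion requires {expected[organ]} columns, got {values.shape[1]}"
        )
    if not np.isfinite(values).all():
        raise ContractError("motion parameters contain non-finite values")
    d = np.abs(np.diff(values, axis=0))
    if organ == "brain":
        fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    else:
        fd = d.mean(axis=1)
    fd_series = np.concatenate([[0.0], fd])
    fd_mean = float(fd_series.mean())
    return fd_series, fd_mean, fd_mean > FD_EXCESS_THRESHOLD_MM


def tsnr(img: BoldImage, mask: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Temporal signal-to-noise ratio: mean over time / std over time.

    Uses the population standard deviation (ddof=0).  Voxels with zero
    temporal std are reported as tSNR 0; their count is returned so the
    caller can warn.  Returns ``(tsnr_map, tsnr_mean, n_degenerate)``
    where the mean is taken over the mask.
    """
    mask = as_mask(mask, img.grid)
    series = img.data[mask]
    mean = series.mean(axis=1)
    sd = series.std(axis=1, ddof=0)
    degenerate = sd == 0
    values = np.zeros(len(series))
    np.divide(mean, sd, out=values, where=~degenerate)
    tsnr_map = np.zeros(img.grid)
    tsnr_map[mask] = values
    return tsnr_map, float(values.mean()), int(degenerate.sum())


def qc_report(
    img: BoldImage,
    mask: np.ndarray,
    motion: MotionParams,
    rotation_radius_mm: float = 50.0,
) -> QCReport:
    """Combined FD + tSNR report for one run."""
    if motion.n_volumes != img.n_volumes:
        raise ContractError("motion rows must equal image volumes")
    fd_series, fd_mean, excess = framewise_displacement(
        motion, img.organ, rotation_radius_mm
    )
    tsnr_map, tsnr_mean, n_deg = tsnr(img, mask)
    return QCReport(fd_series, fd_mean, tsnr_map, tsnr_mean, excess, n_deg)
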