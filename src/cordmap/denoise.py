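"""Confound removal, band-pass filtering and spatial smoothing.

Denoising is an orthogonal projection of the voxel time series onto the
complement of the confound span, applied *jointly* with a zero-phase
band-pass filter: both the data and the regressors are filtered with the
same frequency mask before projection, so the filter cannot reintroduce
removed confounds (and vice versa).
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import ContractError
from .types import BoldImage, NuisanceDesign

__all__ = ["bandpass_filter", "denoise", "smooth", "DEFAULT_BAND_HZ"]

DEFAULT_BAND_HZ = (0.01, 0.17)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _band_mask(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr)
    lo, hi = band
    if not (0 <= lo < hi):
        raise ContractError(f"invalid band {band}")
    eps = 1e-12
    return (freqs >= lo - eps) & (freqs <= hi + eps)


def bandpass_filter(
    series: np.ndarray, tr_seconds: float, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> np.ndarray:
    """Zero-phase frequency-domain band-pass along the last axis.

    Passband edges are inclusive; everything outside (including the DC
    component when the low edge is positive) is zeroed.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    mask = _band_mask(n, tr_seconds, band_hz)
    spec = np.fft.rfft(series, axis=-1)
    spec = spec * mask
    return np.fft.irfft(spec, n=n, axis=-1)


def denoise(
    img: BoldImage,
    design: NuisanceDesign | None,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    standardize: bool = True,
    apply_bandpass: bool = True,
) -> BoldImage:
    """Remove confounds (and optionally band-pass) from a BOLD image.

    Steps: demean per voxel; when ``apply_bandpass``, filter both data
    and (demeaned) regressors with the same zero-phase mask; project the
    data onto the orthogonal complement of the regressor span (least
    squares, rank-deficient designs handled by dropping dependent
    directions with a warning); finally standardize each voxel to unit
    population variance when requested.  With ``apply_bandpass=False``
    only the projection is performed — the full-spectrum path used
    before hemodynamic deconvolution.

    The residual correlation with every (filtered) regressor is zero to
    numerical precision by construction.
    """
    Y = img.data.reshape(-1, img.n_volumes)
    Y = Y - Y.mean(axis=1, keepdims=True)

    X = None
    if design is not None and design.n_regressors > 0:
        if design.n_volumes != img.n_volumes:
            raise ContractError(
                f"design rows ({design.n_volumes}) != image volumes ({img.n_volumes})"
            )
        X = design.matrix - design.matrix.mean(axis=0, keepdims=True)

    if apply_bandpass:
        Y = bandpass_filter(Y, img.tr_seconds, band_hz)
        if X is not None:
            X = bandpass_filter(X.T, img.tr_seconds, band_hz).T

    if X is not None:
        norms = np.linalg.norm(X, axis=0)
        nonzero = norms > 1e-10 * max(1.0, norms.max())
        if not nonzero.all():
            warnings.warn(
                f"dropping {int((~nonzero).sum())} empty confound columns "
                "(zero after filtering/demeaning)", stacklevel=2,
            )
            X = X[:, nonzero]
        if X.shape[1] > 0:
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                warnings.warn(
                    f"rank-deficient confound design (rank {rank} < {X.shape[1]}); "
                    "dependent directions ignored", stacklevel=2,
                )
            beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
            Y = Y - (X @ beta).T

    Y = Y - Y.mean(axis=1, keepdims=True)
    if standardize:
        sd = Y.std(axis=1, ddof=0)
        np.divide(Y, sd[:, None], out=Y, where=(sd > 0)[:, None])
    return img.with_data(Y.reshape(img.data.shape))


def smooth(img: BoldImage, fwhm_mm: tuple[float, float, float]) -> BoldImage:
    """Separable 3D Gaussian smoothing of each volume.

    FWHM is given in mm per axis and converted to voxel-space sigmas via
    the affine; ``fwhm = (0, 0, 0)`` returns the input unchanged.
    Boundaries use zero padding, so total signal is conserved up to
    truncation at the edges.
    """
    fwhm = np.asarray(fwhm_mm, dtype=float)
    if fwhm.shape != (3,):
        raise ContractError("fwhm_mm must have 3 entries")
    if (fwhm < 0).any():
        raise ContractError("fwhm_mm must be nonnegative")
    if (fwhm == 0).all():
        return img.with_data(img.data.copy())
    sigma_vox = fwhm / img.voxel_sizes_mm / _FWHM_TO_SIGMA
    out = ndimage.gaussian_filter(
        img.data, sigma=(*sigma_vox, 0.0), mode="constant", cval=0.0
    )
    return img.with_data(out)
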