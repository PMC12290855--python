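"""Nuisance regressors: RETROICOR, CompCor, DCT detrending, motion.

The default confound set mirrors common cerebro-spinal practice: 3
cardiac + 4 respiratory Fourier harmonics + 1 multiplicative
cardio-respiratory interaction order (18 columns), CSF principal
components (CompCor), the first 5 discrete cosine basis functions, and
the realignment parameters.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import find_peaks

from .errors import ContractError, InsufficientDataError
from .types import BoldImage, MotionParams, NuisanceDesign, PhysioTrace, as_mask

__all__ = [
    "retroicor_phases",
    "retroicor_design",
    "compcor",
    "dct_basis",
    "motion_design",
    "build_design",
]


def _cardiac_peak_times(trace: PhysioTrace) -> np.ndarray:
    if trace.peak_times_seconds is not None and len(trace.peak_times_seconds) >= 2:
        return trace.peak_times_seconds
    # minimum plausible inter-beat interval 0.25 s (240 bpm)
    distance = max(1, int(0.25 * trace.sampling_rate_hz))
    idx, _ = find_peaks(trace.samples, distance=distance)
    return idx / trace.sampling_rate_hz


def retroicor_phases(
    cardiac: PhysioTrace,
    resp: PhysioTrace,
    volume_times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac and respiratory phase at each volume acquisition time.

    Cardiac phase advances linearly from 0 to 2*pi between consecutive
    detected (or supplied) pulse peaks; a volume falling exactly on a
    peak has phase 0.  Respiratory phase follows Glover's convention: a
    histogram-equalized transfer of the belt amplitude, signed by the
    breathing direction (derivative of the trace), yielding values in
    (-pi, pi].
    """
    volume_times = np.asarray(volume_times, dtype=float)
    peaks = _cardiac_peak_times(cardiac)
    if len(peaks) < 2:
        raise InsufficientDataError(
            f"need >= 2 cardiac peaks to assign phases, found {len(peaks)}"
        )
    # interval index for each volume; extrapolate with the edge periods
    periods = np.diff(peaks)
    k = np.clip(np.searchsorted(peaks, volume_times, side="right") - 1,
                0, len(peaks) - 2)
    phi_c = 2 * np.pi * (volume_times - peaks[k]) / periods[k]
    phi_c = np.mod(phi_c, 2 * np.pi)

    # respiratory: histogram equalization over the full belt trace
    b = resp.samples
    b_t = np.interp(volume_times, resp.times, b)
    db = np.gradient(b, 1.0 / resp.sampling_rate_hz)
    db_t = np.interp(volume_times, resp.times, db)
    order = np.sort(b)
    # empirical CDF in (0, 1]
    cdf = np.searchsorted(order, b_t, side="right") / len(order)
    sign = np.where(db_t >= 0, 1.0, -1.0)
    phi_r = np.pi * cdf * sign
    # map -pi exactly to +pi to honour the (-pi, pi] range
    phi_r = np.where(phi_r <= -np.pi, np.pi, phi_r)
    return phi_c, phi_r


def retroicor_design(
    phi_c: np.ndarray,
    phi_r: np.ndarray,
    n_cardiac: int = 3,
    n_resp: int = 4,
    n_interaction: int = 1,
) -> NuisanceDesign:
    """Fourier expansion of the physiological phases.

    Defaults give ``2*3 + 2*4 + 4*1 = 18`` regressors: sin/cos of the
    first three cardiac and four respiratory harmonics plus sin/cos of
    ``phi_c + phi_r`` and ``phi_c - phi_r`` for each interaction order.
    Constant columns (degenerate phases) are kept but flagged with a
    warning so the projection step can drop them.
    """
    if min(n_cardiac, n_resp, n_interaction) < 0:
        raise ContractError("harmonic counts must be >= 0")
    phi_c = np.asarray(phi_c, dtype=float)
    phi_r = np.asarray(phi_r, dtype=float)
    if phi_c.shape != phi_r.shape or phi_c.ndim != 1:
        raise ContractError("phase vectors must be 1D with equal length")
    cols, names = [], []
    for m in range(1, n_cardiac + 1):
        cols += [np.sin(m * phi_c), np.cos(m * phi_c)]
        names += [f"cardiac_sin{m}", f"cardiac_cos{m}"]
    for m in range(1, n_resp + 1):
        cols += [np.sin(m * phi_r), np.cos(m * phi_r)]
        names += [f"resp_sin{m}", f"resp_cos{m}"]
    for m in range(1, n_interaction + 1):
        for combo, label in ((phi_c + phi_r, "plus"), (phi_c - phi_r, "minus")):
            cols += [np.sin(m * combo), np.cos(m * combo)]
            names += [f"interaction_sin{m}{label}", f"interaction_cos{m}{label}"]
    design = NuisanceDesign(np.column_stack(cols) if cols else
                            np.empty((len(phi_c), 0)),
                            names, ["retroicor"] * len(names))
    degenerate = design.degenerate_columns()
    if degenerate:
        warnings.warn(f"degenerate RETROICOR columns: {degenerate}", stacklevel=2)
    return design


def compcor(
    img_unsmoothed: BoldImage,
    csf_mask: np.ndarray,
    n_components: int,
) -> NuisanceDesign:
    """CSF principal components (CompCor) from unsmoothed data.

    Voxel series are demeaned and variance-normalized before the
    decomposition; components are the unit-norm temporal principal
    directions in decreasing explained-variance order with a
    deterministic sign (the largest-magnitude voxel loading is made
    positive).  Explained variances (eigenvalues of the normalized
    voxel covariance) are stored on the returned design as
    ``explained_variance``.
    """
    if n_components < 1:
        raise ContractError("n_components must be >= 1")
    csf_mask = as_mask(csf_mask, img_unsmoothed.grid)
    X = img_unsmoothed.data[csf_mask]  # (n_vox, T)
    if X.shape[0] < n_components:
        raise ContractError(
            f"CSF mask has {X.shape[0]} voxels < n_components={n_components}"
        )
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    keep = sd > 0
    X = np.divide(X, sd[:, None], where=keep[:, None], out=np.zeros_like(X))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    comps = Vt[:n_components]  # (k, T), unit norm
    loadings = U[:, :n_components] * S[:n_components]
    for i in range(n_components):
        j = np.argmax(np.abs(loadings[:, i]))
        if loadings[j, i] < 0:
            comps[i] = -comps[i]
    design = NuisanceDesign(
        comps.T,
        [f"compcor_{i + 1}" for i in range(n_components)],
        ["compcor"] * n_components,
    )
    design.explained_variance = (S[:n_components] ** 2) / X.shape[0]
    return design


def dct_basis(n_volumes: int, n_functions: int = 5) -> NuisanceDesign:
    """The lowest-frequency non-constant DCT-II basis vectors.

    Column ``k`` (1-based) is ``cos(pi * k * (2t + 1) / (2N))``,
    unit-normalized; columns are mutually orthogonal and the first has a
    single sign change (the slowest trend).
    """
    if n_functions >= n_volumes:
        raise ContractError("n_functions must be < n_volumes")
    if n_functions < 1:
        raise ContractError("n_functions must be >= 1")
    t = np.arange(n_volumes)
    cols = []
    for k in range(1, n_functions + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
        cols.append(c / np.linalg.norm(c))
    return NuisanceDesign(
        np.column_stack(cols),
        [f"dct_{k}" for k in range(1, n_functions + 1)],
        ["dct"] * n_functions,
    )


def motion_design(motion: MotionParams) -> NuisanceDesign:
    """Realignment parameters as regressors (demeaned)."""
    values = motion.values
    values = values - values.mean(axis=0, keepdims=True)
    return NuisanceDesign(values, list(motion.table.columns),
                          ["motion"] * values.shape[1])


def build_design(
    img_unsmoothed: BoldImage,
    cardiac: PhysioTrace,
    resp: PhysioTrace,
    csf_mask: np.ndarray,
    motion: MotionParams,
    n_compcor: int | None = None,
    n_cardiac: int = 3,
    n_resp: int = 4,
    n_interaction: int = 1,
    n_dct: int = 5,
) -> NuisanceDesign:
    """Assemble the full confound set for one run.

    CompCor components default to 12 for the brain and 5 for the cord.
    """
    if n_compcor is None:
        n_compcor = 12 if img_unsmoothed.organ == "brain" else 5
    phi_c, phi_r = retroicor_phases(cardiac, resp, img_unsmoothed.frame_times)
    parts = [
        retroicor_design(phi_c, phi_r, n_cardiac, n_resp, n_interaction),
        compcor(img_unsmoothed, csf_mask, n_compcor),
        dct_basis(img_unsmoothed.n_volumes, n_dct),
        motion_design(motion),
    ]
    return NuisanceDesign.concat(parts)
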