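"""NIfTI-1 and table readers/writers.

4D files round-trip as :class:`~cordmap.types.BoldImage` (TR taken from
the header's 4th zoom), 3D integer files as
:class:`~cordmap.types.LabelMap`.  Malformed files raise
:class:`~cordmap.errors.FormatError`; a missing TR must be supplied
explicitly (``tr_override`` / ``--tr``).
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .types import BoldImage, LabelMap, NuisanceDesign

__all__ = ["read_image", "write_image", "write_design_tsv", "read_design_tsv"]


def read_image(
    path: str | Path, tr_override: float | None = None, organ: str = "brain"
) -> BoldImage | LabelMap:
    """Read a NIfTI file as a BoldImage (4D) or LabelMap (3D int)."""
    path = Path(path)
    try:
        nii = nib.load(path)
        data = np.asanyarray(nii.dataobj)
        affine = nii.affine
        zooms = nii.header.get_zooms()
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if data.ndim == 4:
        tr = tr_override
        if tr is None:
            tr = float(zooms[3]) if len(zooms) > 3 else 0.0
            if not tr > 0:
                raise FormatError(
                    f"{path} has no repetition time in its header; pass "
                    "tr_override (CLI: --tr)"
                )
        return BoldImage(np.asarray(data, dtype=float), tr, affine, organ)
    if data.ndim == 3:
        if not np.all(np.mod(data, 1) == 0):
            raise FormatError(f"{path} is 3D but not integer-valued (not a label map)")
        return LabelMap(np.asarray(data).astype(np.int32), affine)
    raise FormatError(f"{path} has unsupported dimensionality {data.ndim}")


def write_image(obj: BoldImage | LabelMap, path: str | Path) -> Path:
    """Write a BoldImage or LabelMap as NIfTI-1 (lossless round trip)."""
    path = Path(path)
    if isinstance(obj, BoldImage):
        nii = nib.Nifti1Image(obj.data.astype(np.float64), obj.affine)
        zooms = tuple(nii.header.get_zooms()[:3]) + (obj.tr_seconds,)
        nii.header.set_zooms(zooms)
        nii.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, LabelMap):
        nii = nib.Nifti1Image(obj.data.astype(np.int32), obj.affine)
    else:
        raise FormatError(f"cannot write object of type {type(obj).__name__}")
    try:
        nib.save(nii, path)
    except Exception as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


def write_design_tsv(design: NuisanceDesign, path: str | Path) -> Path:
    """Nuisance design as TSV with a header row of column labels; the
    provenance tags go to a JSON sidecar."""
    path = Path(path)
    design.to_frame().to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"provenance": design.provenance}))
    return path


def read_design_tsv(path: str | Path) -> NuisanceDesign:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot read design {path}: {exc}") from exc
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())["provenance"]
    else:
        prov = ["other"] * df.shape[1]
    return NuisanceDesign(df.to_numpy(dtype=float), list(df.columns), prov)
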