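"""NIfTI and gradient-table readers/writers plus the run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np

from .scheme import AcquisitionScheme

__all__ = ["read_dwi", "read_gradients", "write_maps", "write_manifest"]


def read_gradients(*paths) -> tuple[np.ndarray, np.ndarray]:
    """Parse a gradient table: MRtrix 4-column (x y z b) or FSL bvals+bvecs.

    One path -> MRtrix dialect; two paths -> (bvals, bvecs).  Returns
    (bvals, bvecs) with bvecs as rows.  b-value units are resolved by
    AcquisitionScheme (s/mm^2 inputs are converted to ms/um^2).
    """
    if len(paths) == 1:
        table = np.loadtxt(paths[0])
        if table.ndim != 2 or table.shape[1] != 4:
            raise ValueError(f"{paths[0]}: expected 4 columns (x y z b)")
        return table[:, 3], table[:, :3]
    if len(paths) == 2:
        bvals = np.loadtxt(paths[0]).ravel()
        bvecs = np.loadtxt(paths[1])
        if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
            bvecs = bvecs.T
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values")
        return bvals, bvecs
    raise ValueError("pass one MRtrix table or a bvals/bvecs pair")


def _normalise_bvecs(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Unit-normalise b>0 rows; zero rows are legal on b=0 volumes."""
    bvecs = np.array(bvecs, dtype=float)
    norms = np.linalg.norm(bvecs, axis=1)
    nz = norms > 1e-8
    bvecs[nz] /= norms[nz, None]
    return bvecs


def read_dwi(image_path, *grad_paths) -> tuple[np.ndarray, AcquisitionScheme, object]:
    """Load a 4D DWI volume with its gradient table.

    Returns (data, scheme, nifti_image); the image object carries the affine
    and header for writing outputs in the same space.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {data.ndim}D")
    bvals, bvecs = read_gradients(*grad_paths)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"image has {data.shape[3]} volumes but gradient table has {bvals.size} rows")
    scheme = AcquisitionScheme(bvals=bvals, bvecs=_normalise_bvecs(bvals, bvecs))
    return data, scheme, img


def write_maps(outputs: dict[str, np.ndarray], reference, out_dir,
               sidecar: dict | None = None) -> dict[str, Path]:
    """Write each output array as NIfTI with the reference affine.

    4D coefficient images document their layout in a JSON sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = reference.affine if reference is not None else np.eye(4)
    written = {}
    for name, arr in outputs.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), p)
        written[name] = p
    if sidecar:
        sp = out_dir / "layout.json"
        sp.write_text(json.dumps(sidecar, indent=2))
        written["layout"] = sp
    return written


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: list = (), seed: int = 0) -> Path:
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return p
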