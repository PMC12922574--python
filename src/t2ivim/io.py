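"""File formats: acquisition schemes (YAML), signal tables (CSV), image
stacks and parameter maps (NIfTI).

Conventions: signal tables are long-format delimited text with columns
(b, te, tr, repetition, signal); 4D NIfTI stacks order volumes b-fastest
(all b ascending within each TE, TEs ascending), matching the joint-fit
flattening, and always travel with a sidecar scheme file.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .ideal_mapping import MAP_PARAMS, ParameterMaps
from .signal_models import AcquisitionGrid
from .simulator import ImageStack, SignalDataset

__all__ = [
    "load_scheme",
    "save_scheme",
    "load_preset_scheme",
    "read_signal_table",
    "write_signal_table",
    "read_image_stack",
    "write_image_stack",
    "write_maps",
]

_SCHEME_FIELDS = ("b_values", "te_values", "tr_values", "averages",
                  "reference_te", "reference_tr")


def _grid_from_mapping(doc: dict, origin: str) -> AcquisitionGrid:
    if "b_values" not in doc or "te_values" not in doc:
        raise ValueError(f"{origin}: scheme must define b_values and te_values")
    kwargs = {k: doc[k] for k in _SCHEME_FIELDS if doc.get(k) is not None}
    try:
        return AcquisitionGrid(**kwargs)
    except ValueError as exc:
        raise ValueError(f"{origin}: invalid scheme: {exc}") from exc


def load_scheme(path) -> AcquisitionGrid:
    """Read and validate a YAML acquisition-scheme file."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: scheme file must hold a mapping")
    return _grid_from_mapping(doc, str(path))


def save_scheme(grid: AcquisitionGrid, path, name: str | None = None,
                metadata: str | None = None) -> None:
    """Write a grid as a YAML scheme file (lossless round trip)."""
    doc = {
        "b_values": list(grid.b_values),
        "te_values": list(grid.te_values),
        "tr_values": list(grid.tr_values),
        "averages": list(grid.averages) if grid.averages else None,
        "reference_te": grid.reference_te,
        "reference_tr": grid.reference_tr,
    }
    if name:
        doc["name"] = name
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_preset_scheme(name: str) -> AcquisitionGrid:
    """Load one of the shipped schemes ('invivo_16b_6te', 'liver_consensus',
    'kidney_set2')."""
    ref = importlib.resources.files("t2ivim") / "schemes" / f"{name}.yaml"
    if not ref.is_file():
        available = sorted(p.stem for p in
                           (importlib.resources.files("t2ivim") / "schemes").iterdir())
        raise KeyError(f"no shipped scheme {name!r}; available: {available}")
    doc = yaml.safe_load(ref.read_text())
    return _grid_from_mapping(doc, f"scheme {name}")


def write_signal_table(ds: SignalDataset, path, repetition: int = 0) -> None:
    """Write a dataset as a long-format (b, te, tr, repetition, signal) CSV."""
    grid = ds.grid
    b, te, tr = np.meshgrid(grid.b_values, grid.te_values, grid.tr_values,
                            indexing="ij")
    pd.DataFrame({
        "b": b.ravel(), "te": te.ravel(), "tr": tr.ravel(),
        "repetition": repetition, "signal": ds.values.ravel(),
    }).to_csv(path, index=False)


def read_signal_table(path, grid: AcquisitionGrid,
                      normalization: str = "per_reference",
                      repetition: int | None = None) -> SignalDataset:
    """Read a long-format signal table back onto a grid (one repetition)."""
    df = pd.read_csv(path)
    missing = {"b", "te", "tr", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "repetition" in df.columns:
        rep = repetition if repetition is not None else df["repetition"].min()
        df = df[df["repetition"] == rep]
    values = np.full(grid.shape, np.nan)
    ib = {v: i for i, v in enumerate(grid.b_values)}
    ite = {v: i for i, v in enumerate(grid.te_values)}
    itr = {v: i for i, v in enumerate(grid.tr_values)}
    for row in df.itertuples(index=False):
        try:
            values[ib[float(row.b)], ite[float(row.te)], itr[float(row.tr)]] = row.signal
        except KeyError as exc:
            raise ValueError(f"{path}: node {exc} not on the scheme grid") from None
    if np.isnan(values).any():
        raise ValueError(f"{path}: table does not cover the full (b, te, tr) grid")
    return SignalDataset(grid=grid, values=values, normalization=normalization)


def read_image_stack(path, grid: AcquisitionGrid) -> ImageStack:
    """Read a 4D NIfTI whose volumes are ordered b-fastest over (b, TE).

    The 4th-dimension length must equal |b|·|TE|; a mismatch is an error
    stating expected vs found.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:   # single-slice (y, x, 1, vols)
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected (y, x, volumes) after squeeze, got {data.shape}")
    nb, nte = len(grid.b_values), len(grid.te_values)
    expected = nb * nte
    if data.shape[2] != expected:
        raise ValueError(
            f"{path}: expected {expected} volumes (= {nb} b × {nte} TE), "
            f"found {data.shape[2]}"
        )
    # volumes are b-fastest: index v = i_te * nb + i_b
    values = data.reshape(data.shape[0], data.shape[1], nte, nb).transpose(0, 1, 3, 2)
    return ImageStack(values=values, grid=grid, affine=img.affine)


def write_image_stack(stack: ImageStack, path) -> None:
    """Write a stack as 4D NIfTI (single slice, volumes b-fastest)."""
    ny, nx, nb, nte = stack.values.shape
    vols = stack.values.transpose(0, 1, 3, 2).reshape(ny, nx, 1, nte * nb)
    affine = stack.affine if stack.affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(vols, affine), str(path))


def write_maps(maps: ParameterMaps, out_dir, affine: np.ndarray | None = None,
               roi_table: pd.DataFrame | None = None) -> dict:
    """Write one NIfTI per parameter map (plus an optional ROI summary CSV);
    returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = affine if affine is not None else np.eye(4)
    written = {}
    for k in MAP_PARAMS:
        p = out_dir / f"{k}.nii.gz"
        nib.save(nib.Nifti1Image(maps[k].astype(np.float64), affine), str(p))
        written[k] = p
    if roi_table is not None:
        p = out_dir / "roi_summary.csv"
        roi_table.to_csv(p, index=False)
        written["roi_summary"] = p
    return written
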