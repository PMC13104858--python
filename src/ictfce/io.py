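"""Readers and writers for the package's file formats.

Statistic matrices travel as whitespace- or comma-delimited square numeric
text, written at full (repr-faithful) precision so cross-process
equivalence checks are meaningful.  Voxel data uses NIfTI (via nibabel)
or a dependency-free plain-text format: a shape line followed by the
flattened (C-order) values.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .core import StatMatrix, TFCEMap, ValidationError
from .inference import GroupDataset
from .voxel import VoxelImage

__all__ = [
    "read_stat_matrix",
    "write_matrix",
    "read_voxel_text",
    "write_voxel_text",
    "read_voxel_image",
    "write_voxel_volume",
    "load_group_dataset",
    "read_network_partition",
    "write_provenance",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _parse_numeric_rows(path: Path) -> list[list[float]]:
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = re.split(r"[,\s]+", stripped)
        row = []
        for col, tok in enumerate(tokens):
            try:
                row.append(float(tok))
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric token {tok!r} at line {lineno}, column {col + 1}"
                ) from None
        rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: file contains no numeric data")
    return rows


def read_stat_matrix(path: str | Path) -> StatMatrix:
    """Strictly parse a delimited square symmetric matrix.

    Ragged rows, non-numeric tokens, non-square shape and asymmetric cells
    all raise :class:`ValidationError` naming the offending location.
    """
    path = Path(path)
    rows = _parse_numeric_rows(path)
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged row {i + 1} has {len(row)} values, expected {width}"
            )
    values = np.array(rows)
    try:
        return StatMatrix(values=values)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_matrix(path: str | Path, m: StatMatrix | TFCEMap | np.ndarray) -> None:
    """Write a matrix as space-delimited text at full precision."""
    values = m.values if isinstance(m, (StatMatrix, TFCEMap)) else np.asarray(m)
    np.savetxt(path, values, fmt="%.17g", delimiter=" ")


def read_voxel_text(path: str | Path) -> np.ndarray:
    """Read the plain-text 3D format: a shape line, then flattened values."""
    path = Path(path)
    rows = _parse_numeric_rows(path)
    shape = tuple(int(v) for v in rows[0])
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValidationError(f"{path}: first line must give a 3D shape, got {shape}")
    flat = np.array([v for row in rows[1:] for v in row])
    if flat.size != int(np.prod(shape)):
        raise ValidationError(
            f"{path}: expected {int(np.prod(shape))} values for shape {shape}, got {flat.size}"
        )
    return flat.reshape(shape)


def write_voxel_text(path: str | Path, volume: np.ndarray) -> None:
    volume = np.asarray(volume)
    with open(path, "w") as fh:
        fh.write(" ".join(str(s) for s in volume.shape) + "\n")
        for row in volume.reshape(volume.shape[0], -1):
            fh.write(" ".join("%.17g" % v for v in row) + "\n")


def _is_nifti(path: Path) -> bool:
    return any(str(path).endswith(s) for s in _NIFTI_SUFFIXES)


def read_voxel_image(
    stat_path: str | Path,
    mask_path: str | Path | None = None,
    connectivity: int = 26,
):
    """Load a statistic volume (NIfTI or text) into a :class:`VoxelImage`.

    Returns ``(image, affine)``; the affine is ``None`` for text input and is
    carried through untouched for NIfTI so outputs can preserve the header.
    """
    import nibabel as nib

    stat_path = Path(stat_path)
    affine = None
    if _is_nifti(stat_path):
        img = nib.load(str(stat_path))
        stats = np.asanyarray(img.dataobj, dtype=float)
        affine = img.affine
    else:
        stats = read_voxel_text(stat_path)
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if _is_nifti(mask_path):
            mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        else:
            mask = read_voxel_text(mask_path) > 0
    return VoxelImage(stats=stats, mask=mask, connectivity=connectivity), affine


def write_voxel_volume(path: str | Path, volume: np.ndarray, affine=None) -> None:
    """Write a volume as NIfTI (when the suffix says so) or as text."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(volume, affine if affine is not None else np.eye(4)), str(path))
    else:
        write_voxel_text(path, volume)


def load_group_dataset(data_dir: str | Path, design_path: str | Path) -> GroupDataset:
    """Load per-subject matrices plus a two-column design file.

    The design file holds ``subject_id group_label`` per line; each subject's
    matrix is read from ``<data_dir>/<subject_id>`` (or ``<subject_id>.txt``).
    A design whose labels are all identical is treated as one-sample.
    """
    data_dir = Path(data_dir)
    design_path = Path(design_path)
    ids: list[str] = []
    labels: list[str] = []
    for lineno, line in enumerate(design_path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValidationError(
                f"{design_path}: line {lineno} must have two columns, got {len(parts)}"
            )
        ids.append(parts[0])
        labels.append(parts[1])
    matrices = []
    for sid in ids:
        candidate = data_dir / sid
        if not candidate.exists():
            candidate = data_dir / f"{sid}.txt"
        if not candidate.exists():
            raise ValidationError(f"no matrix file for subject {sid!r} under {data_dir}")
        matrices.append(read_stat_matrix(candidate).values)
    unique = sorted(set(labels))
    if len(unique) == 1:
        groups = None
    elif len(unique) == 2:
        groups = np.array([unique.index(lab) for lab in labels])
    else:
        raise ValidationError(f"{design_path}: expected 1 or 2 group labels, got {unique}")
    return GroupDataset(subjects=np.array(matrices), groups=groups)


def read_network_partition(path: str | Path, n_rois: int) -> np.ndarray:
    """Two-column ``node_index network_name`` file -> per-node label array."""
    path = Path(path)
    labels = np.array([""] * n_rois, dtype=object)
    seen = np.zeros(n_rois, dtype=bool)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise ValidationError(f"{path}: line {lineno} must have two columns")
        idx = int(parts[0])
        if not 0 <= idx < n_rois:
            raise ValidationError(f"{path}: node index {idx} out of range at line {lineno}")
        labels[idx] = parts[1]
        seen[idx] = True
    if not seen.all():
        missing = np.flatnonzero(~seen)[:5].tolist()
        raise ValidationError(f"{path}: nodes without a network label, e.g. {missing}")
    return labels.astype(str)


def write_provenance(output_path: str | Path, record: dict) -> Path:
    """Write a machine-readable sidecar describing how an output was made."""
    import ictfce

    sidecar = Path(str(output_path) + ".provenance.json")
    payload = {"ictfce_version": ictfce.__version__, "numpy_version": np.__version__}
    payload.update(record)
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return sidecar
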