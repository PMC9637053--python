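"""Image, mask and cohort-table I/O for radial fat-mapping.

Fat-fraction (FI%) slices are 2D axial grids of per-pixel fat percentage
in ``[0, 100]``; pixels outside the body, or with zero total water+fat
signal, carry an explicit missing marker (NaN) and are excluded from all
downstream means.  Supported on-disk formats:

* NIfTI (``.nii`` / ``.nii.gz``), values stored as float with NaN missing;
* 16-bit grayscale PNG plus a JSON sidecar (``<file>.json``) holding the
  integer→percent slope, the reserved missing code and the pixel spacing.

Muscle masks are binary grids in the same pixel grid as their image, one
file per muscle (and optionally per side); grayscale mask files are
binarized at half the representable range.  Cohort metadata is a CSV with
one subject per row.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MUSCLES",
    "SIDES",
    "FatFractionSlice",
    "MuscleMask",
    "CohortTable",
    "compute_fat_fraction",
    "read_fat_fraction",
    "write_fat_fraction",
    "read_mask",
    "write_mask",
    "read_slice_bundle",
]

#: The three paraspinal muscles analyzed at the L4L5 level.
MUSCLES = ("multifidus", "erector_spinae", "psoas")
SIDES = ("left", "right", "merged")

# PNG encoding: FI% in [0, 100] mapped onto 0..65534; 65535 reserved for missing.
_PNG_MISSING = 65535
_PNG_SLOPE = 100.0 / 65534.0


@dataclass
class FatFractionSlice:
    """A single axial fat-infiltration slice.

    Attributes
    ----------
    values
        2D float grid of FI% per pixel; NaN marks missing (outside body /
        zero total signal).  Non-missing values lie in ``[0, 100]``.
    pixel_spacing
        In-plane pixel size in mm (isotropic assumed).
    subject_id, level
        Identifiers; the analysis targets the axial slice at the L4L5 disc center.
    """

    values: np.ndarray
    pixel_spacing: float = 1.0
    subject_id: str = ""
    level: str = "L4L5"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError(f"FI grid must be 2D and at least 2x2, got shape {self.values.shape}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("FI% values must lie in [0, 100]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class MuscleMask:
    """Binary segmentation mask for one muscle (one side or merged)."""

    mask: np.ndarray
    muscle: str
    side: str = "merged"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D grid")
        if self.muscle not in MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {SIDES}")

    @property
    def usable(self) -> bool:
        """A mask with no foreground pixel is flagged unusable, not an error."""
        return bool(self.mask.any())

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


class CohortTable:
    """Per-subject metadata: group, symptoms and disc-pathology grades.

    Wraps a :class:`pandas.DataFrame` with one row per subject.  Required
    columns: ``subject_id`` (unique), ``group`` (``patient``/``control``).
    Optional: ``vas`` (0–10), ``odi`` (0–100), ``cep_damage`` (bool),
    ``pfirrmann`` (1–5), ``modic`` (bool), ``age``, ``sex``, ``bmi`` and
    the four disc-geometry columns ``posterior_row``, ``posterior_col``,
    ``anterior_row``, ``anterior_col``.
    """

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        if "subject_id" not in df.columns or "group" not in df.columns:
            raise ValueError("cohort table requires subject_id and group columns")
        df["subject_id"] = df["subject_id"].astype(str)
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"duplicate subject_id {dup!r}")
        if df["group"].isna().any():
            raise ValueError("group must be non-missing for every subject")
        bad = set(df["group"].unique()) - {"patient", "control"}
        if bad:
            raise ValueError(f"group must be 'patient' or 'control', got {sorted(bad)}")
        if "vas" in df.columns:
            v = pd.to_numeric(df["vas"], errors="coerce")
            if ((v < 0) | (v > 10)).any():
                raise ValueError("vas scores must lie in [0, 10]")
        if "odi" in df.columns:
            v = pd.to_numeric(df["odi"], errors="coerce")
            if ((v < 0) | (v > 100)).any():
                raise ValueError("odi scores must lie in [0, 100]")
        if "pfirrmann" in df.columns:
            v = pd.to_numeric(df["pfirrmann"], errors="coerce")
            if ((v < 1) | (v > 5)).any():
                raise ValueError("pfirrmann grades must lie in 1..5")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data["subject_id"])

    def row(self, subject_id: str) -> pd.Series:
        sel = self.data[self.data["subject_id"] == str(subject_id)]
        if sel.empty:
            raise KeyError(f"subject {subject_id!r} not in cohort table")
        return sel.iloc[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def compute_fat_fraction(
    water: np.ndarray,
    fat: np.ndarray,
    *,
    pixel_spacing: float = 1.0,
    subject_id: str = "",
    level: str = "L4L5",
) -> FatFractionSlice:
    """Fat fraction FI% = 100·F/(F+W) from water/fat channel images.

    Pixels where ``water + fat == 0`` are marked missing rather than set
    to zero.  The result is invariant to joint rescaling of both channels
    by any positive constant.
    """
    w = np.asarray(water, dtype=float)
    f = np.asarray(fat, dtype=float)
    if w.shape != f.shape:
        raise ValueError(f"water/fat shape mismatch: {w.shape} vs {f.shape}")
    if np.nanmin(w) < 0 or np.nanmin(f) < 0:
        raise ValueError("water and fat signal must be non-negative")
    total = w + f
    with np.errstate(invalid="ignore", divide="ignore"):
        fi = np.where(total > 0, 100.0 * f / total, np.nan)
    return FatFractionSlice(fi, pixel_spacing=pixel_spacing, subject_id=subject_id, level=level)


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def write_fat_fraction(fi: FatFractionSlice, path: str | Path) -> None:
    """Write a slice as NIfTI (float, NaN missing) or 16-bit PNG + sidecar."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([fi.pixel_spacing, fi.pixel_spacing, 1.0, 1.0])
        img = nib.Nifti1Image(fi.values.astype(np.float64), affine)
        img.header.set_zooms((fi.pixel_spacing, fi.pixel_spacing))
        nib.save(img, str(path))
    elif path.suffix.lower() == ".png":
        stored = np.full(fi.values.shape, _PNG_MISSING, dtype=np.uint16)
        ok = np.isfinite(fi.values)
        stored[ok] = np.round(fi.values[ok] / _PNG_SLOPE).astype(np.uint16)
        iio.imwrite(path, stored)
        sidecar = {
            "slope": _PNG_SLOPE,
            "missing": _PNG_MISSING,
            "pixel_spacing": fi.pixel_spacing,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_fat_fraction(path: str | Path, *, subject_id: str = "", level: str = "L4L5") -> FatFractionSlice:
    """Read a fat-fraction slice written by :func:`write_fat_fraction`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        values = np.squeeze(values)
        if values.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2D slice, got shape {values.shape}")
        zooms = img.header.get_zooms()[:2]
        spacing = float(zooms[0]) if zooms else 1.0
        return FatFractionSlice(values, pixel_spacing=spacing, subject_id=subject_id, level=level)
    if path.suffix.lower() == ".png":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(f"missing PNG sidecar {sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        stored = np.asarray(iio.imread(path))
        values = stored.astype(float) * float(sidecar["slope"])
        values[stored == int(sidecar["missing"])] = np.nan
        return FatFractionSlice(
            values,
            pixel_spacing=float(sidecar.get("pixel_spacing", 1.0)),
            subject_id=subject_id,
            level=level,
        )
    raise ValueError(f"unsupported image format: {path.name}")


def write_mask(mask: MuscleMask, path: str | Path) -> None:
    path = Path(path)
    if _is_nifti(path):
        img = nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4))
        nib.save(img, str(path))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def read_mask(path: str | Path, muscle: str, side: str = "merged") -> MuscleMask:
    """Read a binary mask; grayscale files are binarized at half range."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        arr = np.squeeze(np.asarray(nib.load(str(path)).dataobj, dtype=float))
        binary = arr > 0.5
    elif path.suffix.lower() == ".png":
        arr = np.asarray(iio.imread(path))
        if np.issubdtype(arr.dtype, np.integer):
            binary = arr.astype(float) > 0.5 * np.iinfo(arr.dtype).max
        else:
            binary = arr > 0.5
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    return MuscleMask(binary, muscle=muscle, side=side)


def read_slice_bundle(
    image_path: str | Path,
    mask_specs: Sequence[tuple[str | Path, str, str]] | Mapping[str, str | Path],
    metadata_row: Mapping | pd.Series | None = None,
) -> tuple[FatFractionSlice, list[MuscleMask]]:
    """Load one subject's image together with its muscle masks.

    Parameters
    ----------
    image_path
        Path to the fat-fraction slice.
    mask_specs
        Either a sequence of ``(path, muscle, side)`` triples, or a mapping
        ``{muscle: path}`` (side taken as ``merged``).
    metadata_row
        Optional cohort row supplying ``subject_id``.

    Masks with zero foreground pixels are kept but flagged unusable, with
    a warning; shape mismatches and unknown muscle labels raise.
    """
    subject_id = ""
    if metadata_row is not None and "subject_id" in metadata_row:
        subject_id = str(metadata_row["subject_id"])
    fi = read_fat_fraction(image_path, subject_id=subject_id)

    if isinstance(mask_specs, Mapping):
        specs: Iterable[tuple[str | Path, str, str]] = [
            (p, m, "merged") for m, p in mask_specs.items()
        ]
    else:
        specs = mask_specs

    masks: list[MuscleMask] = []
    for mask_path, muscle, side in specs:
        m = read_mask(mask_path, muscle=muscle, side=side)
        if m.mask.shape != fi.shape:
            raise ValueError(
                f"mask {Path(mask_path).name} shape {m.mask.shape} does not match "
                f"image shape {fi.shape}"
            )
        if not m.usable:
            warnings.warn(
                f"mask {Path(mask_path).name} ({muscle}/{side}) has no foreground pixels; "
                "flagged unusable",
                stacklevel=2,
            )
        masks.append(m)
    return fi, masks
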