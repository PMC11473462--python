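"""CT volume I/O, slice-thickness resampling and HU-threshold volumetry.

The quantities computed here are the raw ingredients of CT body-composition
analysis (BCA): per-compartment tissue volumes in mL and, inside a given
organ mask, the volume of *fat-isodense* voxels — voxels whose attenuation
falls inside a fat Hounsfield-unit (HU) window.  Two windows are used:

* pulmonary fat attenuation volume (CTpfav): −200 to −60 HU inside the lung
  segmentation (a wider −200 to −40 HU variant is selectable via
  :class:`QuantConfig`);
* inter-/intra-muscular adipose tissue (IMAT): −190 to −30 HU inside the
  muscle segmentation.

Both bounds are inclusive and no morphological post-processing is applied.
Quantification runs at native voxel spacing by default; normalisation to a
target slice thickness is an explicit opt-in stage (:func:`resample_z`),
since interpolation perturbs volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "CTVolume",
    "MaskSet",
    "QuantConfig",
    "BCAVolumes",
    "load_volume",
    "load_mask",
    "resample_z",
    "volume_ml",
    "fat_attenuation_volume",
    "compute_ctpfav",
    "compute_imat",
    "quantify_subject",
]

#: mask labels a full quantification requires, in canonical order
REQUIRED_MASKS = (
    "lung",
    "bone",
    "muscle",
    "subcutaneous_at",
    "visceral_at",
    "epicardial_at",
    "mediastinal_at",
)


@dataclass(frozen=True)
class CTVolume:
    """A 3-D CT image: HU values plus physical voxel spacing in mm.

    Axis order is taken as stored on disk; all quantities downstream are
    orientation-invariant sums, so only the spacing matters.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ShapeError(f"expected a 3-D volume, got {data.ndim}-D")
        if not np.all(np.isfinite(data)):
            raise ParameterError("CT volume contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be three positive lengths, got {spacing!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def voxel_ml(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0


@dataclass(frozen=True)
class MaskSet:
    """Named binary masks aligned to one CT volume."""

    masks: dict[str, np.ndarray]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        clean = {}
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != tuple(self.shape):
                raise AlignmentError(
                    f"mask {name!r} has shape {m.shape}, CT grid is {tuple(self.shape)}"
                )
            clean[name] = (m != 0).astype(np.uint8)
        object.__setattr__(self, "masks", clean)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise ConfigurationError(f"required mask {name!r} is missing") from None

    def __contains__(self, name: str) -> bool:
        return name in self.masks


@dataclass(frozen=True)
class QuantConfig:
    """HU windows, target slice thicknesses and the TAT composition.

    Defaults: pulmonary fat window −200..−60 HU, IMAT window −190..−30 HU,
    5 mm slices for BCA and 1.5 mm for organ volumetry when resampling is
    enabled, and total adipose tissue (TAT) as the sum of all extracted
    adipose compartments.
    """

    pfav_hu_lo: float = -200.0
    pfav_hu_hi: float = -60.0
    imat_hu_lo: float = -190.0
    imat_hu_hi: float = -30.0
    bca_slice_mm: float = 5.0
    organ_slice_mm: float = 1.5
    resample_enabled: bool = False
    tat_components: tuple[str, ...] = ("sat", "vat", "imat", "eat", "mat")

    def __post_init__(self) -> None:
        if self.pfav_hu_lo >= self.pfav_hu_hi:
            raise ParameterError("pfav window: lower bound must be below upper bound")
        if self.imat_hu_lo >= self.imat_hu_hi:
            raise ParameterError("imat window: lower bound must be below upper bound")
        if self.bca_slice_mm <= 0 or self.organ_slice_mm <= 0:
            raise ParameterError("target slice thicknesses must be positive")
        unknown = set(self.tat_components) - {"sat", "vat", "imat", "eat", "mat"}
        if unknown:
            raise ParameterError(f"unknown TAT components: {sorted(unknown)}")


@dataclass(frozen=True)
class BCAVolumes:
    """Raw per-subject tissue volumes in mL; ``tat_ml`` is derived."""

    bone_ml: float
    muscle_ml: float
    sat_ml: float
    vat_ml: float
    imat_ml: float
    eat_ml: float
    mat_ml: float
    lung_ml: float
    ctpfav_ml: float
    tat_ml: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite non-negative volume, got {v}")
        if self.ctpfav_ml > self.lung_ml + 1e-9:
            raise ParameterError("ctpfav_ml exceeds lung_ml")
        if self.imat_ml > self.muscle_ml + 1e-9:
            raise ParameterError("imat_ml exceeds muscle_ml")


def load_volume(path: str | Path) -> CTVolume:
    """Read a 3-D NIfTI image as a :class:`CTVolume`.

    Spacing is taken from the header zooms (mm); axis order as stored.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data=data.astype(np.float64), spacing=spacing)


def load_mask(path: str | Path, ct: CTVolume) -> np.ndarray:
    """Read a segmentation mask and coerce it to {0, 1} on the CT grid.

    Any nonzero label maps to 1.  A grid mismatch with ``ct`` raises
    :class:`~ctbca.errors.AlignmentError`.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    if data.shape != ct.shape:
        raise AlignmentError(f"{path}: mask shape {data.shape} != CT shape {ct.shape}")
    return (data != 0).astype(np.uint8)


def _resample_axis2(data: np.ndarray, dz: float, target_mm: float, mode: str) -> np.ndarray:
    n = data.shape[2]
    n_new = max(1, int(round(n * dz / target_mm)))
    # slice centres of old and new grids share the physical origin
    old_centres = (np.arange(n) + 0.5) * dz
    new_centres = (np.arange(n_new) + 0.5) * target_mm
    if mode == "label":
        idx = np.clip(np.round(new_centres / dz - 0.5).astype(int), 0, n - 1)
        return data[:, :, idx]
    out = np.empty(data.shape[:2] + (n_new,), dtype=np.float64)
    idx = np.clip(np.searchsorted(old_centres, new_centres) - 1, 0, n - 2)
    frac = np.clip((new_centres - old_centres[idx]) / dz, 0.0, 1.0)
    out = data[:, :, idx] * (1.0 - frac) + data[:, :, idx + 1] * frac
    return out


def resample_z(
    vol: CTVolume | np.ndarray,
    target_mm: float,
    mode: str = "continuous",
    spacing: tuple[float, float, float] | None = None,
):
    """Resample along the slice axis (axis 2) to a target slice thickness.

    ``continuous`` interpolates HU linearly between slice centres; ``label``
    picks the nearest slice so the label set is preserved.  In-plane
    resolution is untouched.  If the input is already at the target
    thickness it is returned unchanged.

    Accepts a :class:`CTVolume` (returns a :class:`CTVolume`) or a bare
    array plus ``spacing`` (returns ``(array, new_spacing)``).
    """
    if target_mm <= 0:
        raise ParameterError(f"target slice thickness must be positive, got {target_mm}")
    if mode not in ("continuous", "label"):
        raise ParameterError(f"unknown resampling mode {mode!r}")
    if isinstance(vol, CTVolume):
        data, (sx, sy, dz) = vol.data, vol.spacing
    else:
        if spacing is None:
            raise ParameterError("spacing is required when resampling a bare array")
        data = np.asarray(vol)
        sx, sy, dz = (float(s) for s in spacing)
    if abs(dz - target_mm) < 1e-9:
        return vol
    out = _resample_axis2(np.asarray(data, dtype=np.float64), dz, target_mm, mode)
    if mode == "label":
        out = out.astype(np.uint8)
    new_spacing = (sx, sy, float(target_mm))
    if isinstance(vol, CTVolume):
        return CTVolume(data=out, spacing=new_spacing)
    return out, new_spacing


def volume_ml(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Volume of a binary mask in mL: voxel count × voxel volume / 1000."""
    mask = np.asarray(mask)
    sx, sy, sz = (float(s) for s in spacing)
    if sx <= 0 or sy <= 0 or sz <= 0:
        raise ParameterError("spacing components must be positive")
    return float(np.count_nonzero(mask)) * (sx * sy * sz / 1000.0)


def fat_attenuation_volume(
    ct: CTVolume, mask: np.ndarray, hu_lo: float, hu_hi: float
) -> float:
    """Volume (mL) of voxels inside ``mask`` with HU in [hu_lo, hu_hi].

    Bounds are inclusive on both ends; no post-processing of the selected
    voxels is performed.
    """
    if hu_lo >= hu_hi:
        raise ParameterError("HU window: lower bound must be below upper bound")
    mask = np.asarray(mask)
    if mask.shape != ct.shape:
        raise AlignmentError(f"mask shape {mask.shape} != CT shape {ct.shape}")
    inside = (mask != 0) & (ct.data >= hu_lo) & (ct.data <= hu_hi)
    return float(np.count_nonzero(inside)) * ct.voxel_ml


def compute_ctpfav(
    ct: CTVolume, lung_mask: np.ndarray, cfg: QuantConfig | None = None
) -> tuple[float, float]:
    """Pulmonary fat attenuation volume and lung volume, both in mL."""
    cfg = cfg or QuantConfig()
    lung_mask = np.asarray(lung_mask)
    if lung_mask.shape != ct.shape:
        raise AlignmentError(f"lung mask shape {lung_mask.shape} != CT shape {ct.shape}")
    if not np.any(lung_mask):
        raise DegenerateInputError("empty lung mask: pulmonary fat index is undefined")
    pfav = fat_attenuation_volume(ct, lung_mask, cfg.pfav_hu_lo, cfg.pfav_hu_hi)
    lung = volume_ml(lung_mask, ct.spacing)
    return pfav, lung


def compute_imat(
    ct: CTVolume, muscle_mask: np.ndarray, cfg: QuantConfig | None = None
) -> float:
    """Inter-/intra-muscular adipose tissue volume (mL) inside the muscle mask."""
    cfg = cfg or QuantConfig()
    muscle_mask = np.asarray(muscle_mask)
    if muscle_mask.shape != ct.shape:
        raise AlignmentError(f"muscle mask shape {muscle_mask.shape} != CT shape {ct.shape}")
    if not np.any(muscle_mask):
        raise DegenerateInputError("empty muscle mask: IMAT is undefined")
    return fat_attenuation_volume(ct, muscle_mask, cfg.imat_hu_lo, cfg.imat_hu_hi)


def quantify_subject(ct: CTVolume, masks: MaskSet, cfg: QuantConfig | None = None) -> BCAVolumes:
    """Full per-subject quantification: all compartment volumes plus the
    two fat-attenuation volumes (CTpfav, IMAT) and derived TAT.

    With ``cfg.resample_enabled`` the CT and masks are first normalised to
    ``cfg.bca_slice_mm`` slice thickness (lung and CTpfav to
    ``cfg.organ_slice_mm``); otherwise everything runs at native spacing.
    """
    cfg = cfg or QuantConfig()
    for name in REQUIRED_MASKS:
        if name not in masks:
            raise ConfigurationError(f"required mask {name!r} is missing")
    if masks.shape != ct.shape:
        raise AlignmentError(f"mask grid {masks.shape} != CT grid {ct.shape}")

    def _grids(target_mm: float):
        if not cfg.resample_enabled:
            return ct, {n: masks[n] for n in REQUIRED_MASKS}
        ct_r = resample_z(ct, target_mm, mode="continuous")
        masks_r = {
            n: resample_z(masks[n], target_mm, mode="label", spacing=ct.spacing)
            for n in REQUIRED_MASKS
        }
        masks_r = {n: (m[0] if isinstance(m, tuple) else m) for n, m in masks_r.items()}
        return ct_r, masks_r

    ct_bca, m_bca = _grids(cfg.bca_slice_mm)
    ct_org, m_org = _grids(cfg.organ_slice_mm)

    sp = ct_bca.spacing
    raw = {
        "bone": volume_ml(m_bca["bone"], sp),
        "muscle": volume_ml(m_bca["muscle"], sp),
        "sat": volume_ml(m_bca["subcutaneous_at"], sp),
        "vat": volume_ml(m_bca["visceral_at"], sp),
        "eat": volume_ml(m_bca["epicardial_at"], sp),
        "mat": volume_ml(m_bca["mediastinal_at"], sp),
    }
    raw["imat"] = compute_imat(ct_bca, m_bca["muscle"], cfg) if raw["muscle"] > 0 else 0.0
    ctpfav, lung = compute_ctpfav(ct_org, m_org["lung"], cfg)
    tat = sum(raw[c] for c in cfg.tat_components)
    return BCAVolumes(
        bone_ml=raw["bone"],
        muscle_ml=raw["muscle"],
        sat_ml=raw["sat"],
        vat_ml=raw["vat"],
        imat_ml=raw["imat"],
        eat_ml=raw["eat"],
        mat_ml=raw["mat"],
        lung_ml=lung,
        ctpfav_ml=ctpfav,
        tat_ml=tat,
    )
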