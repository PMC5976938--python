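"""Normalized cartilage depth, zonal and regional labelling, element grids.

The mask of a cartilage cross-section is bounded by two non-intersecting
polylines: the articular surface and the osteochondral junction. For each
masked pixel the normalized depth is

    z = d_surf / (d_surf + d_bone),

where ``d_surf`` and ``d_bone`` are Euclidean distances to the nearest
point on the respective (densely resampled) curve. This definition is
rotation invariant and degrades gracefully on curved samples, where image
columns are not aligned with the tissue depth direction; a column-wise
alternative is available for flat slabs.

Zones partition the mask by depth — superficial (SZ, z < 0.15),
transitional (TZ, 0.15 <= z < 0.65), deep (DZ, z >= 0.65); ties go to the
deeper zone. Regions partition it laterally into a central band (CR) of
fixed physical width centered on the mask centroid column and the
peripheral remainder (PR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DepthField",
    "ZoneLabels",
    "RegionLabels",
    "Element",
    "ElementGrid",
    "ZONES",
    "REGIONS",
    "compute_depth",
    "assign_zones",
    "assign_regions",
    "discretize",
]

ZONES = ("SZ", "TZ", "DZ")
REGIONS = ("CR", "PR")


class DegenerateGeometryError(ValueError):
    """A pixel is at zero distance from both bounding curves."""


@dataclass
class DepthField:
    """Normalized depth per masked pixel (NaN outside the mask)."""

    z: np.ndarray
    mask: np.ndarray = field(repr=False)


@dataclass
class ZoneLabels:
    """Zone index per masked pixel: 0=SZ, 1=TZ, 2=DZ; -1 outside."""

    labels: np.ndarray
    boundaries: tuple[float, float]
    mask: np.ndarray = field(repr=False)

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.labels == ZONES.index(zone)


@dataclass
class RegionLabels:
    """Region index per masked pixel: 0=CR, 1=PR; -1 outside."""

    labels: np.ndarray
    cr_width_mm: float
    mask: np.ndarray = field(repr=False)

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == REGIONS.index(region)


def _densify(curve: np.ndarray, oversample: int) -> np.ndarray:
    """Resample a polyline with ``oversample`` points per segment."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2:
        raise ValueError("curve must be an (N, 2) polyline")
    if len(curve) < 2 or oversample <= 1:
        return curve
    frac = np.linspace(0.0, 1.0, oversample, endpoint=False)
    seg = curve[1:] - curve[:-1]
    pts = curve[:-1, None, :] + frac[None, :, None] * seg[:, None, :]
    return np.vstack([pts.reshape(-1, 2), curve[-1:]])


def compute_depth(sample, method: str = "distance", oversample: int = 8) -> DepthField:
    """Normalized depth field for a masked sample bounded by two curves.

    ``sample`` provides ``mask`` (boolean 2-D) and the ``surface_curve``
    and ``bone_curve`` polylines in pixel coordinates ``(col, row)``.
    ``method="distance"`` (default) uses nearest-point distances to both
    curves; ``method="column"`` interpolates each curve per image column
    and normalizes the row coordinate between them (flat slabs only, where
    columns align with depth).
    """
    mask = np.asarray(sample.mask, dtype=bool)
    surf = np.asarray(sample.surface_curve, dtype=float)
    bone = np.asarray(sample.bone_curve, dtype=float)
    rows, cols = np.nonzero(mask)
    z = np.full(mask.shape, np.nan)

    if method == "distance":
        pts = np.column_stack([cols, rows]).astype(float)  # (x=col, y=row)
        d_s, _ = cKDTree(_densify(surf, oversample)).query(pts)
        d_b, _ = cKDTree(_densify(bone, oversample)).query(pts)
        total = d_s + d_b
        if np.any(total == 0):
            raise DegenerateGeometryError("pixel lies on both curves")
        z[rows, cols] = d_s / total
    elif method == "column":
        ys = np.interp(cols, surf[:, 0], surf[:, 1])
        yb = np.interp(cols, bone[:, 0], bone[:, 1])
        thick = yb - ys
        if np.any(thick <= 0):
            raise DegenerateGeometryError("bone curve not below surface curve")
        z[rows, cols] = np.clip((rows - ys) / thick, 0.0, 1.0)
    else:
        raise ValueError(f"unknown depth method {method!r}")
    return DepthField(z=z, mask=mask)


def assign_zones(
    depth: DepthField, boundaries: tuple[float, float] = (0.15, 0.65)
) -> ZoneLabels:
    """Partition the mask into SZ/TZ/DZ by normalized depth.

    Half-open convention: SZ covers ``[0, b1)``, TZ ``[b1, b2)``, DZ
    ``[b2, 1]`` — a pixel exactly on a boundary belongs to the deeper zone.
    """
    b1, b2 = boundaries
    if not (0.0 < b1 < b2 < 1.0):
        raise ValueError("zone boundaries must satisfy 0 < b1 < b2 < 1")
    mask = depth.mask
    labels = np.full(mask.shape, -1, dtype=int)
    zm = depth.z[mask]
    lab = np.where(zm < b1, 0, np.where(zm < b2, 1, 2))
    labels[mask] = lab
    return ZoneLabels(labels=labels, boundaries=boundaries, mask=mask)


def assign_regions(
    mask: np.ndarray, pixel_spacing_mm: float, cr_width_mm: float = 6.0
) -> RegionLabels:
    """Split the mask into a central band (CR) and the peripheral rest (PR).

    The CR band is ``cr_width_mm`` wide (rounded to a whole number of
    columns) and centered on the mask's centroid column. A CR as wide as
    the sample leaves PR empty, which is reported with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    cols_present = np.nonzero(mask.any(axis=0))[0]
    sample_width_mm = (cols_present[-1] - cols_present[0] + 1) * pixel_spacing_mm
    if cr_width_mm > sample_width_mm + 1e-9:
        raise ValueError(
            f"CR width {cr_width_mm} mm exceeds sample width {sample_width_mm:.2f} mm"
        )
    n_cr = max(1, int(round(cr_width_mm / pixel_spacing_mm)))
    centroid_col = np.nonzero(mask)[1].mean()
    start = int(round(centroid_col - (n_cr - 1) / 2.0))
    cr_cols = np.arange(start, start + n_cr)

    labels = np.full(mask.shape, -1, dtype=int)
    labels[mask] = 1  # PR
    in_cr = np.isin(np.arange(mask.shape[1]), cr_cols)
    labels[mask & in_cr[None, :]] = 0  # CR
    if not np.any(labels == 1):
        warnings.warn("central region covers the whole sample; PR is empty")
    return RegionLabels(labels=labels, cr_width_mm=cr_width_mm, mask=mask)


@dataclass
class Element:
    """One rectangular element: member pixel indices and mean depth."""

    rows: np.ndarray
    cols: np.ndarray
    mean_z: float


@dataclass
class ElementGrid:
    """Rectangular tiling of the mask's bounding box.

    Only elements containing at least one masked pixel are kept; elements
    are disjoint and their union is exactly the mask.
    """

    elements: list[Element]
    element_px: int
    mask: np.ndarray = field(repr=False)

    @property
    def n_elements(self) -> int:
        return len(self.elements)


def discretize(mask: np.ndarray, depth: DepthField, element_px: int) -> ElementGrid:
    """Tile the mask with square elements of ``element_px`` pixels per side."""
    if element_px < 1:
        raise ValueError("element_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    r0, c0 = rows.min(), cols.min()
    elements: list[Element] = []
    for rb in range(r0, rows.max() + 1, element_px):
        for cb in range(c0, cols.max() + 1, element_px):
            block = np.zeros_like(mask)
            block[rb : rb + element_px, cb : cb + element_px] = True
            member = block & mask
            if not member.any():
                continue
            rr, cc = np.nonzero(member)
            elements.append(Element(rr, cc, float(np.mean(depth.z[rr, cc]))))
    return ElementGrid(elements=elements, element_px=element_px, mask=mask)
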