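"""Synthetic osteochondral phantoms and simulated qMRI acquisitions.

The phantom emulates the mid-sagittal cross-section of a convex
osteochondral sample: the articular surface is a circular arc of
prescribed curvature (default 4.4/m, a typical femoral-condyle value),
the osteochondral junction is the concentric arc one cartilage thickness
deeper, and the mask is the rasterized band between them. A curvature of
zero degenerates to a flat slab.

Ground-truth relaxation maps (T1, T1rho, T2*) are linked to the modelled
local fluid fraction by strictly increasing affine maps spanning
physiologic ranges, so that fluid-richer (more superficial) tissue relaxes
more slowly. These links are synthetic test scaffolding — they let every
pipeline stage be verified against a known truth — and encode no
biological claim about the true composition–relaxation relationship.

Simulated magnitude signals follow the sequence signal equations exactly
and are corrupted by Rician noise (the magnitude of a complex Gaussian
perturbation), the noise law of magnitude-reconstructed MRI. The noise
scale is ``sigma = A_max / SNR``; an infinite SNR reproduces the noiseless
forward model bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import compute_depth
from .relaxometry import AcquisitionProtocol
from .tissue_model import CompositionModel, calibrate_default_profiles

__all__ = [
    "LinkParams",
    "PhantomSpec",
    "PhantomSample",
    "GroundTruth",
    "SignalStack",
    "make_geometry",
    "make_ground_truth",
    "simulate_stack",
    "make_phantom",
]


class InvalidSpecError(ValueError):
    """Phantom specification not representable on the pixel grid."""


@dataclass(frozen=True)
class LinkParams:
    """Affine composition-to-relaxation link ranges (ms).

    Each relaxation time is mapped linearly from the composition model's
    global fluid-fraction range onto ``[lo, hi]``; defaults span the
    physiologic magnitudes of healthy femoral cartilage.
    """

    t1_range_ms: tuple[float, float] = (550.0, 750.0)
    t1rho_range_ms: tuple[float, float] = (40.0, 90.0)
    t2star_range_ms: tuple[float, float] = (15.0, 40.0)
    amplitude: float = 1000.0
    noise_floor: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and acquisition parameters of one synthetic sample."""

    width_mm: float = 15.0
    thickness_mm: float = 2.5
    curvature_per_m: float = 4.4
    pixel_spacing_mm: float = 0.1
    snr: float = 50.0
    seed: int = 0
    link_params: LinkParams = field(default_factory=LinkParams)

    def __post_init__(self) -> None:
        if min(self.width_mm, self.thickness_mm, self.pixel_spacing_mm) <= 0:
            raise InvalidSpecError("lengths must be positive")
        if self.curvature_per_m < 0:
            raise InvalidSpecError("curvature must be >= 0")
        if not self.snr > 0:
            raise InvalidSpecError("snr must be positive (may be inf)")
        if self.thickness_mm < 3 * self.pixel_spacing_mm:
            raise InvalidSpecError("thickness not resolvable at this pixel spacing")
        if self.width_mm < 3 * self.pixel_spacing_mm:
            raise InvalidSpecError("width not resolvable at this pixel spacing")


@dataclass
class PhantomSample:
    """Rasterized sample: mask plus bounding curves in pixel coordinates.

    Curves are ``(N, 2)`` polylines of ``(col, row)`` pixel coordinates
    (one vertex per image column); physical position is coordinate times
    ``pixel_spacing_mm``.
    """

    mask: np.ndarray
    surface_curve: np.ndarray
    bone_curve: np.ndarray
    pixel_spacing_mm: float


@dataclass
class GroundTruth:
    """True per-pixel relaxation maps (ms) and signal amplitude; NaN outside."""

    t1_map: np.ndarray
    t1rho_map: np.ndarray
    t2star_map: np.ndarray
    amplitude_map: np.ndarray
    noise_floor: float
    mask: np.ndarray = field(repr=False)

    def map_for(self, kind: str) -> np.ndarray:
        return {"T1": self.t1_map, "T1RHO": self.t1rho_map, "T2STAR": self.t2star_map}[kind]


@dataclass
class SignalStack:
    """Per-pixel signal versus acquisition parameter: shape (rows, cols, n)."""

    data: np.ndarray
    kind: str
    mask: np.ndarray = field(repr=False)


def _curve_rows(x_mm: np.ndarray, spec: PhantomSpec, depth_offset_mm: float) -> np.ndarray:
    """Row coordinate (in mm, y down) of the arc at lateral positions x.

    The surface arc has radius ``R = 1/kappa`` with its centre of
    curvature a full radius below the apex; deeper interfaces are
    concentric arcs of radius ``R - offset``. ``kappa = 0`` gives a
    horizontal line at ``apex + offset``.
    """
    kappa_mm = spec.curvature_per_m / 1000.0
    apex_mm = 2.0 * spec.pixel_spacing_mm  # margin above the surface apex
    if kappa_mm == 0.0:
        return np.full_like(x_mm, apex_mm + depth_offset_mm)
    radius = 1.0 / kappa_mm - depth_offset_mm
    if radius <= spec.width_mm / 2.0:
        raise InvalidSpecError("curvature too strong for the requested width")
    y_center = apex_mm + 1.0 / kappa_mm
    return y_center - np.sqrt(radius**2 - x_mm**2)


def make_geometry(spec: PhantomSpec) -> PhantomSample:
    """Rasterize the convex sample geometry described by ``spec``."""
    dx = spec.pixel_spacing_mm
    n_cols = int(round(spec.width_mm / dx))
    if n_cols < 3:
        raise InvalidSpecError("width not representable at this pixel spacing")
    x_mm = (np.arange(n_cols) - (n_cols - 1) / 2.0) * dx

    y_surf = _curve_rows(x_mm, spec, 0.0)
    y_bone = _curve_rows(x_mm, spec, spec.thickness_mm)
    n_rows = int(np.ceil(y_bone.max() / dx)) + 3

    # membership: pixel-centre depth between the two interfaces, inclusive
    yy = np.arange(n_rows)[:, None] * dx
    mask = (yy >= y_surf[None, :] - 1e-12) & (yy <= y_bone[None, :] + 1e-12)

    surface_curve = np.column_stack([np.arange(n_cols), y_surf / dx])
    bone_curve = np.column_stack([np.arange(n_cols), y_bone / dx])
    return PhantomSample(
        mask=mask,
        surface_curve=surface_curve,
        bone_curve=bone_curve,
        pixel_spacing_mm=dx,
    )


def make_ground_truth(
    sample: PhantomSample,
    model: CompositionModel | None = None,
    spec: PhantomSpec | None = None,
) -> GroundTruth:
    """Derive ground-truth relaxation maps from the composition model.

    Each map is a strictly increasing affine function of the local fluid
    fraction, normalized by the model's global fluid-fraction range (so
    the link spans exactly the configured relaxation range over the full
    depth). Fluid-poor deep tissue therefore has the shortest times,
    mirroring the depth trend of healthy cartilage.
    """
    spec = spec or PhantomSpec()
    model = model or calibrate_default_profiles()
    lp = spec.link_params

    depth = compute_depth(sample)
    mask = sample.mask
    ff = np.full(mask.shape, np.nan)
    ff[mask] = model.fluid(np.clip(depth.z[mask], 0.0, 1.0))

    # global FF range of the model: FF is monotone non-increasing in depth
    ff_hi = float(model.fluid(0.0))
    ff_lo = float(model.fluid(1.0))
    if not ff_hi > ff_lo:
        raise ValueError("composition model has constant fluid fraction; link undefined")
    unit = (ff - ff_lo) / (ff_hi - ff_lo)

    def link(rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        return lo + (hi - lo) * unit

    amp = np.full(mask.shape, np.nan)
    amp[mask] = lp.amplitude
    return GroundTruth(
        t1_map=link(lp.t1_range_ms),
        t1rho_map=link(lp.t1rho_range_ms),
        t2star_map=link(lp.t2star_range_ms),
        amplitude_map=amp,
        noise_floor=lp.noise_floor,
        mask=mask,
    )


def _forward_signal(
    gt: GroundTruth, protocol: AcquisitionProtocol
) -> np.ndarray:
    """Noiseless magnitude signal stack from the sequence signal equations."""
    times = protocol.times[None, None, :]
    amp = gt.amplitude_map[:, :, None]
    tau = gt.map_for(protocol.kind)[:, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        if protocol.kind in ("T2STAR", "T1RHO"):
            sig = amp * np.exp(-times / tau) + gt.noise_floor
        elif protocol.kind == "T1":
            sig = np.abs(
                amp
                * (1.0 - 2.0 * np.exp(-times / tau) + np.exp(-protocol.tr_ms / tau))
            ) + gt.noise_floor
        else:
            raise ValueError(f"unknown sequence kind {protocol.kind!r}")
    return sig


def simulate_stack(
    gt: GroundTruth,
    protocol: AcquisitionProtocol,
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
) -> SignalStack:
    """Simulate one magnitude acquisition series with Rician noise.

    The noise scale is ``sigma = A_max / snr`` with ``A_max`` the peak
    ground-truth amplitude; each sample becomes
    ``sqrt((s + n_re)^2 + n_im^2)`` with independent Gaussian ``n_re``,
    ``n_im``. ``snr = inf`` returns the noiseless forward model.
    """
    clean = _forward_signal(gt, protocol)
    if np.isinf(spec.snr):
        data = clean
    else:
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        sigma = float(np.nanmax(gt.amplitude_map)) / spec.snr
        noise = rng.normal(scale=sigma, size=clean.shape + (2,))
        data = np.sqrt((clean + noise[..., 0]) ** 2 + noise[..., 1] ** 2)
        data[~gt.mask] = np.nan
    return SignalStack(data=data, kind=protocol.kind, mask=gt.mask)


def make_phantom(
    spec: PhantomSpec, model: CompositionModel | None = None
) -> tuple[PhantomSample, GroundTruth]:
    """Convenience: geometry plus ground truth in one call."""
    sample = make_geometry(spec)
    return sample, make_ground_truth(sample, model, spec)
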