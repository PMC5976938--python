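"""Depth-dependent cartilage composition and collagen-fiber architecture.

Articular cartilage is modelled as a fluid-saturated solid matrix of
collagen (CO) fibers and proteoglycan (PG) aggregates. At every
normalized depth ``z`` (0 at the articular surface, 1 at the
osteochondral junction) the constituent volume fractions conserve volume,

    phi_fluid(z) + phi_CO(z) + phi_PG(z) = 1,

with the solid fraction ``phi_s = 1 - phi_fluid``. The fluid fraction
decreases with depth while collagen and proteoglycan increase.

The collagen fiber architecture follows the classical arcade picture:
fibers run parallel to the surface in the superficial zone (90° from the
surface normal), perpendicular to the subchondral bone in the deep zone
(0°), with a linear transition in between. Fiber dispersion is represented
by ``n`` discrete fiber families fanned equiangularly about the mean
direction.

Default composition profiles are not taken from any closed-form source;
they are calibrated so that their zonal means over the superficial
(z < 0.15), transitional (0.15–0.65) and deep (≥ 0.65) zones reproduce
prescribed zonal targets exactly, with conservation enforced by
construction (PG is the remainder of fluid and collagen).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZONE_BOUNDARIES",
    "DEFAULT_ZONAL_TARGETS",
    "CompositionModel",
    "FiberModel",
    "ModelledMaps",
    "composition_at",
    "fiber_angle_at",
    "fiber_families",
    "calibrate_default_profiles",
    "evaluate_on_grid",
]

#: normalized-depth boundaries between superficial/transitional/deep zones
ZONE_BOUNDARIES: tuple[float, float] = (0.15, 0.65)

#: zonal mean volume fractions (SZ, TZ, DZ) used to calibrate the default
#: profiles. The transitional-zone values carry a +1/300 redistribution:
#: the printed zonal references sum to 99% there while volume conservation
#: requires 100%, so the missing percent is split equally across the three
#: constituents (each stays within 0.34 pp of its reference).
DEFAULT_ZONAL_TARGETS: dict[str, tuple[float, float, float]] = {
    "FF": (0.78, 0.70 + 1.0 / 300.0, 0.51),
    "CO": (0.08, 0.09 + 1.0 / 300.0, 0.20),
    "PG": (0.14, 0.20 + 1.0 / 300.0, 0.29),
}


class CalibrationError(ValueError):
    """Zonal targets incompatible with monotone conserved profiles."""


@dataclass(frozen=True)
class CompositionModel:
    """Piecewise-linear depth profiles of the constituent volume fractions.

    ``knots_z`` are the profile breakpoints (the zone boundaries plus the
    endpoints); ``ff_knots`` and ``co_knots`` hold the fluid and collagen
    fractions there. The proteoglycan fraction is always the conservation
    remainder ``1 - FF - CO``, so the sum constraint holds identically at
    every depth, not just at the knots.
    """

    knots_z: tuple[float, ...]
    ff_knots: tuple[float, ...]
    co_knots: tuple[float, ...]
    source: str = "default-calibrated"

    def __post_init__(self) -> None:
        z = np.asarray(self.knots_z)
        ff = np.asarray(self.ff_knots)
        co = np.asarray(self.co_knots)
        pg = 1.0 - ff - co
        if z[0] != 0.0 or z[-1] != 1.0 or np.any(np.diff(z) <= 0):
            raise CalibrationError("knots must increase strictly from 0 to 1")
        for name, v in (("FF", ff), ("CO", co), ("PG", pg)):
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise CalibrationError(f"{name} profile leaves [0, 1]")
        if np.any(np.diff(ff) > 1e-12):
            raise CalibrationError("fluid fraction must be non-increasing in depth")
        if np.any(np.diff(co) < -1e-12) or np.any(np.diff(pg) < -1e-12):
            raise CalibrationError("CO and PG fractions must be non-decreasing in depth")

    def fluid(self, z) -> np.ndarray:
        return np.interp(_check_z(z), self.knots_z, self.ff_knots)

    def collagen(self, z) -> np.ndarray:
        return np.interp(_check_z(z), self.knots_z, self.co_knots)

    def proteoglycan(self, z) -> np.ndarray:
        return 1.0 - self.fluid(z) - self.collagen(z)

    def solid(self, z) -> np.ndarray:
        """Solid volume fraction, ``1 - phi_fluid``."""
        return 1.0 - self.fluid(z)


def _check_z(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ValueError("normalized depth must lie in [0, 1]")
    return z


def composition_at(z, model: CompositionModel):
    """Constituent volume fractions ``(FF, CO, PG)`` at normalized depth."""
    ff = model.fluid(z)
    co = model.collagen(z)
    return ff, co, 1.0 - ff - co


def fiber_angle_at(z, boundaries: tuple[float, float] = ZONE_BOUNDARIES) -> np.ndarray:
    """Mean collagen fiber angle (degrees from the local surface normal).

    90° for ``z`` below the superficial boundary, 0° at and beyond the
    deep boundary, linear ramp in between. Continuous on [0, 1].
    """
    z = _check_z(z)
    b1, b2 = boundaries
    ramp = 90.0 * (b2 - z) / (b2 - b1)
    return np.clip(ramp, 0.0, 90.0)


def fiber_families(
    theta_deg: float, n: int = 8, spread_deg: float = 90.0
) -> np.ndarray:
    """Unit vectors of ``n`` fiber families fanned about the mean direction.

    The fan is symmetric (total width ``spread_deg``) so the circular mean
    of the family angles equals ``theta_deg`` exactly. Angles are measured
    from the local surface normal; the returned array has shape ``(n, 2)``
    with components (normal, tangential).
    """
    if n < 1:
        raise ValueError("need at least one fiber family")
    offsets = np.linspace(-spread_deg / 2.0, spread_deg / 2.0, n) if n > 1 else np.array([0.0])
    ang = np.deg2rad(theta_deg + offsets)
    return np.column_stack([np.cos(ang), np.sin(ang)])


def _solve_knots(means: tuple[float, float, float], decreasing: bool):
    """Interior knot values of a continuous piecewise-linear profile whose
    per-zone means equal ``means``.

    With breakpoints at the zone boundaries, the mean over each zone is
    the average of its endpoint values, leaving one free parameter (the
    value at the first boundary); it is set to the midpoint of its
    feasible interval under the monotonicity constraint.
    """
    m1, m2, m3 = means
    s = -1.0 if decreasing else 1.0
    # work with the increasing profile s*v
    a1, a2, a3 = s * m1, s * m2, s * m3
    lo = max(a1, 2.0 * a2 - a3)
    hi = a2
    if lo > hi + 1e-12:
        raise CalibrationError(f"zonal means {means} admit no monotone profile")
    v1 = (lo + hi) / 2.0
    v0 = 2.0 * a1 - v1
    v2 = 2.0 * a2 - v1
    v3 = 2.0 * a3 - v2
    return tuple(s * v for v in (v0, v1, v2, v3))


def calibrate_default_profiles(
    zonal_targets: dict[str, tuple[float, float, float]] | None = None,
    boundaries: tuple[float, float] = ZONE_BOUNDARIES,
) -> CompositionModel:
    """Build the default composition model from zonal mean targets.

    ``zonal_targets`` maps ``"FF"``, ``"CO"`` (and optionally ``"PG"``,
    used only for validation) to their (SZ, TZ, DZ) mean fractions. The
    fluid and collagen profiles are calibrated independently as monotone
    piecewise-linear curves whose zonal means reproduce the targets
    exactly; proteoglycan is the conservation remainder and its resulting
    zonal means are checked against the PG targets when given.
    """
    targets = dict(DEFAULT_ZONAL_TARGETS if zonal_targets is None else zonal_targets)
    ff_m = targets["FF"]
    co_m = targets["CO"]
    if any(not 0 < v < 1 for v in (*ff_m, *co_m)):
        raise CalibrationError("zonal targets must be fractions in (0, 1)")

    ff_knots = _solve_knots(ff_m, decreasing=True)
    co_knots = _solve_knots(co_m, decreasing=False)
    knots_z = (0.0, boundaries[0], boundaries[1], 1.0)
    model = CompositionModel(knots_z, ff_knots, co_knots, source="default-calibrated")

    if "PG" in targets:
        pg_knots = 1.0 - np.asarray(ff_knots) - np.asarray(co_knots)
        pg_means = (pg_knots[:-1] + pg_knots[1:]) / 2.0
        if np.max(np.abs(pg_means - np.asarray(targets["PG"]))) > 5e-3:
            raise CalibrationError(
                "PG remainder means deviate from PG targets by more than 0.5 pp"
            )
    return model


@dataclass(frozen=True)
class FiberModel:
    """Fiber-architecture parameters: family count, fan width, zone bounds."""

    n_families: int = 8
    spread_deg: float = 90.0
    boundaries: tuple[float, float] = ZONE_BOUNDARIES


@dataclass
class ModelledMaps:
    """Per-pixel modelled composition (fractions) and mean fiber angle (deg).

    Arrays share the mask's shape; NaN outside the mask.
    """

    ff: np.ndarray
    co: np.ndarray
    pg: np.ndarray
    cfo_deg: np.ndarray
    mask: np.ndarray = field(repr=False)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"FF": self.ff, "CO": self.co, "PG": self.pg, "CFO": self.cfo_deg}

    def pooled(self, grid) -> "ModelledMaps":
        """Replace each pixel value by its element mean (see ElementGrid)."""
        out = {}
        for name, arr in self.as_dict().items():
            pooled = np.full(arr.shape, np.nan)
            for elem in grid.elements:
                rr, cc = elem.rows, elem.cols
                pooled[rr, cc] = np.nanmean(arr[rr, cc])
            out[name] = pooled
        return ModelledMaps(out["FF"], out["CO"], out["PG"], out["CFO"], self.mask)


def evaluate_on_grid(
    depth, model: CompositionModel, fiber: FiberModel | None = None
) -> ModelledMaps:
    """Evaluate composition and fiber angle at every masked pixel.

    ``depth`` is a :class:`~cartiqmap.geometry.DepthField` (or any object
    with a ``z`` array and boolean ``mask``).
    """
    fiber = fiber or FiberModel()
    mask = np.asarray(depth.mask, dtype=bool)
    z = np.asarray(depth.z, dtype=float)
    ff = np.full(z.shape, np.nan)
    co = np.full(z.shape, np.nan)
    cfo = np.full(z.shape, np.nan)
    zm = np.clip(z[mask], 0.0, 1.0)
    ff[mask] = model.fluid(zm)
    co[mask] = model.collagen(zm)
    cfo[mask] = fiber_angle_at(zm, fiber.boundaries)
    pg = 1.0 - ff - co
    pg[~mask] = np.nan
    return ModelledMaps(ff, co, pg, cfo, mask)
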