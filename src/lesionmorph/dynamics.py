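"""Signed lesion deformation maps and highly dynamic regions.

From a converged metamorphosis path the per-voxel deformation magnitude
is the time-integrated squared speed ``sum_t |v_t(x)|^2 dt`` (mm^2 per
unit path time).  Its sign encodes the direction of motion relative to
the lesion boundary: the time-averaged projection of the velocity onto
the outward normal (gradient of the signed distance to the lesion mask)
is positive for expansion and negative for contraction.

"Highly" contracting / expanding voxels are extracted with a
mean/standard-deviation rule on the speed (the square root of the
magnitude) computed within the lesion:

* highly contracting: contracting voxels whose speed exceeds
  ``mean_c - sd_c`` of the contracting speeds;
* highly expanding (default, "corrected" rule): expanding voxels whose
  speed exceeds ``mean_e + sd_e`` of the expanding speeds.  The
  "as-printed" variant instead thresholds expansion against the
  contraction statistics ``mean_c + sd_c``.

Both inequalities are strict, so a field with zero spread selects
nothing.  The rule is scale-equivariant: scaling all velocities by k
scales every speed and both thresholds by k and leaves the masks
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .metamorphosis import MetamorphosisPath
from .volume import as_binary_mask

__all__ = [
    "DeformationMap",
    "DynamicRegions",
    "total_deformation_map",
    "sign_deformation",
    "threshold_dynamic_regions",
    "volumetric_proportions",
]

SIGN_DEAD_BAND = 1e-6  # mm per unit path time


@dataclass
class DeformationMap:
    """Signed total deformation over a lesion for one evolution phase."""

    magnitude: np.ndarray  # >= 0, mm^2 per unit path time; zero outside mask
    sign: np.ndarray  # values in {-1, 0, +1}
    lesion_mask: np.ndarray  # bool
    phase: str
    spacing: tuple[float, ...]
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.magnitude.min() < 0:
            raise ValueError("deformation magnitude must be non-negative")

    @property
    def signed_value(self) -> np.ndarray:
        return self.magnitude * self.sign

    @property
    def speed(self) -> np.ndarray:
        """Root of the time-integrated squared speed, mm per unit path time."""
        return np.sqrt(self.magnitude)


@dataclass
class DynamicRegions:
    """Highly contracting / expanding voxels and their lesion-volume shares."""

    contracting_mask: np.ndarray
    expanding_mask: np.ndarray
    thresholds: tuple[float | None, float | None]
    proportions: tuple[float, float]  # percent of lesion volume
    rule: str = "corrected"


def _outward_normal(lesion_mask: np.ndarray, spacing) -> np.ndarray:
    """Unit outward normal from the signed distance to the mask boundary."""
    inside = ndimage.distance_transform_edt(lesion_mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~lesion_mask, sampling=spacing)
    signed = outside - inside  # negative inside, positive outside
    grads = np.stack(np.gradient(signed, *spacing))
    norm = np.sqrt(np.sum(grads**2, axis=0))
    norm[norm == 0] = 1.0
    return grads / norm


def sign_deformation(path: MetamorphosisPath, lesion_mask: np.ndarray) -> np.ndarray:
    """Per-voxel expansion/contraction sign from the outward-normal projection.

    +1 where the time-averaged velocity points out of the lesion
    (expansion), -1 where it points inwards (contraction), 0 inside a
    small dead-band around zero projection.
    """
    lesion_mask = as_binary_mask(lesion_mask, "lesion_mask")
    if not lesion_mask.any():
        raise ValueError("lesion_mask is empty")
    if lesion_mask.shape != path.grid_shape:
        raise ValueError("lesion_mask grid does not match the path grid")
    normal = _outward_normal(lesion_mask, path.spacing)
    proj = np.zeros(path.grid_shape)
    for t in range(path.n_steps):
        proj += np.sum(path.velocities[t] * normal, axis=0) * path.dt
    sign = np.zeros(path.grid_shape, dtype=int)
    sign[proj > SIGN_DEAD_BAND] = 1
    sign[proj < -SIGN_DEAD_BAND] = -1
    return sign


def total_deformation_map(
    path: MetamorphosisPath, lesion_mask: np.ndarray, phase: str
) -> DeformationMap:
    """Total signed deformation map over the lesion for one phase.

    ``magnitude(x) = sum_t |v_t(x)|^2 dt`` inside the lesion mask, zero
    outside; the sign comes from :func:`sign_deformation`.  An
    unconverged path is accepted but recorded as a warning.
    """
    lesion_mask = as_binary_mask(lesion_mask, "lesion_mask")
    if lesion_mask.shape != path.grid_shape:
        raise ValueError("lesion_mask grid does not match the path grid")
    magnitude = np.zeros(path.grid_shape)
    for t in range(path.n_steps):
        magnitude += np.sum(path.velocities[t] ** 2, axis=0) * path.dt
    sign = sign_deformation(path, lesion_mask)
    magnitude[~lesion_mask] = 0.0
    sign[~lesion_mask] = 0
    warnings = []
    if not path.converged:
        warnings.append("metamorphosis path did not converge; deformation map may be biased")
    return DeformationMap(
        magnitude=magnitude,
        sign=sign,
        lesion_mask=lesion_mask,
        phase=phase,
        spacing=path.spacing,
        converged=path.converged,
        warnings=warnings,
    )


def threshold_dynamic_regions(
    def_map: DeformationMap, rule: str = "corrected", boundary_band_only: bool = False
) -> DynamicRegions:
    """Extract highly contracting and expanding voxels by the mean/sd rule.

    ``rule="corrected"`` thresholds each direction against its own speed
    statistics (contraction: mean - sd; expansion: mean + sd);
    ``rule="as-printed"`` thresholds expansion against the contraction
    statistics (mean + sd).  With ``boundary_band_only`` the statistics
    and masks are restricted to the lesion boundary shell (mask minus
    its one-voxel erosion).
    """
    if rule not in ("corrected", "as-printed"):
        raise ValueError(f"unknown rule {rule!r}")
    lesion = def_map.lesion_mask
    if not lesion.any():
        raise ValueError("deformation map has an empty lesion mask")
    domain = lesion
    if boundary_band_only:
        domain = lesion & ~ndimage.binary_erosion(lesion)
    speed = def_map.speed
    contracting = domain & (def_map.sign == -1)
    expanding = domain & (def_map.sign == 1)

    thr_c: float | None = None
    thr_e: float | None = None
    high_c = np.zeros_like(lesion)
    high_e = np.zeros_like(lesion)
    if contracting.any():
        sc = speed[contracting]
        thr_c = float(sc.mean() - sc.std())
        high_c = contracting & (speed > thr_c)
    if expanding.any():
        if rule == "corrected":
            se = speed[expanding]
            thr_e = float(se.mean() + se.std())
        else:  # as-printed: expansion thresholded on the contraction field stats
            if contracting.any():
                sc = speed[contracting]
                thr_e = float(sc.mean() + sc.std())
        if thr_e is not None:
            high_e = expanding & (speed > thr_e)

    n_lesion = int(lesion.sum())
    props = (100.0 * high_c.sum() / n_lesion, 100.0 * high_e.sum() / n_lesion)
    return DynamicRegions(
        contracting_mask=high_c,
        expanding_mask=high_e,
        thresholds=(thr_c, thr_e),
        proportions=props,
        rule=rule,
    )


def volumetric_proportions(
    regions: DynamicRegions, lesion_mask: np.ndarray
) -> tuple[float, float]:
    """Percent of the lesion volume occupied by each highly dynamic mask."""
    lesion_mask = as_binary_mask(lesion_mask, "lesion_mask")
    n = int(lesion_mask.sum())
    if n == 0:
        raise ValueError("lesion_mask is empty")
    return (
        100.0 * float(regions.contracting_mask.sum()) / n,
        100.0 * float(regions.expanding_mask.sum()) / n,
    )
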