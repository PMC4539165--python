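"""Low-level operations on scalar and vector fields.

Conventions used throughout the package:

* scalar fields are arrays of shape ``grid`` (2-D or 3-D);
* vector fields are arrays of shape ``(ndim, *grid)`` with components in
  mm (displacements) or mm per unit path time (velocities);
* deformation maps ("positions") are arrays of shape ``(ndim, *grid)``
  holding voxel-index coordinates, so the identity map at voxel ``x`` is
  ``x`` itself;
* interpolation is trilinear (bilinear in 2-D) and out-of-grid samples
  clamp to the boundary value.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "identity_map",
    "sample_scalar",
    "sample_vector",
    "spatial_gradient",
    "divergence",
    "smooth_vector",
    "jacobian_determinant",
    "warp_scalar",
]


def identity_map(shape: tuple[int, ...]) -> np.ndarray:
    """Voxel-coordinate identity map of shape ``(ndim, *shape)``."""
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"))


def sample_scalar(arr: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample ``arr`` at voxel coordinates ``coords`` (shape (ndim, *out))."""
    ndim = coords.shape[0]
    out_shape = coords.shape[1:]
    flat = coords.reshape(ndim, -1)
    vals = ndimage.map_coordinates(arr, flat, order=1, mode="nearest")
    return vals.reshape(out_shape)


def sample_vector(field: np.ndarray, coords: np.ndarray) -> np.ndarray:
    return np.stack([sample_scalar(field[i], coords) for i in range(field.shape[0])])


def spatial_gradient(arr: np.ndarray, spacing: tuple[float, ...]) -> np.ndarray:
    """Central-difference gradient, shape ``(ndim, *grid)``, units 1/mm."""
    grads = np.gradient(arr, *spacing)
    if arr.ndim == 1:  # np.gradient returns a bare array in 1-D
        grads = [grads]
    return np.stack(grads)


def divergence(field: np.ndarray, spacing: tuple[float, ...]) -> np.ndarray:
    out = np.zeros(field.shape[1:], dtype=float)
    for i in range(field.shape[0]):
        out += np.gradient(field[i], spacing[i], axis=i)
    return out


def smooth_vector(field: np.ndarray, sigma_vox: tuple[float, ...]) -> np.ndarray:
    """Componentwise Gaussian smoothing; realizes the V-norm kernel."""
    return np.stack(
        [ndimage.gaussian_filter(field[i], sigma=sigma_vox, mode="nearest") for i in range(field.shape[0])]
    )


def warp_scalar(arr: np.ndarray, displacement_vox: np.ndarray) -> np.ndarray:
    """Pull-back warp: ``out(x) = arr(x - d(x))`` with ``d`` in voxel units."""
    coords = identity_map(arr.shape) - displacement_vox
    return sample_scalar(arr, coords)


def jacobian_determinant(phi: np.ndarray) -> np.ndarray:
    """Determinant of the Jacobian of a deformation map given in voxel coords."""
    ndim = phi.shape[0]
    J = [[np.gradient(phi[i], axis=j) for j in range(ndim)] for i in range(ndim)]
    if ndim == 2:
        return J[0][0] * J[1][1] - J[0][1] * J[1][0]
    if ndim == 3:
        return (
            J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
            - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
            + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
        )
    raise ValueError(f"unsupported dimensionality {ndim}")
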