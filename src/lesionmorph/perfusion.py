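"""Relative MTT maps and their relation to lesion deformation.

A prolonged mean transit time (MTT) marks hypoperfused tissue.  Because
absolute MTT values vary between acquisitions, each lesion voxel is
normalized by the mean MTT of the homologous contralateral region,
obtained by mirror reflection of the lesion mask about the midsagittal
plane; the resulting relative MTT (rMTT) is unitless.

For each deformation direction the rMTT values of the selected voxels
are binned, the mean deformation speed per bin forms an empirical
deformation-vs-perfusion curve, and a Gaussian ``a * exp(-(x - mu)^2 /
(2 s^2))`` is fit by nonlinear least squares.  The fitted peak ``mu``
is the rMTT level associated with the fastest deformation, and
``[p1, p2] = [mu - s, mu + s]`` brackets the perfusion range of the
most dynamic tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .dynamics import DeformationMap
from .volume import ScalarVolume, as_binary_mask

__all__ = [
    "RMTTMap",
    "DeformationPerfusionSamples",
    "GaussianFit",
    "mirror_reflect",
    "compute_rmtt",
    "deformation_vs_rmtt",
    "gaussian_fit",
    "confidence_interval",
]

CONTRACTION = "contraction"
EXPANSION = "expansion"


@dataclass
class RMTTMap:
    """Per-voxel MTT relative to the contralateral mean (unitless)."""

    values: np.ndarray  # full grid; zero outside region_mask
    region_mask: np.ndarray
    contralateral_mean: float
    midline_index: float
    axis: int = 0
    n_excluded: int = 0  # non-finite / non-positive contralateral voxels


@dataclass
class DeformationPerfusionSamples:
    """Binned mean deformation speed per rMTT value for one direction."""

    bins: np.ndarray  # strictly increasing bin centres
    mean_deformation: np.ndarray  # mm per unit path time
    counts: np.ndarray
    direction: str
    bin_width: float

    @property
    def n_bins(self) -> int:
        return int(self.bins.size)


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit of mean deformation vs rMTT."""

    amplitude: float
    mean: float
    sd: float
    rmse: float
    direction: str
    n_bins: int
    converged: bool = True
    message: str = ""

    @property
    def p1(self) -> float:
        return self.mean - self.sd

    @property
    def p2(self) -> float:
        return self.mean + self.sd


def mirror_reflect(volume: np.ndarray, midline_index: float | None = None, axis: int = 0) -> np.ndarray:
    """Left-right flip about the sagittal plane at ``midline_index``.

    The reflection maps index ``i`` to ``2 * midline_index - i``; twice
    the midline must be integral so the reflected sample lands on the
    lattice and the operation is an exact involution.  Indices whose
    mirror falls outside the grid are left unchanged.  The default
    midline is the grid centre ``(n - 1) / 2`` (a full flip).
    """
    arr = np.asarray(volume)
    n = arr.shape[axis]
    if midline_index is None:
        midline_index = (n - 1) / 2.0
    two_m = 2.0 * midline_index
    if abs(two_m - round(two_m)) > 1e-9:
        raise ValueError("2 * midline_index must be integral for a lattice reflection")
    if not (0 <= midline_index <= n - 1):
        raise ValueError(f"midline_index {midline_index} outside grid axis of length {n}")
    src = np.round(two_m).astype(int) - np.arange(n)
    valid = (src >= 0) & (src < n)
    src = np.where(valid, src, np.arange(n))
    return np.take(arr, src, axis=axis)


def compute_rmtt(
    mtt: ScalarVolume,
    lesion_mask: np.ndarray,
    midline_index: float | None = None,
    axis: int = 0,
) -> RMTTMap:
    """rMTT map: lesion MTT divided by the mean contralateral MTT.

    The contralateral region is the mirror reflection of the lesion
    mask; its mean is taken over finite, positive MTT values only.
    """
    lesion_mask = as_binary_mask(lesion_mask, "lesion_mask")
    if lesion_mask.shape != mtt.shape:
        raise ValueError("lesion mask and MTT map must share one grid")
    n = mtt.shape[axis]
    if midline_index is None:
        midline_index = (n - 1) / 2.0
    mirrored = mirror_reflect(lesion_mask, midline_index, axis=axis)
    if not mirrored.any():
        raise ValueError("mirrored lesion region is empty; cannot normalize")
    contra_vals = mtt.data[mirrored]
    ok = np.isfinite(contra_vals) & (contra_vals > 0)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("no finite positive contralateral MTT values")
    contra_mean = float(contra_vals[ok].mean())
    if contra_mean <= 0:
        raise ValueError(f"contralateral mean MTT is non-positive ({contra_mean})")
    values = np.zeros(mtt.shape)
    values[lesion_mask] = mtt.data[lesion_mask] / contra_mean
    return RMTTMap(
        values=values,
        region_mask=lesion_mask,
        contralateral_mean=contra_mean,
        midline_index=float(midline_index),
        axis=axis,
        n_excluded=n_excluded,
    )


def deformation_vs_rmtt(
    rmtt: RMTTMap,
    def_map: DeformationMap,
    direction: str,
    bin_width: float = 0.01,
) -> DeformationPerfusionSamples:
    """Bin rMTT values of one deformation direction; mean speed per bin.

    ``direction`` selects contracting (sign -1) or expanding (sign +1)
    voxels inside both the rMTT region and the lesion mask.  Empty bins
    are dropped.  An empty selection yields an empty sample set.
    """
    if direction not in (CONTRACTION, EXPANSION):
        raise ValueError(f"direction must be {CONTRACTION!r} or {EXPANSION!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if rmtt.values.shape != def_map.magnitude.shape:
        raise ValueError("rMTT map and deformation map must share one grid")
    want = -1 if direction == CONTRACTION else 1
    sel = rmtt.region_mask & def_map.lesion_mask & (def_map.sign == want)
    if not sel.any():
        return DeformationPerfusionSamples(
            bins=np.empty(0),
            mean_deformation=np.empty(0),
            counts=np.empty(0, dtype=int),
            direction=direction,
            bin_width=bin_width,
        )
    r = rmtt.values[sel]
    speed = def_map.speed[sel]
    idx = np.floor(r / bin_width).astype(np.int64)
    uniq, inv = np.unique(idx, return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=speed)
    centres = (uniq + 0.5) * bin_width
    return DeformationPerfusionSamples(
        bins=centres,
        mean_deformation=sums / counts,
        counts=counts.astype(int),
        direction=direction,
        bin_width=bin_width,
    )


def _gaussian(x: np.ndarray, a: float, mu: float, s: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * s**2))


def gaussian_fit(samples: DeformationPerfusionSamples, weighted: bool = False) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to the binned means.

    Initialized at the amplitude maximum and the deformation-weighted
    mean/sd of the bins; with ``weighted=True`` bins are weighted by
    ``sqrt(count)``.  Requires at least three bins.  A fit that fails to
    converge is returned with ``converged=False`` and a diagnostic
    message rather than raised.
    """
    x = np.asarray(samples.bins, dtype=float)
    y = np.asarray(samples.mean_deformation, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 bins for a Gaussian fit, got {x.size}")
    w = y.clip(min=0)
    wsum = w.sum()
    if wsum > 0:
        mu0 = float((w * x).sum() / wsum)
        s0 = float(np.sqrt((w * (x - mu0) ** 2).sum() / wsum))
    else:
        mu0, s0 = float(x.mean()), float(x.std())
    s0 = max(s0, samples.bin_width / 2.0)
    a0 = float(y.max()) if y.max() > 0 else 1.0
    sigma = 1.0 / np.sqrt(samples.counts) if weighted else None
    try:
        popt, _ = curve_fit(
            _gaussian,
            x,
            y,
            p0=(a0, mu0, s0),
            sigma=sigma,
            bounds=((0.0, -np.inf, 1e-12), (np.inf, np.inf, np.inf)),
            maxfev=20000,
        )
        a, mu, s = (float(p) for p in popt)
        resid = y - _gaussian(x, a, mu, s)
        rmse = float(np.sqrt(np.mean(resid**2)))
        return GaussianFit(a, mu, s, rmse, samples.direction, x.size)
    except RuntimeError as exc:  # pragma: no cover - depends on optimizer
        resid = y - _gaussian(x, a0, mu0, s0)
        rmse = float(np.sqrt(np.mean(resid**2)))
        return GaussianFit(
            a0, mu0, s0, rmse, samples.direction, x.size, converged=False, message=str(exc)
        )


def confidence_interval(fit: GaussianFit) -> tuple[float, float]:
    """The [p1, p2] perfusion interval: fitted peak minus/plus one sd, ordered."""
    lo, hi = fit.mean - fit.sd, fit.mean + fit.sd
    return (min(lo, hi), max(lo, hi))
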