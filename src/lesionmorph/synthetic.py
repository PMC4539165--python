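"""Synthetic longitudinal stroke cases with known ground truth.

The generator emulates the imaging structure the analysis needs — not
MRI physics.  Each case holds three timepoints (acute, subacute, final)
of a DWI/T2-like image plus a binary lesion mask, and an MTT perfusion
map per phase.  Lesion components are smoothed ellipsoids whose
semi-axes change between timepoints by a configured signed radial
growth, so the voxels entering (expansion) and leaving (contraction)
the lesion are known exactly by set algebra and serve as the oracle for
the whole downstream pipeline.

The background phantom is symmetric about the grid's central sagittal
plane, so contralateral mirror reflection is exact by construction: the
MTT value mirrored from the lesion lands on clean baseline tissue, and
relative MTT (rMTT) values planted in the expansion / contraction rings
are recovered unchanged by the normalization.  rMTT draws come from
configured Gaussians, one per ring kind, optionally rank-coupled to the
local true displacement magnitude so that the strongest deformation
sits at the distribution's centre (the unimodal deformation-vs-rMTT
relation the analysis fits).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .fields import identity_map, sample_scalar
from .volume import ScalarVolume, save_nifti, save_mask

__all__ = [
    "RmttSpec",
    "LesionComponent",
    "CaseConfig",
    "SyntheticCase",
    "generate_case",
    "apply_known_displacement",
    "PHASE_1",
    "PHASE_2",
]

PHASE_1 = "acute-subacute"
PHASE_2 = "subacute-final"
TIMEPOINTS = ("acute", "subacute", "final")


@dataclass
class RmttSpec:
    """Generating Gaussians for rMTT in the dynamic rings.

    ``mu_contraction``/``mu_expansion`` are the unitless rMTT ratios
    planted in the voxels that leave / enter the lesion during a phase;
    lesion voxels outside the rings draw from the background Gaussian
    (moderate hypoperfusion).  With ``couple_to_growth`` the draws are
    rank-matched to the local true displacement magnitude so that the
    most strongly deforming voxels carry rMTT values nearest the mean.
    """

    mu_contraction: float = 1.5
    sd_contraction: float = 0.15
    mu_expansion: float = 0.8
    sd_expansion: float = 0.15
    background_mu: float = 1.2
    background_sd: float = 0.25
    couple_to_growth: bool = True
    zone_halo_vox: int = 2


@dataclass
class LesionComponent:
    """One ellipsoidal lesion component.

    ``growth`` gives the signed change of each semi-axis (in voxels) for
    the two phases; a scalar entry means isotropic radial change.
    """

    center: tuple[float, ...]
    radius: float
    growth: tuple = (2.0, 1.5)

    def semi_axes(self, ndim: int, timepoint_index: int) -> np.ndarray:
        axes = np.full(ndim, float(self.radius))
        for phase in range(timepoint_index):
            g = self.growth[phase]
            g = np.full(ndim, float(g)) if np.isscalar(g) else np.asarray(g, dtype=float)
            axes = axes + g
        return axes


@dataclass
class CaseConfig:
    """Configuration of one synthetic case (defaults define the study conditions)."""

    grid_shape: tuple[int, ...] = (64, 64)
    voxel_size_mm: tuple[float, ...] = (1.0, 1.0)
    n_components: int = 2
    growth_spec: tuple = ((2.0, 1.5), (-2.0, -1.5))
    rmtt_spec: RmttSpec = field(default_factory=RmttSpec)
    noise_sd: float = 0.02
    seed: int = 0
    components: tuple[LesionComponent, ...] | None = None
    lesion_intensity: float = 0.75
    background_intensity: float = 0.35
    mtt_baseline: float = 4.0  # seconds; normal-tissue mean transit time
    mtt_margin_vox: int = 3  # hypoperfused halo width beyond the lesion
    include_subacute_mtt: bool = True

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if len(self.voxel_size_mm) != len(self.grid_shape):
            raise ValueError("voxel_size_mm must match grid dimensionality")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.components is not None:
            self.components = tuple(self.components)
            if len(self.components) != self.n_components:
                raise ValueError("components length must equal n_components")
        elif len(self.growth_spec) != self.n_components:
            raise ValueError("growth_spec must have one entry per component")

    # -- default component placement: all in the 'affected' hemisphere ----
    def resolved_components(self) -> tuple[LesionComponent, ...]:
        if self.components is not None:
            return self.components
        nx = self.grid_shape[0]
        rest = self.grid_shape[1:]
        radius = max(3.0, min(nx, *rest) / 9.0)
        cx = nx / 4.0
        comps = []
        for k in range(self.n_components):
            frac = (k + 1) / (self.n_components + 1)
            center = (cx,) + tuple(frac * n for n in rest)
            growth = self.growth_spec[k]
            if np.isscalar(growth):
                growth = (growth, growth)
            comps.append(LesionComponent(center=center, radius=radius, growth=tuple(growth)))
        return tuple(comps)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("components"):
            d["components"] = [asdict(c) if not isinstance(c, dict) else c for c in self.components]
        return d


@dataclass
class SyntheticCase:
    """A generated case: images, masks, perfusion maps and ground truth."""

    images: dict[str, ScalarVolume]  # keys: acute, subacute, final
    masks: dict[str, np.ndarray]  # bool arrays, same keys
    mtt: dict[str, ScalarVolume]  # keys: acute and (optionally) subacute
    truth_expansion: dict[str, np.ndarray]  # keyed by phase label
    truth_contraction: dict[str, np.ndarray]
    truth_displacement: dict[str, np.ndarray]  # (ndim, *grid), mm
    config: CaseConfig

    # phase-1 truth under the names most tests use
    @property
    def truth_expansion_mask(self) -> np.ndarray:
        return self.truth_expansion[PHASE_1]

    @property
    def truth_contraction_mask(self) -> np.ndarray:
        return self.truth_contraction[PHASE_1]

    @property
    def spacing(self) -> tuple[float, ...]:
        return self.images["acute"].spacing

    def content_hash(self) -> str:
        """SHA-256 over every generated array, for determinism checks."""
        h = hashlib.sha256()
        for key in TIMEPOINTS:
            h.update(self.images[key].data.tobytes())
            h.update(self.masks[key].tobytes())
        for key in sorted(self.mtt):
            h.update(self.mtt[key].data.tobytes())
        for phase in (PHASE_1, PHASE_2):
            h.update(self.truth_expansion[phase].tobytes())
            h.update(self.truth_contraction[phase].tobytes())
            h.update(self.truth_displacement[phase].tobytes())
        return h.hexdigest()

    def save(self, out_dir) -> None:
        """Write all volumes as NIfTI plus a JSON sidecar of the config."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spacing = self.spacing
        name_map = {"acute": "acute_dwi", "subacute": "subacute_dwi", "final": "final_t2"}
        for tp in TIMEPOINTS:
            save_nifti(self.images[tp], out / f"{name_map[tp]}.nii.gz")
            save_mask(self.masks[tp], spacing, out / f"{name_map[tp]}_mask.nii.gz")
        for phase_key, vol in self.mtt.items():
            save_nifti(vol, out / f"{phase_key}_mtt.nii.gz")
        for phase, tag in ((PHASE_1, "phase1"), (PHASE_2, "phase2")):
            save_mask(self.truth_expansion[phase], spacing, out / f"truth_{tag}_expansion.nii.gz")
            save_mask(self.truth_contraction[phase], spacing, out / f"truth_{tag}_contraction.nii.gz")
            disp = self.truth_displacement[phase]
            for ax in range(disp.shape[0]):
                save_nifti(ScalarVolume(disp[ax], spacing), out / f"truth_{tag}_disp{ax}.nii.gz")
        cfg = self.config.to_dict()
        (out / "case_config.json").write_text(json.dumps(cfg, indent=2, default=float))


# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid: np.ndarray, center, semi_axes) -> np.ndarray:
    q = np.zeros(grid.shape[1:], dtype=float)
    for i, (c, a) in enumerate(zip(center, semi_axes)):
        q += ((grid[i] - c) / a) ** 2
    return q <= 1.0


def _component_displacement(
    grid: np.ndarray, comp: LesionComponent, phase_index: int, spacing
) -> np.ndarray:
    """Radial per-component displacement field for one phase, in mm.

    Linear inside the start shape (zero at the centre, the full growth
    at the boundary), Gaussian falloff outside, so the true field is
    smooth and invertible for the configured growth magnitudes.
    """
    ndim = grid.shape[0]
    axes0 = comp.semi_axes(ndim, phase_index)
    g = comp.growth[phase_index]
    g = np.full(ndim, float(g)) if np.isscalar(g) else np.asarray(g, dtype=float)
    rel = np.stack([(grid[i] - comp.center[i]) / axes0[i] for i in range(ndim)])
    rho = np.sqrt(np.sum(rel**2, axis=0))
    rbar = float(np.mean(axes0))
    falloff = np.where(rho <= 1.0, 1.0, np.exp(-(((rho - 1.0) * rbar) ** 2) / (2.0 * 2.0**2)))
    disp = np.stack([g[i] * rel[i] * falloff * spacing[i] for i in range(ndim)])
    return disp


def _rank_coupled_draws(
    rng: np.random.Generator, mu: float, sd: float, depth: np.ndarray, couple: bool
) -> np.ndarray:
    """Gaussian draws for one ring; optionally rank-matched to deformation depth."""
    n = depth.size
    draws = rng.normal(mu, sd, size=n)
    if not couple or n < 2:
        return draws
    centrality_order = np.argsort(np.abs(draws - mu))  # closest-to-mean first
    depth_order = np.argsort(-depth)  # deepest first
    out = np.empty(n)
    out[depth_order] = draws[centrality_order]
    return out


def generate_case(config: CaseConfig) -> SyntheticCase:
    """Generate one longitudinal case from a :class:`CaseConfig`.

    Raises ``ValueError`` when the configured growth pushes a component
    outside the grid or across the midline, or shrinks it away entirely.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    ndim = len(shape)
    spacing = config.voxel_size_mm
    grid = identity_map(shape)
    comps = config.resolved_components()
    midline = (shape[0] - 1) / 2.0

    # --- lesion masks per timepoint --------------------------------------
    masks: dict[str, np.ndarray] = {}
    for k, tp in enumerate(TIMEPOINTS):
        mask = np.zeros(shape, dtype=bool)
        for comp in comps:
            axes = comp.semi_axes(ndim, k)
            if np.any(axes < 0.5):
                raise ValueError(
                    f"growth_spec shrinks component at {comp.center} below half a voxel"
                )
            lo = np.asarray(comp.center) - axes
            hi = np.asarray(comp.center) + axes
            if np.any(lo < 0) or np.any(hi > np.asarray(shape) - 1):
                raise ValueError("growth_spec pushes a component outside the grid")
            if hi[0] >= midline - config.mtt_margin_vox:
                raise ValueError("component crosses the midline; lesions must stay in one hemisphere")
            mask |= _ellipsoid_mask(grid, comp.center, axes)
        masks[tp] = mask

    # --- ground-truth rings and displacement per phase --------------------
    truth_exp, truth_con, truth_disp = {}, {}, {}
    for p, (a, b) in enumerate(((0, 1), (1, 2))):
        phase = (PHASE_1, PHASE_2)[p]
        start, end = masks[TIMEPOINTS[a]], masks[TIMEPOINTS[b]]
        truth_exp[phase] = end & ~start
        truth_con[phase] = start & ~end
        disp = np.zeros((ndim,) + shape)
        for comp in comps:
            disp += _component_displacement(grid, comp, p, spacing)
        truth_disp[phase] = disp

    # --- images: symmetric head phantom + lesion, smoothed, noisy ---------
    head_center = tuple((n - 1) / 2.0 for n in shape)
    head_axes = tuple(0.47 * n for n in shape)
    head = _ellipsoid_mask(grid, head_center, head_axes)
    images: dict[str, ScalarVolume] = {}
    for tp in TIMEPOINTS:
        img = np.where(head, config.background_intensity, 0.05)
        img = np.where(masks[tp], config.lesion_intensity, img)
        img = ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        images[tp] = ScalarVolume(np.clip(img, 0.0, 1.0), spacing)

    # --- MTT maps per phase ------------------------------------------------
    spec = config.rmtt_spec
    b0 = config.mtt_baseline
    mtt: dict[str, ScalarVolume] = {}
    phase_for = {"acute": PHASE_1, "subacute": PHASE_2}
    for key in ("acute", "subacute"):
        phase = phase_for[key]
        start = masks["acute" if key == "acute" else "subacute"]
        end = masks["subacute" if key == "acute" else "final"]
        lesion_union = start | end
        halo = ndimage.binary_dilation(lesion_union, iterations=config.mtt_margin_vox)
        vals = np.full(shape, b0)
        n_halo = int(halo.sum())
        bg_draws = np.clip(rng.normal(spec.background_mu, spec.background_sd, n_halo), 0.05, None)
        vals[halo] = b0 * bg_draws
        # the designated zones are a band around each moving boundary: the
        # truth ring dilated into the lesion, so the voxels that deform
        # fastest carry the configured perfusion distribution
        for ring, mu, sd in (
            (truth_con[phase], spec.mu_contraction, spec.sd_contraction),
            (truth_exp[phase], spec.mu_expansion, spec.sd_expansion),
        ):
            if not ring.any():
                continue
            zone = ring
            if spec.zone_halo_vox > 0:
                zone = ndimage.binary_dilation(ring, iterations=spec.zone_halo_vox) & (
                    lesion_union | ring
                )
            depth = np.sqrt(np.sum(truth_disp[phase] ** 2, axis=0))[zone]
            draws = _rank_coupled_draws(rng, mu, sd, depth, spec.couple_to_growth)
            vals[zone] = b0 * np.clip(draws, 0.05, None)
        mtt[key] = ScalarVolume(vals, spacing)
    if not config.include_subacute_mtt:
        del mtt["subacute"]

    return SyntheticCase(
        images=images,
        masks=masks,
        mtt=mtt,
        truth_expansion=truth_exp,
        truth_contraction=truth_con,
        truth_displacement=truth_disp,
        config=config,
    )


def apply_known_displacement(volume: ScalarVolume, displacement: np.ndarray) -> ScalarVolume:
    """Resample a volume under a known displacement field (mm).

    Pull-back convention matching the metamorphosis advection step:
    ``out(x) = volume(x - d(x))``.  Used to manufacture ground truth for
    registration-recovery tests.
    """
    displacement = np.asarray(displacement, dtype=float)
    if displacement.shape != (volume.ndim, *volume.shape):
        raise ValueError("displacement shape does not match the volume grid")
    spac = np.asarray(volume.spacing).reshape((-1,) + (1,) * volume.ndim)
    coords = identity_map(volume.shape) - displacement / spac
    return ScalarVolume(sample_scalar(volume.data, coords), volume.spacing)
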