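"""Two-phase per-case analysis and cohort aggregation.

Each case is analysed in up to two evolution phases: acute DWI to
subacute DWI, and subacute DWI to final T2-w.  A phase runs the chain

    metamorphose -> total deformation map -> highly dynamic regions
    -> rMTT map -> binned deformation-vs-rMTT samples -> Gaussian fits

using the phase-start MTT map as the perfusion reference.  Phase 2 is
attempted only when the subacute MTT exists; its absence is recorded
explicitly, never silently.  Cohort summaries report min / max /
mean +- sd of the fitted rMTT peaks and min / max / median of the
volumetric proportions, per phase.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    DeformationMap,
    DynamicRegions,
    threshold_dynamic_regions,
    total_deformation_map,
)
from .metamorphosis import MetamorphosisParams, MetamorphosisPath, metamorphose, normalize_images
from .perfusion import (
    CONTRACTION,
    EXPANSION,
    GaussianFit,
    RMTTMap,
    compute_rmtt,
    confidence_interval,
    deformation_vs_rmtt,
    gaussian_fit,
)
from .synthetic import PHASE_1, PHASE_2, SyntheticCase
from .volume import ScalarVolume, as_binary_mask, load_mask, load_nifti

__all__ = [
    "AnalysisConfig",
    "CaseInputs",
    "PhaseResult",
    "CaseResult",
    "CohortSummary",
    "run_phase",
    "run_case",
    "cohort_summary",
    "export_report",
]

PHASES = (PHASE_1, PHASE_2)


@dataclass
class AnalysisConfig:
    """All knobs of the per-case analysis in one place."""

    metamorphosis: MetamorphosisParams = field(default_factory=MetamorphosisParams)
    threshold_rule: str = "corrected"
    boundary_band_only: bool = False
    bin_width: float = 0.01
    weighted_fit: bool = False
    midline_index: float | None = None
    reflect_axis: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        meta = MetamorphosisParams(**raw.pop("metamorphosis", {}))
        return cls(metamorphosis=meta, **raw)

    def to_dict(self) -> dict:
        return {
            "metamorphosis": vars(self.metamorphosis),
            "threshold_rule": self.threshold_rule,
            "boundary_band_only": self.boundary_band_only,
            "bin_width": self.bin_width,
            "weighted_fit": self.weighted_fit,
            "midline_index": self.midline_index,
            "reflect_axis": self.reflect_axis,
        }


# canonical on-disk filenames inside a case directory
CASE_FILES = {
    "acute_image": "acute_dwi.nii.gz",
    "acute_mask": "acute_dwi_mask.nii.gz",
    "acute_mtt": "acute_mtt.nii.gz",
    "subacute_image": "subacute_dwi.nii.gz",
    "subacute_mask": "subacute_dwi_mask.nii.gz",
    "subacute_mtt": "subacute_mtt.nii.gz",  # optional
    "final_image": "final_t2.nii.gz",
    "final_mask": "final_t2_mask.nii.gz",
}


@dataclass
class CaseInputs:
    """Pre-aligned per-case volumes on one grid."""

    case_id: str
    images: dict[str, ScalarVolume]  # acute, subacute, final
    masks: dict[str, np.ndarray]
    mtt: dict[str, ScalarVolume]  # acute, optionally subacute
    covariate: float | None = None  # e.g. admission NIHSS, for plot ordering

    @classmethod
    def from_synthetic(cls, case: SyntheticCase, case_id: str = "synthetic") -> "CaseInputs":
        return cls(
            case_id=case_id,
            images=dict(case.images),
            masks={k: np.asarray(v, dtype=bool) for k, v in case.masks.items()},
            mtt=dict(case.mtt),
        )

    @classmethod
    def from_directory(cls, path, case_id: str | None = None) -> "CaseInputs":
        p = Path(path)
        images = {
            tp: load_nifti(p / CASE_FILES[f"{tp}_image"]) for tp in ("acute", "subacute", "final")
        }
        masks = {tp: load_mask(p / CASE_FILES[f"{tp}_mask"]) for tp in ("acute", "subacute", "final")}
        mtt = {"acute": load_nifti(p / CASE_FILES["acute_mtt"])}
        sub = p / CASE_FILES["subacute_mtt"]
        if sub.exists():
            mtt["subacute"] = load_nifti(sub)
        return cls(case_id=case_id or p.name, images=images, masks=masks, mtt=mtt)

    def validate(self) -> None:
        ref = self.images["acute"]
        for tp, img in self.images.items():
            if not ref.same_grid(img):
                raise ValueError(f"image {tp!r} is not on the case grid")
        for tp, m in self.masks.items():
            as_binary_mask(m, f"{tp} mask")
            if m.shape != ref.shape:
                raise ValueError(f"mask {tp!r} is not on the case grid")
        for key, vol in self.mtt.items():
            if not ref.same_grid(vol):
                raise ValueError(f"MTT map {key!r} is not on the case grid")


def _stats(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return {"n": 0, "min": None, "max": None, "mean": None, "sd": None}
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std()),
    }


@dataclass
class PhaseResult:
    """Everything the analysis produced for one phase of one case."""

    case_id: str
    phase: str
    path: MetamorphosisPath
    def_map: DeformationMap
    regions: DynamicRegions
    rmtt: RMTTMap
    fits: dict[str, GaussianFit | None]
    fit_errors: dict[str, str]
    rmtt_summary: dict[str, dict]
    normalization: tuple[float, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def proportions(self) -> tuple[float, float]:
        return self.regions.proportions

    def peak(self, direction: str) -> float | None:
        fit = self.fits.get(direction)
        return fit.mean if fit is not None else None

    def interval(self, direction: str) -> tuple[float, float] | None:
        fit = self.fits.get(direction)
        return confidence_interval(fit) if fit is not None else None

    def manifest(self) -> dict:
        """JSON-serializable record of all scalar outputs (hash-stable)."""
        fits = {}
        for d, f in self.fits.items():
            if f is None:
                fits[d] = {"error": self.fit_errors.get(d, "not computable")}
            else:
                fits[d] = {
                    "amplitude": f.amplitude,
                    "mean": f.mean,
                    "sd": f.sd,
                    "rmse": f.rmse,
                    "p1": f.p1,
                    "p2": f.p2,
                    "n_bins": f.n_bins,
                    "converged": f.converged,
                }
        return {
            "case_id": self.case_id,
            "phase": self.phase,
            "converged": self.path.converged,
            "final_energy": self.path.energy_trace[-1] if self.path.energy_trace else None,
            "endpoint_residuals": self.path.endpoint_residuals,
            "thresholds": list(self.regions.thresholds),
            "proportions": list(self.regions.proportions),
            "threshold_rule": self.regions.rule,
            "contralateral_mean": self.rmtt.contralateral_mean,
            "midline_index": self.rmtt.midline_index,
            "fits": fits,
            "rmtt_summary": self.rmtt_summary,
            "normalization": list(self.normalization),
            "warnings": self.warnings,
            "magnitude_sha256": hashlib.sha256(self.def_map.magnitude.tobytes()).hexdigest(),
            "sign_sha256": hashlib.sha256(
                np.ascontiguousarray(self.def_map.sign).tobytes()
            ).hexdigest(),
        }


@dataclass
class CaseResult:
    case_id: str
    phase1: PhaseResult
    phase2: PhaseResult | None
    skip_records: dict[str, str] = field(default_factory=dict)

    def phase_results(self) -> list[PhaseResult]:
        out = [self.phase1]
        if self.phase2 is not None:
            out.append(self.phase2)
        return out


_PHASE_IO = {
    PHASE_1: ("acute", "subacute", "acute"),
    PHASE_2: ("subacute", "final", "subacute"),
}


def run_phase(inputs: CaseInputs, phase: str, config: AnalysisConfig) -> PhaseResult:
    """Run the full single-phase chain for one case.

    The deformation map is computed over the union of the phase-start
    and phase-end lesion masks (so both the contraction and the
    expansion rings are inside the analysis domain), and the perfusion
    reference is the phase-start MTT map.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    inputs.validate()
    start_tp, end_tp, mtt_key = _PHASE_IO[phase]
    if mtt_key not in inputs.mtt:
        raise KeyError(f"case {inputs.case_id!r} lacks the {mtt_key} MTT map required for {phase}")

    source, target = inputs.images[start_tp], inputs.images[end_tp]
    (src_n, tgt_n), norm = normalize_images(source.data, target.data)
    path = metamorphose(
        ScalarVolume(src_n, source.spacing),
        ScalarVolume(tgt_n, target.spacing),
        config.metamorphosis,
    )
    lesion = inputs.masks[start_tp] | inputs.masks[end_tp]
    def_map = total_deformation_map(path, lesion, phase)
    regions = threshold_dynamic_regions(
        def_map, rule=config.threshold_rule, boundary_band_only=config.boundary_band_only
    )
    rmtt = compute_rmtt(
        inputs.mtt[mtt_key], lesion, midline_index=config.midline_index, axis=config.reflect_axis
    )

    fits: dict[str, GaussianFit | None] = {}
    fit_errors: dict[str, str] = {}
    for direction in (CONTRACTION, EXPANSION):
        samples = deformation_vs_rmtt(rmtt, def_map, direction, bin_width=config.bin_width)
        if samples.n_bins < 3:
            fits[direction] = None
            fit_errors[direction] = (
                f"only {samples.n_bins} rMTT bins with {direction} voxels; fit not computable"
            )
            continue
        fits[direction] = gaussian_fit(samples, weighted=config.weighted_fit)

    rmtt_summary = {
        CONTRACTION: _stats(rmtt.values[regions.contracting_mask]),
        EXPANSION: _stats(rmtt.values[regions.expanding_mask]),
    }
    warn = list(def_map.warnings)
    return PhaseResult(
        case_id=inputs.case_id,
        phase=phase,
        path=path,
        def_map=def_map,
        regions=regions,
        rmtt=rmtt,
        fits=fits,
        fit_errors=fit_errors,
        rmtt_summary=rmtt_summary,
        normalization=norm,
        warnings=warn,
    )


def run_case(inputs: CaseInputs, config: AnalysisConfig) -> CaseResult:
    """Phase 1 always; phase 2 only when the subacute MTT map exists."""
    inputs.validate()
    phase1 = run_phase(inputs, PHASE_1, config)
    skip: dict[str, str] = {}
    phase2 = None
    if "subacute" in inputs.mtt:
        phase2 = run_phase(inputs, PHASE_2, config)
    else:
        skip[PHASE_2] = "subacute MTT map not available; phase skipped"
    return CaseResult(case_id=inputs.case_id, phase1=phase1, phase2=phase2, skip_records=skip)


# ---------------------------------------------------------------------------
# cohort aggregation


@dataclass
class CohortSummary:
    """Cohort table: one row per (phase, metric, statistic)."""

    table: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {"rows": self.table.to_dict(orient="records")}

    @classmethod
    def from_json_dict(cls, d: dict) -> "CohortSummary":
        return cls(pd.DataFrame(d["rows"], columns=COHORT_COLUMNS))


COHORT_COLUMNS = ["phase", "metric", "statistic", "value", "n"]


def _metric_rows(phase: str, metric: str, values: list[float], stats: Sequence[str]) -> list[dict]:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    rows = []
    fns = {
        "min": lambda a: float(a.min()),
        "max": lambda a: float(a.max()),
        "mean": lambda a: float(a.mean()),
        "sd": lambda a: float(a.std()),
        "median": lambda a: float(np.median(a)),
    }
    for stat in stats:
        rows.append(
            {
                "phase": phase,
                "metric": metric,
                "statistic": stat,
                "value": fns[stat](v) if v.size else None,
                "n": int(v.size),
            }
        )
    return rows


def cohort_summary(results: Sequence[PhaseResult]) -> CohortSummary:
    """Min/max/mean+-sd of fitted rMTT peaks and min/max/median of proportions.

    A metric undefined for a case (no fit, empty region) is excluded
    from that cell; the per-cell ``n`` records how many cases entered.
    """
    results = list(results)
    if not results:
        raise ValueError("no phase results to summarize")
    rows: list[dict] = []
    for phase in PHASES:
        in_phase = [r for r in results if r.phase == phase]
        if not in_phase:
            continue
        rows += _metric_rows(
            phase,
            "contraction_peak_rmtt",
            [r.peak(CONTRACTION) for r in in_phase],
            ("min", "max", "mean", "sd"),
        )
        rows += _metric_rows(
            phase,
            "expansion_peak_rmtt",
            [r.peak(EXPANSION) for r in in_phase],
            ("min", "max", "mean", "sd"),
        )
        rows += _metric_rows(
            phase,
            "pct_highly_contracting",
            [r.proportions[0] for r in in_phase],
            ("min", "max", "median"),
        )
        rows += _metric_rows(
            phase,
            "pct_highly_expanding",
            [r.proportions[1] for r in in_phase],
            ("min", "max", "median"),
        )
    return CohortSummary(pd.DataFrame(rows, columns=COHORT_COLUMNS))


def export_report(
    summary: CohortSummary,
    results: Sequence[PhaseResult],
    out_dir,
    order_by: dict[str, float] | None = None,
) -> dict[str, str]:
    """Write the cohort CSV/JSON, per-case fit table and interval plots.

    ``order_by`` maps case ids to an ordering covariate (e.g. admission
    stroke severity); absent covariates fall back to the case id.
    Returns the paths of the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    csv_path = out / "cohort_summary.csv"
    summary.table.to_csv(csv_path, index=False)
    files["summary_csv"] = str(csv_path)

    json_path = out / "cohort_summary.json"
    json_path.write_text(json.dumps(summary.to_json_dict(), indent=2))
    files["summary_json"] = str(json_path)

    results = list(results)
    if not results:
        _warnings.warn("no phase results; report contains headers only", stacklevel=2)
        return files

    rows = []
    for r in results:
        row: dict = {"case_id": r.case_id, "phase": r.phase}
        for d in (CONTRACTION, EXPANSION):
            fit = r.fits.get(d)
            row[f"{d}_peak"] = fit.mean if fit else None
            row[f"{d}_p1"] = fit.p1 if fit else None
            row[f"{d}_p2"] = fit.p2 if fit else None
            row[f"{d}_rmse"] = fit.rmse if fit else None
        row["pct_contracting"], row["pct_expanding"] = r.proportions
        rows.append(row)
    cases_path = out / "per_case_fits.csv"
    pd.DataFrame(rows).to_csv(cases_path, index=False)
    files["per_case_csv"] = str(cases_path)

    for phase in PHASES:
        in_phase = [r for r in results if r.phase == phase]
        if in_phase:
            plot_path = out / f"intervals_{phase}.png"
            _interval_plot(in_phase, plot_path, order_by)
            files[f"plot_{phase}"] = str(plot_path)
    return files


def _interval_plot(results: Sequence[PhaseResult], path, order_by) -> None:
    """Paired vertical [p1, p2] bars with a dot at each fitted peak."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    def key(r: PhaseResult):
        if order_by and r.case_id in order_by:
            return (0, order_by[r.case_id])
        return (1, r.case_id)

    ordered = sorted(results, key=key)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(ordered)), 4))
    colors = {CONTRACTION: "tab:blue", EXPANSION: "tab:red"}
    offsets = {CONTRACTION: -0.15, EXPANSION: 0.15}
    for i, r in enumerate(ordered):
        for d in (CONTRACTION, EXPANSION):
            fit = r.fits.get(d)
            if fit is None:
                continue
            x = i + offsets[d]
            ax.plot([x, x], [fit.p1, fit.p2], color=colors[d], lw=2)
            ax.plot([x], [fit.mean], "o", color=colors[d], ms=4)
    ax.set_xticks(range(len(ordered)))
    ax.set_xticklabels([r.case_id for r in ordered], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("rMTT")
    ax.set_title(f"Perfusion intervals of highly dynamic areas ({ordered[0].phase})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
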