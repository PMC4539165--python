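# lesionmorph

Phase-based metamorphosis analysis of ischemic stroke lesion dynamics.

After an ischemic stroke, the diffusion-weighted imaging (DWI) lesion
keeps changing for days to weeks: some areas expand into surrounding
tissue while others recover. `lesionmorph` quantifies that evolution
from longitudinal MRI and relates it to local perfusion. It is aimed at
stroke imaging researchers who have per-case, pre-aligned acute DWI,
subacute DWI and final T2-weighted images with lesion masks, plus a
mean-transit-time (MTT) perfusion map per phase.

## What it computes

**Metamorphosis registration.** A source image `I_0` is morphed into a
target by jointly estimating a smooth velocity field `v_t` (geometric
path) and an intensity path `I_t` (photometric path), minimizing

    U(I, v) = ∫ |v_t|²_V dt + (1/σ²) ∫ | dI_t/dt + ∇I_t · v_t |²_L2 dt

subject to the path fitting every observation exactly. The V-norm is a
Gaussian-kernel (LDDMM-style) norm that enforces deformation
smoothness; `σ` trades deformation against pointwise intensity change.
The accumulated flow `ϕ_t` (with `dϕ_t/dt = v_t(ϕ_t)`, `ϕ_0 = id`) is
kept diffeomorphic (positive Jacobian) throughout.

**Lesion deformation maps.** Per voxel, the total deformation magnitude
is the time-integrated squared speed `Σ_t |v_t(x)|² Δt`, signed by the
projection of the velocity on the outward lesion normal: `+`
(expansion) or `−` (contraction). Highly dynamic areas are voxels whose
speed exceeds a mean ± sd threshold computed within the lesion, and
their volumetric proportions are reported.

**Perfusion relation.** Relative MTT (rMTT) divides each lesion voxel's
MTT by the mean MTT of the mirror-reflected contralateral region
(unitless). For each direction, mean deformation speed is binned per
rMTT value and fit with a Gaussian `a·exp(−(x−μ)²/2s²)`; the peak `μ`
is the perfusion level associated with the fastest deformation and
`[p1, p2] = [μ−s, μ+s]` is its perfusion interval.

Two phases are analysed per case — acute→subacute DWI and
subacute DWI→final T2-w (the latter only when a subacute MTT map
exists) — and cohort summaries aggregate peaks and proportions across
cases.

A synthetic-data module generates longitudinal cases (ellipsoidal
lesion components with configured growth, a symmetric two-hemisphere
phantom, MTT maps with planted rMTT Gaussians in the dynamic zones) so
every stage of the pipeline can be validated against known ground
truth.

## Worked example

```python
from lesionmorph import (AnalysisConfig, CaseConfig, CaseInputs,
                         PHASE_1, generate_case, run_phase,
                         confidence_interval)

case = generate_case(CaseConfig(seed=3))          # 64x64, two components
res = run_phase(CaseInputs.from_synthetic(case, "demo"), PHASE_1,
                AnalysisConfig())

fc = res.fits["contraction"]; fe = res.fits["expansion"]
print(f"contraction peak rMTT {fc.mean:.3f}, interval "
      f"({fc.p1:.3f}, {fc.p2:.3f}), fit RMSE {fc.rmse:.4f}")
print(f"expansion   peak rMTT {fe.mean:.3f}, interval "
      f"({fe.p1:.3f}, {fe.p2:.3f}), fit RMSE {fe.rmse:.4f}")
print("pct lesion highly contracting / expanding:",
      tuple(round(p, 2) for p in res.proportions))
```

prints (machine-exact values may differ in the last digits):

```
contraction peak rMTT 1.524, interval (1.152, 1.896), fit RMSE 0.3575
expansion   peak rMTT 0.739, interval (0.445, 1.033), fit RMSE 0.2811
pct lesion highly contracting / expanding: (31.28, 5.69)
```

The case was generated with contraction-zone rMTT ~ N(1.5, 0.15) and
expansion-zone rMTT ~ N(0.8, 0.15): the fitted peaks recover the
planted means, and the two perfusion intervals are disjoint — the
situation where perfusion clearly differs between recovering and
growing lesion areas.

The same analysis is scriptable from the shell:

```sh
lesionmorph simulate --out case0/ --seed 7
lesionmorph run --cases cases.yaml --out results/
```

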