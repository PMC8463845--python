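# spheroscale

Metabolic scaling analysis of simulated cell-laden spheroids with
correlated fluctuations in mass and metabolic rate.

## The problem

Kleiber's law states that an organism's metabolic rate B scales with its
mass as B ∝ m^δ with δ ≈ 3/4; cultured cells are usually assumed to
scale isometrically (δ = 1). Spheroids and organoids sit in between:
oxygen must diffuse in from the surface, so as aggregates grow their
interior becomes oxygen-limited, metabolism per unit volume drops, and
eventually a nonviable anoxic core appears. Real spheroid populations
also fluctuate — in size and in single-cell oxygen consumption rate
(sOCR) — and almost everything known about their scaling ignores those
fluctuations.

`spheroscale` provides an in-silico pipeline for studying how scaling
exponents emerge from *distributions* rather than averages, and for
identifying the **physiologically relevant size window**: the range of
spheroid sizes that scales nonisometrically (δ ≠ 1) while keeping less
than 10% of its volume below the viability oxygen threshold. It is aimed
at tissue engineers designing statistically meaningful spheroid/organoid
experiments and at quantitative biologists interested in finite-size
scaling of biological distributions.

## The model and the statistics

1. **Populations** — log-normal radii around 17 mean values (31 μm–5 mm,
   Var(R) = q₂⟨R⟩², default q₂ = 0.01) paired with Gaussian sOCR values
   (SD = 20% of the mean); mass m = ω(4/3)πR³.
2. **Oxygen** — per spheroid, the stationary reaction–diffusion problem
   D∇²c = sOCR·ρ_c·c/(k_M+c) with c(R) = c₀ is solved in spherical
   symmetry; the metabolic rate B is the total oxygen consumption
   (equal to the inward surface flux at steady state) and Φ is the
   volume percentage below C_crit = 0.04 mol·m⁻³. A dimensionless
   lookup table (per cell type) makes million-spheroid runs a vectorized
   interpolation, audited against direct solves.
3. **Collapse** — scaling exponents are estimated by collapsing
   distributions from different size classes onto a single scaling
   function:

   * marginal: p(B|⟨m⟩) = B⁻¹F(B/⟨m⟩^δ), exponent δ from the
     distance-based functional f_dis(δ) or the Bhattacharjee–Seno
     residual functional f_res(δ);
   * joint: p(m,B|⟨m⟩) = m⁻¹B⁻¹G(m/⟨m⟩^γ, B/⟨m⟩^δ), exponents (γ, δ)
     from a 3D distance functional g(γ, δ).

   Collapses are validated by a k-sample Anderson–Darling test
   (marginal) or a Henze–Zirkler normality gate plus a MANOVA
   mean-vector test (joint).
4. **Windows & experiments** — consecutive size distributions are grouped
   into collapsing windows, classified isometric/nonisometric and
   viable/nonviable; meta-experiments study the minimum sample number N
   for stable collapses, the effect of variability amplitude on δ, and
   sensitivity to kinetic parameters.

See `docs/methods.md` for the full model description, estimator details
and limitations.

## Worked example

Collapse the 9th–11th stem-cell size distributions (200 spheroids each):

```python
from spheroscale import (stem_cell_params, radius_ladder, build_ladder_populations,
                         DimensionlessTable, solve_population, optimize_delta)

params = stem_cell_params()                    # stem-cell kinetics, sigma_sOCR = 20%
ladder = radius_ladder()                       # 17 mean radii, 31 um ... 5 mm
table = DimensionlessTable(params)             # dimensionless lookup, built once

pops = build_ladder_populations(ladder, params, n_samples=200, q2=0.01,
                                master_seed=1, indices=[9, 10, 11])
sols = [solve_population(p, params, fast=True, table=table) for p in pops]
for s in sols:
    print(f"rung {s.population.spec.index}: <R> = {s.population.spec.mean_radius*1e6:6.0f} um, "
          f"mean B = {s.B.mean():.3e} mol/s, mean Phi = {s.phi.mean():.2f}%")

res = optimize_delta(sols, method="distance")
print(f"delta_hat = {res.delta_hat:.3f}  interval = ({res.delta_interval[0]:.3f}, "
      f"{res.delta_interval[1]:.3f})  AD p = {res.ad_pvalue:.3f}")
```

Output:

```
rung 9: <R> =    394 um, mean B = 2.008e-12 mol/s, mean Phi = 0.00%
rung 10: <R> =    541 um, mean B = 4.702e-12 mol/s, mean Phi = 0.02%
rung 11: <R> =    743 um, mean B = 1.121e-11 mol/s, mean Phi = 4.27%
delta_hat = 0.885  interval = (0.870, 0.895)  AD p = 0.250
```

Reading it: the three size classes are viable (mean Φ well below 10%),
their rescaled B distributions collapse onto one curve at δ ≈ 0.88 —
significantly below isometric scaling, because oxygen limitation is
already bending B(m) at these radii — and the Anderson–Darling test does
not reject a common parent distribution (p is clipped at 0.25 by scipy).
The interval is the 1%-variation band of the functional around its
minimum.

The same operations are available from a CLI:

```bash
spheroscale collapse-marginal --members 9,10,11 --n 200 --seed 1 --out collapse.json
spheroscale windows --mode marginal --seed 1 --out windows.json
spheroscale run --seed 1 --out report/
```

Every command accepts `--config config.yaml` to override the size
ladder, kinetic parameters (per cell type), bin counts, search grids and
decision thresholds; radii in config files are given in μm.

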