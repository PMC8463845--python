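"""Meta-experiments: minimum sample size, variability sweep, sensitivity.

Three studies that exercise the full pipeline:

* :func:`min_n_analysis` — how the collapse functional minimum behaves
  as the number of spheroids per size distribution N grows, and the
  smallest N from which it is stable (the "plateau");
* :func:`variability_sweep` — how the estimated scaling exponents
  change with the amplitude of mass (q2) and metabolic (σsOCR)
  fluctuations, including the zero-variability limit where the
  exponents follow exactly from the three mean (m, B) points;
* :func:`sensitivity_analysis` — robustness of the estimated δ to
  one-at-a-time perturbations of the kinetic and transport parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collapse_joint import JointCollapseResult, optimize_gamma_delta
from .collapse_marginal import CollapseResult, optimize_delta
from .oxygen import DimensionlessTable, solve_population
from .params import KineticParams
from .population import build_ladder_populations

__all__ = [
    "PlateauCurve",
    "SweepResult",
    "min_n_analysis",
    "variability_sweep",
    "sensitivity_analysis",
    "DEFAULT_N_LADDER",
    "DEFAULT_SWEEP_COMBOS",
]

#: default N ladder for the plateau study
DEFAULT_N_LADDER = (25, 50, 100, 200, 400, 1_000, 3_000, 10_000, 30_000, 100_000)

#: default (q2, socr_sd_frac) combinations for the variability sweep:
#: none, intermediate, and the reference study conditions
DEFAULT_SWEEP_COMBOS = ((0.0, 0.0), (0.001, 0.10), (0.01, 0.20))


@dataclass(frozen=True)
class PlateauCurve:
    """Functional minima versus the number of samples per distribution."""

    n_values: tuple[int, ...]
    f_minima: tuple[float, ...]
    plateau_n: int | None
    mode: str
    method: str

    def as_dict(self) -> dict:
        return {
            "n_values": list(self.n_values),
            "f_minima": list(self.f_minima),
            "plateau_n": self.plateau_n,
            "mode": self.mode,
            "method": self.method,
        }


@dataclass(frozen=True)
class SweepResult:
    """Exponent estimates for one (q2, σsOCR) variability combination."""

    q2: float
    socr_sd_frac: float
    delta_hat: float
    delta_interval: tuple[float, float]
    gamma_hat: float
    gamma_interval: tuple[float, float]
    exact: bool = False


def detect_plateau(
    n_values: np.ndarray, minima: np.ndarray, rel_tol: float = 0.10
) -> int | None:
    """Smallest N from which all later minima stay within ``rel_tol``
    (relative) of the final value; None if even the last point alone
    fails (cannot happen) or the band is never entered before the end.
    """
    final = minima[-1]
    if final == 0:
        # degenerate zero-variability runs: minima identically zero
        ok = minima == 0
    else:
        ok = np.abs(minima / final - 1.0) <= rel_tol
    # find the earliest index from which all subsequent values are ok
    for i in range(len(ok)):
        if np.all(ok[i:]):
            return int(n_values[i])
    return None


def min_n_analysis(
    mean_radii: list[float],
    member_indices: list[int],
    params: KineticParams,
    q2: float,
    master_seed: int,
    n_ladder: tuple[int, ...] = DEFAULT_N_LADDER,
    mode: str = "marginal",
    method: str = "distance",
    plateau_rel_tol: float = 0.10,
    table: DimensionlessTable | None = None,
    **collapse_kwargs,
) -> PlateauCurve:
    """Functional minimum versus N for one window of size distributions.

    For each N on the ladder the member populations are regenerated
    with fresh child seeds (derived from ``master_seed`` and N), solved
    through the oxygen model, and collapsed; the functional minimum is
    recorded.  The plateau is the smallest N from which all subsequent
    minima stay within ``plateau_rel_tol`` of the final value.
    """
    if len(n_ladder) < 3:
        raise ValueError("the N ladder needs at least 3 points")
    if sorted(n_ladder) != list(n_ladder):
        raise ValueError("the N ladder must be strictly increasing")
    if table is None:
        table = DimensionlessTable(params)
    minima = []
    for step, n in enumerate(n_ladder):
        pops = build_ladder_populations(
            mean_radii,
            params,
            n_samples=int(n),
            q2=q2,
            master_seed=master_seed + 7919 * (step + 1),
            indices=list(member_indices),
        )
        sols = [solve_population(p, params, fast=True, table=table) for p in pops]
        if mode == "marginal":
            res = optimize_delta(sols, method=method, run_ad_test=False, **collapse_kwargs)
        else:
            res = optimize_gamma_delta(sols, run_tests=False, **collapse_kwargs)
        minima.append(res.f_min if mode == "marginal" else res.g_min)
    n_values = np.asarray(n_ladder, dtype=int)
    minima_arr = np.asarray(minima, dtype=float)
    return PlateauCurve(
        n_values=tuple(int(v) for v in n_values),
        f_minima=tuple(float(v) for v in minima_arr),
        plateau_n=detect_plateau(n_values, minima_arr, plateau_rel_tol),
        mode=mode,
        method=method,
    )


def variability_sweep(
    mean_radii: list[float],
    member_indices: list[int],
    params: KineticParams,
    master_seed: int,
    combos: tuple[tuple[float, float], ...] = DEFAULT_SWEEP_COMBOS,
    n_samples: int = 10_000,
    table: DimensionlessTable | None = None,
    **collapse_kwargs,
) -> list[SweepResult]:
    """Joint-collapse exponents for a set of (q2, σsOCR) combinations.

    The zero-variability combination degenerates to one (⟨m⟩, B(⟨R⟩))
    point per member; the collapse is then the exact power-law solve
    through those points.  Matched seeds across combinations make the
    monotone effect of increasing variability directly comparable.
    """
    if len(combos) == 0:
        raise ValueError("need at least one (q2, socr_sd_frac) combination")
    # the lookup table depends only on the dimensionless kinetics (kappa,
    # C_crit/c0), not on the fluctuation amplitudes, so one table serves
    # every combination
    if table is None:
        table = DimensionlessTable(params)
    results = []
    for q2, sd in combos:
        p = params.with_(socr_sd_frac=sd)
        tab = table
        n = 1 if (q2 == 0.0 and sd == 0.0) else n_samples
        pops = build_ladder_populations(
            mean_radii, p, n_samples=n, q2=q2,
            master_seed=master_seed, indices=list(member_indices),
        )
        sols = [solve_population(pop, p, fast=True, table=tab) for pop in pops]
        res = optimize_gamma_delta(sols, run_tests=False, **collapse_kwargs)
        results.append(
            SweepResult(
                q2=q2,
                socr_sd_frac=sd,
                delta_hat=res.delta_hat,
                delta_interval=res.delta_interval,
                gamma_hat=res.gamma_hat,
                gamma_interval=res.gamma_interval,
                exact=res.exact,
            )
        )
    return results


#: kinetic parameters perturbed one at a time in the sensitivity study
SENSITIVITY_PARAMS = ("socr_mean", "rho_c", "k_M", "D", "c0")


def sensitivity_analysis(
    mean_radii: list[float],
    member_indices: list[int],
    params: KineticParams,
    q2: float,
    master_seed: int,
    perturbation_frac: float = 0.05,
    n_samples: int = 200,
    method: str = "distance",
    **collapse_kwargs,
) -> dict[str, dict[str, float]]:
    """|Δδ̂| under ±``perturbation_frac`` one-at-a-time parameter changes.

    Reruns the marginal collapse on a reference window with each of the
    kinetic/transport parameters perturbed up and down; the same
    population seeds are used throughout so the shift isolates the
    parameter effect.
    """
    if not perturbation_frac >= 0:
        raise ValueError("perturbation_frac must be >= 0")

    # the lookup table depends on the kinetics only through the
    # dimensionless pair (kappa, C_crit/c0); perturbations of sOCR,
    # rho_c and D reuse the baseline table
    tables: dict[tuple[float, float], DimensionlessTable] = {}

    def run(p: KineticParams) -> float:
        key = (p.kappa, p.C_crit / p.c0)
        if key not in tables:
            tables[key] = DimensionlessTable(p)
        pops = build_ladder_populations(
            mean_radii, p, n_samples=n_samples, q2=q2,
            master_seed=master_seed, indices=list(member_indices),
        )
        sols = [
            solve_population(pop, p, fast=True, table=tables[key]) for pop in pops
        ]
        return optimize_delta(
            sols, method=method, run_ad_test=False, **collapse_kwargs
        ).delta_hat

    baseline = run(params)
    out: dict[str, dict[str, float]] = {"baseline": {"delta_hat": baseline}}
    for name in SENSITIVITY_PARAMS:
        row = {}
        for sign, tag in ((1.0, "up"), (-1.0, "down")):
            p = params.with_(**{name: getattr(params, name) * (1 + sign * perturbation_frac)})
            row[f"delta_{tag}"] = run(p)
            row[f"shift_{tag}"] = row[f"delta_{tag}"] - baseline
        out[name] = row
    return out
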