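"""Iterative identification of size windows and physiological relevance.

Size distributions are grouped into "size windows": maximal runs of at
least three consecutive distributions whose (marginal or joint)
distributions collapse onto one scaling function with a common
exponent set.  Starting from the three smallest distributions, a
triplet is collapsed; if the collapse criteria pass (a functional
minimum is found and the validation test clears its threshold), the
next larger distribution is added, until extension fails.  The window
is then closed and the search restarts from the next unassigned
triplet, so every distribution belongs to at most one window.

Each window is classified as

* isometric / nonisometric — whether the 1%-variation interval of δ
  contains 1;
* viable / nonviable — whether every member distribution keeps its
  population summary of the nonviable fraction Φ below a threshold
  (default: mean Φ < 10%);
* physiologically relevant — nonisometric AND viable AND the
  statistical validation passed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collapse_joint import JointCollapseResult, optimize_gamma_delta
from .collapse_marginal import CollapseResult, optimize_delta
from .oxygen import PopulationSolution

__all__ = ["SizeWindowReport", "find_windows", "classify_viability"]

#: default acceptance threshold for the Anderson-Darling p-value
AD_ALPHA = 0.05
#: default acceptance threshold for the joint mean-vector p-value
JOINT_ALPHA = 0.01
#: nonviable-core threshold (% of volume)
VIABILITY_PHI_MAX = 10.0


@dataclass(frozen=True)
class SizeWindowReport:
    """Verdict for one collapsed window of consecutive size distributions."""

    member_indices: tuple[int, ...]
    collapse: CollapseResult | JointCollapseResult
    isometric: bool
    viable: bool
    tests_passed: bool

    @property
    def relevant(self) -> bool:
        return (not self.isometric) and self.viable and self.tests_passed


def classify_viability(
    solutions: list[PopulationSolution],
    phi_max: float = VIABILITY_PHI_MAX,
    rule: str = "mean",
    quantile: float = 0.9,
) -> bool:
    """Window-level viability from the per-spheroid nonviable fractions.

    A window is viable iff every member distribution's population
    summary of Φ is below ``phi_max`` percent.  ``rule="mean"`` uses
    the mean Φ per member (default); ``rule="quantile"`` uses the
    ``quantile``-th quantile, a stricter alternative.
    """
    for sol in solutions:
        phi = np.asarray(sol.phi, dtype=float)
        phi = phi[np.isfinite(phi)]
        if phi.size == 0:
            return False
        summary = float(np.mean(phi)) if rule == "mean" else float(
            np.quantile(phi, quantile)
        )
        if not summary < phi_max:
            return False
    return True


def _collapse_passes(result, mode: str, ad_alpha: float, joint_alpha: float) -> bool:
    if mode == "marginal":
        return result.ad_pvalue is not None and result.ad_pvalue > ad_alpha
    # joint mode: HZ normality gate at 1% on every member, then the
    # mean-vector equality test
    if result.meanvec_pvalue is None or len(result.hz_pvalues) == 0:
        return False
    if any(p <= 0.01 for p in result.hz_pvalues):
        return False
    return result.meanvec_pvalue > joint_alpha


def find_windows(
    solutions: list[PopulationSolution],
    mode: str = "marginal",
    method: str = "distance",
    ad_alpha: float = AD_ALPHA,
    joint_alpha: float = JOINT_ALPHA,
    phi_max: float = VIABILITY_PHI_MAX,
    viability_rule: str = "mean",
    n_bins: int | None = None,
    **collapse_kwargs,
) -> list[SizeWindowReport]:
    """Group solved size distributions into collapsing size windows.

    ``solutions`` must be ordered by increasing mean radius.  Windows
    are grown greedily from the smallest unassigned triplet; extension
    stops when the enlarged window no longer satisfies the collapse
    criteria.  Windows never overlap.
    """
    if mode not in ("marginal", "joint"):
        raise ValueError(f"mode must be 'marginal' or 'joint', got {mode!r}")
    if len(solutions) < 3:
        raise ValueError("need at least 3 size distributions")
    if n_bins is not None:
        collapse_kwargs["n_bins"] = n_bins

    def collapse(members):
        if mode == "marginal":
            return optimize_delta(members, method=method, **collapse_kwargs)
        return optimize_gamma_delta(members, **collapse_kwargs)

    reports: list[SizeWindowReport] = []
    start = 0
    n = len(solutions)
    while start + 3 <= n:
        window = list(range(start, start + 3))
        result = collapse([solutions[i] for i in window])
        if not _collapse_passes(result, mode, ad_alpha, joint_alpha):
            # this triplet does not form a window; slide the start
            start += 1
            continue
        best = result
        while window[-1] + 1 < n:
            trial = window + [window[-1] + 1]
            trial_result = collapse([solutions[i] for i in trial])
            if _collapse_passes(trial_result, mode, ad_alpha, joint_alpha):
                window = trial
                best = trial_result
            else:
                break
        member_sols = [solutions[i] for i in window]
        lo, hi = best.delta_interval
        reports.append(
            SizeWindowReport(
                member_indices=tuple(
                    s.population.spec.index for s in member_sols
                ),
                collapse=best,
                isometric=(lo <= 1.0 <= hi),
                viable=classify_viability(
                    member_sols, phi_max=phi_max, rule=viability_rule
                ),
                tests_passed=True,
            )
        )
        start = window[-1] + 1
    return reports
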