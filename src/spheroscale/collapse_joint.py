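"""Collapse of joint mass–metabolic-rate distributions.

The bivariate density of (m, B) conditioned on ⟨m⟩ is assumed to obey
the generalized finite-size-scaling form

    p(m, B | ⟨m⟩, α, β) = m^(−α) B^(−β) G(m/⟨m⟩^γ, B/⟨m⟩^δ),

with both normalization exponents fixed at one and two scaling
exponents: γ for mass (equal to one when the mass law is self-similar)
and δ for metabolic rate.  With α = β = 1 the invariant surface height
is G = m·B·p(m, B), which does not change under the rescaling — so
each member's surface is estimated once (2D histogram of (log m, log B)
on the member's own ranges) and a candidate (γ, δ) acts as a rigid
translation of the fixed point cloud by (−γ·log10⟨m⟩, −δ·log10⟨m⟩).

The functional g(γ, δ) extends the distance-based method to three
dimensions: summed mean squared nearest-neighbor distance between the
members' (log s, log u, log G) point clouds, all axes standardized by
the pooled range.

Statistical validation of a collapse: a Henze–Zirkler multivariate
normality test per member on the rescaled log coordinates (gate at the
1% level), then a test of equality of the members' bivariate mean
vectors — by default a one-way MANOVA (Wilks' lambda) on the two
rescaled coordinates with member identity as the factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binning import DEFAULT_BINS, log_edges, pairwise_nn_distance
from .collapse_marginal import DegenerateSampleError

__all__ = [
    "JointDensity",
    "JointCollapseResult",
    "as_joint_groups",
    "rescale_joint",
    "g",
    "optimize_gamma_delta",
    "hz_test",
    "meanvec_test",
]

DEFAULT_GAMMA_GRID = (0.8, 1.2, 0.01)
DEFAULT_DELTA_GRID = (0.5, 1.3, 0.01)


@dataclass(frozen=True)
class JointDensity:
    """2D histogram estimate of a rescaled joint (mass, B) density."""

    x_bin_centers: np.ndarray
    y_bin_centers: np.ndarray
    density: np.ndarray
    n_samples: int
    log_points: np.ndarray  # (log10 x, log10 y, log10 G) over nonzero cells


@dataclass(frozen=True)
class JointCollapseResult:
    """Optimal (γ, δ) for one window of joint distributions."""

    gamma_hat: float
    delta_hat: float
    gamma_interval: tuple[float, float]
    delta_interval: tuple[float, float]
    g_min: float
    member_indices: tuple[int, ...]
    hz_pvalues: tuple[float, ...] = ()
    meanvec_pvalue: float | None = None
    multimodal: bool = False
    exact: bool = False

    @property
    def isometric(self) -> bool:
        lo, hi = self.delta_interval
        return lo <= 1.0 <= hi


def as_joint_groups(solutions) -> list[tuple[np.ndarray, np.ndarray, float, int]]:
    """Normalize inputs to (m, B, mean_mass, index) tuples.

    Accepts :class:`~spheroscale.oxygen.PopulationSolution` objects or
    plain ``(m, B, mean_mass[, index])`` tuples.
    """
    groups = []
    for i, s in enumerate(solutions):
        if hasattr(s, "B") and hasattr(s, "mean_mass"):
            idx = getattr(s.population.spec, "index", i + 1)
            groups.append(
                (
                    np.asarray(s.masses, dtype=float),
                    np.asarray(s.B, dtype=float),
                    float(s.mean_mass),
                    idx,
                )
            )
        else:
            m, B, M = s[0], s[1], s[2]
            idx = s[3] if len(s) > 3 else i + 1
            groups.append(
                (np.asarray(m, dtype=float), np.asarray(B, dtype=float), float(M), int(idx))
            )
    return groups


def rescale_joint(
    m_samples: np.ndarray,
    B_samples: np.ndarray,
    mean_mass: float,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    delta: float = 1.0,
    n_bins: int = DEFAULT_BINS,
    x_edges: np.ndarray | None = None,
    y_edges: np.ndarray | None = None,
) -> JointDensity:
    """Rescale one member and histogram the collapsed joint surface.

    Surface points are (s, u, m^α·B^β·p(m, B)) on a 2D log-spaced grid;
    with α = β = 1 the height s·u·p(s, u) is ⟨m⟩-free under perfect
    scaling.
    """
    m = np.asarray(m_samples, dtype=float)
    B = np.asarray(B_samples, dtype=float)
    if m.size == 0 or m.size != B.size:
        raise ValueError("m and B samples must be nonempty and equal-length")
    s = m / mean_mass**gamma
    u = B / mean_mass**delta
    if np.all(s == s[0]) or np.all(u == u[0]):
        raise DegenerateSampleError("all-equal samples: degenerate joint density")
    if x_edges is None:
        x_edges = log_edges(s, n_bins)
    if y_edges is None:
        y_edges = log_edges(u, n_bins)
    counts, _, _ = np.histogram2d(s, u, bins=[x_edges, y_edges])
    dx = np.diff(x_edges)
    dy = np.diff(y_edges)
    dens = counts / (m.size * np.outer(dx, dy))
    xc = np.sqrt(x_edges[:-1] * x_edges[1:])
    yc = np.sqrt(y_edges[:-1] * y_edges[1:])
    # lift to the invariant height G = s^alpha u^beta p(s, u)
    G = dens * np.outer(xc**alpha, yc**beta)
    iz, jz = np.nonzero(G)
    pts = np.column_stack([np.log10(xc[iz]), np.log10(yc[jz]), np.log10(G[iz, jz])])
    return JointDensity(
        x_bin_centers=xc,
        y_bin_centers=yc,
        density=dens,
        n_samples=m.size,
        log_points=pts,
    )


# ---------------------------------------------------------------------------
# fixed clouds and functional
# ---------------------------------------------------------------------------


class _FixedSurfaces:
    """Per-member joint surfaces, estimated once and translated by (γ, δ)."""

    def __init__(self, groups, n_bins: int):
        self.pts = []  # (log10 m, log10 B, log10 G + const) per member
        self.log_M = []
        for m, B, M, _ in groups:
            if np.any(m <= 0) or np.any(B <= 0):
                raise ValueError("masses and rates must be positive for log binning")
            lm = np.log10(m)
            lb = np.log10(B)
            if lm.min() == lm.max() or lb.min() == lb.max():
                raise DegenerateSampleError("all-equal samples: degenerate joint density")
            x_edges = np.linspace(lm.min(), lm.max() + 1e-9 * (lm.max() - lm.min()), n_bins + 1)
            y_edges = np.linspace(lb.min(), lb.max() + 1e-9 * (lb.max() - lb.min()), n_bins + 1)
            counts, _, _ = np.histogram2d(lm, lb, bins=[x_edges, y_edges])
            dx = np.diff(x_edges)
            dy = np.diff(y_edges)
            dens = counts / (m.size * np.outer(dx, dy))
            iz, jz = np.nonzero(dens)
            if iz.size < 4:
                raise DegenerateSampleError(
                    "fewer than 4 nonzero cells in a member distribution"
                )
            xc = 0.5 * (x_edges[:-1] + x_edges[1:])
            yc = 0.5 * (y_edges[:-1] + y_edges[1:])
            self.pts.append(
                np.column_stack([xc[iz], yc[jz], np.log10(dens[iz, jz])])
            )
            self.log_M.append(float(np.log10(M)))

    def clouds(self, gamma: float, delta: float) -> list[np.ndarray]:
        out = []
        for pts, lM in zip(self.pts, self.log_M):
            t = pts.copy()
            t[:, 0] -= gamma * lM
            t[:, 1] -= delta * lM
            out.append(t)
        return out

    def value(self, gamma: float, delta: float) -> float:
        return pairwise_nn_distance(self.clouds(gamma, delta))


def g(gamma: float, delta: float, solutions, n_bins: int = DEFAULT_BINS) -> float:
    """3D distance-based collapse functional at exponents (γ, δ).

    Summed mean squared nearest-neighbor distance between the members'
    (log s, log u, log G) point clouds, standardized by pooled range;
    nonnegative and invariant to member ordering.
    """
    groups = as_joint_groups(solutions)
    if len(groups) < 2:
        raise ValueError("need at least 2 distributions")
    return _FixedSurfaces(groups, n_bins).value(gamma, delta)


def _is_degenerate(groups) -> bool:
    return all(np.all(m == m[0]) and np.all(B == B[0]) for m, B, _, _ in groups)


def optimize_gamma_delta(
    solutions,
    gamma_grid: tuple[float, float, float] = DEFAULT_GAMMA_GRID,
    delta_grid: tuple[float, float, float] = DEFAULT_DELTA_GRID,
    n_bins: int = DEFAULT_BINS,
    min_members: int = 3,
    run_tests: bool = True,
) -> JointCollapseResult:
    """Minimize g(γ, δ) over a 2D grid with local refinement.

    Intervals are the bounding box of the 1%-sublevel set of g around
    its minimum.  Henze–Zirkler p-values per member and the mean-vector
    equality p-value at the optimum are attached when ``run_tests``.
    """
    groups = as_joint_groups(solutions)
    if len(groups) < min_members:
        raise ValueError(f"need at least {min_members} adjacent distributions")
    indices = tuple(grp[3] for grp in groups)

    if _is_degenerate(groups):
        # zero-variability inputs: exact power-law solve through the means
        M = np.array([grp[2] for grp in groups])
        m_pts = np.array([float(grp[0][0]) for grp in groups])
        B_pts = np.array([float(grp[1][0]) for grp in groups])
        gam, _ = np.polyfit(np.log(M), np.log(m_pts), 1)
        dlt, _ = np.polyfit(np.log(M), np.log(B_pts), 1)
        return JointCollapseResult(
            gamma_hat=float(gam),
            delta_hat=float(dlt),
            gamma_interval=(float(gam), float(gam)),
            delta_interval=(float(dlt), float(dlt)),
            g_min=0.0,
            member_indices=indices,
            exact=True,
        )

    surfaces = _FixedSurfaces(groups, n_bins)
    g_lo, g_hi, g_step = gamma_grid
    d_lo, d_hi, d_step = delta_grid
    gammas = np.arange(g_lo, g_hi + g_step / 2, g_step)
    deltas = np.arange(d_lo, d_hi + d_step / 2, d_step)
    surface = np.empty((len(gammas), len(deltas)))
    for i, ga in enumerate(gammas):
        for j, de in enumerate(deltas):
            surface[i, j] = surfaces.value(ga, de)
    i0, j0 = np.unravel_index(np.argmin(surface), surface.shape)
    g_best = surface[i0, j0]

    sub = surface <= 1.01 * g_best
    multimodal = _sublevel_disconnected(sub)

    # 10x-finer local pass around the coarse minimum
    fg = np.arange(
        gammas[max(i0 - 1, 0)],
        gammas[min(i0 + 1, len(gammas) - 1)] + g_step / 20,
        g_step / 10,
    )
    fd = np.arange(
        deltas[max(j0 - 1, 0)],
        deltas[min(j0 + 1, len(deltas) - 1)] + d_step / 20,
        d_step / 10,
    )
    fine = np.empty((len(fg), len(fd)))
    for i, ga in enumerate(fg):
        for j, de in enumerate(fd):
            fine[i, j] = surfaces.value(ga, de)
    fi, fj = np.unravel_index(np.argmin(fine), fine.shape)
    if fine[fi, fj] <= g_best:
        gamma_hat, delta_hat, g_min = float(fg[fi]), float(fd[fj]), float(fine[fi, fj])
    else:
        gamma_hat, delta_hat, g_min = float(gammas[i0]), float(deltas[j0]), float(g_best)

    # 1%-variation bounding box over both passes
    thr = 1.01 * g_min
    ga_in = np.concatenate(
        [
            np.repeat(gammas, len(deltas))[surface.ravel() <= thr],
            np.repeat(fg, len(fd))[fine.ravel() <= thr],
        ]
    )
    de_in = np.concatenate(
        [
            np.tile(deltas, len(gammas))[surface.ravel() <= thr],
            np.tile(fd, len(fg))[fine.ravel() <= thr],
        ]
    )
    gamma_interval = (float(ga_in.min()), float(ga_in.max()))
    delta_interval = (float(de_in.min()), float(de_in.max()))

    hz_ps: tuple[float, ...] = ()
    mv_p = None
    if run_tests:
        log_groups = [
            (np.log10(m / M**gamma_hat), np.log10(B / M**delta_hat))
            for m, B, M, _ in groups
        ]
        hz_ps = tuple(hz_test(x, y) for x, y in log_groups)
        mv_p = meanvec_test(log_groups)

    return JointCollapseResult(
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_interval=gamma_interval,
        delta_interval=delta_interval,
        g_min=g_min,
        member_indices=indices,
        hz_pvalues=hz_ps,
        meanvec_pvalue=mv_p,
        multimodal=multimodal,
    )


def _sublevel_disconnected(mask: np.ndarray) -> bool:
    """True if the 2D boolean sublevel set has >1 four-connected component."""
    from scipy.ndimage import label

    _, n = label(mask)
    return n > 1


# ---------------------------------------------------------------------------
# statistical validation
# ---------------------------------------------------------------------------


def hz_test(x: np.ndarray, y: np.ndarray) -> float:
    """Henze–Zirkler multivariate normality p-value for one member.

    Applied to the (log-rescaled mass, log-rescaled B) coordinates —
    the underlying laws are log-normal-like, which makes normality in
    log space the meaningful gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 20:
        raise ValueError("Henze-Zirkler test needs at least 20 samples")
    data = np.column_stack([x, y])
    if np.linalg.matrix_rank(np.cov(data.T)) < 2:
        raise ValueError("singular covariance: coordinates are collinear")
    import pingouin

    res = pingouin.multivariate_normality(data, alpha=0.01)
    return float(res.pval)


def meanvec_test(log_groups, method: str = "manova") -> float:
    """Equality of bivariate mean vectors across collapsed members.

    ``manova`` (default): one-way MANOVA on the two rescaled log
    coordinates with member identity as the factor; returns the Wilks'
    lambda p-value.  ``anova``: per-coordinate one-way ANOVA with a
    Bonferroni-combined p-value, provided as a cruder alternative.
    Under perfect collapse all members share one mean vector.
    """
    xs, ys, labels = [], [], []
    for gi, (x, y) in enumerate(log_groups):
        xs.append(np.asarray(x, dtype=float))
        ys.append(np.asarray(y, dtype=float))
        labels.append(np.full(len(np.asarray(x)), gi))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lab = np.concatenate(labels)

    if method == "anova":
        from scipy.stats import f_oneway

        px = f_oneway(*[x[lab == k] for k in np.unique(lab)]).pvalue
        py = f_oneway(*[y[lab == k] for k in np.unique(lab)]).pvalue
        return float(min(1.0, 2.0 * min(px, py)))

    import pandas as pd
    from statsmodels.multivariate.manova import MANOVA

    df = pd.DataFrame({"x": x, "y": y, "group": pd.Categorical(lab)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mv = MANOVA.from_formula("x + y ~ group", data=df)
        tab = mv.mv_test().results["group"]["stat"]
    return float(tab.loc["Wilks' lambda", "Pr > F"])
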