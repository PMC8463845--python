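"""Parameter containers for spheroid populations and oxygen kinetics.

All quantities are SI internally: lengths in metres, concentrations in
mol·m⁻³, rates in mol·s⁻¹.  Configuration files may express radii in μm;
they are converted at the boundary (see :mod:`spheroscale.config`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SizeDistributionSpec",
    "KineticParams",
    "radius_ladder",
    "stem_cell_params",
    "hepatocyte_params",
    "sphere_mass",
]

#: density of the aggregate, approximated by that of water (kg·m⁻³)
WATER_DENSITY = 1000.0

#: default second-order moment coefficient: Var(R) = q2·⟨R⟩²  (CV = 10%)
DEFAULT_Q2 = 0.01

#: default fractional SD of the single-cell oxygen consumption rate
DEFAULT_SOCR_SD_FRAC = 0.20

#: default size ladder bounds (m): 17 mean radii from 31 μm to 5 mm
LADDER_R_MIN = 31e-6
LADDER_R_MAX = 5000e-6
LADDER_SIZE = 17


def sphere_mass(radius: float, omega: float = WATER_DENSITY) -> float:
    """Mass (kg) of a homogeneous sphere of ``radius`` (m) and density ``omega``."""
    return omega * (4.0 / 3.0) * math.pi * radius**3


@dataclass(frozen=True)
class SizeDistributionSpec:
    """One log-normal spheroid size distribution.

    Parameters
    ----------
    index
        1-based position on the size ladder.
    mean_radius
        Population mean radius ⟨R⟩ in metres.
    q2
        Second-order moment coefficient; Var(R) = q2·⟨R⟩², so the
        coefficient of variation of R is √q2.
    n_samples
        Number of spheroids N to draw.
    seed
        Seed for this distribution's generator (derived from the run
        master seed; see :func:`spheroscale.population.child_seed`).
    """

    index: int
    mean_radius: float
    q2: float = DEFAULT_Q2
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"index must be >= 1, got {self.index}")
        if not self.mean_radius > 0:
            raise ValueError(f"mean_radius must be > 0, got {self.mean_radius}")
        if self.q2 < 0:
            raise ValueError(f"q2 must be >= 0, got {self.q2}")
        if self.q2 >= 1.0:
            # log-normal moment matching needs CV = sqrt(q2) < 1
            raise ValueError(
                f"q2 = {self.q2} implies a radius CV >= 100%; "
                "log-normal parameterization rejected"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass(frozen=True)
class KineticParams:
    """Transport and uptake parameters of the oxygen sink.

    Attributes
    ----------
    socr_mean
        Mean single-cell oxygen consumption rate, mol·s⁻¹·cell⁻¹.
    socr_sd_frac
        SD of the sOCR as a fraction of its mean (Gaussian spread).
    rho_c
        Cell density inside the aggregate, cells·m⁻³.
    k_M
        Michaelis constant of the uptake kinetics, mol·m⁻³.
    D
        Oxygen diffusivity in the aggregate (taken as in water), m²·s⁻¹.
    c0
        Oxygen concentration at the spheroid surface, mol·m⁻³.
    C_crit
        Viability threshold concentration, mol·m⁻³; tissue below it
        counts toward the nonviable fraction Φ.
    omega
        Aggregate mass density, kg·m⁻³.
    kinetic_law
        ``"michaelis_menten"`` (default) or ``"hill"``; the Hill variant
        replaces c/(k_M+c) by cⁿ/(k_Mⁿ+cⁿ) with exponent ``hill_n``.
    """

    socr_mean: float
    socr_sd_frac: float = DEFAULT_SOCR_SD_FRAC
    rho_c: float = 1.0e14
    k_M: float = 0.04
    D: float = 3.0e-9
    c0: float = 0.2
    C_crit: float = 0.04
    omega: float = WATER_DENSITY
    kinetic_law: str = "michaelis_menten"
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        for name in ("socr_mean", "rho_c", "k_M", "D", "c0", "C_crit", "omega"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.socr_sd_frac < 1.0:
            raise ValueError("socr_sd_frac must lie in [0, 1)")
        if not self.C_crit < self.c0:
            raise ValueError("C_crit must be below the surface concentration c0")
        if self.kinetic_law not in ("michaelis_menten", "hill"):
            raise ValueError(f"unknown kinetic_law {self.kinetic_law!r}")
        if self.kinetic_law == "hill" and not self.hill_n > 0:
            raise ValueError("hill_n must be > 0")

    # -- dimensionless groups -------------------------------------------------

    @property
    def kappa(self) -> float:
        """k_M / c0, the saturation parameter of the dimensionless problem."""
        return self.k_M / self.c0

    def thiele(self, radius: float, socr: float | None = None) -> float:
        """Squared Thiele-type modulus Φ_T = sOCR·ρ_c·R² / (D·c0)."""
        s = self.socr_mean if socr is None else socr
        return s * self.rho_c * radius**2 / (self.D * self.c0)

    def with_(self, **kwargs) -> "KineticParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def radius_ladder(
    r_min: float = LADDER_R_MIN,
    r_max: float = LADDER_R_MAX,
    n: int = LADDER_SIZE,
) -> list[float]:
    """Geometric ladder of ``n`` mean radii (m) from ``r_min`` to ``r_max``.

    Consecutive rungs differ by (r_max/r_min)^(1/(n-1)) ≈ 1.374 for the
    default 17-point ladder between 31 μm and 5 mm.
    """
    if n < 2:
        raise ValueError("ladder needs at least two rungs")
    ratio = (r_max / r_min) ** (1.0 / (n - 1))
    return [r_min * ratio**k for k in range(n)]


def stem_cell_params(**overrides) -> KineticParams:
    """Default stem-cell kinetics.

    The sOCR mean sits in the tens-of-attomoles-per-second-per-cell
    range reported for cultured cells; the effective tissue-level
    Michaelis constant, cell density, diffusivity and boundary
    concentration are literature values for dense aggregates in
    air-equilibrated aqueous medium.
    """
    defaults = dict(socr_mean=9.0e-17)
    defaults.update(overrides)
    return KineticParams(**defaults)


def hepatocyte_params(**overrides) -> KineticParams:
    """Default hepatocyte kinetics: a few-fold higher sOCR than stem cells."""
    defaults = dict(socr_mean=3.2e-16)
    defaults.update(overrides)
    return KineticParams(**defaults)
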