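"""Dynamical models of obligate metabolite cross-feeding.

The system modeled here is a pair of auxotrophic microbial strains, each
unable to synthesize one essential metabolite and engineered (or evolved)
to overproduce and release the metabolite its partner needs.  Live cells of
strain 1 release metabolite B at a per-cell rate and consume a fixed amount
of metabolite A per cell division; strain 2 mirrors this.  The same strain
phenotypes parameterize three settings:

* a single strain in a nutrient-limited chemostat (the assay used to
  measure release per consumption),
* the closed two-strain community (a well-mixed patch with no in/outflow),
* two genotypes competing for one limiting nutrient in a chemostat.

Units follow one convention throughout: metabolite concentrations in µM,
cell densities in cells/ml, per-cell metabolite amounts in fmol, rates in
1/hr.  1 µM corresponds to 1e6 fmol/ml, the only conversion factor needed.

The central closed-form result: once both metabolite pools are supply
limited, both strains and the whole community grow exponentially at the
geometric mean of the two strains' exchange ratios (release rate per cell
divided by consumption per cell birth, units 1/hr), with the strain ratio
set by the square root of the ratio of the cross exchange rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "UM_TO_FMOL_PER_ML",
    "MoserParams",
    "StrainPhenotype",
    "ChemostatConfig",
    "CommunityConfig",
    "ChemostatTrajectory",
    "CommunityTrajectory",
    "CompetitionTrajectory",
    "IntegrationError",
    "moser_rate",
    "community_steady_growth",
    "community_steady_ratio",
    "chemostat_steady_state",
    "simulate_chemostat",
    "simulate_community",
    "simulate_competition",
]

#: 1 µM of metabolite equals this many fmol per ml of culture.
UM_TO_FMOL_PER_ML = 1.0e6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending parameters."""


@dataclass(frozen=True)
class MoserParams:
    """Saturating (Hill-type) growth kinetics b(L) = b_max L^n / (K^n + L^n).

    This generalizes Monod kinetics (n = 1) with a cooperativity exponent n
    describing the sigmoidal shape of growth rate versus nutrient.

    Parameters
    ----------
    b_max : maximal birth rate at saturating nutrient (1/hr).
    K : half-saturation concentration (µM); b(K) = b_max / 2.
    n : cooperativity exponent (dimensionless).
    """

    b_max: float
    K: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if not self.b_max > 0:
            raise ValueError(f"b_max must be > 0, got {self.b_max}")
        if not self.K > 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not self.n > 0:
            raise ValueError(f"n must be > 0, got {self.n}")

    def rate(self, L):
        return moser_rate(L, self)


def moser_rate(L, p: MoserParams):
    """Birth rate (1/hr) at nutrient concentration ``L`` (µM).

    Accepts scalars or arrays; rejects negative concentrations.  The rate is
    0 at L = 0, b_max/2 at L = K, and increases monotonically toward (never
    reaching) b_max.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("nutrient concentration must be non-negative")
    # (L/K)^n form avoids overflow for large K^n
    x = (L / p.K) ** p.n
    out = p.b_max * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StrainPhenotype:
    """Per-cell phenotype of one cross-feeding strain.

    Parameters
    ----------
    release_rate : metabolite released per live cell per hour (fmol/cell/hr).
    consumption_per_birth : partner-supplied metabolite consumed to produce
        one new cell (fmol/cell).
    kinetics : growth kinetics on the consumed metabolite.
    death_rate : per-capita death rate (1/hr); default 0.
    """

    release_rate: float
    consumption_per_birth: float
    kinetics: MoserParams
    death_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.release_rate < 0:
            raise ValueError("release_rate must be >= 0")
        if not self.consumption_per_birth > 0:
            raise ValueError("consumption_per_birth must be > 0")
        if self.death_rate < 0:
            raise ValueError("death_rate must be >= 0")

    @property
    def exchange_ratio(self) -> float:
        """Release rate per consumption amount (1/hr): the strain's benefit
        supply rate per intake benefit."""
        return self.release_rate / self.consumption_per_birth

    def with_release_fold(self, fold: float) -> "StrainPhenotype":
        """A copy with the release rate (hence exchange ratio) scaled by ``fold``."""
        if fold < 0:
            raise ValueError("fold must be >= 0")
        return replace(self, release_rate=self.release_rate * fold)


@dataclass(frozen=True)
class ChemostatConfig:
    """Continuous-culture configuration for a single nutrient-limited strain.

    ``dilution_rate`` is flow rate / culture volume (1/hr); for a culture
    run at doubling time T it equals ln2/T.  ``inflow_conc`` is the limiting
    nutrient concentration in the feed (µM).
    """

    dilution_rate: float
    inflow_conc: float
    inoculum_live: float = 1.0e6
    inoculum_dead: float = 0.0
    initial_nutrient: float | None = None  # defaults to inflow_conc
    initial_product: float = 0.0

    def __post_init__(self) -> None:
        if not self.dilution_rate > 0:
            raise ValueError("dilution_rate must be > 0")
        if not self.inflow_conc > 0:
            raise ValueError("inflow_conc must be > 0")
        if self.inoculum_live < 0 or self.inoculum_dead < 0:
            raise ValueError("inocula must be >= 0")
        if self.initial_product < 0:
            raise ValueError("initial_product must be >= 0")

    @classmethod
    def from_doubling_time(cls, doubling_time: float, **kwargs) -> "ChemostatConfig":
        if not doubling_time > 0:
            raise ValueError("doubling_time must be > 0")
        return cls(dilution_rate=np.log(2) / doubling_time, **kwargs)

    @property
    def nutrient0(self) -> float:
        return self.inflow_conc if self.initial_nutrient is None else self.initial_nutrient


@dataclass(frozen=True)
class CommunityConfig:
    """A closed, well-mixed two-strain community.

    ``phenotype_1`` consumes metabolite A and releases B; ``phenotype_2``
    consumes B and releases A.  Abundances are cells/ml, pools in µM.
    """

    phenotype_1: StrainPhenotype
    phenotype_2: StrainPhenotype
    n1_0: float = 1.0e5
    n2_0: float = 1.0e5
    pool_a_0: float = 0.0
    pool_b_0: float = 0.0

    def __post_init__(self) -> None:
        if self.n1_0 < 0 or self.n2_0 < 0:
            raise ValueError("initial abundances must be >= 0")
        if self.pool_a_0 < 0 or self.pool_b_0 < 0:
            raise ValueError("initial pools must be >= 0")


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("time grid must be 1-D with at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


@dataclass(frozen=True)
class ChemostatTrajectory:
    """Time courses of live/dead densities, residual nutrient and released
    product in a single-strain chemostat."""

    times: np.ndarray
    live: np.ndarray
    dead: np.ndarray
    nutrient: np.ndarray
    product: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times,
                "live_per_ml": self.live,
                "dead_per_ml": self.dead,
                "nutrient_uM": self.nutrient,
                "product_uM": self.product,
            }
        )


@dataclass(frozen=True)
class CommunityTrajectory:
    """Time courses of both strains' abundances and the two metabolite pools."""

    times: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    pool_a: np.ndarray
    pool_b: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.n1 + self.n2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times,
                "n1_per_ml": self.n1,
                "n2_per_ml": self.n2,
                "pool_a_uM": self.pool_a,
                "pool_b_uM": self.pool_b,
            }
        )


@dataclass(frozen=True)
class CompetitionTrajectory:
    """Two genotypes sharing one limiting nutrient under dilution."""

    times: np.ndarray
    live_a: np.ndarray
    live_b: np.ndarray
    nutrient: np.ndarray

    @property
    def frequency_a(self) -> np.ndarray:
        tot = self.live_a + self.live_b
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.live_a / tot, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times,
                "live_a_per_ml": self.live_a,
                "live_b_per_ml": self.live_b,
                "nutrient_uM": self.nutrient,
            }
        )


# ---------------------------------------------------------------------------
# Closed-form steady-state theory
# ---------------------------------------------------------------------------

def community_steady_growth(phen1: StrainPhenotype, phen2: StrainPhenotype) -> float:
    """Steady-state exponential growth rate (1/hr) of the two-strain community.

    Once both shared metabolite pools are supply limited, each strain's
    growth is paced by its partner's release, giving the linear system
    dN1/dt = (r2/c1) N2, dN2/dt = (r1/c2) N1 whose dominant eigenvalue is
    sqrt((r1/c1)(r2/c2)) — the geometric mean of the two strains' exchange
    ratios.  Symmetric in its arguments.
    """
    return float(np.sqrt(phen1.exchange_ratio * phen2.exchange_ratio))


def community_steady_ratio(phen1: StrainPhenotype, phen2: StrainPhenotype) -> float:
    """Steady-state abundance ratio N1/N2 of the two strains.

    The dominant eigenvector of the same linear system gives
    N1/N2 = sqrt((r2/c1)/(r1/c2)); swapping the strains inverts it.
    """
    supply_1 = phen2.release_rate / phen1.consumption_per_birth
    supply_2 = phen1.release_rate / phen2.consumption_per_birth
    return float(np.sqrt(supply_1 / supply_2))


def chemostat_steady_state(cfg: ChemostatConfig, phen: StrainPhenotype) -> dict:
    """Analytic steady state of the single-strain chemostat.

    At steady state the net growth rate equals the dilution rate, so the
    birth rate satisfies b(L_ss) = dil + death.  Nutrient mass balance then
    fixes the live density, and product balance the released-metabolite
    concentration.  Returns a dict with keys ``nutrient_uM``, ``live_per_ml``,
    ``dead_per_ml``, ``product_uM``.  Raises ValueError when the required
    birth rate exceeds b_max (washout: no positive steady state exists).
    """
    dil, k = cfg.dilution_rate, phen.kinetics
    b_req = dil + phen.death_rate
    if b_req >= k.b_max:
        raise ValueError(
            f"washout: required birth rate {b_req:.4g}/hr >= b_max {k.b_max:.4g}/hr"
        )
    L_ss = k.K * (b_req / (k.b_max - b_req)) ** (1.0 / k.n)
    if L_ss >= cfg.inflow_conc:
        raise ValueError("washout: residual nutrient would exceed the feed concentration")
    n_ss = dil * (cfg.inflow_conc - L_ss) * UM_TO_FMOL_PER_ML / (
        phen.consumption_per_birth * b_req
    )
    d_ss = phen.death_rate * n_ss / dil
    h_ss = phen.release_rate * n_ss / (dil * UM_TO_FMOL_PER_ML)
    return {
        "nutrient_uM": L_ss,
        "live_per_ml": n_ss,
        "dead_per_ml": d_ss,
        "product_uM": h_ss,
    }


# ---------------------------------------------------------------------------
# ODE simulations
# ---------------------------------------------------------------------------

_RTOL = 1e-8
_ATOL = 1e-10


def _solve(rhs, y0, t, context: str):
    sol = solve_ivp(
        rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA", rtol=_RTOL, atol=_ATOL
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed for {context}: {sol.message}")
    # metabolite pools may overshoot 0 by ~atol; clip after the fact
    return np.clip(sol.y, 0.0, None)


def simulate_chemostat(
    cfg: ChemostatConfig, phen: StrainPhenotype, t_grid: Sequence[float]
) -> ChemostatTrajectory:
    """Integrate the single-strain chemostat.

    dN/dt = (b(L) − d − dil) N           live cells
    dD/dt = d N − dil D                  dead cells
    dL/dt = dil (L0 − L) − c b(L) N / u  limiting nutrient (µM)
    dH/dt = r N / u − dil H              released product (µM)

    with u = 1e6 fmol/ml per µM.  The time grid must start at 0 and be
    strictly increasing.
    """
    t = _check_times(t_grid)
    if t[0] != 0:
        raise ValueError("t_grid must start at 0")
    dil, d = cfg.dilution_rate, phen.death_rate
    c, r, kin = phen.consumption_per_birth, phen.release_rate, phen.kinetics

    def rhs(_t, y):
        N, D, L, H = y
        b = moser_rate(max(L, 0.0), kin)
        return [
            (b - d - dil) * N,
            d * N - dil * D,
            dil * (cfg.inflow_conc - L) - c * b * N / UM_TO_FMOL_PER_ML,
            r * N / UM_TO_FMOL_PER_ML - dil * H,
        ]

    y0 = [cfg.inoculum_live, cfg.inoculum_dead, cfg.nutrient0, cfg.initial_product]
    try:
        y = _solve(rhs, y0, t, f"chemostat(cfg={cfg}, phen={phen})")
    except IntegrationError:
        raise
    return ChemostatTrajectory(t, y[0], y[1], y[2], y[3])


def simulate_community(
    cfg: CommunityConfig, t_grid: Sequence[float]
) -> CommunityTrajectory:
    """Integrate the closed two-strain community.

    Strain 1 grows on pool A (released by strain 2) and releases into pool
    B; strain 2 mirrors.  No inflow or outflow; pools in µM:

    dN1/dt = (b1(A) − d1) N1
    dN2/dt = (b2(B) − d2) N2
    dA/dt  = r2 N2 / u − c1 b1(A) N1 / u
    dB/dt  = r1 N1 / u − c2 b2(B) N2 / u
    """
    t = _check_times(t_grid)
    p1, p2 = cfg.phenotype_1, cfg.phenotype_2

    def rhs(_t, y):
        N1, N2, A, B = y
        b1 = moser_rate(max(A, 0.0), p1.kinetics)
        b2 = moser_rate(max(B, 0.0), p2.kinetics)
        return [
            (b1 - p1.death_rate) * N1,
            (b2 - p2.death_rate) * N2,
            (p2.release_rate * N2 - p1.consumption_per_birth * b1 * N1)
            / UM_TO_FMOL_PER_ML,
            (p1.release_rate * N1 - p2.consumption_per_birth * b2 * N2)
            / UM_TO_FMOL_PER_ML,
        ]

    y0 = [cfg.n1_0, cfg.n2_0, cfg.pool_a_0, cfg.pool_b_0]
    y = _solve(rhs, y0, t, f"community(cfg={cfg})")
    return CommunityTrajectory(t, y[0], y[1], y[2], y[3])


def simulate_competition(
    cfg: ChemostatConfig,
    phen_a: StrainPhenotype,
    phen_b: StrainPhenotype,
    t_grid: Sequence[float],
    inoculum_b: float | None = None,
) -> CompetitionTrajectory:
    """Two genotypes competing for one limiting nutrient in a chemostat.

    ``cfg.inoculum_live`` seeds genotype A; genotype B starts at
    ``inoculum_b`` (defaults to the same density).  After transients the
    genotype with the higher birth rate at the common residual nutrient
    rises monotonically in frequency.
    """
    t = _check_times(t_grid)
    if t[0] != 0:
        raise ValueError("t_grid must start at 0")
    nb0 = cfg.inoculum_live if inoculum_b is None else inoculum_b
    if nb0 < 0:
        raise ValueError("inoculum_b must be >= 0")
    dil = cfg.dilution_rate

    def rhs(_t, y):
        NA, NB, L = y
        Lc = max(L, 0.0)
        ba = moser_rate(Lc, phen_a.kinetics)
        bb = moser_rate(Lc, phen_b.kinetics)
        uptake = (
            phen_a.consumption_per_birth * ba * NA
            + phen_b.consumption_per_birth * bb * NB
        ) / UM_TO_FMOL_PER_ML
        return [
            (ba - phen_a.death_rate - dil) * NA,
            (bb - phen_b.death_rate - dil) * NB,
            dil * (cfg.inflow_conc - L) - uptake,
        ]

    y0 = [cfg.inoculum_live, nb0, cfg.nutrient0]
    y = _solve(rhs, y0, t, f"competition(cfg={cfg})")
    return CompetitionTrajectory(t, y[0], y[1], y[2])
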