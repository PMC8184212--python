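"""Synthetic assay data with known ground truth.

Every table the estimators consume can be generated here: exponential
fluorescence growth curves with a lag, chemostat time courses of live/dead
densities and released metabolite, two-strain community abundance
trajectories, bead-spiked cytometry event counts, and linear bioassay
standard curves.  Each generator is deterministic given its seed and
returns the observable table together with a flat "truth" dict recording
the generating parameters — round-trip tests read truth only from that
record.

Noise model: lognormal multiplicative noise (coefficient of variation
``multiplicative_cv``) for intensities, densities and concentrations;
Poisson noise for cytometry event counts.

The default phenotypes describe the two engineered yeast strains of a
synthetic obligate mutualism: the lysine-requiring, hypoxanthine-releasing
strain and its hypoxanthine-requiring, lysine-releasing partner.  The
ancestor's exchange ratio is 0.10/hr (matching the ~0.1/hr growth rate of
the ancestral community) and consuming 3 fmol of lysine per cell birth
(21 µM of feed lysine supports 7e6 cells/ml); the characteristic mutant
releases 1.6-fold more product per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import CytometrySample
from .model import (
    ChemostatConfig,
    CommunityConfig,
    MoserParams,
    StrainPhenotype,
    chemostat_steady_state,
    community_steady_growth,
    community_steady_ratio,
    simulate_chemostat,
    simulate_community,
)

__all__ = [
    "NoiseSpec",
    "ancestor_phenotype",
    "mutant_phenotype",
    "partner_phenotype",
    "default_chemostat_config",
    "default_community_config",
    "gen_microscopy_series",
    "gen_chemostat_series",
    "gen_community_series",
    "gen_cytometry_events",
    "gen_bioassay_curve",
]

#: release fold-change of the characteristic partner-serving mutant
MUTANT_RELEASE_FOLD = 1.6


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise settings for the generators."""

    multiplicative_cv: float = 0.0
    count_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_cv < 0:
            raise ValueError("multiplicative_cv must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1 + cv**2))
    # mean-1 lognormal so noise is unbiased on the natural scale
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Default study phenotypes and configurations
# ---------------------------------------------------------------------------

def ancestor_phenotype() -> StrainPhenotype:
    """Ancestral focal strain: exchange ratio 0.10/hr (release 0.3 fmol/cell/hr,
    consumption 3 fmol/cell), high-affinity saturating kinetics."""
    return StrainPhenotype(
        release_rate=0.3,
        consumption_per_birth=3.0,
        kinetics=MoserParams(b_max=0.44, K=0.2, n=2.0),
        death_rate=0.0,
    )


def mutant_phenotype() -> StrainPhenotype:
    """Partner-serving mutant: ancestor with 1.6-fold higher release rate."""
    return ancestor_phenotype().with_release_fold(MUTANT_RELEASE_FOLD)


def partner_phenotype() -> StrainPhenotype:
    """Partner strain: symmetric defaults with its own exchange ratio 0.10/hr."""
    return StrainPhenotype(
        release_rate=0.3,
        consumption_per_birth=3.0,
        kinetics=MoserParams(b_max=0.44, K=0.2, n=2.0),
        death_rate=0.0,
    )


def default_chemostat_config(doubling_time: float = 6.0) -> ChemostatConfig:
    """Nutrient-limited chemostat as used for exchange-ratio assays:
    20 µM feed nutrient, inoculated near the expected steady-state density."""
    return ChemostatConfig.from_doubling_time(
        doubling_time, inflow_conc=20.0, inoculum_live=5.0e6, initial_nutrient=1.0
    )


def default_community_config(
    phen1: StrainPhenotype | None = None, phen2: StrainPhenotype | None = None
) -> CommunityConfig:
    """Closed two-strain community patch seeded 1:1 at low density."""
    return CommunityConfig(
        phenotype_1=phen1 or ancestor_phenotype(),
        phenotype_2=phen2 or partner_phenotype(),
        n1_0=1.0e5,
        n2_0=1.0e5,
        pool_a_0=0.5,
        pool_b_0=0.5,
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_microscopy_series(
    rate: float = 0.44,
    lag: float = 2.0,
    n_points: int = 12,
    dt: float = 2.0,
    noise: NoiseSpec = NoiseSpec(),
    baseline: float = 100.0,
    series_id: str = "s1",
) -> tuple[pd.DataFrame, dict]:
    """Fluorescence-intensity growth curve: flat baseline during the lag,
    then exponential growth at ``rate`` (1/hr), with multiplicative noise.

    Defaults emulate imaging every 2 hr for ~24 hr of a culture growing at
    its saturated rate.  Note the downstream max-window estimator carries
    an upward bias of roughly the window-slope noise (about 1.4·cv/(dt·√5)
    for 4-point windows), so recovery accuracy is relative, not absolute:
    slower growth at the same noise level is recovered with larger relative
    bias.  Returns a (series_id, time_hr, value) table and a truth record
    carrying the generating rate.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(n_points) * dt
    clean = baseline * np.exp(rate * np.clip(t - lag, 0.0, None))
    obs = clean * _lognormal_factors(noise.rng(), noise.multiplicative_cv, n_points)
    table = pd.DataFrame({"series_id": series_id, "time_hr": t, "value": obs})
    truth = {"rate_per_hr": rate, "lag_hr": lag, "baseline": baseline, "cv": noise.multiplicative_cv, "seed": noise.seed}
    return table, truth


def gen_chemostat_series(
    phen: StrainPhenotype | None = None,
    cfg: ChemostatConfig | None = None,
    times: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Chemostat time course (live/dead densities, residual nutrient,
    released product) with observational noise, plus analytic truth.

    Truth carries the generating exchange ratio r/c and the analytic steady
    states, so estimator round-trips never re-derive them from the table.
    """
    phen = phen or ancestor_phenotype()
    cfg = cfg or default_chemostat_config()
    t = np.asarray(times if times is not None else np.arange(0.0, 120.1, 2.0), float)
    traj = simulate_chemostat(cfg, phen, t)
    frame = traj.to_frame()
    rng = noise.rng()
    for col in ("live_per_ml", "dead_per_ml", "nutrient_uM", "product_uM"):
        frame[col] = frame[col].to_numpy() * _lognormal_factors(
            rng, noise.multiplicative_cv, len(frame)
        )
    ss = chemostat_steady_state(cfg, phen)
    truth = {
        "exchange_ratio_per_hr": phen.exchange_ratio,
        "release_rate_fmol_per_cell_hr": phen.release_rate,
        "consumption_per_birth_fmol": phen.consumption_per_birth,
        "dilution_rate_per_hr": cfg.dilution_rate,
        "inflow_uM": cfg.inflow_conc,
        "live_ss_per_ml": ss["live_per_ml"],
        "nutrient_ss_uM": ss["nutrient_uM"],
        "product_ss_uM": ss["product_uM"],
        "cv": noise.multiplicative_cv,
        "seed": noise.seed,
    }
    return frame, truth


def gen_community_series(
    cfg: CommunityConfig | None = None,
    times: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Two-strain community abundance trajectory with observational noise.

    Emulates periodic absolute-abundance measurements of a growing
    community patch: an initial lag while the shared metabolite pools
    equilibrate, then steady exponential growth at the geometric mean of
    the two exchange ratios.
    """
    cfg = cfg or default_community_config()
    # default cadence matches periodic cytometry sampling of a growing patch
    t = np.asarray(times if times is not None else np.arange(0.0, 72.1, 8.0), float)
    traj = simulate_community(cfg, t)
    frame = traj.to_frame()
    rng = noise.rng()
    for col in ("n1_per_ml", "n2_per_ml"):
        frame[col] = frame[col].to_numpy() * _lognormal_factors(
            rng, noise.multiplicative_cv, len(frame)
        )
    truth = {
        "steady_growth_per_hr": community_steady_growth(cfg.phenotype_1, cfg.phenotype_2),
        "steady_ratio_n1_n2": community_steady_ratio(cfg.phenotype_1, cfg.phenotype_2),
        "exchange_ratio_1_per_hr": cfg.phenotype_1.exchange_ratio,
        "exchange_ratio_2_per_hr": cfg.phenotype_2.exchange_ratio,
        "cv": noise.multiplicative_cv,
        "seed": noise.seed,
    }
    return frame, truth


def gen_cytometry_events(
    true_live: float,
    true_dead: float,
    bead_stock_density: float = 1.0e6,
    bead_volume: float = 0.05,
    sample_volume: float = 1.0,
    acquisition_fraction: float = 0.01,
    seed: int = 0,
) -> tuple[CytometrySample, dict]:
    """Poisson-sampled cytometry event counts for known cell densities.

    The instrument acquires ``acquisition_fraction`` of the bead-spiked
    sample; cells and beads are counted with Poisson statistics.  The
    acquisition fraction cancels in the density calculation, so the
    bead-ratio estimator is unbiased.
    """
    if true_live < 0 or true_dead < 0:
        raise ValueError("densities must be >= 0")
    if not 0 < acquisition_fraction <= 1:
        raise ValueError("acquisition_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    acquired_ml = sample_volume * acquisition_fraction
    mean_live = true_live * acquired_ml
    mean_dead = true_dead * acquired_ml
    mean_beads = bead_stock_density * bead_volume * acquisition_fraction
    sample = CytometrySample(
        fluorescent_cell_events=int(rng.poisson(mean_live)),
        nonfluorescent_cell_events=int(rng.poisson(mean_dead)),
        bead_events=int(rng.poisson(mean_beads)),
        bead_stock_density=bead_stock_density,
        bead_volume=bead_volume,
        sample_volume=sample_volume,
    )
    truth = {
        "live_per_ml": true_live,
        "dead_per_ml": true_dead,
        "expected_bead_events": mean_beads,
        "seed": seed,
    }
    return sample, truth


def gen_bioassay_curve(
    slope: float = 0.02,
    intercept: float = 0.05,
    concentrations: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 40.0),
    noise: NoiseSpec = NoiseSpec(),
    spiked: Sequence[float] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Linear yield-bioassay standard curve plus optional spiked samples.

    Turbidity = intercept + slope·concentration, with multiplicative noise.
    Returns (standard-curve table, spiked-sample table, truth).
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    conc = np.asarray(concentrations, float)
    rng = noise.rng()
    turb = (intercept + slope * conc) * _lognormal_factors(
        rng, noise.multiplicative_cv, len(conc)
    )
    curve_table = pd.DataFrame({"conc_uM": conc, "turbidity": turb})
    spiked = np.asarray(spiked, float)
    spiked_turb = (intercept + slope * spiked) * _lognormal_factors(
        rng, noise.multiplicative_cv, len(spiked)
    )
    sample_table = pd.DataFrame({"true_conc_uM": spiked, "turbidity": spiked_turb})
    truth = {
        "slope_od_per_uM": slope,
        "intercept_od": intercept,
        "cv": noise.multiplicative_cv,
        "seed": noise.seed,
    }
    return curve_table, sample_table, truth
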