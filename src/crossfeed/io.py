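"""File I/O: CSV table schemas and YAML configuration.

All tables are plain comma-separated UTF-8 files with a header row, '.'
decimal separators and times in hours.  Schema violations raise
:class:`SchemaError` naming the missing column.  Configuration files are
flat YAML key-value mappings whose keys carry units
(e.g. ``release_rate_fmol_per_cell_hr``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .model import ChemostatConfig, CommunityConfig, MoserParams, StrainPhenotype

__all__ = [
    "SchemaError",
    "TIMESERIES_COLUMNS",
    "CHEMOSTAT_COLUMNS",
    "COMMUNITY_COLUMNS",
    "CYTOMETRY_COLUMNS",
    "STANDARD_CURVE_COLUMNS",
    "read_table",
    "read_timeseries",
    "read_chemostat",
    "read_community",
    "read_cytometry",
    "read_standard_curve",
    "write_table",
    "phenotype_to_dict",
    "phenotype_from_dict",
    "chemostat_config_to_dict",
    "chemostat_config_from_dict",
    "load_yaml",
    "dump_yaml",
]


class SchemaError(ValueError):
    """A table is missing required columns or is empty."""


TIMESERIES_COLUMNS = ("series_id", "time_hr", "value")
CHEMOSTAT_COLUMNS = ("time_hr", "live_per_ml", "dead_per_ml", "nutrient_uM", "product_uM")
COMMUNITY_COLUMNS = ("time_hr", "n1_per_ml", "n2_per_ml")
CYTOMETRY_COLUMNS = ("sample_id", "fluor_events", "nonfluor_events", "bead_events")
STANDARD_CURVE_COLUMNS = ("conc_uM", "turbidity")


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a CSV and check its schema; empty tables and missing columns
    produce explicit errors naming the file and column."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(expected {', '.join(required_columns)})"
        )
    if len(df) == 0:
        raise SchemaError(f"{path}: table has a header but no rows")
    return df


def read_timeseries(path) -> pd.DataFrame:
    return read_table(path, TIMESERIES_COLUMNS)


def read_chemostat(path) -> pd.DataFrame:
    return read_table(path, CHEMOSTAT_COLUMNS)


def read_community(path) -> pd.DataFrame:
    return read_table(path, COMMUNITY_COLUMNS)


def read_cytometry(path) -> pd.DataFrame:
    return read_table(path, CYTOMETRY_COLUMNS)


def read_standard_curve(path) -> pd.DataFrame:
    return read_table(path, STANDARD_CURVE_COLUMNS)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# YAML configuration with unit-suffixed keys
# ---------------------------------------------------------------------------

def phenotype_to_dict(p: StrainPhenotype) -> dict:
    return {
        "release_rate_fmol_per_cell_hr": p.release_rate,
        "consumption_per_birth_fmol_per_cell": p.consumption_per_birth,
        "b_max_per_hr": p.kinetics.b_max,
        "half_saturation_uM": p.kinetics.K,
        "cooperativity_n": p.kinetics.n,
        "death_rate_per_hr": p.death_rate,
    }


def phenotype_from_dict(d: dict) -> StrainPhenotype:
    return StrainPhenotype(
        release_rate=float(d["release_rate_fmol_per_cell_hr"]),
        consumption_per_birth=float(d["consumption_per_birth_fmol_per_cell"]),
        kinetics=MoserParams(
            b_max=float(d["b_max_per_hr"]),
            K=float(d["half_saturation_uM"]),
            n=float(d.get("cooperativity_n", 1.0)),
        ),
        death_rate=float(d.get("death_rate_per_hr", 0.0)),
    )


def chemostat_config_to_dict(cfg: ChemostatConfig) -> dict:
    return {
        "dilution_rate_per_hr": cfg.dilution_rate,
        "inflow_uM": cfg.inflow_conc,
        "inoculum_live_per_ml": cfg.inoculum_live,
        "inoculum_dead_per_ml": cfg.inoculum_dead,
        "initial_nutrient_uM": cfg.nutrient0,
        "initial_product_uM": cfg.initial_product,
    }


def chemostat_config_from_dict(d: dict) -> ChemostatConfig:
    if "dilution_rate_per_hr" in d:
        dil = float(d["dilution_rate_per_hr"])
    elif "doubling_time_hr" in d:
        import numpy as np

        dil = float(np.log(2) / float(d["doubling_time_hr"]))
    else:
        raise SchemaError("config needs dilution_rate_per_hr or doubling_time_hr")
    return ChemostatConfig(
        dilution_rate=dil,
        inflow_conc=float(d["inflow_uM"]),
        inoculum_live=float(d.get("inoculum_live_per_ml", 1.0e6)),
        inoculum_dead=float(d.get("inoculum_dead_per_ml", 0.0)),
        initial_nutrient=(
            float(d["initial_nutrient_uM"]) if "initial_nutrient_uM" in d else None
        ),
        initial_product=float(d.get("initial_product_uM", 0.0)),
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a flat key-value mapping")
    return data


def _to_builtin(value):
    if hasattr(value, "item"):  # numpy scalars
        return value.item()
    if isinstance(value, dict):
        return {k: _to_builtin(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_to_builtin(v) for v in value]
    return value


def dump_yaml(data: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_builtin(data), fh, sort_keys=True)
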