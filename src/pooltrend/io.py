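"""Readers/writers and run configuration.

The pooled-sample table is plain delimited text (CSV) with a required header
row and optional ``#`` comment lines carrying the schema version and the
generating seed::

    # pooltrend pooled-table schema=1 seed=42
    ocp,age_group,gender,period,concentration_ng_g_lipid,pool_n
    HCB,5-15,male,2002/03,21.93,100

Age group and period are serialized as the printed study labels.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .synthetic import (
    AGE_GROUPS,
    GENDERS,
    PERIODS,
    GenerativeParams,
    PooledObservation,
    ValidationError,
    default_design,
    example_params,
    make_design,
)

SCHEMA_VERSION = 1
TABLE_COLUMNS = ("ocp", "age_group", "gender", "period", "concentration_ng_g_lipid", "pool_n")


def write_pooled_table(
    data: Sequence[PooledObservation], path: Union[str, Path], seed: Optional[int] = None
) -> None:
    """Write observations as a commented CSV table."""
    df = pd.DataFrame(
        {
            "ocp": [o.ocp for o in data],
            "age_group": [o.age_group for o in data],
            "gender": [o.gender for o in data],
            "period": [o.period for o in data],
            "concentration_ng_g_lipid": [o.concentration for o in data],
            "pool_n": [o.pool_size for o in data],
        }
    )
    header = f"# pooltrend pooled-table schema={SCHEMA_VERSION}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_pooled_table(path: Union[str, Path]) -> list[PooledObservation]:
    """Read and validate a pooled-sample table.

    Unknown age/gender/period labels and non-positive concentrations are
    rejected with the offending data row number in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    if not body.strip():
        raise ValidationError(f"{path}: empty table")
    try:
        df = pd.read_csv(_io.StringIO(body), dtype=str)
    except Exception as e:
        raise ValidationError(f"{path}: unparseable table: {e}") from e
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    obs: list[PooledObservation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.age_group not in AGE_GROUPS:
            raise ValidationError(f"{path} row {i}: unknown age group {row.age_group!r}")
        if row.gender not in GENDERS:
            raise ValidationError(f"{path} row {i}: unknown gender {row.gender!r}")
        if row.period not in PERIODS:
            raise ValidationError(f"{path} row {i}: unknown period {row.period!r}")
        try:
            conc = float(row.concentration_ng_g_lipid)
            pool_n = int(row.pool_n)
        except (TypeError, ValueError) as e:
            raise ValidationError(f"{path} row {i}: unparseable number: {e}") from e
        if conc <= 0:
            raise ValidationError(f"{path} row {i}: concentration must be positive, got {conc}")
        try:
            obs.append(
                PooledObservation.from_log(
                    ocp=row.ocp,
                    age_group=row.age_group,
                    gender=row.gender,
                    period=row.period,
                    log_concentration=math.log(conc),
                    pool_size=pool_n,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path} row {i}: {e}") from e
    return obs


@dataclass
class SimulationConfig:
    """Synthetic-data block: which design, which generative model, which seed."""

    model_spec: int = 3
    design: str = "default"  # "default" or "balanced"
    n_pools_per_cell: int = 4
    pool_size: int = 100
    seed: int = 0
    ocp: str = "HCB"
    params: Optional[dict] = None  # overrides for example_params fields

    def build_design(self):
        if self.design == "default":
            return default_design()
        if self.design == "balanced":
            return make_design(self.n_pools_per_cell, self.pool_size)
        raise ValidationError(f"unknown design {self.design!r}")

    def build_params(self) -> GenerativeParams:
        base = example_params(self.model_spec)
        if self.params:
            for k, v in self.params.items():
                if not hasattr(base, k):
                    raise ValidationError(f"unknown generative parameter {k!r}")
                setattr(base, k, v)
            base.__post_init__()
        return base


@dataclass
class BRTConfig:
    shrinkage: float = 0.01
    max_trees: int = 5000
    tree_depth: int = 3
    split_seed: int = 0
    patience: int = 50


@dataclass
class MCMCConfig:
    specs: tuple[int, ...] = (1, 2, 3)
    n_chains: int = 2
    n_iter: int = 10000
    n_burnin: int = 10000
    seed: int = 0
    include_gender_offset: bool = False


@dataclass
class PipelineConfig:
    """Full two-stage pipeline configuration.

    Exactly one of ``input_path`` (a pooled-sample table on disk) or
    ``simulation`` (a synthetic-data block) must be set.
    """

    out_dir: str = "pooltrend_out"
    input_path: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    brt: BRTConfig = field(default_factory=BRTConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    assessment_levels: tuple[float, ...] = (0.2, 0.1, 0.05)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValidationError("exactly one of input_path / simulation must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        brt = d.pop("brt", None)
        mcmc = d.pop("mcmc", None)
        cfg = cls(
            out_dir=d.pop("out_dir", "pooltrend_out"),
            input_path=d.pop("input_path", None),
            simulation=SimulationConfig(**sim) if sim is not None else None,
            brt=BRTConfig(**brt) if brt else BRTConfig(),
            mcmc=MCMCConfig(**{**mcmc, "specs": tuple(mcmc.get("specs", (1, 2, 3)))})
            if mcmc
            else MCMCConfig(),
            assessment_levels=tuple(d.pop("assessment_levels", (0.2, 0.1, 0.05))),
        )
        if d:
            raise ValidationError(f"unknown config keys {sorted(d)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def write_table(df: pd.DataFrame, path: Union[str, Path], seed: Optional[int] = None) -> None:
    """Write an output table with the schema/seed comment header."""
    header = f"# pooltrend table schema={SCHEMA_VERSION}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, sep="\t")
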