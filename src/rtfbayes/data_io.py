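"""Reading and writing of tab-separated parameter-estimation tables.

The measurement and parameter tables follow the PEtab dialect: tab-separated,
UTF-8, "." decimal.  A measurement table needs the columns ``observableId``,
``simulationConditionId``, ``time`` and ``measurement``; an optional
``replicateId`` labels replicates, otherwise replicates are inferred
positionally from repeated (condition, time) rows.  Extra PEtab columns are
accepted and ignored with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesDataset",
    "RunConfig",
    "SchemaError",
    "read_measurement_table",
    "write_measurement_table",
    "read_parameter_table",
    "filter_nonnegative",
    "write_results",
    "write_sbml_stub",
]

MEASUREMENT_COLUMNS = ("observableId", "simulationConditionId", "time", "measurement")
PARAMETER_COLUMNS = ("parameterId", "lowerBound", "upperBound", "estimate", "parameterScale")


class SchemaError(ValueError):
    """A required table column is missing or malformed."""


@dataclass
class TimeSeriesDataset:
    """Replicate time-series measurements for one (condition, observable).

    ``times``, ``replicates`` and ``values`` are parallel arrays, one entry
    per record m^(j)(t_k); row order of the source table is preserved.
    """

    condition_id: str
    observable_id: str
    times: np.ndarray
    replicates: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.replicates = np.asarray(self.replicates)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.times) == len(self.replicates) == len(self.values)):
            raise ValueError("times, replicates and values must have equal length")
        if not np.all(np.isfinite(self.times)) or np.any(self.times < 0):
            raise ValueError("times must be finite and >= 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("measurement values must be finite")
        if len(np.unique(self.times)) < 2:
            raise ValueError("dataset needs at least 2 distinct time points")

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def unique_times(self) -> np.ndarray:
        return np.unique(self.times)

    @property
    def n_timepoints(self) -> int:
        return len(self.unique_times)

    def replicates_per_timepoint(self) -> dict[float, int]:
        t, c = np.unique(self.times, return_counts=True)
        return dict(zip(t.tolist(), c.tolist()))

    @property
    def observation_range(self) -> float:
        return float(self.times.max() - self.times.min())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observableId": self.observable_id,
                "simulationConditionId": self.condition_id,
                "time": self.times,
                "measurement": self.values,
                "replicateId": self.replicates,
            }
        )


@dataclass
class RunConfig:
    """Resolved settings for one inference run."""

    model_id: str = "rtf"
    seed: int | None = None
    chain_length: int = 50_000
    n_chains: int = 2
    burn_in_fraction: float = 0.3
    temperature_ladder: list[float] | None = None
    alpha: float = 0.05
    grid_size: int = 201
    drop_negative: bool = False
    estimate_sigma: bool = True
    sigma_value: float | None = None
    fixed_parameters: dict[str, float] = field(default_factory=dict)
    prior_overrides: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.chain_length < 100:
            raise ValueError("chain_length must be >= 100")
        if not 0 <= self.burn_in_fraction <= 0.9:
            raise ValueError("burn_in_fraction must be in [0, 0.9]")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if not self.estimate_sigma and self.sigma_value is None:
            raise ValueError("sigma_value required when estimate_sigma is False")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_measurement_table(path: str | Path) -> list[TimeSeriesDataset]:
    """Read a PEtab-dialect measurement TSV into per-(condition, observable) datasets.

    Replicate labels come from ``replicateId`` when present; otherwise the
    j-th occurrence of a (condition, time) pair in file order becomes
    replicate j.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table {path} is missing column(s): {missing}")
    extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS + ("replicateId",)]
    if extra:
        logger.info("ignoring extra measurement-table column(s): %s", extra)
    for col in ("time", "measurement"):
        try:
            df[col] = df[col].astype(float)
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise SchemaError(
                f"non-numeric value in column {col!r} at data row {bad + 1}"
            ) from None
    if "replicateId" not in df.columns:
        df = df.copy()
        df["replicateId"] = (
            df.groupby(["simulationConditionId", "time"], sort=False)
            .cumcount()
            .astype(str)
        )
    datasets = []
    for (cond, obs), grp in df.groupby(
        ["simulationConditionId", "observableId"], sort=False
    ):
        datasets.append(
            TimeSeriesDataset(
                condition_id=str(cond),
                observable_id=str(obs),
                times=grp["time"].to_numpy(),
                replicates=grp["replicateId"].to_numpy(),
                values=grp["measurement"].to_numpy(),
            )
        )
    return datasets


def write_measurement_table(
    datasets: Iterable[TimeSeriesDataset], path: str | Path
) -> None:
    """Write datasets back to a single measurement TSV (17 significant digits)."""
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_parameter_table(path: str | Path):
    """Read a PEtab-dialect parameter TSV.

    Returns
    -------
    priors : list of (parameterId, lowerBound, upperBound, scale)
        One entry per row with ``estimate = 1``; bounds are on the linear
        scale, ``scale`` in {"lin", "log10"} states the sampling scale.
    fixed : dict
        parameterId -> nominalValue for rows with ``estimate = 0``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARAMETER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"parameter table {path} is missing column(s): {missing}")
    priors = []
    fixed: dict[str, float] = {}
    for _, row in df.iterrows():
        pid = str(row["parameterId"])
        scale = str(row["parameterScale"])
        if scale not in ("lin", "log10"):
            raise SchemaError(f"unknown parameterScale {scale!r} for {pid}")
        if int(row["estimate"]) == 1:
            lb, ub = float(row["lowerBound"]), float(row["upperBound"])
            if not lb < ub:
                raise SchemaError(
                    f"lowerBound must be < upperBound for estimated parameter "
                    f"{pid} (got {lb} >= {ub})"
                )
            if scale == "log10" and lb <= 0:
                raise SchemaError(f"log10-scaled parameter {pid} needs bounds > 0")
            priors.append((pid, lb, ub, scale))
        else:
            if "nominalValue" not in df.columns or pd.isna(row.get("nominalValue")):
                raise SchemaError(f"fixed parameter {pid} needs a nominalValue")
            fixed[pid] = float(row["nominalValue"])
    return priors, fixed


def filter_nonnegative(dataset: TimeSeriesDataset) -> tuple[TimeSeriesDataset, int]:
    """Drop records with negative values (physically meaningless readings).

    Returns the filtered copy and the number of removed records.  If the
    filter empties a time point a warning is logged and the dataset is still
    returned.
    """
    keep = dataset.values >= 0
    removed = int((~keep).sum())
    if removed == 0:
        return dataset, 0
    emptied = set(dataset.times.tolist()) - set(dataset.times[keep].tolist())
    if emptied:
        logger.warning(
            "negative-value filter emptied time point(s) %s in condition %s",
            sorted(emptied),
            dataset.condition_id,
        )
    out = TimeSeriesDataset(
        condition_id=dataset.condition_id,
        observable_id=dataset.observable_id,
        times=dataset.times[keep],
        replicates=dataset.replicates[keep],
        values=dataset.values[keep],
    )
    return out, removed


def write_results(
    out_dir: str | Path,
    samples: pd.DataFrame,
    diagnostics: dict,
    config: RunConfig,
    tube: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write one run's artefacts: samples TSV, diagnostics JSON, config YAML
    and optionally a tube TSV.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["samples"] = out / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False, float_format="%.17g")
    paths["diagnostics"] = out / "diagnostics.json"
    with open(paths["diagnostics"], "w", encoding="utf-8") as fh:
        json.dump(diagnostics, fh, indent=2, sort_keys=True)
    paths["config"] = out / "config.yaml"
    config.to_yaml(paths["config"])
    if tube is not None:
        paths["tube"] = out / "tube.tsv"
        tube.to_csv(paths["tube"], sep="\t", index=False, float_format="%.17g")
    return paths


_SBML_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="rtf" name="retarded transient function">
    <listOfParameters>
{params}    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="f">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>f(t) = Asus*(1 - exp(-tau/t1)) + Atrans*(1 - exp(-tau/t11))*exp(-tau/t2) + p0,
               tau = Trange*(log10(10^(t/Trange) + 10^Tshift) - log10(1 + 10^Tshift))</p>
          </body>
        </notes>
      </assignmentRule>
    </listOfRules>
  </model>
</sbml>
"""


def write_sbml_stub(path: str | Path, parameters: dict[str, float] | None = None) -> None:
    """Export-only SBML stub encoding the RTF as an assignment rule.

    Interoperability aid; this package never imports or simulates SBML.
    """
    parameters = parameters or {}
    lines = "".join(
        f'      <parameter id="{k}" value="{v!r}" constant="true"/>\n'
        for k, v in parameters.items()
    )
    lines += '      <parameter id="f" value="0" constant="false"/>\n'
    Path(path).write_text(_SBML_TEMPLATE.format(params=lines), encoding="utf-8")
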