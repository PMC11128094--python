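"""Synthetic replicate time-series generation.

The generator realizes exactly the assumed data model: a deterministic
simulation trajectory plus additive i.i.d. Gaussian noise,

    m^(j)(t_k) = s(t_k, theta*) + eps_jk,   eps_jk ~ N(0, sigma*^2),

so the full pipeline can be exercised and calibrated without any external
data.  Two presets emulate the shapes of typical sparse in-vivo studies:

``pvl-like``
    Five conditions on a 0-5 day grid (5 time points x 5 replicates),
    mixing transiently hyper-perfused and persistently hypo-perfused
    responses around a common baseline — the shape of organ-perfusion
    courses after portal vein ligation.

``steatosis-like``
    Three conditions on a 0-6 hour grid (8 time points; 4, 6 and 6
    replicates), peak-and-elimination pharmacokinetic shapes in which the
    slowest condition clears the compound with a visible delay.

Negative synthetic values are kept: excluding them is an application-level
preprocessing choice, not part of the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import TimeSeriesDataset
from .models import RTFParameters, get_model

__all__ = ["SyntheticSpec", "generate_dataset", "generate_study", "PRESETS"]


@dataclass
class SyntheticSpec:
    """Ground truth for one synthetic condition."""

    params: dict[str, float]
    times: np.ndarray
    n_replicates: int
    sigma: float
    seed: int
    condition_id: str = "c0"
    observable_id: str = "obs"
    model_id: str = "rtf"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if isinstance(self.params, RTFParameters):
            self.params = self.params.as_dict()


def generate_dataset(spec: SyntheticSpec) -> tuple[TimeSeriesDataset, dict]:
    """Generate one replicate dataset plus its truth record.

    The truth record carries theta*, sigma* and the noiseless curve on the
    measurement grid, for recovery and coverage tests.
    """
    model = get_model(spec.model_id)
    noiseless = np.asarray(model.evaluate(spec.times, spec.params), dtype=float)
    rng = np.random.default_rng(spec.seed)
    T, N = len(spec.times), spec.n_replicates
    noise = rng.normal(0.0, spec.sigma, size=(N, T)) if spec.sigma > 0 else np.zeros((N, T))
    values = noiseless[None, :] + noise
    # row order: all replicates of t_1, then t_2, ... (column-major over reps)
    times = np.repeat(spec.times, N)
    reps = np.tile(np.arange(N).astype(str), T)
    vals = values.T.ravel()
    ds = TimeSeriesDataset(
        condition_id=spec.condition_id,
        observable_id=spec.observable_id,
        times=times,
        replicates=reps,
        values=vals,
    )
    truth = {
        "condition_id": spec.condition_id,
        "model_id": spec.model_id,
        "params": dict(spec.params),
        "sigma": spec.sigma,
        "times": spec.times.copy(),
        "noiseless": noiseless,
        "seed": spec.seed,
    }
    return ds, truth


def _pvl_like_specs(seed: int) -> list[SyntheticSpec]:
    times = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
    base = dict(Tshift=-2.0, Trange=5.0, p0=100.0)
    shapes = {
        # persistently hypo-perfused: fast drop to a lower plateau
        "lig_a": dict(Asus=-45.0, t1=0.5, Atrans=0.0, t11=0.5, t2=1.0),
        "lig_b": dict(Asus=-35.0, t1=0.7, Atrans=0.0, t11=0.5, t2=1.0),
        "lig_c": dict(Asus=-50.0, t1=0.4, Atrans=-10.0, t11=0.3, t2=2.0),
        # transiently hyper-perfused: peak near day 1, back to baseline
        "nonlig_a": dict(Asus=0.0, t1=1.0, Atrans=60.0, t11=0.4, t2=0.8),
        "nonlig_b": dict(Asus=10.0, t1=2.0, Atrans=40.0, t11=0.5, t2=1.5),
    }
    specs = []
    for i, (cond, shape) in enumerate(shapes.items()):
        specs.append(
            SyntheticSpec(
                params={**base, **shape},
                times=times,
                n_replicates=5,
                sigma=8.0,
                seed=seed + i,
                condition_id=cond,
                observable_id="perfusion",
            )
        )
    return specs


def _steatosis_like_specs(seed: int) -> list[SyntheticSpec]:
    times = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0])
    base = dict(Tshift=-2.0, Trange=6.0, Asus=0.0, t1=1.0, p0=0.05)
    shapes = {
        "control": (dict(Atrans=1.0, t11=0.15, t2=0.8), 4),
        "diet_2wk": (dict(Atrans=1.1, t11=0.15, t2=1.0), 6),
        # delayed clearance and higher peak in the severe condition
        "diet_4wk": (dict(Atrans=1.5, t11=0.2, t2=2.2), 6),
    }
    specs = []
    for i, (cond, (shape, n)) in enumerate(shapes.items()):
        specs.append(
            SyntheticSpec(
                params={**base, **shape},
                times=times,
                n_replicates=n,
                sigma=0.08,
                seed=seed + i,
                condition_id=cond,
                observable_id="concentration",
            )
        )
    return specs


PRESETS = {"pvl-like": _pvl_like_specs, "steatosis-like": _steatosis_like_specs}


@dataclass
class StudyResult:
    measurements: pd.DataFrame
    truths: list[dict] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {"condition_id": t["condition_id"], "model_id": t["model_id"],
                   "sigma": t["sigma"], "seed": t["seed"]}
            row.update({f"param_{k}": v for k, v in t["params"].items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "measurements": out / "measurements.tsv",
            "truths": out / "truths.tsv",
        }
        self.measurements.to_csv(
            paths["measurements"], sep="\t", index=False, float_format="%.17g"
        )
        self.truth_frame().to_csv(
            paths["truths"], sep="\t", index=False, float_format="%.17g"
        )
        return paths


def generate_study(
    specs: list[SyntheticSpec] | None = None,
    preset: str | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Generate a multi-condition measurement table plus truth records.

    Either pass explicit per-condition specs, or a preset name with a seed.
    """
    if specs is None:
        if preset is None or seed is None:
            raise ValueError("need either specs or (preset, seed)")
        try:
            specs = PRESETS[preset](seed)
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            ) from None
    if len(specs) < 2:
        raise ValueError("a study needs >= 2 conditions")
    ids = [s.condition_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate condition ids: {ids}")
    frames, truths = [], []
    for spec in specs:
        ds, truth = generate_dataset(spec)
        frames.append(ds.to_frame())
        truths.append(truth)
    return StudyResult(
        measurements=pd.concat(frames, ignore_index=True), truths=truths
    )
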