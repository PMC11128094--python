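"""Posterior-ensemble trajectories, credible tubes and condition comparison.

Uncertainty is carried from parameter space into the data space by evaluating
the simulation model at every retained posterior draw,

    s_i(t) = s(t, theta_i),   i = 1..P,   (no measurement noise added)

and summarizing the trajectory ensemble pointwise.  The (1-alpha)*100%
credible tube takes, at each grid point, the empirical alpha/2 and
1 - alpha/2 percentiles of the ensemble (linear interpolation between order
statistics, the "type-7" convention) together with the median; between grid
points the tube is understood as linearly interpolated.  Posterior
predictive draws add Gaussian noise sigma_i per draw and are therefore at
least as variable as the ensemble at every time point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .inference import PosteriorSampleSet
from .models import ModelSpec

__all__ = [
    "EnsembleTrajectories",
    "CredibleTube",
    "ComparisonResult",
    "simulate_ensemble",
    "posterior_predictive",
    "credible_tube",
    "hdi",
    "compare_conditions",
]


@dataclass
class EnsembleTrajectories:
    """Model trajectories evaluated at posterior draws (rows) on a grid."""

    grid: np.ndarray
    values: np.ndarray  # shape (n_draws, len(grid))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("evaluation grid must be strictly ascending")
        if self.values.shape[1] != len(self.grid):
            raise ValueError("values row length must match grid length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]


@dataclass
class CredibleTube:
    """Pointwise percentile band of an ensemble at nominal level 1 - alpha."""

    level: float
    grid: np.ndarray
    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.median = np.asarray(self.median, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if np.any(self.lower > self.median) or np.any(self.median > self.upper):
            raise ValueError("tube must satisfy lower <= median <= upper")

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def interpolate(self, grid: np.ndarray) -> "CredibleTube":
        """Linearly interpolate the tube onto another grid (within range)."""
        grid = np.asarray(grid, dtype=float)
        return CredibleTube(
            level=self.level,
            grid=grid,
            lower=np.interp(grid, self.grid, self.lower),
            median=np.interp(grid, self.grid, self.median),
            upper=np.interp(grid, self.grid, self.upper),
        )

    def to_frame(self, condition_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time": self.grid, "median": self.median,
             "lower": self.lower, "upper": self.upper}
        )
        if condition_id is not None:
            df.insert(0, "condition", condition_id)
        return df


def simulate_ensemble(
    samples: PosteriorSampleSet,
    model: ModelSpec,
    grid: np.ndarray,
    max_draws: int | None = None,
    seed: int | None = None,
) -> EnsembleTrajectories:
    """Evaluate the model at every retained draw (no noise added).

    If the posterior holds more than ``max_draws`` draws, a uniform
    subsample without replacement is taken (seed-controlled).
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior sample set")
    grid = np.asarray(grid, dtype=float)
    lin = samples.priors.to_linear(samples.draws_sampling)
    idx = np.arange(samples.n_draws)
    if max_draws is not None and samples.n_draws > max_draws:
        rng = np.random.default_rng(samples.seed if seed is None else seed)
        idx = np.sort(rng.choice(samples.n_draws, size=max_draws, replace=False))
    model_names = [n for n in samples.parameter_names if n != "sigma"]
    name_idx = [samples.parameter_names.index(n) for n in model_names]
    out = np.empty((len(idx), len(grid)))
    for row, i in enumerate(idx):
        params = dict(zip(model_names, lin[i, name_idx]))
        params.update(samples.fixed_parameters)
        out[row] = model.evaluate(grid, params)
    return EnsembleTrajectories(grid=grid, values=out)


def posterior_predictive(
    samples: PosteriorSampleSet,
    model: ModelSpec,
    grid: np.ndarray,
    seed: int,
    max_draws: int | None = None,
) -> EnsembleTrajectories:
    """Monte-Carlo posterior predictive draws: s(t, theta_i) + N(0, sigma_i^2)
    noise i.i.d. per grid point.  Requires sigma (estimated or fixed)."""
    ens = simulate_ensemble(samples, model, grid, max_draws=max_draws, seed=seed)
    sigmas = samples.sigma_draws()
    if max_draws is not None and samples.n_draws > max_draws:
        # reproduce the subsample indices used by simulate_ensemble
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(samples.n_draws, size=max_draws, replace=False))
        sigmas = sigmas[idx]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    noise = rng.standard_normal(ens.values.shape) * sigmas[:, None]
    return EnsembleTrajectories(grid=ens.grid, values=ens.values + noise)


def credible_tube(traj: EnsembleTrajectories, alpha: float = 0.05) -> CredibleTube:
    """Pointwise percentile tube [z_{alpha/2}, z_{1-alpha/2}] with median."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if traj.n_draws < 20 and alpha <= 0.05:
        warnings.warn(
            f"only {traj.n_draws} trajectories for alpha={alpha}: tail "
            "percentiles are poorly determined",
            stacklevel=2,
        )
    lower, median, upper = np.quantile(
        traj.values, [alpha / 2.0, 0.5, 1.0 - alpha / 2.0], axis=0, method="linear"
    )
    return CredibleTube(
        level=1.0 - alpha, grid=traj.grid, lower=lower, median=median, upper=upper
    )


def hdi(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval containing
    ``ceil(level * P)`` of the sorted draws (ties broken towards the smallest
    lower bound)."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 draws for an HDI, got {n}")
    k = int(np.ceil(level * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum
    return float(x[i]), float(x[i + k - 1])


@dataclass
class ComparisonResult:
    """Pairwise tube-disjointness summary, optionally with marginal HDIs."""

    grid: np.ndarray
    conditions: list[str]
    pairwise_disjoint: dict[tuple[str, str], np.ndarray]
    disjoint_fraction: dict[tuple[str, str], float]
    hdi_intervals: dict[str, dict[str, tuple[float, float]]] | None = None
    hdi_overlap: dict[tuple[str, str], dict[str, bool]] | None = None

    def to_dict(self) -> dict:
        out = {
            "conditions": self.conditions,
            "grid": self.grid.tolist(),
            "pairs": [
                {
                    "a": a,
                    "b": b,
                    "disjoint_fraction": self.disjoint_fraction[(a, b)],
                    "disjoint_flags": self.pairwise_disjoint[(a, b)].astype(bool).tolist(),
                }
                for (a, b) in self.disjoint_fraction
            ],
        }
        if self.hdi_intervals is not None:
            out["hdi"] = {
                cond: {p: list(iv) for p, iv in params.items()}
                for cond, params in self.hdi_intervals.items()
            }
        if self.hdi_overlap is not None:
            out["hdi_overlap"] = [
                {"a": a, "b": b, "overlap": {p: bool(v) for p, v in flags.items()}}
                for (a, b), flags in self.hdi_overlap.items()
            ]
        return out


def compare_conditions(
    tubes: dict[str, CredibleTube],
    marginals: dict[str, pd.DataFrame] | None = None,
    hdi_level: float = 0.95,
) -> ComparisonResult:
    """Compare conditions by pointwise tube disjointness.

    Two tubes are disjoint at a grid point when the upper bound of one lies
    strictly below the lower bound of the other; the per-pair summary is the
    fraction of grid points where that holds.  If per-condition marginal
    draws are given, per-parameter HDIs at ``hdi_level`` and their overlap
    flags are reported as well.  The result is symmetric in the pair order.
    """
    if len(tubes) < 2:
        raise ValueError("need >= 2 conditions to compare")
    conditions = list(tubes)
    grids = [tubes[c].grid for c in conditions]
    if all(np.array_equal(g, grids[0]) for g in grids[1:]):
        grid = grids[0]
        interp = tubes
    else:
        lo = max(g.min() for g in grids)
        hi = min(g.max() for g in grids)
        if not lo < hi:
            raise ValueError("tube grids do not overlap")
        n = max(len(g) for g in grids)
        grid = np.linspace(lo, hi, n)
        interp = {c: tubes[c].interpolate(grid) for c in conditions}
    pairwise, fractions = {}, {}
    for a, b in combinations(conditions, 2):
        ta, tb = interp[a], interp[b]
        disjoint = (ta.upper < tb.lower) | (tb.upper < ta.lower)
        pairwise[(a, b)] = disjoint
        fractions[(a, b)] = float(disjoint.mean())
    hdi_intervals = hdi_overlap = None
    if marginals is not None:
        hdi_intervals = {}
        for cond, df in marginals.items():
            cols = [c for c in df.columns if c != "log_posterior"]
            hdi_intervals[cond] = {c: hdi(df[c].to_numpy(), hdi_level) for c in cols}
        hdi_overlap = {}
        for a, b in combinations(conditions, 2):
            if a not in hdi_intervals or b not in hdi_intervals:
                continue
            flags = {}
            for p in hdi_intervals[a]:
                if p not in hdi_intervals[b]:
                    continue
                (la, ua), (lb, ub) = hdi_intervals[a][p], hdi_intervals[b][p]
                flags[p] = not (ua < lb or ub < la)
            hdi_overlap[(a, b)] = flags
    return ComparisonResult(
        grid=grid,
        conditions=conditions,
        pairwise_disjoint=pairwise,
        disjoint_fraction=fractions,
        hdi_intervals=hdi_intervals,
        hdi_overlap=hdi_overlap,
    )
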