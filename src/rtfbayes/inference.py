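"""Posterior construction and MCMC sampling.

The data model is additive i.i.d. Gaussian noise around a deterministic
simulation model,

    m^(j)(t_k) = s(t_k, theta) + eps,   eps ~ N(0, sigma^2),

with one pooled noise standard deviation ``sigma`` shared by all time points
and replicates of a dataset.  Priors are independent uniforms, either on the
linear scale or on log10 (sampling uniformly on log10 makes scale-spanning
positivity constraints natural for timescales and sigma).  The posterior is
sampled with an adaptive Metropolis algorithm (Haario-style covariance
adaptation plus a global step-size tuned towards an acceptance rate of
0.234), optionally wrapped in parallel tempering for multimodal targets.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import RunConfig, TimeSeriesDataset
from .models import ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "PriorEntry",
    "PriorSpec",
    "PosteriorSampleSet",
    "log_likelihood",
    "default_priors",
    "log_posterior",
    "sample_posterior",
    "parallel_tempering",
    "effective_sample_size",
    "gelman_rubin",
]

_LOG_2PI = math.log(2.0 * math.pi)

# Adaptation schedule of the Metropolis sampler: covariance is re-estimated
# from the chain history every ADAPT_INTERVAL steps once ADAPT_START steps
# have been taken; 1e-10*I regularization keeps the proposal full rank.
ADAPT_START = 500
ADAPT_INTERVAL = 50
TARGET_ACCEPT = 0.234
COV_EPS = 1e-10


@dataclass(frozen=True)
class PriorEntry:
    name: str
    lower: float
    upper: float
    scale: str = "lin"  # "lin" | "log10"; bounds are always on the linear scale

    def __post_init__(self) -> None:
        if self.scale not in ("lin", "log10"):
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        if not self.lower < self.upper:
            raise ValueError(
                f"prior for {self.name}: lower must be < upper "
                f"({self.lower} >= {self.upper})"
            )
        if self.scale == "log10" and self.lower <= 0:
            raise ValueError(f"log10 prior for {self.name} needs bounds > 0")


class PriorSpec:
    """Ordered collection of independent uniform priors.

    ``constraints`` is an optional list of ``(a, b)`` parameter-name pairs
    restricting the support to ``a <= b`` on the linear scale.  The RTF
    priors use it to impose ``t11 <= t2`` (transient rise no slower than its
    decay): without it the transient term can degenerate into a second
    sustained term, making the timescales non-identifiable.
    """

    def __init__(
        self,
        entries: list[PriorEntry | tuple],
        constraints: list[tuple[str, str]] | None = None,
    ):
        self.entries = [
            e if isinstance(e, PriorEntry) else PriorEntry(*e) for e in entries
        ]
        if len({e.name for e in self.entries}) != len(self.entries):
            raise ValueError("duplicate parameter names in prior")
        self.names = [e.name for e in self.entries]
        self.log_mask = np.array([e.scale == "log10" for e in self.entries])
        lo = np.array([e.lower for e in self.entries], dtype=float)
        hi = np.array([e.upper for e in self.entries], dtype=float)
        # bounds on the sampling scale
        self.lo = np.where(self.log_mask, np.log10(lo, where=lo > 0, out=np.full_like(lo, -np.inf)), lo)
        self.hi = np.where(self.log_mask, np.log10(hi, where=hi > 0, out=np.full_like(hi, -np.inf)), hi)
        self.constraints = list(constraints or [])
        for a, b in self.constraints:
            if a not in self.names or b not in self.names:
                raise ValueError(f"constraint ({a!r}, {b!r}) names unknown parameters")
        self._constraint_idx = [
            (self.names.index(a), self.names.index(b)) for a, b in self.constraints
        ]

    def __len__(self) -> int:
        return len(self.entries)

    def __repr__(self) -> str:
        return f"PriorSpec({self.entries!r}, constraints={self.constraints!r})"

    def satisfies_constraints(self, x: np.ndarray) -> bool:
        """Whether sampling-scale point ``x`` meets all ordering constraints."""
        lin = self.to_linear(x)
        return all(lin[i] <= lin[j] for i, j in self._constraint_idx)

    def contains(self, x: np.ndarray) -> bool:
        """Whether sampling-scale point ``x`` lies in the prior support."""
        return bool(
            np.all(x >= self.lo)
            and np.all(x <= self.hi)
            and self.satisfies_constraints(x)
        )

    def to_linear(self, x: np.ndarray) -> np.ndarray:
        """Map sampling-scale point(s) to the linear parameter scale."""
        x = np.asarray(x, dtype=float)
        return np.where(self.log_mask, 10.0 ** x, x)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` points uniformly on the sampling scale."""
        return rng.uniform(self.lo, self.hi, size=(n, len(self)))


def log_likelihood(
    dataset: TimeSeriesDataset,
    params,
    sigma: float,
    model: ModelSpec,
) -> float:
    """Gaussian log-likelihood of a dataset under the simulation model.

    The model is evaluated once per distinct time point and reused across
    replicates.  Non-finite model output yields ``-inf`` (the point is
    rejected), never an exception.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    unique_t, inverse = np.unique(dataset.times, return_inverse=True)
    try:
        s = np.asarray(model.evaluate(unique_t, params), dtype=float)
    except (ValueError, FloatingPointError, ZeroDivisionError):
        return -np.inf
    if not np.all(np.isfinite(s)):
        return -np.inf
    resid = dataset.values - s[inverse]
    n = dataset.n_records
    return float(
        -n * (math.log(sigma) + 0.5 * _LOG_2PI)
        - np.dot(resid, resid) / (2.0 * sigma**2)
    )


def default_priors(
    dataset: TimeSeriesDataset,
    model: ModelSpec,
    trange: float | None = None,
    estimate_sigma: bool = True,
    exclude: tuple[str, ...] = ("Tshift",),
) -> PriorSpec:
    """Data-informed wide uniform priors.

    With ``delta = max(m) - min(m)`` and ``R`` the observation range:
    amplitudes get ``[-2*delta, 2*delta]`` linear, the baseline
    ``[min(m)-delta, max(m)+delta]`` linear, timescales ``[R/100, 10R]`` on
    log10, and sigma ``[delta/1000, 2*delta]`` on log10.  Parameters listed
    in ``exclude`` (by default the delay shift, conventionally fixed at -2)
    get no prior and must be supplied as fixed values.  For the RTF the
    support carries the ordering constraint ``t11 <= t2``.
    """
    m = dataset.values
    delta = float(m.max() - m.min())
    if delta <= 0:
        raise ValueError(
            "constant data (max == min): data-informed priors are undefined, "
            "supply priors manually"
        )
    R = float(trange) if trange is not None else dataset.observation_range
    entries: list[PriorEntry] = []
    if model.model_id == "rtf":
        rules = {
            "Asus": PriorEntry("Asus", -2 * delta, 2 * delta, "lin"),
            "Atrans": PriorEntry("Atrans", -2 * delta, 2 * delta, "lin"),
            "p0": PriorEntry("p0", float(m.min()) - delta, float(m.max()) + delta, "lin"),
            "t1": PriorEntry("t1", R / 100, 10 * R, "log10"),
            "t11": PriorEntry("t11", R / 100, 10 * R, "log10"),
            "t2": PriorEntry("t2", R / 100, 10 * R, "log10"),
            "Tshift": PriorEntry("Tshift", -10.0, 5.0, "lin"),
        }
        for name in model.parameter_names:
            if name not in exclude:
                entries.append(rules[name])
    elif model.model_id == "pk2c":
        # rate bounds span responses much faster/slower than the observation
        # window; the volume prior brackets dose / observed signal level
        peak = float(np.abs(m).max())
        if peak <= 0:
            raise ValueError("pk2c priors need a nonzero signal level")
        for name in model.parameter_names:
            if name in exclude or name in ("dose", "c0"):
                continue
            if name in ("ka", "ke"):
                entries.append(PriorEntry(name, 0.1 / R, 100.0 / R, "log10"))
            elif name == "V":
                entries.append(PriorEntry("V", 0.01 / peak, 100.0 / peak, "log10"))
    else:
        raise ValueError(
            f"no default-prior rule for model {model.model_id!r}; supply priors"
        )
    if estimate_sigma:
        entries.append(PriorEntry("sigma", delta / 1000, 2 * delta, "log10"))
    names = {e.name for e in entries}
    constraints = (
        [("t11", "t2")] if model.model_id == "rtf" and {"t11", "t2"} <= names else None
    )
    return PriorSpec(entries, constraints=constraints)


def _make_log_posterior(
    dataset: TimeSeriesDataset,
    priors: PriorSpec,
    model: ModelSpec,
    fixed: dict[str, float],
    sigma_value: float | None,
):
    """Build fast closures log_post(x) and log_lik(x) on the sampling scale.

    A uniform prior contributes only its support: constant inside the box,
    -inf outside (sampling uniformly on log10 carries the Jacobian
    implicitly).  Returns (log_post, log_lik, names).
    """
    unique_t, inverse = np.unique(dataset.times, return_inverse=True)
    values = dataset.values
    n = len(values)
    names = priors.names
    has_sigma = "sigma" in names
    if not has_sigma and sigma_value is None:
        raise ValueError("sigma must be estimated or fixed via sigma_value")
    sigma_idx = names.index("sigma") if has_sigma else -1
    model_names = [nm for nm in names if nm != "sigma"]
    model_idx = [i for i, nm in enumerate(names) if nm != "sigma"]
    lo, hi = priors.lo, priors.hi
    log_mask = priors.log_mask

    # fast path: scatter the estimated parameters into a flat RTF vector and
    # skip per-call dict assembly and argument validation
    from .models import _RTF_ORDER, _rtf_raw, rtf_evaluate

    use_raw_rtf = model.evaluator is rtf_evaluate and set(model_names) | set(fixed) >= set(_RTF_ORDER)
    if use_raw_rtf:
        template = np.array([fixed.get(nm, 0.0) for nm in _RTF_ORDER])
        scatter = np.array([_RTF_ORDER.index(nm) for nm in model_names])

    def _evaluate(lin: np.ndarray) -> np.ndarray | None:
        if use_raw_rtf:
            vec = template.copy()
            vec[scatter] = lin[model_idx]
            return _rtf_raw(unique_t, vec)
        params = dict(zip(model_names, lin[model_idx]))
        params.update(fixed)
        try:
            return np.asarray(model.evaluate(unique_t, params), dtype=float)
        except (ValueError, FloatingPointError, ZeroDivisionError):
            return None

    def log_lik(x: np.ndarray) -> float:
        lin = np.where(log_mask, 10.0 ** np.clip(x, -300, 300), x)
        sigma = lin[sigma_idx] if has_sigma else sigma_value
        s = _evaluate(lin)
        if s is None or not np.all(np.isfinite(s)):
            return -np.inf
        resid = values - s[inverse]
        return (
            -n * (math.log(sigma) + 0.5 * _LOG_2PI)
            - np.dot(resid, resid) / (2.0 * sigma**2)
        )

    def log_post(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return -np.inf
        if priors._constraint_idx and not priors.satisfies_constraints(x):
            return -np.inf
        return log_lik(x)

    return log_post, log_lik


def log_posterior(
    x: np.ndarray,
    dataset: TimeSeriesDataset,
    priors: PriorSpec,
    model: ModelSpec,
    fixed: dict[str, float] | None = None,
    sigma_value: float | None = None,
) -> float:
    """Unnormalized log posterior at sampling-scale point ``x``.

    Equals the log likelihood plus a constant inside the prior box and
    ``-inf`` outside it.
    """
    lp, _ = _make_log_posterior(dataset, priors, model, dict(fixed or {}), sigma_value)
    return float(lp(np.asarray(x, dtype=float)))


@dataclass
class PosteriorSampleSet:
    """Retained MCMC draws with chain metadata and convergence diagnostics."""

    parameter_names: list[str]
    draws_sampling: np.ndarray          # (P, d) on the sampling scale
    log_posterior: np.ndarray           # (P,)
    chains: list[np.ndarray]            # per-chain retained draws, sampling scale
    priors: PriorSpec
    fixed_parameters: dict[str, float]
    model_id: str
    seed: int
    acceptance_rate: float
    diagnostics: dict = field(default_factory=dict)
    sigma_value: float | None = None

    @property
    def n_draws(self) -> int:
        return self.draws_sampling.shape[0]

    def linear_draws(self) -> pd.DataFrame:
        """Draws mapped to the linear parameter scale, plus log-posterior."""
        lin = self.priors.to_linear(self.draws_sampling)
        df = pd.DataFrame(lin, columns=self.parameter_names)
        df["log_posterior"] = self.log_posterior
        return df

    def sigma_draws(self) -> np.ndarray:
        """Per-draw noise SD (estimated column or the fixed value)."""
        if "sigma" in self.parameter_names:
            i = self.parameter_names.index("sigma")
            return self.priors.to_linear(self.draws_sampling)[:, i]
        if self.sigma_value is None:
            raise ValueError("no sigma available: neither estimated nor fixed")
        return np.full(self.n_draws, self.sigma_value)


class _AdaptiveWalker:
    """One adaptive-Metropolis chain with running covariance adaptation."""

    def __init__(self, log_target, priors: PriorSpec, rng: np.random.Generator):
        self.log_target = log_target
        self.priors = priors
        self.rng = rng
        d = len(priors)
        self.d = d
        # start from the best of 1000 prior draws with finite log-target
        x, best_lp = None, -np.inf
        for draw in priors.sample(rng, 1000):
            lp = log_target(draw)
            if np.isfinite(lp) and lp > best_lp:
                x, best_lp = draw, lp
        if x is None:
            raise RuntimeError(
                "could not initialize chain: 1000 prior draws all had "
                "non-finite posterior"
            )
        self.lp = best_lp
        self.x = x
        self.scale = 2.38 / math.sqrt(d)
        width = priors.hi - priors.lo
        self._chol = np.diag(width / 50.0)
        # running moments for Haario-style adaptation
        self._mean = x.copy()
        self._m2 = np.zeros((d, d))
        self._count = 1
        self.n_steps = 0
        self.n_accept = 0
        self._window_accept = 0

    def step(self) -> None:
        prop = self.x + self.scale * (self._chol @ self.rng.standard_normal(self.d))
        lp_prop = self.log_target(prop)
        if math.log(self.rng.uniform()) < lp_prop - self.lp:
            self.x, self.lp = prop, lp_prop
            self.n_accept += 1
            self._window_accept += 1
        self.n_steps += 1
        delta = self.x - self._mean
        self._count += 1
        self._mean += delta / self._count
        self._m2 += np.outer(delta, self.x - self._mean)
        if self.n_steps >= ADAPT_START and self.n_steps % ADAPT_INTERVAL == 0:
            cov = self._m2 / (self._count - 1) + COV_EPS * np.eye(self.d)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass
            rate = self._window_accept / ADAPT_INTERVAL
            self.scale *= math.exp(rate - TARGET_ACCEPT)
            self._window_accept = 0


def _chain_diagnostics(chains: list[np.ndarray], names: list[str]) -> dict:
    per_param = {}
    for j, name in enumerate(names):
        ess = sum(effective_sample_size(c[:, j]) for c in chains)
        if len(chains) >= 2:
            rhat = gelman_rubin([c[:, j] for c in chains])
        else:
            c = chains[0][:, j]
            half = len(c) // 2
            rhat = gelman_rubin([c[:half], c[half : 2 * half]])
        per_param[name] = {"ess": float(ess), "rhat": float(rhat)}
        if rhat > 1.1:
            logger.warning("R-hat for %s is %.3f (> 1.1): chains may not have converged", name, rhat)
    return per_param


def sample_posterior(
    dataset: TimeSeriesDataset,
    priors: PriorSpec,
    model: ModelSpec,
    config: RunConfig,
    fixed: dict[str, float] | None = None,
) -> PosteriorSampleSet:
    """Sample the posterior with adaptive Metropolis chains.

    Runs ``config.n_chains`` independent chains of ``config.chain_length``
    steps each, discards the burn-in fraction, concatenates the remainder and
    attaches per-parameter ESS and split-R-hat diagnostics.  Fully
    reproducible given (seed, config, data).
    """
    fixed = dict(fixed or {})
    sigma_value = None if config.estimate_sigma else config.sigma_value
    log_post, _ = _make_log_posterior(dataset, priors, model, fixed, sigma_value)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    burn = int(config.chain_length * config.burn_in_fraction)
    chains, lps_all = [], []
    total_acc = total_steps = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        walker = _AdaptiveWalker(log_post, priors, rng)
        draws = np.empty((config.chain_length, len(priors)))
        lps = np.empty(config.chain_length)
        for i in range(config.chain_length):
            walker.step()
            draws[i] = walker.x
            lps[i] = walker.lp
        chains.append(draws[burn:])
        lps_all.append(lps[burn:])
        total_acc += walker.n_accept
        total_steps += walker.n_steps
    retained = np.concatenate(chains, axis=0)
    lp_retained = np.concatenate(lps_all)
    acc = total_acc / total_steps
    diag = {
        "parameters": _chain_diagnostics(chains, priors.names),
        "acceptance_rate": float(acc),
        "n_chains": config.n_chains,
        "seed": config.seed,
    }
    return PosteriorSampleSet(
        parameter_names=list(priors.names),
        draws_sampling=retained,
        log_posterior=lp_retained,
        chains=chains,
        priors=priors,
        fixed_parameters=fixed,
        model_id=model.model_id,
        seed=config.seed,
        acceptance_rate=float(acc),
        diagnostics=diag,
        sigma_value=sigma_value,
    )


def parallel_tempering(
    dataset: TimeSeriesDataset,
    priors: PriorSpec,
    model: ModelSpec,
    config: RunConfig,
    fixed: dict[str, float] | None = None,
    swap_interval: int = 10,
) -> PosteriorSampleSet:
    """Parallel-tempered adaptive Metropolis.

    Chain ``l`` targets the likelihood raised to ``1/T_l`` times the prior;
    adjacent chains exchange states by stochastic even/odd swap moves every
    ``swap_interval`` steps.  Only the cold chain (T = 1) is returned; swap
    acceptance rates are logged in the diagnostics.
    """
    ladder = config.temperature_ladder
    if not ladder:
        raise ValueError("config.temperature_ladder required for parallel tempering")
    ladder = [float(T) for T in ladder]
    if ladder[0] != 1.0:
        raise ValueError("coldest temperature must be 1.0")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("temperature ladder must be strictly ascending")
    if len(ladder) == 1:
        # degenerate ladder: plain adaptive MH
        return sample_posterior(dataset, priors, model, config, fixed)

    fixed = dict(fixed or {})
    sigma_value = None if config.estimate_sigma else config.sigma_value
    _, log_lik = _make_log_posterior(dataset, priors, model, fixed, sigma_value)
    lo, hi = priors.lo, priors.hi

    def tempered(beta):
        def lp(x):
            if np.any(x < lo) or np.any(x > hi):
                return -np.inf
            return beta * log_lik(x)
        return lp

    betas = [1.0 / T for T in ladder]
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(len(ladder) + 1)
    swap_rng = np.random.default_rng(chain_seeds[-1])
    walkers = [
        _AdaptiveWalker(tempered(b), priors, np.random.default_rng(ss))
        for b, ss in zip(betas, chain_seeds[:-1])
    ]
    n = config.chain_length
    burn = int(n * config.burn_in_fraction)
    cold = np.empty((n, len(priors)))
    cold_lp = np.empty(n)
    n_pairs = len(ladder) - 1
    swap_attempts = np.zeros(n_pairs)
    swap_accepts = np.zeros(n_pairs)
    parity = 0
    for i in range(n):
        for w in walkers:
            w.step()
        if (i + 1) % swap_interval == 0:
            for k in range(parity, n_pairs, 2):
                a, b = walkers[k], walkers[k + 1]
                # lp = beta * loglik, so recover loglik to form the swap ratio
                ll_a = a.lp / betas[k] if np.isfinite(a.lp) else -np.inf
                ll_b = b.lp / betas[k + 1] if np.isfinite(b.lp) else -np.inf
                log_ratio = (betas[k] - betas[k + 1]) * (ll_b - ll_a)
                swap_attempts[k] += 1
                if math.log(swap_rng.uniform()) < log_ratio:
                    swap_accepts[k] += 1
                    a.x, b.x = b.x.copy(), a.x.copy()
                    a.lp, b.lp = betas[k] * ll_b, betas[k + 1] * ll_a
            parity = 1 - parity
        cold[i] = walkers[0].x
        cold_lp[i] = walkers[0].lp
    retained = cold[burn:]
    swap_rates = [
        float(sa / max(1, at)) for sa, at in zip(swap_accepts, swap_attempts)
    ]
    half = len(retained) // 2
    diag_chains = [retained[:half], retained[half : 2 * half]]
    acc = walkers[0].n_accept / walkers[0].n_steps
    diag = {
        "parameters": _chain_diagnostics(diag_chains, priors.names),
        "acceptance_rate": float(acc),
        "n_chains": 1,
        "seed": config.seed,
        "swap_rates": swap_rates,
        "temperature_ladder": ladder,
    }
    return PosteriorSampleSet(
        parameter_names=list(priors.names),
        draws_sampling=retained,
        log_posterior=cold_lp[burn:],
        chains=[retained],
        priors=priors,
        fixed_parameters=fixed,
        model_id=model.model_id,
        seed=config.seed,
        acceptance_rate=float(acc),
        diagnostics=diag,
        sigma_value=sigma_value,
    )


def effective_sample_size(chain: np.ndarray) -> float:
    """ESS = P / (1 + 2 * sum of autocorrelations), truncated by Geyer's
    initial-positive-sequence rule (stop before the first negative sum of
    adjacent autocorrelation pairs)."""
    x = np.asarray(chain, dtype=float).ravel()
    n = len(x)
    if n < 100:
        raise ValueError(f"need >= 100 draws for an ESS estimate, got {n}")
    var = np.var(x)
    if var == 0:
        warnings.warn("constant chain: ESS reported as 0", stacklevel=2)
        return 0.0
    # FFT autocovariance
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(n, n / tau))


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Split-R-hat: each chain is halved, then the classic between/within
    variance ratio is computed over all half-chains."""
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    arrays = [np.asarray(c, dtype=float).ravel() for c in chains]
    n_min = min(len(a) for a in arrays)
    if any(len(a) != n_min for a in arrays):
        logger.info("gelman_rubin: truncating chains to common length %d", n_min)
        arrays = [a[:n_min] for a in arrays]
    half = n_min // 2
    if half < 2:
        raise ValueError("chains too short for split-R-hat")
    split = []
    for a in arrays:
        split.append(a[:half])
        split.append(a[half : 2 * half])
    mat = np.stack(split)            # (m, half)
    m, n = mat.shape
    chain_means = mat.mean(axis=1)
    W = mat.var(axis=1, ddof=1).mean()
    B = n * np.var(chain_means, ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))
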