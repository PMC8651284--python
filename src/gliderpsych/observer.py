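"""Bayesian ideal observer for 2AFC texture-vs-noise discrimination.

On each trial a texture with statistic level s (0 for white noise) evokes a
percept x drawn from a Gaussian centered on s with standard deviation sigma,
truncated to the statistic's admissible range [a, b] = [-1, 1]. The observer
knows the generative model — the K-level grid of positive statistic values,
a prior with log-odds alpha = ln p(s=0)/p(s>0) splitting the texture mass
uniformly over the grid — and reports "noise" when the posterior log-odds

    D(x) = alpha + ln p(x | s=0) - ln [ (1/K) sum_k p(x | s_k) ]

is positive. D is strictly decreasing in x, so the decision rule is a
threshold at the unique root x* of D, and the psychometric function is the
truncated-Gaussian mass below x*:

    p(report noise | s) = [Phi((x*-s)/sigma) - Phi((a-s)/sigma)]
                          / [Phi((b-s)/sigma) - Phi((a-s)/sigma)].

With a single level s1 and the truncation removed, this collapses to the
classical cumulative-Normal psychometric curve
Phi[ (sigma/s1) * alpha - (s - s1/2)/sigma ].
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm, truncnorm

__all__ = [
    "ObserverParams",
    "LevelGrid",
    "default_grid",
    "percept_density",
    "percept_cdf",
    "sample_percept",
    "decision_variable",
    "decision_boundary",
    "prob_report_noise",
    "single_level_closed_form",
]


@dataclass(frozen=True)
class ObserverParams:
    """Ideal-observer parameters.

    prior_logodds : float
        alpha = ln p(noise) / p(texture); positive favors "noise" reports.
    noise_sd : float
        sigma, the perceptual noise SD in statistic units; 1/sigma is the
        observer's sensitivity.
    percept_lo, percept_hi : float
        Truncation bounds of the percept axis (the statistic range).
    """

    prior_logodds: float
    noise_sd: float
    percept_lo: float = -1.0
    percept_hi: float = 1.0

    def __post_init__(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not self.percept_lo < self.percept_hi:
            raise ValueError("percept_lo must be < percept_hi")

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.noise_sd

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "prior_logodds": self.prior_logodds,
                "noise_sd": self.noise_sd,
                "bounds": [self.percept_lo, self.percept_hi],
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ObserverParams":
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        lo, hi = obj.get("bounds", (-1.0, 1.0))
        return cls(obj["prior_logodds"], obj["noise_sd"], lo, hi)


@dataclass(frozen=True)
class LevelGrid:
    """Ordered positive statistic levels s_1 < ... < s_K in (0, 1]."""

    levels: tuple[float, ...]

    def __init__(self, levels) -> None:
        arr = np.asarray(levels, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("levels must be a nonempty 1-D sequence")
        if not ((arr > 0).all() and (arr <= 1).all()):
            raise ValueError("levels must lie in (0, 1]")
        if not (np.diff(arr) > 0).all():
            raise ValueError("levels must be strictly increasing")
        object.__setattr__(self, "levels", tuple(arr.tolist()))

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.levels)


def default_grid() -> LevelGrid:
    """The standard testing grid: 0.02 to 0.93 in steps of 0.07, plus 1."""
    return LevelGrid(np.concatenate([np.arange(0.02, 0.935, 0.07), [1.0]]))


def _std_bounds(s, params: ObserverParams):
    sd = params.noise_sd
    s = np.asarray(s, dtype=float)
    return (params.percept_lo - s) / sd, (params.percept_hi - s) / sd


def percept_density(x, s, params: ObserverParams):
    """Truncated-Gaussian percept density p(x | s); integrates to 1 on
    [percept_lo, percept_hi]."""
    a, b = _std_bounds(s, params)
    return truncnorm.pdf(x, a, b, loc=s, scale=params.noise_sd)


def percept_cdf(x, s, params: ObserverParams):
    """CDF of the percept distribution."""
    a, b = _std_bounds(s, params)
    return truncnorm.cdf(x, a, b, loc=s, scale=params.noise_sd)


def sample_percept(s, params: ObserverParams, size=None,
                   rng: np.random.Generator | int | None = None):
    """Draw percepts from the truncated Gaussian at level(s) ``s``."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b = _std_bounds(s, params)
    return truncnorm.rvs(a, b, loc=s, scale=params.noise_sd, size=size,
                         random_state=rng)


def _log_percept_density(x, s, params: ObserverParams):
    a, b = _std_bounds(s, params)
    return truncnorm.logpdf(x, a, b, loc=s, scale=params.noise_sd)


def decision_variable(x, params: ObserverParams, grid: LevelGrid):
    """Posterior log-odds D(x) of noise vs texture; strictly decreasing in x."""
    if len(grid) == 0:
        raise ValueError("empty level grid")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    log_noise = _log_percept_density(x_arr, 0.0, params)
    levels = grid.array[:, None]
    log_mix = logsumexp(
        _log_percept_density(x_arr[None, :], levels, params), axis=0
    ) - np.log(len(grid))
    d = params.prior_logodds + log_noise - log_mix
    return float(d[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else d


def decision_boundary(params: ObserverParams, grid: LevelGrid) -> float:
    """The percept threshold x* with D(x*) = 0.

    Monotonicity of D makes the root unique. If D does not change sign on
    the percept range the boundary is clamped: D > 0 everywhere -> upper
    bound (observer always says "noise"); D < 0 everywhere -> lower bound.
    """
    lo, hi = params.percept_lo, params.percept_hi
    f = lambda x: decision_variable(x, params, grid)
    d_lo, d_hi = f(lo), f(hi)
    if d_lo <= 0:  # D decreasing: max at lo
        return lo
    if d_hi >= 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def prob_report_noise(s, params: ObserverParams, grid: LevelGrid):
    """Psychometric function p(report "noise" | s); non-increasing in s."""
    xstar = decision_boundary(params, grid)
    s_arr = np.asarray(s, dtype=float)
    s_flat = np.atleast_1d(s_arr)
    p = np.atleast_1d(
        np.asarray(percept_cdf(xstar, s_flat, params), dtype=float)
    )
    # vanishing-noise limit: percept == s, report noise iff s below threshold
    bad = ~np.isfinite(p)
    if bad.any():
        p[bad] = np.where(s_flat[bad] < xstar, 1.0, 0.0)
    p = np.clip(p, 0.0, 1.0)
    return float(p[0]) if s_arr.ndim == 0 else p


def single_level_closed_form(s, s1: float, alpha: float, sigma: float):
    """Unbounded-percept psychometric curve for a single texture level s1:
    Phi[(sigma/s1) * alpha - (s - s1/2) / sigma]."""
    if not s1 > 0:
        raise ValueError(f"s1 must be > 0, got {s1}")
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    s = np.asarray(s, dtype=float)
    val = norm.cdf((sigma / s1) * alpha - (s - s1 / 2.0) / sigma)
    return float(val) if s.ndim == 0 else val
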