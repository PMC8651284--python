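"""Synthetic behavioral experiment: 2AFC sessions and the adaptive staircase.

Trial sequences mimic the discrimination task: noise and structured trials
occur with equal probability, subject to a cap on consecutive same-category
trials (forced alternation after a maximal run); structured trials carry a
statistic level drawn uniformly from the testing grid. Responses come from
the ideal observer: a truncated-Gaussian percept compared against the
decision boundary x*.

The staircase emulates the training phase in which the minimum statistic
level adapts to performance: structured levels are sampled from a geometric
distribution peaked at the current minimum, and every ten trials the
fraction correct on minimum-level trials moves the minimum down a step
(above 70% correct), up a step (below 50%), or leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import (LevelGrid, ObserverParams, decision_boundary,
                       default_grid, sample_percept)
from .psychometric import PsychometricDataset

__all__ = [
    "SessionConfig",
    "TrialRecord",
    "StaircaseConfig",
    "StaircaseResult",
    "generate_trial_sequence",
    "simulate_response",
    "simulate_session",
    "simulate_staircase",
    "trials_to_frame",
]

NOISE = "noise"
STRUCTURED = "structured"


@dataclass(frozen=True)
class SessionConfig:
    """One simulated testing session."""

    n_trials: int
    true_params: ObserverParams
    level_grid: LevelGrid = field(default_factory=default_grid)
    p_structured: float = 0.5
    max_consecutive: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.p_structured < 1:
            raise ValueError("p_structured must be in (0, 1)")
        if self.max_consecutive < 1:
            raise ValueError("max_consecutive must be >= 1")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    category: str          # "noise" | "structured"
    level: float           # 0 for noise trials
    response: str          # "noise" | "structured"
    correct: bool


def _draw_categories(n: int, p_structured: float, max_consecutive: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Bernoulli categories with forced alternation after a maximal run."""
    out = np.empty(n, dtype=bool)  # True = structured
    run_len = 0
    for i in range(n):
        if i > 0 and run_len >= max_consecutive:
            cat = not out[i - 1]
        else:
            cat = rng.random() < p_structured
        out[i] = cat
        run_len = run_len + 1 if i > 0 and out[i] == out[i - 1] else 1
    return out


def generate_trial_sequence(config: SessionConfig,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Categories (bool, True = structured) and statistic levels (0 for
    noise trials; structured levels uniform over the grid)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    structured = _draw_categories(config.n_trials, config.p_structured,
                                  config.max_consecutive, rng)
    levels = np.zeros(config.n_trials)
    n_struct = int(structured.sum())
    levels[structured] = rng.choice(config.level_grid.array, size=n_struct)
    return structured, levels


def _simulate_responses(levels: np.ndarray, params: ObserverParams,
                        grid: LevelGrid, rng: np.random.Generator,
                        xstar: float | None = None) -> np.ndarray:
    """Vector of booleans, True = "noise" report, via percept thresholding."""
    if xstar is None:
        xstar = decision_boundary(params, grid)
    percepts = sample_percept(levels, params, size=levels.shape, rng=rng)
    return percepts < xstar


def simulate_response(s: float, true_params: ObserverParams, grid: LevelGrid,
                      rng: np.random.Generator | int | None = None) -> str:
    """One ideal-observer response at level ``s``: sample a percept and
    report "noise" iff it falls below the decision boundary."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    is_noise = _simulate_responses(np.asarray([float(s)]), true_params, grid,
                                   rng)[0]
    return NOISE if is_noise else STRUCTURED


def simulate_session(config: SessionConfig
                     ) -> tuple[list[TrialRecord], PsychometricDataset]:
    """Simulate a full session; returns trial records and their per-level
    aggregate (every grid level appears in the aggregate, possibly with
    zero trials)."""
    rng = np.random.default_rng(config.seed)
    structured, levels = generate_trial_sequence(config, rng)
    noise_report = _simulate_responses(levels, config.true_params,
                                       config.level_grid, rng)
    records = []
    for i in range(config.n_trials):
        cat = STRUCTURED if structured[i] else NOISE
        resp = NOISE if noise_report[i] else STRUCTURED
        records.append(TrialRecord(index=i, category=cat,
                                   level=float(levels[i]), response=resp,
                                   correct=resp == cat))
    all_levels = np.concatenate([[0.0], config.level_grid.array])
    t = np.zeros(all_levels.size, dtype=int)
    n = np.zeros(all_levels.size, dtype=int)
    for k, lev in enumerate(all_levels):
        mask = levels == lev if lev > 0 else ~structured
        t[k] = int(mask.sum())
        n[k] = int(noise_report[mask].sum())
    dataset = PsychometricDataset.from_counts(all_levels, t, n)
    return records, dataset


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame (columns trial, category, level,
    response, correct)."""
    return pd.DataFrame({
        "trial": [r.index for r in records],
        "category": [r.category for r in records],
        "level": [r.level for r in records],
        "response": [r.response for r in records],
        "correct": [r.correct for r in records],
    })


@dataclass(frozen=True)
class StaircaseConfig:
    """Adaptive-staircase simulation settings."""

    n_trials: int = 2000
    max_level: float = 0.95
    start_min_level: float | None = None  # default: start at max_level
    step: float = 0.05
    window: int = 10
    raise_threshold: float = 0.5   # below this fraction correct -> raise min
    lower_threshold: float = 0.7   # above this fraction correct -> lower min
    geometric_p: float = 0.5
    floor_level: float = 0.02
    p_structured: float = 0.5
    max_consecutive: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.raise_threshold < self.lower_threshold < 1:
            raise ValueError("need 0 < raise_threshold < lower_threshold < 1")
        if not 0 < self.step < self.max_level:
            raise ValueError("need 0 < step < max_level")
        if not 0 < self.geometric_p < 1:
            raise ValueError("geometric_p must be in (0, 1)")
        if not 0 < self.floor_level <= self.max_level:
            raise ValueError("need 0 < floor_level <= max_level")


@dataclass(frozen=True)
class StaircaseResult:
    """Minimum-level trajectory of one staircase run."""

    min_level_trajectory: np.ndarray  # per trial, before that trial's stimulus
    final_min_level: float
    asymptote: float                  # mean min level over the last quarter

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(self.min_level_trajectory.size),
            "min_level": self.min_level_trajectory,
        })


def _staircase_levels(cfg: StaircaseConfig) -> np.ndarray:
    n_steps = int(round((cfg.max_level - cfg.floor_level) / cfg.step))
    return cfg.floor_level + cfg.step * np.arange(n_steps + 1)


def simulate_staircase(config: StaircaseConfig,
                       true_params: ObserverParams) -> StaircaseResult:
    """Run the adaptive staircase against a simulated ideal observer.

    Structured levels are sampled geometrically (success probability
    ``geometric_p`` over level indices ascending from the current minimum,
    renormalized over the finite range) so the minimum level is by far the
    most frequent. Every ``window`` trials the fraction correct on
    minimum-level structured trials within the window adjusts the minimum
    by ``step`` (down above ``lower_threshold``, up below
    ``raise_threshold``); no minimum-level trials, no update.
    """
    rng = np.random.default_rng(config.seed)
    level_set = _staircase_levels(config)
    # the observer's internal grid is the full discretized level range
    grid = LevelGrid(level_set)
    xstar = decision_boundary(true_params, grid)

    min_idx = (level_set.size - 1 if config.start_min_level is None
               else int(np.argmin(np.abs(level_set - config.start_min_level))))
    trajectory = np.empty(config.n_trials)
    window_min_trials: list[bool] = []  # correctness on min-level trials
    structured = _draw_categories(config.n_trials, config.p_structured,
                                  config.max_consecutive, rng)
    q = config.geometric_p
    for i in range(config.n_trials):
        trajectory[i] = level_set[min_idx]
        if structured[i]:
            k = level_set.size - min_idx  # available levels from min upward
            w = q * (1 - q) ** np.arange(k)
            idx = min_idx + rng.choice(k, p=w / w.sum())
            s = level_set[idx]
        else:
            idx, s = None, 0.0
        percept = sample_percept(s, true_params, rng=rng)
        says_noise = percept < xstar
        correct = says_noise == (not structured[i])
        if structured[i] and idx == min_idx:
            window_min_trials.append(bool(correct))
        if (i + 1) % config.window == 0:
            if window_min_trials:
                perf = float(np.mean(window_min_trials))
                if perf > config.lower_threshold:
                    min_idx = max(min_idx - 1, 0)
                elif perf < config.raise_threshold:
                    min_idx = min(min_idx + 1, level_set.size - 1)
            window_min_trials = []
    tail = trajectory[-max(1, config.n_trials // 4):]
    return StaircaseResult(min_level_trajectory=trajectory,
                           final_min_level=float(level_set[min_idx]),
                           asymptote=float(tail.mean()))
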