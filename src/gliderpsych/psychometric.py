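"""Maximum-likelihood fitting of the ideal-observer psychometric model.

The observed data are, for each statistic level s (including s = 0, white
noise), the number of trials T_s and the number of "noise" reports N_s.
Conditionally on (alpha, sigma) the N_s are independent Binomials with
success probability given by the ideal-observer psychometric function, so
the log likelihood is a sum of binomial terms and the two parameters are
found by bounded derivative-free maximization started from (alpha, sigma) =
(0.1, 0.4). The quantity of scientific interest is the sensitivity
1/sigma-hat.

Usage follows the model/results pattern::

    model = IdealObserverModel(dataset)
    res = model.fit()
    print(res.summary())
    res.predict([0.02, 0.3, 1.0])
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import binom

from .observer import LevelGrid, ObserverParams, prob_report_noise

__all__ = [
    "PsychometricDataset",
    "IdealObserverModel",
    "IdealObserverResults",
    "log_likelihood",
    "fit",
    "predicted_curve",
]

ALPHA_BOUNDS = (-10.0, 10.0)
SIGMA_BOUNDS = (1e-3, 10.0)
START_PARAMS = (0.1, 0.4)  # (alpha, sigma)


class PsychometricDataset:
    """Per-level response counts for one subject.

    Rows of (level, n_trials, n_noise_reports) with exactly one level-0
    (white noise) row; levels are distinct and nonnegative.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"level", "n_trials", "n_noise_reports"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        tab = table.loc[:, ["level", "n_trials", "n_noise_reports"]].copy()
        tab = tab.astype({"level": float, "n_trials": int, "n_noise_reports": int})
        tab = tab.sort_values("level").reset_index(drop=True)
        if tab["level"].duplicated().any():
            raise ValueError("levels must be distinct")
        if (tab["level"] < 0).any():
            raise ValueError("levels must be >= 0")
        if (tab["level"] == 0).sum() != 1:
            raise ValueError("dataset must contain exactly one level-0 row")
        if (tab["n_trials"] < 0).any():
            raise ValueError("n_trials must be >= 0")
        bad = (tab["n_noise_reports"] < 0) | (tab["n_noise_reports"] > tab["n_trials"])
        if bad.any():
            raise ValueError("need 0 <= n_noise_reports <= n_trials in every row")
        self.table = tab

    # -- constructors -------------------------------------------------
    @classmethod
    def from_counts(cls, levels, n_trials, n_noise_reports) -> "PsychometricDataset":
        return cls(pd.DataFrame({
            "level": levels, "n_trials": n_trials,
            "n_noise_reports": n_noise_reports,
        }))

    @classmethod
    def from_trials(cls, trials: pd.DataFrame) -> "PsychometricDataset":
        """Aggregate a trial table (columns ``level`` and ``response``, the
        latter 'noise'/'structured') into per-level counts."""
        if not {"level", "response"} <= set(trials.columns):
            raise ValueError("trial table needs 'level' and 'response' columns")
        grp = trials.groupby("level")["response"]
        tab = pd.DataFrame({
            "level": grp.count().index,
            "n_trials": grp.count().to_numpy(),
            "n_noise_reports": grp.apply(lambda r: int((r == "noise").sum())).to_numpy(),
        })
        if (tab["level"] == 0).sum() == 0:
            tab = pd.concat(
                [pd.DataFrame({"level": [0.0], "n_trials": [0],
                               "n_noise_reports": [0]}), tab],
                ignore_index=True,
            )
        return cls(tab)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PsychometricDataset":
        df = pd.read_csv(path)
        if {"level", "n_trials", "n_noise_reports"} <= set(df.columns):
            return cls(df)
        return cls.from_trials(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    # -- views --------------------------------------------------------
    @property
    def levels(self) -> np.ndarray:
        return self.table["level"].to_numpy()

    @property
    def n_trials(self) -> np.ndarray:
        return self.table["n_trials"].to_numpy()

    @property
    def n_noise_reports(self) -> np.ndarray:
        return self.table["n_noise_reports"].to_numpy()

    @property
    def grid(self) -> LevelGrid:
        """The positive levels, which the ideal observer takes as its
        texture-level grid."""
        return LevelGrid(self.levels[self.levels > 0])

    @property
    def n_total(self) -> int:
        return int(self.n_trials.sum())

    def __repr__(self) -> str:
        return (f"PsychometricDataset({len(self.table)} levels, "
                f"{self.n_total} trials)")


def log_likelihood(data: PsychometricDataset, alpha: float, sigma: float,
                   percept_bounds: tuple[float, float] = (-1.0, 1.0)) -> float:
    """Binomial log likelihood of the counts under the ideal observer.

    Returns -inf (rather than raising) when a predicted probability of 0 or
    1 contradicts the observed counts.
    """
    params = ObserverParams(alpha, sigma, *percept_bounds)
    p = prob_report_noise(data.levels, params, data.grid)
    with np.errstate(divide="ignore"):
        terms = binom.logpmf(data.n_noise_reports, data.n_trials, p)
    return float(np.sum(terms))


@dataclass
class IdealObserverResults:
    """Fit output: parameter estimates, likelihood, and diagnostics."""

    model: "IdealObserverModel"
    prior_logodds: float
    noise_sd: float
    log_likelihood: float
    converged: bool
    at_bound: bool
    n_trials_total: int
    n_function_evals: int

    @property
    def sensitivity(self) -> float:
        """1/sigma-hat, the fitted perceptual sensitivity."""
        return 1.0 / self.noise_sd

    @property
    def params(self) -> ObserverParams:
        return ObserverParams(self.prior_logodds, self.noise_sd,
                              *self.model.percept_bounds)

    @property
    def llf(self) -> float:
        return self.log_likelihood

    def predict(self, levels=None) -> np.ndarray:
        """p(report noise | s) on the given levels (default: data levels)."""
        if levels is None:
            levels = self.model.data.levels
        return np.atleast_1d(
            prob_report_noise(np.asarray(levels, float), self.params,
                              self.model.data.grid)
        )

    def bootstrap(self, n_boot: int = 200,
                  seed: int | None = None) -> pd.DataFrame:
        """Nonparametric bootstrap over trials (binomial resampling of the
        per-level counts), refitting each replicate."""
        rng = np.random.default_rng(seed)
        data = self.model.data
        t = data.n_trials
        phat = np.divide(data.n_noise_reports, np.maximum(t, 1), dtype=float)
        rows = []
        for _ in range(n_boot):
            n_new = rng.binomial(t, phat)
            boot = PsychometricDataset.from_counts(data.levels, t, n_new)
            res = IdealObserverModel(boot, self.model.percept_bounds).fit()
            rows.append((res.prior_logodds, res.noise_sd, res.sensitivity))
        return pd.DataFrame(rows, columns=["prior_logodds", "noise_sd",
                                           "sensitivity"])

    def summary(self) -> str:
        d = self.model.data
        lines = [
            "Ideal observer psychometric fit",
            "=" * 47,
            f"{'levels':<28}{len(d.table):>19d}",
            f"{'total trials':<28}{self.n_trials_total:>19d}",
            f"{'log-likelihood':<28}{self.log_likelihood:>19.4f}",
            f"{'converged':<28}{str(self.converged):>19}",
            f"{'at parameter bound':<28}{str(self.at_bound):>19}",
            "-" * 47,
            f"{'prior log-odds (alpha)':<28}{self.prior_logodds:>19.6f}",
            f"{'perceptual noise SD (sigma)':<28}{self.noise_sd:>19.6f}",
            f"{'sensitivity (1/sigma)':<28}{self.sensitivity:>19.6f}",
            "=" * 47,
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "prior_logodds": self.prior_logodds,
            "noise_sd": self.noise_sd,
            "sensitivity": self.sensitivity,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "at_bound": self.at_bound,
            "n_trials_total": self.n_trials_total,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def plot(self, ax=None):
        """Plot empirical fractions classified 'structured' with the fitted
        psychometric curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.data
        mask = d.n_trials > 0
        frac = 1.0 - d.n_noise_reports[mask] / d.n_trials[mask]
        ax.plot(d.levels[mask], frac, "ko", label="data")
        xs = np.linspace(0, max(d.levels.max(), 1.0), 200)
        ax.plot(xs, 1.0 - self.predict(xs), "b-", label="fitted model")
        ax.set_xlabel("statistic level")
        ax.set_ylabel("fraction classified as structured")
        ax.legend()
        return ax


class IdealObserverModel:
    """Two-parameter (alpha, sigma) ideal-observer psychometric model.

    Parameters
    ----------
    data : PsychometricDataset
        Per-level counts, including the white-noise (level 0) row.
    percept_bounds : (float, float)
        Truncation range of the percept axis.
    """

    def __init__(self, data: PsychometricDataset,
                 percept_bounds: tuple[float, float] = (-1.0, 1.0)) -> None:
        if not (data.levels > 0).any():
            raise ValueError("dataset needs at least one positive level")
        self.data = data
        self.percept_bounds = tuple(percept_bounds)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "IdealObserverModel":
        return cls(PsychometricDataset(df), **kwargs)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, **kwargs) -> "IdealObserverModel":
        return cls(PsychometricDataset.from_trials(trials), **kwargs)

    def loglike(self, alpha: float, sigma: float) -> float:
        return log_likelihood(self.data, alpha, sigma, self.percept_bounds)

    def fit(self, start_params: tuple[float, float] = START_PARAMS,
            alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
            sigma_bounds: tuple[float, float] = SIGMA_BOUNDS,
            ) -> IdealObserverResults:
        """Maximize the likelihood over (alpha, log sigma).

        Bounded Nelder-Mead on the log-sigma scale; non-convergence and
        boundary solutions are flagged on the result, never raised.
        """
        a0, s0 = start_params
        log_sig_bounds = (np.log(sigma_bounds[0]), np.log(sigma_bounds[1]))

        def nll(theta):
            alpha, log_sigma = theta
            val = self.loglike(alpha, float(np.exp(log_sigma)))
            return -val if np.isfinite(val) else 1e12

        res = minimize(
            nll, x0=np.array([a0, np.log(s0)]), method="Nelder-Mead",
            bounds=[alpha_bounds, log_sig_bounds],
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        alpha_hat, log_sigma_hat = res.x
        sigma_hat = float(np.exp(log_sigma_hat))
        tol = 1e-3
        at_bound = (
            min(alpha_hat - alpha_bounds[0], alpha_bounds[1] - alpha_hat) < tol
            or min(log_sigma_hat - log_sig_bounds[0],
                   log_sig_bounds[1] - log_sigma_hat) < tol
        )
        # complete separation: the likelihood plateaus and the prior-bias
        # estimate is unbounded in the limit
        d = self.data
        active = d.n_trials > 0
        if active.any():
            n, t = d.n_noise_reports[active], d.n_trials[active]
            if (n == t).all() or (n == 0).all():
                at_bound = True
        return IdealObserverResults(
            model=self,
            prior_logodds=float(alpha_hat),
            noise_sd=sigma_hat,
            log_likelihood=float(-res.fun),
            converged=bool(res.success),
            at_bound=bool(at_bound),
            n_trials_total=self.data.n_total,
            n_function_evals=int(res.nfev),
        )


def fit(data: PsychometricDataset, **kwargs) -> IdealObserverResults:
    """Convenience wrapper: fit the ideal observer to a dataset."""
    return IdealObserverModel(data).fit(**kwargs)


def predicted_curve(result: IdealObserverResults, levels) -> np.ndarray:
    """Fitted p(report noise | s) on the requested levels."""
    return result.predict(levels)
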