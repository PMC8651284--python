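"""Degree of correspondence between sensitivity vectors.

Two sets of sensitivities (1/sigma per texture statistic, so all components
are nonnegative) are compared through their cosine similarity, the "degree
of correspondence" c = u.v / (|u||v|), which lies in [0, 1] and equals 1
exactly when the vectors are proportional.

Significance is assessed against a Monte Carlo null of two random unit
vectors in the positive orthant of R^3, parameterized by spherical angles
theta, phi drawn independently and uniformly on [0, pi/2]:

    c_null = cos(theta1) cos(theta2) + cos(phi1 - phi2) sin(theta1) sin(theta2)

and the p-value is the fraction of null samples strictly exceeding the
observed c (default 10^7 samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensitivityVector",
    "CorrespondenceResult",
    "degree_of_correspondence",
    "unit_normalize",
    "sample_null_cosines",
    "monte_carlo_pvalue",
    "correspondence_test",
]

DEFAULT_N_NULL = 10_000_000


@dataclass(frozen=True)
class SensitivityVector:
    """Labeled nonnegative sensitivities (1/sigma units)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels, values) -> None:
        labels = tuple(str(x) for x in labels)
        vals = np.asarray(values, dtype=float)
        if vals.ndim != 1 or len(labels) != vals.size:
            raise ValueError("labels and values must be 1-D and equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be distinct")
        if (vals < 0).any():
            raise ValueError("sensitivities must be nonnegative")
        if not (vals > 0).any():
            raise ValueError("sensitivity vector must not be all zero")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", vals)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensitivityVector":
        df = pd.read_csv(path)
        if not {"label", "value"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns 'label,value'")
        return cls(df["label"], df["value"])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"label": self.labels, "value": self.values}).to_csv(
            path, index=False)


def unit_normalize(v: SensitivityVector) -> SensitivityVector:
    """Rescale to Euclidean norm 1, preserving direction."""
    return SensitivityVector(v.labels, v.values / v.norm)


def _as_aligned_arrays(u, v) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(u, SensitivityVector) and isinstance(v, SensitivityVector):
        if u.labels != v.labels:
            raise ValueError(
                f"label mismatch: {list(u.labels)} vs {list(v.labels)}")
        return u.values, v.values
    ua, va = np.asarray(u, dtype=float), np.asarray(v, dtype=float)
    if ua.shape != va.shape:
        raise ValueError("vectors must have equal length")
    return ua, va


def degree_of_correspondence(u, v) -> float:
    """Cosine similarity u.v / (|u||v|); scale invariant, in [0, 1] for
    nonnegative inputs."""
    ua, va = _as_aligned_arrays(u, v)
    nu, nv = np.linalg.norm(ua), np.linalg.norm(va)
    if nu == 0 or nv == 0:
        raise ValueError("cannot compare a zero vector")
    return float(np.dot(ua, va) / (nu * nv))


def sample_null_cosines(n: int, seed=None,
                        chunk: int = 1_000_000) -> np.ndarray:
    """Draw ``n`` null cosines from the positive-orthant angular null.

    Angles theta1, theta2, phi1, phi2 are i.i.d. uniform on [0, pi/2] for
    each sample; all returned values lie in [0, 1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        ang = rng.uniform(0.0, np.pi / 2.0, size=(4, m))
        t1, t2, p1, p2 = ang
        out[done:done + m] = (np.cos(t1) * np.cos(t2)
                              + np.cos(p1 - p2) * np.sin(t1) * np.sin(t2))
        done += m
    return out


def monte_carlo_pvalue(c_obs: float, n: int = DEFAULT_N_NULL,
                       seed=None) -> float:
    """Fraction of ``n`` null cosines strictly greater than ``c_obs``."""
    if not 0.0 <= c_obs <= 1.0:
        raise ValueError(f"c_obs must be in [0, 1], got {c_obs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    done = 0
    chunk = 1_000_000
    while done < n:
        m = min(chunk, n - done)
        count += int((sample_null_cosines(m, rng) > c_obs).sum())
        done += m
    return count / n


@dataclass(frozen=True)
class CorrespondenceResult:
    """Observed correspondence plus its Monte Carlo significance."""

    c: float
    p_value: float
    n_null_samples: int
    seed: int | None
    pair: tuple[str, str] | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "c": self.c, "p_value": self.p_value,
            "n_null_samples": self.n_null_samples, "seed": self.seed,
            "pair": list(self.pair) if self.pair else None,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def correspondence_test(u, v, n: int = DEFAULT_N_NULL, seed: int | None = None,
                        pair: tuple[str, str] | None = None) -> CorrespondenceResult:
    """Degree of correspondence between two sensitivity vectors with its
    positive-orthant Monte Carlo p-value."""
    c = degree_of_correspondence(u, v)
    c_clipped = min(max(c, 0.0), 1.0)
    p = monte_carlo_pvalue(c_clipped, n=n, seed=seed)
    return CorrespondenceResult(c=c, p_value=p, n_null_samples=n, seed=seed,
                                pair=pair)
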