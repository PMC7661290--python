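"""Covariate standardization shared by the survival and logistic engines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCovariateError


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return u.size <= 2 and np.all(np.isin(u, (0.0, 1.0)))


@dataclass
class ScalingRecord:
    """Per-covariate centering/scaling; binary covariates pass through.

    ``center``/``scale`` use weighted mean and *population* standard
    deviation so that e.g. values {0, 10} with equal weight map to
    {-1, +1}.  Sufficient to invert the transform and to convert fitted
    coefficients between the standardized and natural scales.
    """

    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    binary: frozenset = frozenset()

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        names: list[str],
        weights: np.ndarray | None = None,
        binary: set[str] | None = None,
    ) -> "ScalingRecord":
        X = np.asarray(X, dtype=float)
        if weights is None:
            weights = np.ones(X.shape[0])
        weights = np.asarray(weights, dtype=float)
        center: dict[str, float] = {}
        scale: dict[str, float] = {}
        flagged: set[str] = set()
        for j, name in enumerate(names):
            col = X[:, j]
            if (binary is not None and name in binary) or (
                binary is None and _is_binary(col)
            ):
                flagged.add(name)
                center[name] = 0.0
                scale[name] = 1.0
                continue
            w = weights / weights.sum()
            mu = float(np.sum(w * col))
            sd = float(np.sqrt(np.sum(w * (col - mu) ** 2)))
            if sd <= 0:
                raise DegenerateCovariateError(
                    f"covariate {name!r} has zero variance"
                )
            center[name] = mu
            scale[name] = sd
        return cls(center=center, scale=scale, binary=frozenset(flagged))

    def apply(self, X: np.ndarray, names: list[str]) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        for j, name in enumerate(names):
            X[:, j] = (X[:, j] - self.center[name]) / self.scale[name]
        return X

    def invert(self, X: np.ndarray, names: list[str]) -> np.ndarray:
        X = np.array(X, dtype=float, copy=True)
        for j, name in enumerate(names):
            X[:, j] = X[:, j] * self.scale[name] + self.center[name]
        return X

    def beta_to_natural(self, beta: np.ndarray, names: list[str]) -> np.ndarray:
        return np.asarray(beta, dtype=float) / np.array(
            [self.scale[n] for n in names]
        )

    def beta_to_standardized(self, beta: np.ndarray, names: list[str]) -> np.ndarray:
        return np.asarray(beta, dtype=float) * np.array(
            [self.scale[n] for n in names]
        )

    def to_dict(self) -> dict:
        return {
            "center": dict(self.center),
            "scale": dict(self.scale),
            "binary": sorted(self.binary),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingRecord":
        return cls(
            center=dict(d["center"]),
            scale=dict(d["scale"]),
            binary=frozenset(d["binary"]),
        )
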