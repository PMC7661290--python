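"""First-attempt commit model: logistic regression by IRLS.

The outcome is whether a fish passed fully through a fishway on its first
attempt (first fishway entry equals last fishway entry); covariates are
evaluated at the day/hour of the first fishway entry, the decision point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConvergenceError, DataError
from .records import CovariateSeries, FishRecord
from .scaling import ScalingRecord
from .survival import GROUP_COLUMNS, THRESHOLD_NAME, _check_rank, aicc_from


@dataclass
class CommitTable:
    """Per-fish binary commit outcomes with decision-time covariates."""

    y: np.ndarray
    X: np.ndarray
    covariates: list[str]
    groups: pd.DataFrame
    scaling: ScalingRecord | None = None
    raw_X: np.ndarray | None = None
    count_threshold: float | None = None
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float).reshape(len(self.y), len(self.covariates))
        if not np.all(np.isin(np.unique(self.y), (0.0, 1.0))):
            raise DataError("commit outcomes must be binary")
        if not np.all(np.isfinite(self.X)):
            raise DataError("commit covariates must be finite")

    @property
    def n(self) -> int:
        return self.y.size

    def columns(self, names: list[str]) -> np.ndarray:
        idx = [self.covariates.index(n) for n in names]
        return self.X[:, idx]


def build_commit_table(
    fish: list[FishRecord],
    cov: CovariateSeries,
    covariates: tuple[str, ...] = ("temperature", "diel", "count"),
    count_threshold: float | None = None,
) -> CommitTable:
    """Outcome 1 iff first fishway entry equals last fishway entry."""
    names = list(covariates)
    if count_threshold is not None:
        if "count" not in names:
            raise ConfigurationError("count_threshold requires the count covariate")
        names = names + [THRESHOLD_NAME]
    ys: list[float] = []
    rows: list[np.ndarray] = []
    group_rows: list[dict] = []
    exclusions: dict[str, int] = {}
    for f in fish:
        if f.t_first_fishway_entry is None or f.t_last_fishway_entry is None:
            exclusions["missing_timestamp"] = exclusions.get("missing_timestamp", 0) + 1
            continue
        t = f.t_first_fishway_entry
        try:
            vals = [
                float(cov.value(name, t, dam=f.dam, species=f.species)[0])
                for name in covariates
            ]
        except DataError as exc:
            raise DataError(f"fish {f.fish_id}: {exc}") from exc
        if count_threshold is not None:
            count_val = vals[list(covariates).index("count")]
            vals.append(1.0 if count_val <= count_threshold else 0.0)
        ys.append(1.0 if f.t_first_fishway_entry == f.t_last_fishway_entry else 0.0)
        rows.append(np.array(vals))
        group_rows.append(
            {
                "fish_id": f.fish_id,
                "species": f.species,
                "run": f.run,
                "dam": f.dam,
                "fishway": f.fishway,
                "entry_hour": t,
            }
        )
    X = np.vstack(rows) if rows else np.zeros((0, len(names)))
    return CommitTable(
        y=np.asarray(ys),
        X=X,
        covariates=names,
        groups=pd.DataFrame(group_rows, columns=GROUP_COLUMNS),
        count_threshold=count_threshold,
        exclusions=exclusions,
    )


def standardize_commit(
    table: CommitTable, binary: set[str] | None = None
) -> tuple[CommitTable, ScalingRecord]:
    """Unweighted analogue of the survival-engine standardization."""
    base = table.raw_X if table.raw_X is not None else table.X
    record = ScalingRecord.fit(base, table.covariates, binary=binary)
    out = replace(table, X=record.apply(base, table.covariates))
    out.raw_X = base.copy()
    out.scaling = record
    return out, record


@dataclass
class LogisticFit:
    """Fitted commit model (log-odds per standardized covariate)."""

    covariates: list[str]  # without the intercept
    beta: np.ndarray  # intercept first when present
    cov_matrix: np.ndarray
    loglik: float
    aicc: float
    n: int
    scaling: ScalingRecord | None
    intercept: bool
    n_iter: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_matrix))

    def coefficient(self, name: str) -> float:
        offset = 1 if self.intercept else 0
        return float(self.beta[self.covariates.index(name) + offset])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        eta = X @ self.beta
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n": self.n,
            "scaling": None if self.scaling is None else self.scaling.to_dict(),
        }


def fit_logistic(
    table: CommitTable,
    covariate_set: list[str] | None = None,
    intercept: bool = True,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
) -> LogisticFit:
    """Maximum likelihood via iteratively reweighted least squares."""
    names = list(table.covariates) if covariate_set is None else list(covariate_set)
    missing = [n for n in names if n not in table.covariates]
    if missing:
        raise ConfigurationError(f"unknown covariates: {missing}")
    y = table.y
    if y.size == 0:
        raise DataError("empty commit table")
    if np.all(y == y[0]):
        raise DataError("single-class outcome: cannot fit logistic model")
    X = table.columns(names)
    if names:
        _check_rank(X, names)
    D = np.column_stack([np.ones(y.size), X]) if intercept else X
    if D.shape[1] == 0:
        raise ConfigurationError("model has no parameters")
    beta = np.zeros(D.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        grad = D.T @ (y - p)
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        H = (D * W[:, None]).T @ D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular IRLS system: {exc}") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            raise ConvergenceError(
                "coefficients diverged (|beta| > 30): complete separation suspected"
            )
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = D @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    W = p * (1.0 - p)
    H = (D * W[:, None]).T @ D
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2.0
    k = D.shape[1]
    return LogisticFit(
        covariates=names,
        beta=beta,
        cov_matrix=cov,
        loglik=loglik,
        aicc=aicc_from(loglik, k, y.size),
        n=y.size,
        scaling=table.scaling,
        intercept=intercept,
        n_iter=n_iter,
        converged=converged,
    )


def predict_commit_rate(
    fit: LogisticFit,
    table: CommitTable,
    density_factor: float = 1.0,
    count_name: str = "count",
) -> float:
    """Mean predicted commit probability after rescaling counts by a factor.

    The raw count covariate is multiplied by ``density_factor``,
    re-standardized with the fit's stored ScalingRecord, the threshold
    indicator (if present) recomputed, and the inverse-logit averaged over
    the supplied covariate rows.
    """
    if density_factor < 0:
        raise ConfigurationError("density_factor must be >= 0")
    raw = table.raw_X if table.raw_X is not None else table.X
    raw = np.array(raw, copy=True)
    names = table.covariates
    if count_name in names and density_factor != 1.0:
        j = names.index(count_name)
        raw[:, j] = raw[:, j] * density_factor
        if THRESHOLD_NAME in names and table.count_threshold is not None:
            raw[:, names.index(THRESHOLD_NAME)] = (
                raw[:, j] <= table.count_threshold
            ).astype(float)
    if fit.scaling is not None:
        Xs = fit.scaling.apply(raw, names)
    else:
        Xs = raw
    idx = [names.index(n) for n in fit.covariates]
    return float(np.mean(fit.predict_proba(Xs[:, idx])))
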