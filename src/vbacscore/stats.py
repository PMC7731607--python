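"""Statistical kernel for the validation pipeline.

Self-contained implementations of the procedures the evaluation uses:

* binary logistic regression by iteratively reweighted least squares
  (IRLS), all predictors entered simultaneously ("enter method"), with
  Wald standard errors from the inverse observed information;
* ROC curve and AUC under the Mann-Whitney convention (ties count 1/2),
  oriented so that a higher score predicts success;
* stratified percentile-bootstrap confidence interval for the AUC;
* two-sample t procedures from summary statistics (pooled by default,
  Welch optional), so intervals can be reproduced from published
  means/SDs/ns without raw data;
* Pearson chi-square test of independence on r x c count tables.

scipy supplies only reference distributions (normal, t, chi-square); the
estimators themselves live here so every numerical choice is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as spstats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "RocResult",
    "TwoSampleResult",
    "ChiSquareResult",
    "SeparationError",
    "ConvergenceError",
    "fit_logistic",
    "roc_auc",
    "auc_bootstrap_ci",
    "two_sample_t",
    "chi_square",
]


class SeparationError(RuntimeError):
    """A covariate (or combination) perfectly separates the outcomes.

    The logistic MLE does not exist in this case; the offending covariate
    is named when a single column is responsible.
    """


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the score-norm tolerance within the iteration cap."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    Odds ratios are ``exp(coefficients)``; confidence intervals are Wald
    intervals on the log-odds scale, exponentiated for the OR columns.
    """

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    n_iter: int
    log_likelihood: float
    n_obs: int
    alpha: float = 0.05

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def wald_z(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    @property
    def wald_p_values(self) -> np.ndarray:
        return 2.0 * spstats.norm.sf(np.abs(self.wald_z))

    @property
    def conf_int(self) -> np.ndarray:
        """(k, 2) Wald interval bounds on the log-odds scale."""
        z = spstats.norm.ppf(1.0 - self.alpha / 2.0)
        half = z * self.standard_errors
        return np.column_stack([self.coefficients - half, self.coefficients + half])

    @property
    def or_conf_int(self) -> np.ndarray:
        return np.exp(self.conf_int)

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.coef(name)))

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])

    def to_dict(self) -> dict:
        ci = self.or_conf_int
        return {
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
            "terms": {
                name: {
                    "coefficient": float(self.coefficients[i]),
                    "standard_error": float(self.standard_errors[i]),
                    "odds_ratio": float(np.exp(self.coefficients[i])),
                    "or_ci_low": float(ci[i, 0]),
                    "or_ci_high": float(ci[i, 1]),
                    "p_value": float(self.wald_p_values[i]),
                }
                for i, name in enumerate(self.names)
            },
        }


def _check_single_covariate_separation(X: np.ndarray, y: np.ndarray,
                                       names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        pos, neg = col[y == 1], col[y == 0]
        if pos.min() > neg.max() or pos.max() < neg.min():
            raise SeparationError(
                f"covariate {name!r} perfectly separates the outcomes; "
                "the maximum-likelihood estimate does not exist")


def fit_logistic(X, y, names: Optional[Sequence[str]] = None,
                 add_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 100, alpha: float = 0.05) -> LogisticFit:
    """Fit outcome ~ covariates by IRLS (Newton-Raphson on the log-likelihood).

    Parameters
    ----------
    X : (n, k) array-like
        Covariate matrix, without an intercept column unless
        ``add_intercept=False``.
    y : (n,) array-like of 0/1
        Binary outcomes; both classes must be present.
    tol : float
        Convergence tolerance on the max-norm of the score (gradient).
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`.

    Step-halving guards the Newton update so the log-likelihood never
    decreases.  Perfect separation by a single covariate is detected up
    front and reported by name; joint separation surfaces as divergence.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class; logistic fit undefined")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    names = list(names)
    if len(names) != k:
        raise ValueError("names length does not match number of columns")

    _check_single_covariate_separation(X, y, names)
    if add_intercept:
        if np.any(np.ptp(X, axis=0) == 0):
            bad = [names[j] for j in np.flatnonzero(np.ptp(X, axis=0) == 0)]
            raise ValueError(f"constant covariate column(s) {bad} are collinear "
                             "with the intercept")
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    ll = _loglik(y, eta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(eta)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            n_iter -= 1
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {n_iter}: {exc}") from exc
        # step-halving: never accept a step that lowers the log-likelihood
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            cand_ll = _loglik(y, X @ cand)
            if cand_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, eta, ll = cand, X @ cand, cand_ll
    else:
        p = expit(eta)
        score_norm = float(np.max(np.abs(X.T @ (y - p))))
        if np.max(np.abs(beta)) > 25.0:
            raise SeparationError(
                "coefficients diverging (max |beta| "
                f"{np.max(np.abs(beta)):.1f} after {max_iter} iterations); "
                "data are likely separated")
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(score max-norm {score_norm:.3e}, tolerance {tol:g})")

    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(names=names, coefficients=beta, standard_errors=se,
                       converged=True, n_iter=n_iter, log_likelihood=float(ll),
                       n_obs=n, alpha=alpha)


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class RocResult:
    """ROC curve points and Mann-Whitney AUC.

    At threshold t the rule predicts success when score >= t; thresholds
    descend so the curve runs from (0, 0) to (1, 1) in (1-specificity,
    sensitivity) space.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "thresholds": [float(t) for t in self.thresholds],
            "sensitivities": self.sensitivities.tolist(),
            "specificities": self.specificities.tolist(),
        }


def _mann_whitney_auc(scores: np.ndarray, y: np.ndarray) -> float:
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = spstats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_auc(scores, outcomes) -> RocResult:
    """ROC curve of a score against a binary outcome (success coded 1).

    The AUC is the probability that a randomly chosen success outscores a
    randomly chosen failure, ties counting one half; the trapezoidal
    integral of the returned curve equals it identically.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(outcomes, dtype=float).ravel()
    if scores.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("ROC undefined with a single outcome class")

    auc = _mann_whitney_auc(scores, y)
    n1, n0 = y.sum(), (1 - y).sum()
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (y == 1)).sum() / n1
        spec[i] = (~pred & (y == 0)).sum() / n0
    return RocResult(thresholds=thresholds, sensitivities=sens,
                     specificities=spec, auc=auc)


def auc_bootstrap_ci(scores, outcomes, n_boot: int = 2000, alpha: float = 0.05,
                     seed: Optional[int] = None) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC.

    Successes and failures are resampled separately (case resampling
    within outcome class), so every resample retains both classes.
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for a stable percentile interval")
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(outcomes, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("bootstrap CI undefined with a single outcome class")
    rng = np.random.default_rng(seed)
    s1, s0 = scores[y == 1], scores[y == 0]
    n1, n0 = len(s1), len(s0)
    aucs = np.empty(n_boot)
    yy = np.concatenate([np.ones(n1), np.zeros(n0)])
    for b in range(n_boot):
        rs = np.concatenate([rng.choice(s1, n1, replace=True),
                             rng.choice(s0, n0, replace=True)])
        aucs[b] = _mann_whitney_auc(rs, yy)
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


@dataclass
class TwoSampleResult:
    """Two-sample comparison of means from summary statistics."""

    mean_diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mean_diff", "ci_low", "ci_high", "t_stat", "df", "p_value", "method")}


def two_sample_t(mean_a: float, sd_a: float, n_a: int,
                 mean_b: float, sd_b: float, n_b: int,
                 alpha: float = 0.05, method: str = "pooled") -> TwoSampleResult:
    """t-test and CI for a difference in means, from summary statistics.

    ``method="pooled"`` (default) assumes equal variances with
    df = n_a + n_b − 2; ``method="welch"`` uses the Welch-Satterthwaite
    approximation.  Operating on summaries lets published mean±SD tables
    be checked directly.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if method not in ("pooled", "welch"):
        raise ValueError("method must be 'pooled' or 'welch'")
    diff = mean_a - mean_b
    if method == "pooled":
        sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        df = float(n_a + n_b - 2)
    else:
        va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    t_stat = diff / se
    p = 2.0 * spstats.t.sf(abs(t_stat), df)
    half = spstats.t.ppf(1.0 - alpha / 2.0, df) * se
    return TwoSampleResult(mean_diff=float(diff), ci_low=float(diff - half),
                           ci_high=float(diff + half), t_stat=float(t_stat),
                           df=float(df), p_value=float(p), method=method)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}


def chi_square(table, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default; ``yates=True`` applies the
    standard |O−E|−0.5 correction (2x2 tables only).
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (O < 0).any():
        raise ValueError("counts must be nonnegative")
    rows, cols = O.sum(axis=1), O.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal row/column makes expected counts undefined")
    E = np.outer(rows, cols) / O.sum()
    dev = np.abs(O - E)
    if yates:
        if O.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChiSquareResult(statistic=stat, df=df,
                           p_value=float(spstats.chi2.sf(stat, df)))
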