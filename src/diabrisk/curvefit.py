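"""Seven-pattern least-squares dose-response fitting with regression diagnostics.

The seven candidate shapes are the classic SPSS "curve estimation" family:

======================  =============================  =================
pattern                 response-scale form            fitting scale
======================  =============================  =================
``linear``              y = b0 + b1 x                  y
``logarithmic``         y = b0 + b1 ln x               y
``quadratic``           y = b0 + b1 x + b2 x^2         y
``cubic``               y = b0 + ... + b3 x^3          y
``power``               y = b0 x^b1                    ln y
``s``                   y = exp(b0 + b1 / x)           ln y
``exponential``         y = b0 exp(b1 x)               ln y
======================  =============================  =================

Power, S and exponential are linearised by taking logs of the response and
fitted by ordinary least squares on that scale; all diagnostics (R², F,
adjusted R², SEE, Durbin-Watson) are reported on the fitting scale, which is
why their standard errors of estimate are an order of magnitude smaller than
the polynomial ones on the same data.

Model quality is summarised by R² = SS_M/SS_T, the F ratio MS_M/MS_R with its
p-value, two shrinkage-adjusted R² values (Wherry's, estimating population
fit, and Stein's, estimating cross-validated fit), the standard error of
estimate, and the Durbin-Watson serial-correlation statistic on the residuals
taken in ascending factor order.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .evidence import DoseResponseDataset

__all__ = [
    "PATTERN_NAMES",
    "FitStats",
    "FittedCurve",
    "fit_pattern",
    "fit_all",
    "select_best",
    "predict",
    "compute_fit_stats",
    "adjusted_stats",
    "durbin_watson",
]

logger = logging.getLogger(__name__)

#: Canonical pattern order; also the final tie-break order in select_best.
PATTERN_NAMES = (
    "linear",
    "logarithmic",
    "quadratic",
    "cubic",
    "power",
    "s",
    "exponential",
)


@dataclass(frozen=True)
class _PatternDef:
    name: str
    n_coef: int
    needs_positive_x: bool
    needs_positive_y: bool
    log_response: bool
    design: Callable[[np.ndarray], np.ndarray]  # columns beyond the intercept
    evaluate: Callable[[Sequence[float], np.ndarray], np.ndarray]  # response scale
    # map OLS solution on the fitting scale -> stored coefficients and back
    from_ols: Callable[[np.ndarray], tuple[float, ...]]
    to_linear_predictor: Callable[[Sequence[float], np.ndarray], np.ndarray]


def _lin_design(cols: Callable[[np.ndarray], list[np.ndarray]]):
    def f(x: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones_like(x)] + cols(x))

    return f


_PATTERNS: dict[str, _PatternDef] = {}


def _register(p: _PatternDef) -> None:
    _PATTERNS[p.name] = p


_register(
    _PatternDef(
        "linear", 2, False, False, False,
        _lin_design(lambda x: [x]),
        lambda b, x: b[0] + b[1] * x,
        lambda c: (float(c[0]), float(c[1])),
        lambda b, x: b[0] + b[1] * x,
    )
)
_register(
    _PatternDef(
        "logarithmic", 2, True, False, False,
        _lin_design(lambda x: [np.log(x)]),
        lambda b, x: b[0] + b[1] * np.log(x),
        lambda c: (float(c[0]), float(c[1])),
        lambda b, x: b[0] + b[1] * np.log(x),
    )
)
_register(
    _PatternDef(
        "quadratic", 3, False, False, False,
        _lin_design(lambda x: [x, x**2]),
        lambda b, x: b[0] + b[1] * x + b[2] * x**2,
        lambda c: tuple(float(v) for v in c),
        lambda b, x: b[0] + b[1] * x + b[2] * x**2,
    )
)
_register(
    _PatternDef(
        "cubic", 4, False, False, False,
        _lin_design(lambda x: [x, x**2, x**3]),
        lambda b, x: b[0] + b[1] * x + b[2] * x**2 + b[3] * x**3,
        lambda c: tuple(float(v) for v in c),
        lambda b, x: b[0] + b[1] * x + b[2] * x**2 + b[3] * x**3,
    )
)
# power: ln y = ln b0 + b1 ln x; b0 stored on the response scale
_register(
    _PatternDef(
        "power", 2, True, True, True,
        _lin_design(lambda x: [np.log(x)]),
        lambda b, x: b[0] * x ** b[1],
        lambda c: (float(np.exp(c[0])), float(c[1])),
        lambda b, x: np.log(b[0]) + b[1] * np.log(x),
    )
)
# s: ln y = b0 + b1 / x; both coefficients live on the log scale
_register(
    _PatternDef(
        "s", 2, True, True, True,
        _lin_design(lambda x: [1.0 / x]),
        lambda b, x: np.exp(b[0] + b[1] / x),
        lambda c: (float(c[0]), float(c[1])),
        lambda b, x: b[0] + b[1] / x,
    )
)
# exponential: ln y = ln b0 + b1 x; b0 stored on the response scale
_register(
    _PatternDef(
        "exponential", 2, False, True, True,
        _lin_design(lambda x: [x]),
        lambda b, x: b[0] * np.exp(b[1] * x),
        lambda c: (float(np.exp(c[0])), float(c[1])),
        lambda b, x: np.log(b[0]) + b[1] * x,
    )
)


@dataclass(frozen=True)
class FitStats:
    """Diagnostic block of one least-squares fit (on the fitting scale)."""

    r_squared: float
    wherry_adj: float
    stein_adj: float
    see: float
    f_ratio: float
    p_value: float
    durbin_watson: float
    n: int
    k_predictors: int


@dataclass(frozen=True)
class FittedCurve:
    """A fitted pattern: name, coefficients (b0..bk) and diagnostics."""

    pattern: str
    coefficients: tuple[float, ...]
    n_points: int
    stats: FitStats
    factor_name: str = ""
    complication_name: str = ""
    domain: tuple[float, float] = (-math.inf, math.inf)

    def predict(self, factor_value: float | np.ndarray) -> float | np.ndarray:
        return predict(self, factor_value)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        d["domain"] = list(self.domain)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCurve":
        stats = FitStats(**d["stats"])
        return cls(
            pattern=d["pattern"],
            coefficients=tuple(d["coefficients"]),
            n_points=int(d["n_points"]),
            stats=stats,
            factor_name=d.get("factor_name", ""),
            complication_name=d.get("complication_name", ""),
            domain=tuple(d.get("domain", (-math.inf, math.inf))),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson statistic: sum of squared successive residual
    differences over the residual sum of squares.

    Lies in [0, 4]; 2 means uncorrelated errors, and the conventional
    acceptance band for independent errors is 1.5-2.5. The residuals must be
    supplied in the dataset's row order (ascending factor value here), since
    serial correlation is only defined relative to an ordering.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("Durbin-Watson needs at least 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise ValueError("Durbin-Watson is undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def adjusted_stats(
    r_squared: float, n: int, k_predictors: int
) -> tuple[float, float, float]:
    """(Wherry adjusted R², Stein adjusted R², F ratio) from a bare R².

    Wherry: 1 - (1-R²)(n-1)/(n-k-1), the population-shrinkage estimate.
    Stein: 1 - [(n-1)/(n-k-1)][(n-2)/(n-k-2)][(n+1)/n](1-R²), the
    cross-validation estimate (always the smaller of the two for n > k+2).
    F: (R²/k) / ((1-R²)/(n-k-1)) = MS_M/MS_R.
    """
    k = int(k_predictors)
    if n <= k + 2:
        raise ValueError(f"need n > k+2 (n={n}, k={k})")
    dfr = n - k - 1
    miss = 1.0 - r_squared
    wherry = 1.0 - miss * (n - 1) / dfr
    stein = 1.0 - ((n - 1) / dfr) * ((n - 2) / (n - k - 2)) * ((n + 1) / n) * miss
    f_ratio = math.inf if miss <= 0 else (r_squared / k) / (miss / dfr)
    return wherry, stein, f_ratio


def compute_fit_stats(
    observed: Sequence[float],
    predicted: Sequence[float],
    k_predictors: int,
) -> FitStats:
    """Full diagnostic block from observed and predicted responses.

    R² = SS_M/SS_T with SS_M the model (explained) sum of squares about the
    observed mean; F = MS_M/MS_R = (R²/k) / ((1-R²)/(n-k-1)), with its
    p-value from the F(k, n-k-1) distribution; Wherry's adjusted
    R² = 1 - (1-R²)(n-1)/(n-k-1); Stein's cross-validation estimate
    1 - [(n-1)/(n-k-1)][(n-2)/(n-k-2)][(n+1)/n](1-R²); SEE = sqrt(SS_R/(n-k-1)).

    The Durbin-Watson statistic is computed on the residuals in input order;
    callers are responsible for supplying observations in the ordering that
    serial correlation should be judged against (ascending factor value for
    dose-response fits). A perfect fit has no residual sequence to correlate
    and is reported as DW = 0.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    k = int(k_predictors)
    if n <= k + 2:
        raise ValueError(f"need n > k+2 observations (n={n}, k={k})")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("constant response: total sum of squares is zero")
    ssr = float(np.sum((y - yhat) ** 2))
    ssm = float(np.sum((yhat - y.mean()) ** 2))
    r2 = ssm / sst
    dfm, dfr = k, n - k - 1
    wherry, stein, f_ratio = adjusted_stats(r2, n, k)
    p_value = 0.0 if math.isinf(f_ratio) else float(sps.f.sf(f_ratio, dfm, dfr))
    see = math.sqrt(ssr / dfr)
    resid = y - yhat
    dw = durbin_watson(resid) if np.any(resid != 0) else 0.0
    return FitStats(
        r_squared=r2,
        wherry_adj=wherry,
        stein_adj=stein,
        see=see,
        f_ratio=f_ratio,
        p_value=p_value,
        durbin_watson=dw,
        n=n,
        k_predictors=k,
    )


def _check_domain(p: _PatternDef, x: np.ndarray, y: np.ndarray) -> None:
    if p.needs_positive_x and np.any(x <= 0):
        bad = float(x[x <= 0][0])
        raise ValueError(
            f"pattern '{p.name}' requires strictly positive factor values; "
            f"offending value {bad}"
        )
    if p.needs_positive_y and np.any(y <= 0):
        bad = float(y[y <= 0][0])
        raise ValueError(
            f"pattern '{p.name}' requires strictly positive risks (log-scale "
            f"fit); offending risk {bad}"
        )


def fit_pattern(dataset: DoseResponseDataset, pattern: str) -> FittedCurve:
    """Fit one pattern to a dataset by ordinary least squares.

    Log-response patterns (power, s, exponential) are fitted on ln(risk);
    diagnostics are reported on that fitting scale. Residuals for the
    Durbin-Watson statistic are taken in ascending factor order, the order
    the datasets are stored in.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERN_NAMES}")
    p = _PATTERNS[pattern]
    x, y = dataset.x, dataset.y
    if x.size < p.n_coef + 1:
        raise ValueError(
            f"pattern '{pattern}' needs at least {p.n_coef + 1} points, got {x.size}"
        )
    _check_domain(p, x, y)
    resp = np.log(y) if p.log_response else y
    X = p.design(x)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for pattern '{pattern}' (e.g. duplicated "
            "factor values spanning too few distinct locations)"
        )
    sol, *_ = np.linalg.lstsq(X, resp, rcond=None)
    coefs = p.from_ols(sol)
    fitted = X @ sol
    stats = compute_fit_stats(resp, fitted, k_predictors=p.n_coef - 1)
    return FittedCurve(
        pattern=pattern,
        coefficients=coefs,
        n_points=int(x.size),
        stats=stats,
        factor_name=dataset.factor_name,
        complication_name=dataset.complication_name,
        domain=(float(x.min()), float(x.max())),
    )


def fit_all(dataset: DoseResponseDataset) -> list[FittedCurve]:
    """Fit every applicable pattern; inapplicable ones are skipped with a warning."""
    fits: list[FittedCurve] = []
    for name in PATTERN_NAMES:
        try:
            fits.append(fit_pattern(dataset, name))
        except ValueError as exc:
            logger.warning(
                "skipping pattern %s for %s-%s: %s",
                name, dataset.factor_name, dataset.complication_name, exc,
            )
    return fits


def select_best(fits: Sequence[FittedCurve]) -> FittedCurve:
    """Pick the best fit by Wherry's adjusted R².

    The adjustment penalises the extra coefficients of the polynomial
    patterns, so a cubic is not preferred over a simpler shape merely for
    chasing noise in a 16-point table; on the reference tables this ranking
    reproduces the published pattern choices where raw R² would not.
    Ties break toward fewer coefficients, then toward the canonical pattern
    order. Values are compared across fitting scales directly, matching how
    the pattern family is conventionally ranked.
    """
    if not fits:
        raise ValueError("select_best requires at least one fit")
    order = {name: i for i, name in enumerate(PATTERN_NAMES)}
    # round away float dust so exact ties resolve by parsimony, not noise
    return max(
        fits,
        key=lambda f: (
            round(f.stats.wherry_adj, 12),
            -len(f.coefficients),
            -order[f.pattern],
        ),
    )


def predict(curve: FittedCurve, factor_value: float | np.ndarray) -> float | np.ndarray:
    """Evaluate a fitted curve on the response (risk percent) scale."""
    p = _PATTERNS[curve.pattern]
    x = np.asarray(factor_value, dtype=float)
    if p.needs_positive_x and np.any(x <= 0):
        raise ValueError(
            f"pattern '{curve.pattern}' is undefined at non-positive factor values"
        )
    out = p.evaluate(curve.coefficients, x)
    if np.ndim(factor_value) == 0:
        return float(out)
    return out
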