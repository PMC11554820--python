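"""Demographic regression norms and single-case inference.

The global score of a healthy examinee is modelled by ordinary least squares
on demographic predictors (age, education, cognitive reserve, sex).  An
individual's observed score is then compared with the score predicted for a
person with the same demographics using the Crawford-Garthwaite single-case
method: the discrepancy is referred to a t distribution with the
new-observation standard error

    se = s * sqrt(1 + x0' (X'X)^-1 x0),      df = n - k - 1,

so the one-tailed p can be read as the proportion of the healthy population
expected to score as low or lower.  Cut-offs invert the same statistic.

Model selection among nested predictor sets uses the Gaussian full-likelihood
Akaike Information Criterion

    AIC = n ln(2 pi RSS / n) + n + 2 (k + 2),

the convention of mainstream statistical environments (only AIC differences
are meaningful).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    ComputationError,
    DegenerateModelError,
    ValidationError,
)
from .session_io import NormativeTable

__all__ = [
    "ExamineeRecord",
    "NormativeModel",
    "SingleCaseResult",
    "fit_normative_model",
    "model_aic",
    "select_model",
    "single_case_test",
    "cutoff_score",
    "DEFAULT_PREDICTORS",
    "CANDIDATE_LADDER",
]

DEFAULT_PREDICTORS = ("age", "education", "cr", "sex")

#: The nested one-predictor-at-a-time ladder used for AIC selection.
CANDIDATE_LADDER = (
    ("age",),
    ("age", "education"),
    ("age", "education", "cr"),
    ("age", "education", "cr", "sex"),
)

#: Numeric coding of sex; configurable because the reported coefficient sign
#: depends on it (F = 0, M = 1 by default).
DEFAULT_SEX_CODING = {"F": 0.0, "M": 1.0}


@dataclass
class ExamineeRecord:
    """Demographics (and optionally the observed total) for one person."""

    age: float
    education: float
    sex: str = "F"
    cr: float = 100.0
    observed_total: float | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(f"age {self.age} below 18")
        if self.education < 0:
            raise ValidationError(f"education {self.education} negative")
        if self.cr <= 0:
            raise ValidationError(f"cr {self.cr} not positive")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex {self.sex!r} not in {{F, M}}")


@dataclass
class NormativeModel:
    """Fitted OLS norms with everything needed for new-case inference."""

    predictor_names: tuple[str, ...]
    beta: np.ndarray                 # intercept first
    residual_sd: float
    xtx_inverse: np.ndarray          # (k+1) x (k+1), intercept included
    n: int
    r_squared: float
    rss: float
    beta_p: np.ndarray = field(default=None)
    f_stat: float = float("nan")
    f_p: float = float("nan")
    sex_coding: dict = field(default_factory=lambda: dict(DEFAULT_SEX_CODING))

    @property
    def k(self) -> int:
        return len(self.predictor_names)

    @property
    def df(self) -> int:
        return self.n - self.k - 1

    @property
    def aic(self) -> float:
        return model_aic(self)

    def design_vector(self, case: ExamineeRecord) -> np.ndarray:
        vals = {"age": case.age, "education": case.education, "cr": case.cr,
                "sex": self.sex_coding[case.sex]}
        return np.array([1.0] + [vals[p] for p in self.predictor_names])

    def predict(self, case: ExamineeRecord) -> float:
        return float(self.design_vector(case) @ self.beta)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "predictor_names": list(self.predictor_names),
            "beta": self.beta.tolist(),
            "residual_sd": self.residual_sd,
            "xtx_inverse": self.xtx_inverse.tolist(),
            "n": self.n,
            "r_squared": self.r_squared,
            "rss": self.rss,
            "beta_p": None if self.beta_p is None else self.beta_p.tolist(),
            "f_stat": self.f_stat,
            "f_p": self.f_p,
            "sex_coding": self.sex_coding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            beta=np.asarray(d["beta"], dtype=float),
            residual_sd=float(d["residual_sd"]),
            xtx_inverse=np.asarray(d["xtx_inverse"], dtype=float),
            n=int(d["n"]),
            r_squared=float(d["r_squared"]),
            rss=float(d["rss"]),
            beta_p=None if d.get("beta_p") is None
            else np.asarray(d["beta_p"], dtype=float),
            f_stat=float(d.get("f_stat", float("nan"))),
            f_p=float(d.get("f_p", float("nan"))),
            sex_coding=d.get("sex_coding", dict(DEFAULT_SEX_CODING)),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "NormativeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SingleCaseResult:
    predicted: float
    discrepancy: float
    t_stat: float
    df: int
    p_one_tailed: float
    p_two_tailed: float
    percentile: float
    below_cutoff: bool
    alpha: float


def _design_frame(table, predictors, sex_coding) -> tuple[pd.DataFrame, pd.Series]:
    df = table.valid() if isinstance(table, NormativeTable) else table
    cols = {}
    for p in predictors:
        if p == "sex":
            cols[p] = df["sex"].map(sex_coding).astype(float)
        else:
            cols[p] = pd.to_numeric(df[p], errors="coerce")
    X = pd.DataFrame(cols, index=df.index)
    y = pd.to_numeric(df["total"], errors="coerce")
    keep = X.notna().all(axis=1) & y.notna()   # listwise deletion
    return X[keep], y[keep]


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    out = []
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        others = np.column_stack(
            [np.ones(len(arr))] + [arr[:, i] for i in range(arr.shape[1]) if i != j]
        )
        resid = arr[:, j] - others @ np.linalg.lstsq(others, arr[:, j], rcond=None)[0]
        denom = np.var(arr[:, j]) * len(arr)
        if denom == 0 or resid @ resid < 1e-10 * max(denom, 1.0):
            out.append(name)
    return out


def fit_normative_model(
    table,
    predictors=DEFAULT_PREDICTORS,
    sex_coding: dict | None = None,
    min_rows: int = 30,
) -> NormativeModel:
    """Fit OLS norms for the total score on demographic predictors.

    Accepts a :class:`NormativeTable` or a plain DataFrame with the same
    columns.  Rows with missing predictors are dropped listwise.
    """
    predictors = tuple(predictors)   # () = intercept-only (predicts the mean)
    sex_coding = dict(sex_coding or DEFAULT_SEX_CODING)
    X, y = _design_frame(table, predictors, sex_coding)
    n = len(X)
    if n < max(min_rows, len(predictors) + 2):
        raise ComputationError(f"only {n} complete rows; need >= {min_rows}")
    Xd = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise CollinearityError(_collinear_columns(X) or list(predictors))
    res = sm.OLS(y.to_numpy(), Xd.to_numpy()).fit()
    k = len(predictors)
    rss = float(res.ssr)
    resid_sd = math.sqrt(rss / (n - k - 1)) if n > k + 1 else 0.0
    return NormativeModel(
        predictor_names=tuple(predictors),
        beta=res.params.copy(),
        residual_sd=resid_sd,
        xtx_inverse=np.linalg.inv(Xd.to_numpy().T @ Xd.to_numpy()),
        n=n,
        r_squared=float(res.rsquared),
        rss=rss,
        beta_p=res.pvalues.copy(),
        f_stat=float(res.fvalue) if k else float("nan"),
        f_p=float(res.f_pvalue) if k else float("nan"),
        sex_coding=sex_coding,
    )


def model_aic(model: NormativeModel) -> float:
    """Gaussian full-likelihood AIC; lower is better."""
    n, k, rss = model.n, model.k, model.rss
    if rss <= 1e-10 * n:   # numerically perfect fit
        warnings.warn("zero residual sum of squares; AIC is -inf")
        return float("-inf")
    return n * math.log(2 * math.pi * rss / n) + n + 2 * (k + 2)


def select_model(
    table,
    candidate_predictor_sets=CANDIDATE_LADDER,
    sex_coding: dict | None = None,
):
    """Fit each candidate predictor set and rank ascending by AIC.

    Returns ``(ranked, report, errors)``: fitted models sorted by AIC (stable
    for ties), a Table-5-style report DataFrame, and per-candidate fit errors.
    """
    fitted: list[tuple[tuple, NormativeModel]] = []
    errors: dict[tuple, Exception] = {}
    for preds in candidate_predictor_sets:
        preds = tuple(preds)
        try:
            fitted.append((preds, fit_normative_model(table, preds, sex_coding)))
        except Exception as exc:  # propagate per candidate, continue others
            errors[preds] = exc
    ranked = sorted(fitted, key=lambda item: item[1].aic)
    rows = []
    for i, (preds, m) in enumerate(fitted, start=1):
        for j, p in enumerate(preds):
            rows.append(
                {
                    "model": f"Model {i}",
                    "predictor": p,
                    "beta": m.beta[j + 1],
                    "p": m.beta_p[j + 1] if m.beta_p is not None else np.nan,
                    "r_squared": m.r_squared if j == 0 else np.nan,
                    "f": m.f_stat if j == 0 else np.nan,
                    "f_p": m.f_p if j == 0 else np.nan,
                    "aic": m.aic if j == 0 else np.nan,
                }
            )
    report = pd.DataFrame(rows)
    return ranked, report, errors


def _new_case_se(model: NormativeModel, x0: np.ndarray) -> float:
    if model.residual_sd <= 0:
        raise DegenerateModelError(
            "degenerate normative model: zero residual standard deviation"
        )
    return model.residual_sd * math.sqrt(1.0 + x0 @ model.xtx_inverse @ x0)


def single_case_test(
    model: NormativeModel,
    case: ExamineeRecord,
    alpha: float = 0.05,
    two_tailed: bool = False,
) -> SingleCaseResult:
    """Crawford-Garthwaite comparison of one examinee against the norms.

    The one-tailed p (deficit direction: lower scores abnormal) estimates the
    proportion of the healthy population expected to obtain a score as low or
    lower than the observed one, given the examinee's demographics.
    """
    if case.observed_total is None:
        raise ValidationError("case has no observed_total to compare")
    x0 = model.design_vector(case)
    predicted = float(x0 @ model.beta)
    se = _new_case_se(model, x0)
    discrepancy = case.observed_total - predicted
    t = discrepancy / se
    df = model.df
    p_low = float(stats.t.cdf(t, df))
    p_two = float(2 * min(p_low, 1 - p_low))
    p_used = p_two if two_tailed else p_low
    return SingleCaseResult(
        predicted=predicted,
        discrepancy=discrepancy,
        t_stat=float(t),
        df=df,
        p_one_tailed=p_low,
        p_two_tailed=p_two,
        percentile=100.0 * p_low,
        below_cutoff=bool(p_used < alpha and discrepancy < 0) if two_tailed
        else bool(p_used < alpha),
        alpha=alpha,
    )


def cutoff_score(
    model: NormativeModel,
    case_demographics: ExamineeRecord,
    alpha: float = 0.05,
) -> float:
    """Largest score with one-tailed p below ``alpha`` for these demographics."""
    if not 0 < alpha <= 0.5:
        raise ValidationError(f"alpha {alpha} outside (0, 0.5]")
    x0 = model.design_vector(case_demographics)
    se = _new_case_se(model, x0)
    predicted = float(x0 @ model.beta)
    return predicted + float(stats.t.ppf(alpha, model.df)) * se


def single_case_p_batch(
    model: NormativeModel, X0: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Vectorised one-tailed p for many cases (rows of ``X0`` incl. intercept)."""
    if model.residual_sd <= 0:
        raise DegenerateModelError("degenerate normative model")
    quad = np.einsum("ij,jk,ik->i", X0, model.xtx_inverse, X0)
    se = model.residual_sd * np.sqrt(1.0 + quad)
    t = (observed - X0 @ model.beta) / se
    return stats.t.cdf(t, model.df)
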