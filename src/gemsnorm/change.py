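"""Test-retest reliability, practice effects and significant-change thresholds.

A retested examinee's second score is predicted from the first by OLS; the
observed retest is classified as a significant change when it falls outside
the two-tailed new-observation prediction interval

    predicted +- t(1 - alpha/2, df) * s * sqrt(1 + x0' (X'X)^-1 x0).

Because the regression intercept absorbs the mean practice effect, the
classification accounts for expected familiarity gains: "stable" means
"changed no more than a typical healthy retest".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    ComputationError,
    DegenerateModelError,
    ValidationError,
)
from .scoring import ScoreProfile
from .tasks import Task

__all__ = [
    "RetestPair",
    "ChangeModel",
    "ChangeClassification",
    "PairedTResult",
    "test_retest_r",
    "practice_effect",
    "fit_change_model",
    "classify_change",
]


@dataclass(frozen=True)
class RetestPair:
    """Baseline (t0) and retest (t1) profiles for one examinee."""

    examinee_id: str
    t0_profile: ScoreProfile
    t1_profile: ScoreProfile
    versions: tuple[str, str] = ("A", "A")
    interval_days: float = 28.0

    def __post_init__(self) -> None:
        if self.interval_days <= 0:
            raise ValidationError("interval_days must be positive")
        if self.versions not in (("A", "A"), ("A", "B")):
            raise ValidationError(
                f"versions must be (A,A) or (A,B), got {self.versions}"
            )


def _level_scores(pairs, level) -> tuple[np.ndarray, np.ndarray]:
    if level == "total":
        t0 = np.array([p.t0_profile.total for p in pairs])
        t1 = np.array([p.t1_profile.total for p in pairs])
    else:
        task = Task(level)
        t0 = np.array([p.t0_profile[task].weighted for p in pairs])
        t1 = np.array([p.t1_profile[task].weighted for p in pairs])
    return t0, t1


def test_retest_r(pairs, level="total") -> float:
    """Pearson correlation between baseline and retest scores."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ComputationError("need at least 3 retest pairs")
    t0, t1 = _level_scores(pairs, level)
    if np.std(t0) == 0 or np.std(t1) == 0:
        raise ComputationError(
            f"undefined correlation: zero variance at level {level!r}"
        )
    return float(stats.pearsonr(t0, t1).statistic)


@dataclass(frozen=True)
class PairedTResult:
    t_stat: float
    df: int
    p_value: float
    mean_difference: float   # mean(t1) - mean(t0); positive = improvement
    mean_t0: float
    mean_t1: float


def practice_effect(pairs, level="total") -> PairedTResult:
    """Two-tailed paired t test on retest minus baseline scores."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ComputationError("need at least 2 retest pairs")
    t0, t1 = _level_scores(pairs, level)
    d = t1 - t0
    n = len(d)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if sd_d == 0:
        # all differences identical: t is 0 or an infinite-t sentinel
        t = 0.0 if mean_d == 0 else math.copysign(math.inf, mean_d)
        p = 1.0 if mean_d == 0 else 0.0
    else:
        res = stats.ttest_rel(t1, t0)
        t, p = float(res.statistic), float(res.pvalue)
    return PairedTResult(t, n - 1, p, mean_d, float(np.mean(t0)),
                         float(np.mean(t1)))


@dataclass
class ChangeModel:
    """OLS of retest total on baseline total with new-observation error."""

    beta: np.ndarray              # (intercept, slope on baseline, ...)
    residual_sd: float
    xtx_inverse: np.ndarray
    n: int
    version_pair: tuple[str, str]

    @property
    def df(self) -> int:
        return self.n - len(self.beta)

    def predict(self, baseline: float) -> float:
        return float(np.array([1.0, baseline]) @ self.beta)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "residual_sd": self.residual_sd,
            "xtx_inverse": self.xtx_inverse.tolist(),
            "n": self.n,
            "version_pair": list(self.version_pair),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChangeModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            residual_sd=float(d["residual_sd"]),
            xtx_inverse=np.asarray(d["xtx_inverse"], dtype=float),
            n=int(d["n"]),
            version_pair=tuple(d["version_pair"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ChangeModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_change_model(pairs=None, t0=None, t1=None,
                     version_pair=None, min_pairs=10) -> ChangeModel:
    """Fit the baseline-to-retest regression.

    Accepts either :class:`RetestPair` objects (which must share a single
    version pair) or raw ``t0``/``t1`` total-score arrays plus an explicit
    ``version_pair``.
    """
    if pairs is not None:
        pairs = list(pairs)
        vps = {p.versions for p in pairs}
        if len(vps) > 1:
            raise ValidationError(f"mixed version pairs in one fit: {sorted(vps)}")
        version_pair = version_pair or (pairs[0].versions if pairs else ("A", "A"))
        t0, t1 = _level_scores(pairs, "total")
    else:
        t0 = np.asarray(t0, dtype=float)
        t1 = np.asarray(t1, dtype=float)
        version_pair = tuple(version_pair or ("A", "A"))
    n = len(t0)
    if n < min_pairs:
        raise ComputationError(f"only {n} pairs; need >= {min_pairs}")
    X = np.column_stack([np.ones(n), t0])
    beta, _, rank, _ = np.linalg.lstsq(X, t1, rcond=None)
    if rank < 2:
        raise ComputationError("baseline scores are constant; cannot fit")
    resid = t1 - X @ beta
    rss = float(resid @ resid)
    residual_sd = math.sqrt(rss / (n - 2))
    return ChangeModel(
        beta=beta,
        residual_sd=residual_sd,
        xtx_inverse=np.linalg.inv(X.T @ X),
        n=n,
        version_pair=tuple(version_pair),
    )


@dataclass(frozen=True)
class ChangeClassification:
    predicted_t1: float
    lower: float
    upper: float
    observed_t1: float
    verdict: str          # worsened | stable | improved
    alpha: float


def classify_change(
    model: ChangeModel, baseline: float, retest: float, alpha: float = 0.05
) -> ChangeClassification:
    """Classify a retest against the two-tailed prediction interval."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if model.residual_sd <= 1e-8:
        raise DegenerateModelError("degenerate change model: zero residual sd")
    x0 = np.array([1.0, baseline])
    se = model.residual_sd * math.sqrt(1.0 + x0 @ model.xtx_inverse @ x0)
    predicted = float(x0 @ model.beta)
    tcrit = float(stats.t.ppf(1 - alpha / 2, model.df))
    lower, upper = predicted - tcrit * se, predicted + tcrit * se
    if retest < lower:
        verdict = "worsened"
    elif retest > upper:
        verdict = "improved"
    else:
        verdict = "stable"
    return ChangeClassification(predicted, lower, upper, retest, verdict, alpha)


def classify_change_batch(model, baseline, retest, alpha=0.05) -> np.ndarray:
    """Vectorised verdicts (-1 worsened, 0 stable, +1 improved)."""
    if model.residual_sd <= 1e-8:
        raise DegenerateModelError("degenerate change model")
    baseline = np.asarray(baseline, dtype=float)
    retest = np.asarray(retest, dtype=float)
    X0 = np.column_stack([np.ones(len(baseline)), baseline])
    quad = np.einsum("ij,jk,ik->i", X0, model.xtx_inverse, X0)
    se = model.residual_sd * np.sqrt(1.0 + quad)
    predicted = X0 @ model.beta
    tcrit = float(stats.t.ppf(1 - alpha / 2, model.df))
    out = np.zeros(len(baseline), dtype=int)
    out[retest < predicted - tcrit * se] = -1
    out[retest > predicted + tcrit * se] = 1
    return out
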