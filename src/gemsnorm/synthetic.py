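"""Synthetic normative cohorts, score matrices and retest pairs.

The generator emulates the published normative study so every statistical
module is testable without the real data:

* demographics follow the printed age-band x education-band stratification
  of the n = 1308 normative sample (quota sampling reproduces each cell count
  exactly; proportional mode apportions any n by largest remainder);
* total scores follow the published four-predictor regression
  (age -0.29, education +0.81, cognitive reserve +0.05, sex(M=1) -1.14)
  with Gaussian residual sd 8.5 (total SD 11.4 at R^2 = 0.44), the intercept
  calibrated so the cohort mean matches the published 81.8, and totals
  clipped to the instrument's 0-100 range;
* per-task weighted scores are distributed around the total through a
  qualitative factor template (a trail-making speed factor, an episodic
  memory factor, task-specific noise), with task means/SDs and item-total
  correlations taken from the published descriptives, then discretised to
  each task's raw scale and re-weighted;
* retest pairs target the published test-retest correlations (0.88 same
  version, 0.55 parallel version) and the mean practice gain of 2.19 points
  applied for same-version retests only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .scoring import ScoreProfile, TaskResult
from .session_io import NormativeTable, TASK_COLUMNS
from .change import RetestPair
from .tasks import INTEGER_RAW_TASKS, RAW_MAX, TASK_ORDER, TOTAL_RESCALE, Task

__all__ = [
    "GeneratorConfig",
    "SyntheticCohort",
    "STRATA_COUNTS",
    "AGE_BANDS",
    "EDUCATION_YEARS",
    "sample_demographics",
    "generate_total_scores",
    "generate_cohort",
    "generate_retest_pairs",
    "profile_from_row",
    "equicorrelated_scores",
    "simulate_factor_model",
]

#: Age-band x education-band cell counts of the published normative sample
#: (rows 18-30 ... >80; columns 0-5, 6-8, 9-13, 14-16, 17-18, >18 years).
STRATA_COUNTS = np.array(
    [
        [1, 4, 115, 110, 42, 14],
        [0, 0, 16, 18, 21, 23],
        [1, 14, 38, 15, 20, 13],
        [4, 107, 215, 68, 68, 18],
        [8, 44, 67, 15, 42, 10],
        [37, 34, 24, 9, 14, 0],
        [37, 13, 5, 1, 2, 1],
    ]
)

AGE_BANDS = ((18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79),
             (80, 93))
#: Band-representative education in years (the study reports education in
#: years but stratifies in bands; the top of each band stands for the band).
EDUCATION_YEARS = (5, 8, 13, 16, 18, 21)

# Published per-task descriptives (weighted 0-9 scale) and item-total
# correlations, in fixed task order.
TASK_MEANS = (7.8, 7.2, 8.1, 8.9, 8.6, 6.1, 8.4, 7.6, 4.9, 4.7, 8.5)
# The puzzle SD is bounded above by sqrt((9 - 8.9) * 8.9) ~ 0.94 for a
# variable on [0, 9] with mean 8.9; 0.9 is the feasible value consistent
# with the published near-ceiling distribution.
TASK_SDS = (1.7, 1.8, 1.8, 0.9, 0.5, 2.3, 1.1, 2.6, 2.8, 2.9, 2.1)
ITEM_TOTAL_R = (0.30, 0.69, 0.44, 0.24, 0.41, 0.68, 0.34, 0.46, 0.75, 0.73,
                0.45)

#: Group factors of the qualitative loading template: trail-making speed and
#: episodic memory; the shared global factor is the total itself, and the
#: months-backwards working-memory factor has no second marker so it folds
#: into task-specific variance.
GROUP_FACTORS = {
    "speed": (Task.TMT_A, Task.TMT_B),
    "memory": (Task.IMMEDIATE_MEMORY, Task.DELAYED_MEMORY),
}
GROUP_SHARE = 0.7   # fraction of non-global SD loading on the group factor


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic normative cohort."""

    n: int = 1308
    strata: np.ndarray = field(default_factory=lambda: STRATA_COUNTS.copy())
    quota: bool = True          # exact cell counts (n must match the table)
    beta: dict = field(default_factory=lambda: {
        "age": -0.29, "education": 0.81, "cr": 0.05, "sex": -1.14,
    })
    intercept: float | None = None     # None: calibrate to target_mean
    target_mean: float = 81.8
    total_sd: float = 11.4             # reference dispersion of the total
    residual_sd: float = 8.5           # 11.4 * sqrt(1 - 0.44)
    female_prop: float = 0.60
    #: cognitive reserve as an affine function of education plus noise,
    #: truncated to the observed range
    cr_intercept: float = 99.4
    cr_slope: float = 1.8
    cr_noise_sd: float = 14.0
    cr_bounds: tuple[float, float] = (70.0, 210.0)
    clip: bool = True                  # clip totals to the 0-100 instrument range
    practice_shift: float = 2.19       # same-version retest gain, total scale
    retest_r_same: float = 0.88
    retest_r_parallel: float = 0.55
    task_means: tuple = TASK_MEANS
    task_sds: tuple = TASK_SDS
    item_total_r: tuple = ITEM_TOTAL_R

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticCohort:
    table: NormativeTable
    latent: pd.DataFrame
    config: GeneratorConfig
    seed: int


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Deterministic apportionment of n among cells proportional to weights."""
    quota = weights / weights.sum() * n
    base = np.floor(quota).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def sample_demographics(config: GeneratorConfig | None = None,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample demographics stratified by the published quota table.

    Ages are uniform integers within band; education takes the band's
    representative year value; sex is Bernoulli (60% female); cognitive
    reserve is an affine function of education plus truncated Gaussian noise.
    """
    config = config or GeneratorConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    strata = np.asarray(config.strata)
    if config.quota:
        if config.n != strata.sum():
            raise ValidationError(
                f"quota mode: n={config.n} != strata total {strata.sum()}"
            )
        counts = strata
    else:
        counts = _largest_remainder(strata.astype(float).ravel(),
                                    config.n).reshape(strata.shape)
    ages, edus = [], []
    for i, (lo, hi) in enumerate(AGE_BANDS):
        for j, c in enumerate(counts[i]):
            if c:
                ages.append(rng.integers(lo, hi + 1, size=int(c)))
                edus.append(np.full(int(c), EDUCATION_YEARS[j], dtype=float))
    age = np.concatenate(ages).astype(float)
    education = np.concatenate(edus)
    n = len(age)
    sex = np.where(rng.random(n) < config.female_prop, "F", "M")
    cr = np.clip(
        config.cr_intercept + config.cr_slope * education
        + rng.normal(0.0, config.cr_noise_sd, n),
        *config.cr_bounds,
    )
    return pd.DataFrame(
        {"age": age, "education": education, "sex": sex, "cr": np.round(cr, 1)}
    )


def _linear_predictor(demog: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    sexnum = (demog["sex"] == "M").astype(float).to_numpy()
    return (
        config.beta["age"] * demog["age"].to_numpy()
        + config.beta["education"] * demog["education"].to_numpy()
        + config.beta["cr"] * demog["cr"].to_numpy()
        + config.beta["sex"] * sexnum
    )


def _task_decomposition(config: GeneratorConfig):
    """Loadings of each task on the standardised total and noise budget."""
    sds = np.array(config.task_sds)
    r = np.array(config.item_total_r)
    b = r * sds                       # per-SD-of-total loading (z-scaled)
    noise_sd = sds * np.sqrt(1 - r ** 2)
    group_load = np.zeros(len(TASK_ORDER))
    for tasks in GROUP_FACTORS.values():
        for t in tasks:
            i = TASK_ORDER.index(t)
            group_load[i] = GROUP_SHARE * noise_sd[i]
    unique_sd = np.sqrt(np.clip(noise_sd ** 2 - group_load ** 2, 0.0, None))
    return b, group_load, unique_sd


def _discretise(w: np.ndarray) -> np.ndarray:
    """Clip to [0,9]; snap integer-scale tasks to their raw grid."""
    w = np.clip(w, 0.0, 9.0)
    for i, task in enumerate(TASK_ORDER):
        if task in INTEGER_RAW_TASKS:
            rmax = RAW_MAX[task]
            raw = np.rint(w[:, i] * rmax / 9.0)
            w[:, i] = raw * 9.0 / rmax
        else:
            w[:, i] = np.round(w[:, i], 1)
    return w


def _task_scores(total: np.ndarray, config: GeneratorConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    n = len(total)
    z = (total - config.target_mean) / config.total_sd
    b, group_load, unique_sd = _task_decomposition(config)
    factors = {name: rng.standard_normal(n) for name in GROUP_FACTORS}
    w = (np.array(config.task_means)[None, :]
         + np.outer(z, b)
         + rng.standard_normal((n, len(TASK_ORDER))) * unique_sd[None, :])
    for name, tasks in GROUP_FACTORS.items():
        for t in tasks:
            i = TASK_ORDER.index(t)
            w[:, i] += group_load[i] * factors[name]
    latent = pd.DataFrame({"z_total": z, **{f"f_{k}": v
                                            for k, v in factors.items()}})
    return _discretise(w), latent


def generate_total_scores(
    demographics: pd.DataFrame,
    config: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
    tasks: bool = True,
) -> tuple[NormativeTable, pd.DataFrame]:
    """Generate total (and optionally per-task) scores for given demographics.

    Totals are the demographic regression plus Gaussian residual noise,
    clipped to [0, 100] when ``config.clip`` (the instrument's hard range);
    the intercept is calibrated against the sampled demographic means so the
    cohort mean sits at ``config.target_mean``.
    """
    config = config or GeneratorConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lin = _linear_predictor(demographics, config)
    intercept = (config.target_mean - float(lin.mean())
                 if config.intercept is None else config.intercept)
    total = intercept + lin + rng.normal(0.0, config.residual_sd, len(lin))
    if config.clip:
        total = np.clip(total, 0.0, 100.0)
    total = np.round(total, 1)
    data = demographics.reset_index(drop=True).copy()
    if tasks:
        w, latent = _task_scores(total, config, rng)
        for i, col in enumerate(TASK_COLUMNS):
            data[col] = w[:, i]
    else:
        latent = pd.DataFrame(index=data.index)
        for col in TASK_COLUMNS:
            data[col] = 0.0
    data["total"] = total
    return NormativeTable(data), latent


def generate_cohort(config: GeneratorConfig | None = None,
                    seed: int = 0, tasks: bool = True) -> SyntheticCohort:
    """Sample demographics and scores in one reproducible step."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    demog = sample_demographics(config, rng)
    table, latent = generate_total_scores(demog, config, rng, tasks=tasks)
    return SyntheticCohort(table, latent, config, seed)


def profile_from_row(row) -> ScoreProfile:
    """Build a ScoreProfile from a normative-table row of weighted scores."""
    results = []
    for task in TASK_ORDER:
        w = float(row[task.value])
        results.append(TaskResult(task, w * RAW_MAX[task] / 9.0, RAW_MAX[task]))
    return ScoreProfile(tuple(results))


def _box_shift(w: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Per-task shift truncated so each score stays inside [0, 9]."""
    return np.clip(w + pattern, 0.0, 9.0) - w


def _fill_to_sum(w: np.ndarray, target_sum: float, share: np.ndarray,
                 max_rounds: int = 30) -> np.ndarray:
    """Move ``w`` (box [0, 9] per task) so its sum hits ``target_sum``.

    The change is distributed proportionally to ``share`` (each task's share
    of the total's common variance); overflow beyond a task's bound is
    re-distributed over the tasks with headroom, so the total change is not
    eaten by the score ceiling.
    """
    w = w.copy()
    target_sum = float(np.clip(target_sum, 0.0, 9.0 * len(w)))
    remaining = target_sum - w.sum()
    for _ in range(max_rounds):
        if abs(remaining) < 1e-9:
            break
        room = (9.0 - w) if remaining > 0 else w
        active = room > 1e-12
        if not active.any():
            break
        wts = np.where(active, share, 0.0)
        if wts.sum() == 0:
            wts = active.astype(float)
        wts = wts / wts.sum()
        step = np.minimum(np.abs(remaining) * wts, room)
        w = w + math.copysign(1.0, remaining) * step
        remaining = target_sum - w.sum()
    return w


#: Same-version per-task practice pattern (retest minus baseline, weighted
#: scale), from the published task-level mean differences; rescaled so the
#: implied total-scale gain equals the configured practice shift.
PRACTICE_PATTERN = (-0.25, 0.84, 0.37, 0.08, -0.03, 1.01, -0.12, 0.37,
                    -0.03, 0.07, -0.12)


def generate_retest_pairs(
    cohort: SyntheticCohort,
    config: GeneratorConfig | None = None,
    version_pair: tuple[str, str] = ("A", "A"),
    n_pairs: int = 73,
    seed: int | np.random.Generator = 1,
    interval_days: float = 28.0,
) -> list[RetestPair]:
    """Draw a retest sub-sample and simulate second administrations.

    The retest total moves by the practice shift (same-version only) plus
    noise scaled to hit the configured baseline-retest correlation; the
    change is distributed over tasks proportionally to their share of the
    total's common variance, on top of the per-task practice pattern.
    """
    config = config or cohort.config
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = cohort.table.data
    if n_pairs > len(df):
        raise ValidationError(
            f"requested {n_pairs} pairs from a cohort of {len(df)}"
        )
    if version_pair == ("A", "A"):
        target_r, shift = config.retest_r_same, config.practice_shift
    elif version_pair == ("A", "B"):
        target_r, shift = config.retest_r_parallel, 0.0
    else:
        raise ValidationError(f"unsupported version pair {version_pair}")

    idx = rng.choice(len(df), size=n_pairs, replace=False)
    w0 = df.iloc[idx][list(TASK_COLUMNS)].to_numpy(dtype=float)
    t0 = w0.sum(axis=1) * TOTAL_RESCALE

    # bivariate-normal retest: regression to the mean keeps high scorers
    # inside the 0-100 range instead of piling noise onto the ceiling
    mu = float(np.mean(t0))
    sd0 = float(np.std(t0, ddof=1))
    noise_sd = sd0 * np.sqrt(max(1.0 - target_r ** 2, 0.0))
    t1 = ((mu + shift) + target_r * (t0 - mu)
          + rng.normal(0.0, noise_sd, n_pairs))
    t1 = np.clip(t1, 0.0, 100.0)

    b, _, _ = _task_decomposition(config)
    share = b / b.sum()
    pattern = np.array(PRACTICE_PATTERN)
    pat_total = pattern.sum() * TOTAL_RESCALE
    pattern = pattern * (shift / pat_total) if pat_total and shift else 0.0 * pattern
    w1 = np.empty_like(w0)
    for i in range(n_pairs):
        w1[i] = _fill_to_sum(w0[i] + _box_shift(w0[i], pattern),
                             t1[i] / TOTAL_RESCALE, share)
    # retest task scores stay on a 0.1 grid; snapping back to each task's raw
    # grid near the ceiling would reflect noise and bias the retest upward
    w1 = np.clip(np.round(w1, 1), 0.0, 9.0)

    pairs = []
    for row0, row1, i in zip(w0, w1, idx):
        p0 = ScoreProfile(tuple(
            TaskResult(t, row0[j] * RAW_MAX[t] / 9.0, RAW_MAX[t])
            for j, t in enumerate(TASK_ORDER)
        ))
        p1 = ScoreProfile(tuple(
            TaskResult(t, row1[j] * RAW_MAX[t] / 9.0, RAW_MAX[t])
            for j, t in enumerate(TASK_ORDER)
        ))
        pairs.append(RetestPair(f"sim-{i}", p0, p1, version_pair,
                                interval_days))
    return pairs


# ---------------------------------------------------------------------------
# auxiliary simulators for psychometric property checks


def equicorrelated_scores(n: int, k: int, r_bar: float,
                          seed: int = 0,
                          means=None, sds=None) -> pd.DataFrame:
    """Gaussian score matrix with a common pairwise correlation ``r_bar``.

    Built from a single shared factor with loading sqrt(r_bar); used to probe
    internal-consistency formulas at a known population alpha.
    """
    if not 0 <= r_bar < 1:
        raise ValidationError("r_bar must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, k))
    z = np.sqrt(r_bar) * g + np.sqrt(1 - r_bar) * e
    means = np.zeros(k) if means is None else np.asarray(means)
    sds = np.ones(k) if sds is None else np.asarray(sds)
    return pd.DataFrame(z * sds + means,
                        columns=[f"item_{i + 1}" for i in range(k)])


def simulate_factor_model(loadings, n: int, seed: int = 0,
                          uniquenesses=None) -> pd.DataFrame:
    """Draw standardised scores from an exact orthogonal factor model."""
    L = np.asarray(loadings, dtype=float)
    p, m = L.shape
    comm = (L ** 2).sum(axis=1)
    if uniquenesses is None:
        uniquenesses = 1.0 - comm
    psi = np.asarray(uniquenesses, dtype=float)
    if np.any(psi < 0):
        raise ValidationError("communalities exceed 1")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, m))
    e = rng.standard_normal((n, p)) * np.sqrt(psi)
    names = list(getattr(loadings, "index", range(p)))
    return pd.DataFrame(f @ L.T + e, columns=names)
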