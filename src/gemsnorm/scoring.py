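"""Item-level scoring for the 11-task screening battery.

Each task yields a raw score on its own scale (e.g. 4 of 6 words recalled),
which is proportionally re-weighted to 0-9 (``raw * 9 / raw_max``) so that
every task weighs the same on the global score.  The global score is the sum
of the eleven weighted scores rescaled to 0-100 and reported to one decimal.

The answer keys (word lists, naming targets, metaphor option, ...) are
configuration, not code: the published task descriptions do not print the
full item content of either parallel version, so :class:`ScoringConfig`
ships editable defaults (the naming pictures are the four printed objects;
the word lists are synthetic placeholders).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import yaml

from .exceptions import ScoringError, ValidationError
from .tasks import (
    ORDER_FREE_TASKS,
    RAW_MAX,
    TASK_ORDER,
    TOTAL_RESCALE,
    WEIGHTED_MAX,
    Task,
)

__all__ = [
    "TaskResult",
    "ScoreProfile",
    "CRShortResult",
    "ScoringConfig",
    "weight_task_score",
    "score_keyed_task",
    "score_months_backwards",
    "score_comprehension",
    "score_tmt",
    "total_score",
    "score_cri_short",
    "score_session",
    "orientation_key",
    "round_half_up",
]

ITALIAN_MONTHS_BACKWARD = ("ottobre", "agosto", "giugno", "aprile", "febbraio")

SEASONS = ("primavera", "estate", "autunno", "inverno")
# Astronomical-calendar season starts (month, day): spring, summer, autumn,
# winter.  A +-grace window around each boundary accepts either season.
_SEASON_STARTS = ((3, 21), (6, 21), (9, 23), (12, 21))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching clinical score reporting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _norm(text: str) -> str:
    return str(text).strip().lower()


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class TaskResult:
    """Raw and weighted score for one task."""

    task_id: Task
    raw: float
    raw_max: float

    def __post_init__(self) -> None:
        if self.raw_max <= 0:
            raise ScoringError(f"{self.task_id.value}: raw_max must be positive")
        if not 0 <= self.raw <= self.raw_max:
            raise ScoringError(
                f"{self.task_id.value}: raw {self.raw} outside [0, {self.raw_max}]"
            )

    @property
    def weighted(self) -> float:
        return weight_task_score(self.raw, self.raw_max)


@dataclass(frozen=True)
class ScoreProfile:
    """Eleven task results in fixed order plus the 0-100 global score."""

    results: tuple[TaskResult, ...]

    def __post_init__(self) -> None:
        ids = tuple(r.task_id for r in self.results)
        if ids != TASK_ORDER:
            missing = [t.value for t in TASK_ORDER if t not in ids]
            raise ScoringError(
                "profile must contain exactly the 11 tasks in fixed order; "
                f"missing/misordered: {missing or list(map(str, ids))}"
            )

    @property
    def weighted_scores(self) -> tuple[float, ...]:
        return tuple(r.weighted for r in self.results)

    @property
    def total(self) -> float:
        return total_score(self.results)

    def __getitem__(self, task: Task) -> TaskResult:
        return self.results[TASK_ORDER.index(task)]

    def as_dict(self) -> dict[str, float]:
        d = {r.task_id.value: round_half_up(r.weighted, 1) for r in self.results}
        d["total"] = self.total
        return d


@dataclass(frozen=True)
class CRShortResult:
    """Cognitive-reserve index from the 6-item short questionnaire.

    Three subscores (education, working activity, leisure time) on a
    CRIq-style scale; the total is their arithmetic mean.
    """

    cr_education: float
    cr_working: float
    cr_leisure: float

    @property
    def cr_total(self) -> float:
        return (self.cr_education + self.cr_working + self.cr_leisure) / 3.0


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ScoringConfig:
    """Answer keys and scoring parameters for one battery version.

    The word lists and option keys for version A/B are not published item by
    item; defaults are documented placeholders and should be replaced with the
    deployed keys via YAML when scoring real sessions.
    """

    version: str = "A"
    #: six-word list for immediate/delayed recall (synthetic default key)
    memory_words: tuple[str, ...] = (
        "pane", "casa", "fiume", "gatto", "stella", "treno",
    )
    #: the four pictured non-living objects
    naming_answers: tuple[str, ...] = ("pera", "tavolo", "bussola", "sassofono")
    #: keyed option id of the metaphor explanation
    metaphor_answer: str = "2"
    #: clock-hands judgements, one per trial
    spatial_answers: tuple[str, ...] = ("opposte", "destra", "sinistra")
    months_expected: tuple[str, ...] = ITALIAN_MONTHS_BACKWARD
    #: Rome relative to Venice
    geography_answer: str = "sud"
    season_grace_days: int = 7
    #: (t_fast, t_slow) seconds per trail-making variant
    tmt_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"A": (20.0, 120.0), "B": (30.0, 180.0)}
    )
    #: CR subscore = cr_center + cr_step * (item1 + item2 - 4), items on 0-4
    cr_center: float = 122.0
    cr_step: float = 11.0
    #: lenient typed-text matching (edit distance 1); strict by default
    lenient_text: bool = False

    def for_version(self, version: str) -> "ScoringConfig":
        if version not in ("A", "B"):
            raise ValidationError(f"unknown battery version {version!r}")
        return replace(self, version=version)

    def to_yaml(self, path) -> None:
        data = {
            "version": self.version,
            "memory_words": list(self.memory_words),
            "naming_answers": list(self.naming_answers),
            "metaphor_answer": self.metaphor_answer,
            "spatial_answers": list(self.spatial_answers),
            "months_expected": list(self.months_expected),
            "geography_answer": self.geography_answer,
            "season_grace_days": self.season_grace_days,
            "tmt_bounds": {k: list(v) for k, v in self.tmt_bounds.items()},
            "cr_center": self.cr_center,
            "cr_step": self.cr_step,
            "lenient_text": self.lenient_text,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, allow_unicode=True, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        for key in ("memory_words", "naming_answers", "spatial_answers",
                    "months_expected"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "tmt_bounds" in kwargs:
            kwargs["tmt_bounds"] = {
                k: tuple(v) for k, v in kwargs["tmt_bounds"].items()
            }
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# elementary operations


def weight_task_score(raw: float, raw_max: float) -> float:
    """Re-weight a raw score to the common 0-9 scale (``raw * 9 / raw_max``)."""
    if raw_max <= 0:
        raise ScoringError(f"raw_max must be positive, got {raw_max}")
    if not 0 <= raw <= raw_max:
        raise ScoringError(f"raw score {raw} outside [0, {raw_max}]")
    return raw * WEIGHTED_MAX / raw_max


def _text_match(response: str, target: str, lenient: bool) -> bool:
    r, t = _norm(response), _norm(target)
    if r == t:
        return True
    if not lenient or abs(len(r) - len(t)) > 1:
        return False
    # edit distance <= 1 without external dependencies
    if len(r) == len(t):
        return sum(a != b for a, b in zip(r, t)) <= 1
    short, long_ = (r, t) if len(r) < len(t) else (t, r)
    for i in range(len(long_)):
        if short == long_[:i] + long_[i + 1:]:
            return True
    return False


def score_keyed_task(
    task_id: Task,
    responses: list[str],
    key: list,
    lenient: bool = False,
) -> float:
    """Count correct items against an answer key.

    ``key`` holds one target per item; a target may be a single string or a
    collection of acceptable strings.  Typed text is compared lowercase and
    whitespace-trimmed.  For the two word-recall tasks matching is order-free
    and each target is creditable once: the raw score is the size of a maximum
    matching between response tokens and targets, which for exact string
    equality is ``sum_t min(#responses == t, #targets == t)``.
    """
    if task_id in (Task.MONTHS_BACKWARDS, Task.COMPREHENSION, Task.TMT_A,
                   Task.TMT_B):
        raise ScoringError(f"{task_id.value} is not scored by answer key")

    def accepts(target, resp) -> bool:
        options = [target] if isinstance(target, str) else list(target)
        return any(_text_match(resp, opt, lenient) for opt in options)

    if task_id in ORDER_FREE_TASKS:
        # exact matching: group by normalised token
        targets = [_norm(t) for t in key]
        tokens = [_norm(r) for r in responses if _norm(r)]
        score = 0
        for t in set(targets):
            score += min(tokens.count(t), targets.count(t))
        if lenient:  # greedy one-credit pass for near-miss tokens
            unused = [tok for tok in tokens if tok not in targets]
            open_targets = [t for t in targets
                            if tokens.count(t) < 1]
            for tok in unused:
                for t in list(open_targets):
                    if _text_match(tok, t, True):
                        score += 1
                        open_targets.remove(t)
                        break
        return float(min(score, len(key)))

    n = min(len(responses), len(key))
    return float(sum(accepts(key[i], responses[i]) for i in range(n)))


def orientation_key(
    administration_date: _dt.date,
    grace_days: int = 7,
    geography_answer: str = "sud",
) -> list:
    """Derive the orientation answer key from the administration date.

    Seasons follow the astronomical calendar (21 Mar / 21 Jun / 23 Sep /
    21 Dec); within ``grace_days`` of a boundary either adjacent season is
    accepted.  Items: season, year, geography (fixed).
    """
    year = administration_date.year
    boundaries = []
    for y in (year - 1, year, year + 1):
        for i, (m, d) in enumerate(_SEASON_STARTS):
            boundaries.append((_dt.date(y, m, d), i))
    boundaries.sort()
    # season index in effect on the date
    current = 3  # winter before the first boundary of year-1
    acceptable = set()
    for bdate, idx in boundaries:
        if bdate <= administration_date:
            current = idx
    acceptable.add(SEASONS[current])
    for bdate, idx in boundaries:
        if abs((bdate - administration_date).days) <= grace_days:
            acceptable.add(SEASONS[idx])
            acceptable.add(SEASONS[(idx - 1) % 4])
    return [sorted(acceptable), [str(year)], [geography_answer]]


def score_months_backwards(
    responses: list[str],
    expected: tuple[str, ...] = ITALIAN_MONTHS_BACKWARD,
) -> float:
    """Positional comparison against the skip-one backward month sequence."""
    score = 0
    for given, target in zip(responses[: len(expected)], expected):
        if _norm(given) == _norm(target):
            score += 1
    return float(score)


def score_comprehension(keypresses: list[str]) -> float:
    """1 iff the recorded key sequence is exactly B, A, A."""
    seq = [_norm(k) for k in keypresses]
    return float(seq == ["b", "a", "a"])


def tmt_targets(variant: str) -> list[str]:
    """Target click sequence: 1..14 for variant A, 1-A-2-B-...-7-G for B."""
    if variant == "A":
        return [str(i) for i in range(1, 15)]
    if variant == "B":
        out = []
        for i in range(1, 8):
            out.append(str(i))
            out.append(chr(ord("A") + i - 1))
        return out
    raise ScoringError(f"unknown TMT variant {variant!r}")


def score_tmt(
    clicks: list[str],
    duration_s: float,
    variant: str,
    time_bounds: tuple[float, float] | None = None,
) -> float:
    """Accuracy-by-speed trail-making score on a 0-14 raw scale.

    Accuracy is the longest correct prefix of the 14-item target sequence
    (the self-administered interface cannot re-cue after an error) divided by
    14; the speed factor falls linearly from 1 at ``t_fast`` to 0 at
    ``t_slow``; the raw score is ``accuracy * speed * 14``.
    """
    if duration_s <= 0:
        raise ScoringError("TMT duration must be positive")
    if time_bounds is None:
        time_bounds = {"A": (20.0, 120.0), "B": (30.0, 180.0)}[variant]
    t_fast, t_slow = time_bounds
    if not 0 < t_fast < t_slow:
        raise ScoringError("require 0 < t_fast < t_slow")
    targets = tmt_targets(variant)
    prefix = 0
    for given, want in zip(clicks, targets):
        if _norm(given) != _norm(want):
            break
        prefix += 1
    accuracy = prefix / len(targets)
    speed = min(1.0, max(0.0, (t_slow - duration_s) / (t_slow - t_fast)))
    return accuracy * speed * RAW_MAX[Task.TMT_A]


def total_score(results) -> float:
    """Global 0-100 score: sum of the 11 weighted scores times 100/99."""
    results = tuple(results)
    ids = tuple(r.task_id for r in results)
    if sorted(ids) != sorted(TASK_ORDER):
        missing = [t.value for t in TASK_ORDER if t not in ids]
        raise ScoringError(f"missing task results: {missing}")
    return round_half_up(sum(r.weighted for r in results) * TOTAL_RESCALE, 1)


def score_cri_short(items: dict[str, int], config: ScoringConfig | None = None,
                    ) -> CRShortResult:
    """Score the 6-item cognitive-reserve short form.

    ``items`` maps the six item ids (``education_1``, ``education_2``,
    ``work_1``, ``work_2``, ``leisure_1``, ``leisure_2``) to ordinal responses
    on 0-4.  Each domain subscore is an affine map of its two items onto a
    CRIq-style scale (mean 100-ish population metric); the total is the mean
    of the three subscores.
    """
    config = config or ScoringConfig()
    required = ("education_1", "education_2", "work_1", "work_2",
                "leisure_1", "leisure_2")
    missing = [k for k in required if k not in items]
    if missing:
        raise ValidationError(f"missing CR items: {missing}")
    vals = {}
    for k in required:
        v = items[k]
        try:
            v = int(v)
        except (TypeError, ValueError):
            raise ValidationError(f"CR item {k} not an integer: {items[k]!r}")
        if not 0 <= v <= 4:
            raise ValidationError(f"CR item {k} outside 0-4: {v}")
        vals[k] = v

    def sub(a, b):
        return config.cr_center + config.cr_step * (vals[a] + vals[b] - 4)

    return CRShortResult(
        cr_education=sub("education_1", "education_2"),
        cr_working=sub("work_1", "work_2"),
        cr_leisure=sub("leisure_1", "leisure_2"),
    )


# ---------------------------------------------------------------------------
# session-level dispatch


def _item_sorted(events):
    # events already ordered by the reader; keep stable order
    return [e.response for e in events]


def score_session(session, config: ScoringConfig | None = None) -> ScoreProfile:
    """Score a validated session file into an 11-task profile.

    Raises :class:`ScoringError` when any of the 11 tasks is absent.
    """
    config = config or ScoringConfig()
    if session.version != config.version:
        config = config.for_version(session.version)
    groups: dict[str, list] = {}
    for ev in session.events:
        groups.setdefault(ev.task_id, []).append(ev)

    missing = [t.value for t in TASK_ORDER if t.value not in groups]
    if missing:
        raise ScoringError(f"session lacks tasks: {missing}")

    keys = {
        Task.ORIENTATION: orientation_key(
            session.administration_date,
            config.season_grace_days,
            config.geography_answer,
        ),
        Task.IMMEDIATE_MEMORY: list(config.memory_words),
        Task.DELAYED_MEMORY: list(config.memory_words),
        Task.NAMING: list(config.naming_answers),
        Task.METAPHOR: [config.metaphor_answer],
        Task.SPATIAL_REPRESENTATION: list(config.spatial_answers),
    }

    results = []
    for task in TASK_ORDER:
        events = groups[task.value]
        responses = _item_sorted(events)
        if task in (Task.TMT_A, Task.TMT_B):
            duration = max((e.elapsed_s for e in events), default=0.0)
            raw = score_tmt(
                responses,
                duration,
                "A" if task is Task.TMT_A else "B",
                config.tmt_bounds["A" if task is Task.TMT_A else "B"],
            )
        elif task is Task.MONTHS_BACKWARDS:
            raw = score_months_backwards(responses, config.months_expected)
        elif task is Task.COMPREHENSION:
            raw = score_comprehension(responses)
        elif task is Task.PUZZLE:
            # response = slot index where the piece was dropped; item_id
            # piece_<k> is correct in slot <k>
            raw = 0.0
            for ev in events:
                piece = ev.item_id.rsplit("_", 1)[-1]
                if _norm(ev.response) == _norm(piece):
                    raw += 1
            raw = min(raw, RAW_MAX[Task.PUZZLE])
        else:
            raw = score_keyed_task(
                task, responses, keys[task], lenient=config.lenient_text
            )
        raw_max = RAW_MAX[task]
        if task is Task.SPATIAL_REPRESENTATION:
            raw_max = len(config.spatial_answers)
        results.append(TaskResult(task, raw, raw_max))
    return ScoreProfile(tuple(results))
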