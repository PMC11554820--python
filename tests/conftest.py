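"""Shared fixtures: programmatically built sessions and synthetic cohorts."""

from __future__ import annotations

import datetime as dt

import pytest

from gemsnorm.scoring import ScoringConfig
from gemsnorm.session_io import SessionEvent, SessionFile
from gemsnorm.synthetic import GeneratorConfig, generate_cohort
from gemsnorm.tasks import Task

CONFIG = ScoringConfig()
SESSION_DATE = dt.date(2024, 7, 15)   # mid-summer: season unambiguous


def perfect_events(config: ScoringConfig = CONFIG) -> list[SessionEvent]:
    """Events of a flawless version-A administration."""
    ev = []

    def add(task, item, response, elapsed=1.0):
        ev.append(SessionEvent(task.value, item, response, elapsed))

    add(Task.ORIENTATION, "season", "estate")
    add(Task.ORIENTATION, "year", str(SESSION_DATE.year))
    add(Task.ORIENTATION, "geography", config.geography_answer)
    for i, word in enumerate(config.memory_words, 1):
        add(Task.IMMEDIATE_MEMORY, f"slot_{i}", word)
    for i, month in enumerate(config.months_expected, 1):
        add(Task.MONTHS_BACKWARDS, f"slot_{i}", month)
    for i in range(1, 5):
        add(Task.PUZZLE, f"piece_{i}", str(i))
    for i, ans in enumerate(config.spatial_answers, 1):
        add(Task.SPATIAL_REPRESENTATION, f"trial_{i}", ans)
    for i, word in enumerate(config.memory_words, 1):
        add(Task.DELAYED_MEMORY, f"slot_{i}", word)
    for i, name in enumerate(config.naming_answers, 1):
        add(Task.NAMING, f"item_{i}", name)
    for i, key in enumerate(["b", "a", "a"], 1):
        add(Task.COMPREHENSION, f"press_{i}", key)
    for i in range(1, 15):
        add(Task.TMT_A, f"click_{i}", str(i), elapsed=i)
    seq_b = [s for pair in zip("1234567", "ABCDEFG") for s in pair]
    for i, label in enumerate(seq_b, 1):
        add(Task.TMT_B, f"click_{i}", label, elapsed=1.5 * i)
    add(Task.METAPHOR, "choice", config.metaphor_answer)
    return ev


def blank_events(config: ScoringConfig = CONFIG) -> list[SessionEvent]:
    """Events of a fully failed administration (every response wrong)."""
    ev = []

    def add(task, item, response, elapsed=1.0):
        ev.append(SessionEvent(task.value, item, response, elapsed))

    for item in ("season", "year", "geography"):
        add(Task.ORIENTATION, item, "")
    for i in range(1, 7):
        add(Task.IMMEDIATE_MEMORY, f"slot_{i}", "")
        add(Task.DELAYED_MEMORY, f"slot_{i}", "")
    for i in range(1, 6):
        add(Task.MONTHS_BACKWARDS, f"slot_{i}", "")
    for i in range(1, 5):
        add(Task.PUZZLE, f"piece_{i}", str(i % 4 + 1))   # every piece misplaced
        add(Task.NAMING, f"item_{i}", "")
    for i in range(1, 4):
        add(Task.SPATIAL_REPRESENTATION, f"trial_{i}", "")
    add(Task.COMPREHENSION, "press_1", "c")
    add(Task.TMT_A, "click_1", "9", elapsed=200.0)       # wrong first click
    add(Task.TMT_B, "click_1", "9", elapsed=200.0)
    add(Task.METAPHOR, "choice", "")
    return ev


def make_session(events, examinee_id="ex-001", date=SESSION_DATE,
                 version="A") -> SessionFile:
    return SessionFile(examinee_id, date, version, tuple(events))


@pytest.fixture
def perfect_session() -> SessionFile:
    return make_session(perfect_events())


@pytest.fixture
def blank_session() -> SessionFile:
    return make_session(blank_events())


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic normative cohort (n = 1308), seeded."""
    return generate_cohort(GeneratorConfig(), seed=0)


@pytest.fixture(scope="session")
def cohort_noclip():
    """Cohort without the 0-100 ceiling, for estimator calibration checks."""
    return generate_cohort(GeneratorConfig(clip=False), seed=0, tasks=False)
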