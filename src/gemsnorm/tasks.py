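"""Task registry for the 11-task screening battery.

The battery presents eleven tasks in a fixed order; each produces a raw score
on its own scale which is re-weighted to 0-9 so that every task contributes
equally to the 0-100 global score.
"""

from __future__ import annotations

from enum import Enum


class Task(str, Enum):
    ORIENTATION = "orientation"
    IMMEDIATE_MEMORY = "immediate_memory"
    MONTHS_BACKWARDS = "months_backwards"
    PUZZLE = "puzzle"
    SPATIAL_REPRESENTATION = "spatial_representation"
    DELAYED_MEMORY = "delayed_memory"
    NAMING = "naming"
    COMPREHENSION = "comprehension"
    TMT_A = "tmt_a"
    TMT_B = "tmt_b"
    METAPHOR = "metaphor"


#: Fixed administration / reporting order.
TASK_ORDER: tuple[Task, ...] = tuple(Task)

#: Default raw-score maximum per task.  Orientation asks 3 questions, the two
#: word lists have 6 words, months backwards 5 slots, the puzzle 4 pieces,
#: spatial representation 3 clock trials, naming 4 pictures, comprehension a
#: single keyed command, the two trail-making variants are scored on a 0-14
#: accuracy-by-speed scale, and the metaphor has one keyed choice.
RAW_MAX: dict[Task, float] = {
    Task.ORIENTATION: 3,
    Task.IMMEDIATE_MEMORY: 6,
    Task.MONTHS_BACKWARDS: 5,
    Task.PUZZLE: 4,
    Task.SPATIAL_REPRESENTATION: 3,
    Task.DELAYED_MEMORY: 6,
    Task.NAMING: 4,
    Task.COMPREHENSION: 1,
    Task.TMT_A: 14,
    Task.TMT_B: 14,
    Task.METAPHOR: 1,
}

#: Tasks whose raw score counts typed words order-free (one credit per target).
ORDER_FREE_TASKS = frozenset({Task.IMMEDIATE_MEMORY, Task.DELAYED_MEMORY})

#: Tasks whose raw scale is a small integer count (discretised in simulation).
INTEGER_RAW_TASKS = frozenset(Task) - {Task.TMT_A, Task.TMT_B}

WEIGHTED_MAX = 9.0
N_TASKS = 11
#: Eleven tasks at 9 points sum to 99; the global score is reported on 0-100.
TOTAL_RESCALE = 100.0 / 99.0

#: Non-task event channels allowed in a session file.
CHANNEL_DEMOGRAPHICS = "demographics"
CHANNEL_COGNITIVE_RESERVE = "cognitive_reserve"
KNOWN_CHANNELS = frozenset(t.value for t in Task) | {
    CHANNEL_DEMOGRAPHICS,
    CHANNEL_COGNITIVE_RESERVE,
}
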