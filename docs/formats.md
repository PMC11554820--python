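# File formats

All files are comma-separated UTF-8 text with a mandatory header row and dot
decimal separators. Dates are ISO-8601 (`YYYY-MM-DD`). Validation is
collect-all: every violation is reported (per row), nothing is silently
dropped.

## Session file (one administration)

One row per recorded event, in presentation order. Read by
`read_session_csv` / `gems-norm score`, written by `write_session_csv`.

| column | meaning |
| --- | --- |
| `examinee_id` | opaque identifier, constant within the file |
| `administration_date` | ISO date; drives the orientation answer key |
| `version` | battery version, `A` or `B` |
| `task_id` | one of the 11 task ids, `demographics`, or `cognitive_reserve` |
| `item_id` | item within the task (see below) |
| `response` | raw response payload (typed text, option id, clicked label) |
| `elapsed_s` | non-negative seconds since task onset |

Task ids and item conventions:

- `orientation` — items `season`, `year`, `geography`; typed/selected text.
- `immediate_memory`, `delayed_memory` — items `slot_1..slot_6`; typed words,
  matched case-insensitively, order-free, one credit per target word.
- `months_backwards` — items `slot_1..slot_5`; compared positionally against
  October, August, June, April, February (Italian lexicon by default).
- `puzzle` — items `piece_1..piece_4`; response is the slot index where the
  piece was dropped (`piece_k` is correct in slot `k`).
- `spatial_representation` — items `trial_1..trial_n`; keyed options.
- `naming` — items `item_1..item_4`; typed object names.
- `comprehension` — items `press_1..`; recorded keys, correct iff exactly
  B, A, A.
- `tmt_a`, `tmt_b` — items `click_1..`; response is the clicked label; the
  task duration is the largest `elapsed_s` in the task block.
- `metaphor` — item `choice`; selected option id.
- `demographics` — items `age`, `education`, `sex`.
- `cognitive_reserve` — items `education_1`, `education_2`, `work_1`,
  `work_2`, `leisure_1`, `leisure_2`; ordinal responses 0–4.

Unknown `task_id` values are collected into a rejects report, never dropped.

## Normative cohort table

One row per examinee. Read by `read_normative_table` /
`gems-norm norms fit` / `gems-norm validate`; written by
`write_normative_table` and `gems-norm simulate`.

Columns: `age` (years, ≥ 18), `education` (years), `sex` (`F`/`M`),
`cr` (cognitive-reserve index, > 0), the 11 weighted task scores
(`orientation` … `metaphor`, each in [0, 9]), `total` (in [0, 100]).

Rows violating a range are flagged with the specific violation and excluded
from fitting (`NormativeTable.valid()`), but retained in the table.

## Retest pair table

One row per examinee retested. Read by `read_retest_table` /
`gems-norm change fit`; written by `gems-norm simulate --retest`.

Columns: `examinee_id`, `version_t0`, `version_t1` (A/B), `interval_days`
(> 0), `t0_total`, `t1_total`.
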