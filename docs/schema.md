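# Table schemas

All tables are comma-separated text with a header row. Times are in
milliseconds; locations and keys are 1-based, left to right.

## Trial table (`trials.csv`, `trials_filtered.csv`)

| column | type | meaning |
|---|---|---|
| participant | int | unique participant id |
| scenario | str | generating scenario label |
| material | str | `probabilistic` or `mixed_deterministic` |
| instructions | str | `concealed` or `revealed` |
| block | int | SRTT block, 1..14 |
| block_pair | int | ceil(block/2), 1..7 |
| trial | int | trial index within block, 1..144 |
| stimulus_location | int | stimulus location, 1..6 |
| trial_type | str | `regular`, `nonregular`, `deterministic`, `undefined` |
| block_kind | str | `probabilistic`, `random`, `deterministic` |
| predicted_location | int | sequence successor of the previous stimulus (0 on the session's first trial) |
| pressed_key | int | executed key, 1..6 |
| rt_ms | float | response time (ms) |
| correct | bool | pressed_key equals stimulus_location |
| deadline_ms | float | response deadline of this trial (ms) |
| deadline_exceeded | bool | rt_ms > deadline_ms |
| post_feedback | bool | previous trial was an error or deadline violation |
| motor_regular | bool | pressed_key equals predicted_location |

## Participant table (`participants.csv`)

| column | type | meaning |
|---|---|---|
| participant | int | unique participant id |
| scenario / material / instructions | str | as above |
| sequence | str | the six-item sequence, e.g. `2-1-6-5-3-4` |
| belief_sequenced | bool | interview: believed the material was sequenced |
| free_recall_correct | int | correctly reproduced transitions, 0..6 |
| forced_choice_correct | int | correct forced-choice answers, 0..6 |
| offset_* | float | true link-scale participant offsets (synthetic data only) |

## Screening report (`screening_report.csv`, `screening_rates.csv`)

Per participant: `included` flag and human-readable `reason`; rates
table holds per-block-pair `error_rate`, `slow_rate` and `n_trials`.

## Posterior draws (`mu_draws.csv`, `sigma_draws.csv`)

One column per group-level quantity (e.g. `beta[regular,3]`,
`alpha[all,2]`, `xi[all,4]`, or `delta[regular,slope]` for the
regression structure), link scale, one row per retained draw, plus a
`chain` column. `posterior_summary.csv` carries per-quantity posterior
mean/SD/CI on link and natural scales with R-hat and effective sample
size; `fit_metadata.json` records chains, draws, seed, coding and
convergence status.
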