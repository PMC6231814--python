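# Cohort CSV schema

Wide format: one row per participant, UTF-8, header row, empty cell =
missing. Column order as produced by `promval.cohort.expected_columns`.

| column | type | meaning |
|---|---|---|
| `participant_id` | string, unique | opaque identifier |
| `has_low_back_pain` | 0/1 | low back pain is the main complaint (inclusion flag) |
| `chronicity` | `acute_subacute` \| `chronic` | pain duration < 3 months vs longer |
| `none_box_available` | 0/1 | whether the "none of the above" confirmation box existed when this participant enrolled (0 = early era, zero-imputation rules apply) |
| `submitted_t0`, `submitted_t1w`, `submitted_t6w` | 0/1 | a submission was made at the timepoint (needed because a blank score with a submission is not the same as no submission) |
| `ermdq_t0`, `ermdq_t1w`, `ermdq_t6w` | integer 0–24 | disability questionnaire sum score |
| `evas_t0`, `evas_t1w`, `evas_t6w` | integer 0–100 | pain-intensity slider, scale units |
| `enrs_t0`, `enrs_t1w`, `enrs_t6w` | integer 0–10 | pain-intensity rating (required on submission) |
| `transition_t1w`, `transition_t6w` | integer 1–7 | global rating of change: 1 completely recovered, 2 much improved, 3 slightly improved, 4 no change, 5 slightly worsened, 6 much worsened, 7 vastly worsened |

Validation on read rejects out-of-range or off-grid scores, transition
values outside 1–7, non-binary flags, unknown chronicity levels, and
duplicate participant ids, naming the participant and field in each
problem.
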