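# promtriage

Routine follow-up after total hip arthroplasty (THA) traditionally means a
hospital visit around six weeks after surgery, yet most patients recover
uneventfully and could be seen by video instead.  Many hospitals already
collect patient-reported outcome measures (PROMs) at three months —
numeric rating scales (NRS) for pain at rest and during activity, the
EQ-5D-3L with EQ VAS, the Oxford Hip Score (OHS), the HOOS Physical-function
Shortform, and an anchor question.  `promtriage` turns that existing PROM
stream into a triage instrument: it scores the instruments, reduces a
candidate set of threshold questions by clinimetric criteria on a training
cohort, and allocates each patient to a **hospital** or **video**
consultation.

The package is written for orthopaedic outcome researchers and registry
analysts who want a tested, reproducible implementation of this workflow —
including a synthetic cohort generator, because no patient-level data are
distributed with the underlying study.

## The triage rule

Two clinical criteria — *moderate or severe pain* and *using 2 crutches* —
are operationalised as per-question thresholds (question, worse-side
comparator, cutoff):

| group | question | threshold |
|---|---|---|
| pain | NRS pain at rest (0–10) | ≥ 4 |
| pain | NRS pain during activity (0–10) | ≥ 4 |
| pain | EQ-5D-3L q4 pain/discomfort (1–3) | ≥ 3 |
| pain | OHS q1 usual pain (0–4) | ≤ 1 |
| pain | OHS q8 pain standing up (0–4) | ≤ 2 |
| pain | OHS q10 sudden pain (0–4) | ≤ 1 |
| pain | OHS q12 pain in bed (0–4) | ≤ 2 |
| crutches | EQ-5D-3L q1 mobility (1–3) | ≥ 3 |
| crutches | OHS q6 walking time (0–4) | ≤ 2 |

A patient crossing **any** threshold at three months is allocated to a
hospital consultation; a patient observed on at least one rule item who
crosses none goes to video.  Both the nine-question candidate rule and the
six-question final rule ship as package data (`candidate_9item`,
`final_6item`).

## Clinimetric item selection

`run_selection` reduces the candidate questions on a training cohort in a
fixed, logged order:

1. **distribution** — drop questions whose 3-month median and quartiles
   coincide (no discrimination);
2. **floor effect** — drop questions with > 15% of respondents at the worst
   score;
3. **responsiveness** — Wilcoxon signed-rank on preoperative vs 3-month
   paired scores, drop if p > .05;
4. **patient journey** — drop questions whose threshold-crossers at 3 months
   have "scored well" by 12 months (12-month median no longer crossing);
5. **correlation** — Spearman redundancy pruning: within each correlated set
   keep one question;
6. **homogeneity** — Cronbach α per criterion group with scale-if-item-
   deleted; a question whose deletion raises α above 0.7 misfits its group.

Two configuration profiles ship: `stated` (correlation cutoff |ρ| ≥ 0.7) and
`paper` (cutoff 0.6 with an NRS-activity keep-list).  See
`docs/methods.md` for why both exist and for every other numerical choice.

## Worked example

```sh
promtriage run --seed 1 --outdir out
```

simulates the two-cohort synthetic population (training n=746, test n=482),
runs the selection with the replication profile, triages both cohorts with
the resulting rule, and prints:

```json
{
  "n_training": 746,
  "n_test": 482,
  "removed": ["NRS_REST", "OHS_Q1", "OHS_Q10"],
  "retained": ["NRS_ACTIVITY", "EQ5D3L_Q4", "OHS_Q8", "OHS_Q12",
               "EQ5D3L_Q1", "OHS_Q6"],
  "response_rate_m3_training": 94.1,
  "hospital_percent_training": 30.2,
  "hospital_percent_test": 28.2,
  "p_value": 0.497
}
```

Reading: NRS pain at rest and OHS question 1 were pruned as redundant with
NRS pain during activity, OHS question 10 carried no information at three
months, and the remaining six questions send roughly 30% of each cohort to a
hospital consultation; the chi-square p-value says the two cohorts' rates
are statistically compatible.  `out/` contains the per-patient allocations,
the selection report, the final rule JSON, and a manifest with digests and
seeds; a rerun with the same seed reproduces every artifact byte for byte.

The same steps are available as a library:

```python
from promtriage import (make_paperlike_fixture, run_selection, paper_profile,
                        load_rule, triage_cohort, Timepoint)

training, test = make_paperlike_fixture(seed=1)
sel = run_selection(training, load_rule("candidate_9item"), paper_profile())
summary, outcomes = triage_cohort(test, sel.final_rule, Timepoint.M3)
print(sel.retained, summary.hospital_percent)
```

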