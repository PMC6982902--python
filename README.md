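# motiontutor

An adaptive motion-teaching engine for wearable motor-learning systems.
It implements, as a tested Python library plus CLI, the complete software
loop of a prototype that teaches fast periodic movements (the motivating
task is a butterfly-stroke arm drill) through vibrotactile feedback:

* **Preprocessing** of MEMS inertial streams: quaternion attitude →
  rotation matrix `A`, sensor→inertial frame change `a_iner = Aᵀ·a`,
  gravity removal, a first-order IIR low-pass
  `oᵏ = (1−α)oᵏ⁻¹ + α·fᵏ`, and bounded-drift integration to velocity and
  position.
* **Invariant pattern matching.** A one-period template `P = (p¹…p^w)` is
  compared with the trailing window of a signal `S = (s¹…s^m)` through

  `g(P,S,a,b,c,d) = (1/n) Σₖ (p^{wrap(round(b−ak))}·c + d − s^{m−k})²`,

  and the distance `h = min g` over a discrete grid of the four transform
  parameters (time scale/shift `a, b`; value scale/offset `c, d`) is found
  with a two-stage coarse-to-fine search after normalizing both windows to
  `[−0.6, 0.6]`.
* **kNNModel classification** of the current multi-dimensional signal
  against a labelled pattern bank, `dist(P_u, S) = (1/N) Σᵢ h(P_{i,u}, Sᵢ)`,
  majority vote over the k nearest entries.
* **Synchronization**: the fitted time shift `b` *is* the current pattern
  probe ("time point" τ); per-signal candidates are merged by a
  reliability-weighted circular mean.
* **Teaching algorithms.** Per 10 ms tick, the motion-error vector
  `e` drives per-actuator vectors `gᵢ = C·e`, `wᵢ = A·gᵢ`, `oᵢ = G·wᵢ`;
  the **Cα** regulator pulses the dominant actuator's directional unit at
  period end, gated by `len = 0.03 m`, `elaps = 2.5 s` and an
  outward-crossing test; the **Cβ** algorithm pulses a teacher-chosen unit
  when τ crosses a configured probe. Classification selects which
  algorithm runs.
* **Evaluation**: phase-aligned RMSE per position signal, the efficiency
  parameters E1 (mean RMSE on 0.3–0.9 of the test signal), E2 (30 s window
  anchored at the longest correctly-classified interval) and
  E3 = E2_test − 0.25·E2_pre, plus the Shapiro–Wilk / Levene / one-sided
  pooled-t battery with a bundled per-participant table.
* **A virtual learner** replaces hardware and human subjects: a seeded
  generator of closed x–z hand trajectories (2 s period, a timed pause at
  the top in the correct class, no pause in the error class) rendered as
  sensor-frame accelerations with gravity, orientation wobble and
  0.4 mg/√Hz accelerometer noise.

## Worked example

The statistical battery on the bundled participant table (two groups of
nine learners; method 1 uses classification-driven algorithm selection,
method 2 a fixed algorithm; all values in millimetres):

```text
$ motiontutor stats --out stats.json
E1: mean1=71.3 sd1=15.0 mean2=94.6 sd2=34.6 t=1.85 (crit 1.746) p=0.042
E2: mean1=69.1 sd1=20.7 mean2=95.9 sd2=36.6 t=1.91 (crit 1.746) p=0.037
E3: mean1=44.2 sd1=25.7 mean2=70.2 sd2=31.1 t=1.93 (crit 1.746) p=0.036
```

Each row compares the two teaching methods on one efficiency parameter:
the classification-assisted group shows smaller errors, the pooled
one-sided t exceeds its critical value, and p < 0.05 — the adaptive
method teaches measurably better.

A full closed-loop session from synthetic data:

```sh
motiontutor simulate --seed 11 --mode c_alpha --duration 8 --out a1.csv
motiontutor simulate --seed 11 --mode c_beta  --duration 8 --out b1.csv
# ... two more recordings per class (seeds 12, 13) ...
motiontutor build-patterns --out bank.json \
    --stream a1.csv --label c_alpha --stream b1.csv --label c_beta # ...
motiontutor simulate --seed 21 --duration 12 --out test.csv
motiontutor classify --bank bank.json --stream test.csv --out timeline.csv
motiontutor teach    --bank bank.json --stream test.csv --out log.csv
motiontutor evaluate --bank bank.json --stream test.csv \
    --timeline timeline.csv --out report.json
```

`log.csv` holds one row per 10 ms tick (`t, tau, reliable, label,
actuator_id, unit_id`); `report.json` holds the E1/E2 values of the test
recording in millimetres.

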