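# rwpt — scoring and cohort statistics for the 3D real-world pointing task

`rwpt` analyzes a clinical bedside test of spatial orientation: a seated,
blindfolded participant points at remembered wall targets (a 3 × 3 matrix at
192 cm, eye level on the center row) before, during and after passive
90° whole-body yaw rotations.  The task probes whether a patient can update
their mental representation of static world targets from vestibular and
somatosensory rotation cues alone — the ability that is degraded in
bilateral vestibulopathy (BVP, peripheral loss of rotation sensing) and,
despite an intact labyrinth, in persistent postural–perceptual dizziness
(PPPD, hypothesized central suppression or misintegration of vestibular
input).

The package provides:

* **Geometry & scoring** — pointing directions in room-frame spherical
  coordinates (azimuth φ = horizontal, the plane of the rotations; polar
  θ = vertical).  For each test paradigm *p*, reference frame
  *c* ∈ {retinotopic, world} and plane, the accuracy score is the mean
  absolute angular deviation over the nine targets,
  D<sub>p,c</sub> = (1/9) Σ<sub>t</sub> |φ<sub>t</sub> − φ̂<sub>t,c</sub>|
  (floor 0°), with deviations computed against each participant's own
  calibrations.  Derived metrics: overall accuracy (mean over the five
  paradigms), initial reproduction, transformation (pointing while rotated),
  post-rotation (back at start), the encoding-strategy index
  S = D<sub>retinotopic</sub> − D<sub>world</sub> (negative ⇒ egocentric
  encoding), and a disorganization metric (mean SD of the nine signed
  per-target deviations).
* **A synthetic-cohort generator** — a minimal generative model (motor
  noise, cumulative vestibular heading error with gain and per-rotation
  tracking noise, reference-frame weighting) that emits raw trial logs and
  metadata for an HC/BVP/PPPD cohort (32/43/32 by default), so the full
  pipeline runs and is testable with no external data.
* **The statistical battery** — age-corrected one-way ANCOVAs with
  bootstrap/Tukey post hoc contrasts, Levene-gated Kruskal–Wallis + Dunn
  tests, Welch t-tests, Spearman correlations with Fisher's
  z = atanh(ρ), and the a priori noncentral-F sample-size computation
  (λ = f²·N).

## Worked example

```python
from dataclasses import replace
from rwpt import PointingCohortModel, PowerSpec, anova_required_n
from rwpt.io import _frame_to_trials
from rwpt.simulate import SimulationConfig, simulate_cohort
from rwpt.stats import default_plan

anova_required_n(PowerSpec(effect_size_f=0.40, alpha=0.05, power=0.95, n_groups=3))
# 102   <- balanced total N needed to detect a large effect at 95% power

trials, metadata = simulate_cohort(SimulationConfig(master_seed=0))
model = PointingCohortModel.from_trials(_frame_to_trials(trials), metadata,
                                        plan=replace(default_plan(seed=0), n_boot=200))
res = model.fit()

j = model.metrics.merge(metadata, on="participant_id")
j[(j.frame == "retinotopic") & (j.plane == "azimuth")] \
    .groupby("group")[["overall_dev", "postrotation_dev", "strategy_index"]].mean().round(2)
#        overall_dev  postrotation_dev  strategy_index
# group
# BVP           9.11              8.40           -0.09
# HC            4.75              4.84           -0.00
# PPPD          6.56              6.91           -0.02

res.pvalue("postrotation_retinotopic_azimuth")   # 0.0000 — groups separate in azimuth
res.pvalue("postrotation_retinotopic_polar")     # 0.2848 — no group effect in polar
print(res.summary())                             # full Markdown report
```

The numbers show the structure the task is designed to expose: the synthetic
BVP cohort accumulates the largest heading error after the rotations
(post-rotation deviation 8.4° vs 4.8° in controls, PPPD intermediate), and
the group effect is confined to the azimuth plane — the plane of the
vestibular stimulus — while vertical pointing is indistinguishable across
groups.

A YAML-driven CLI wraps the same pipeline
(`rwpt simulate | score | stats | power | run`, see `configs/demo.yaml`):

```bash
rwpt run --config configs/demo.yaml --seed 0
rwpt power -f 0.40 --alpha 0.05 --power 0.95 -k 3
```

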