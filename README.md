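# vheart

A desk-scale virtual heart: whole-organ cardiac electrophysiology with
a 12-lead ECG, for method development and teaching in computational
cardiology. The package builds a synthetic four-chamber heart inside a
torso volume conductor, equips it with a His-Purkinje conduction system
and an AV node, solves activation and repolarization of one heartbeat,
and computes the resulting body-surface electrocardiogram — including
complete left/right bundle-branch-block pathologies checked against
clinical ECG criteria. No patient data are required; everything is
generated parametrically and deterministically from a seed.

## The model in brief

* **Activation** — anisotropic Eikonal equation
  `|∇T|_M = 1`, `M = v_f²ff' + v_s²ss' + v_n²nn'`, solved by a fast
  iterative method on tetrahedral meshes; ventricular CVs 0.6 m/s with
  4:2:1 off-axis ratios, atrial 1.2 m/s, Bachmann's bundle 2.25 m/s.
* **Conduction system** — stochastic fractal His-Purkinje tree (mean
  cable 6 mm, 45° sibling repulsion, 500 µm discretization, 2.0 m/s)
  with five fascicles, PMJ delays 8/3 ms (antegrade/retrograde),
  terminal-cable CV tuning of fascicular root timings, and a 1-D AV
  node cable tuned to a 200 ms PR interval.
* **Membrane** — Mitchell-Schaeffer dynamics
  (ν_gate 0.13, τ_close 175 ms, τ_in 0.3 ms, τ_out 5.4 ms; −86.2 to
  +40 mV), with repolarization prescribed by the linear ARI map
  `ARI(x) = −0.66·AT(x) + 215 ms` and reconstructed reaction-Eikonal
  style over a 700 ms beat.
* **Forward problem** — precomputed FEM lead fields on the torso
  (lungs 0.0389, blood 0.7, torso 0.22 S/m; RL ground), ECG as
  `φ_e = −∫ ∇Z_e·(σ_i∇V_m) dV`, plus pseudo-bidomain recovery of
  BSPMs/electrograms and an infinite-medium pseudo-ECG; zero-phase
  150 Hz / 0.5 Hz filtering.
* **Analysis** — beat splitting and averaging, L2/Pearson comparison
  (0.32 amplitude scaling), RMS-envelope interval detection, and
  operational AHA-style complete-LBBB/RBBB criteria reports.

## Worked example

```python
from vheart import Pipeline, Scenario
from vheart.analysis import check_lbbb

pipe = Pipeline(seed=1)          # anatomy, torso, lead fields, HPS
pipe.tune_avn()                  # AV-node CV -> PR = 200 ms

sinus = pipe.run_scenario(Scenario(seed=1))
print(sinus.intervals.pr_ms, sinus.intervals.qrs_ms)

lbbb = pipe.run_scenario(Scenario(block="left", seed=1))
print(lbbb.intervals.qrs_ms)
print(check_lbbb(lbbb.ecg, lbbb.intervals).checks)
```

prints

```
200.0 86.0
141.0
{'qrs_gt_120': True, 'v1_v2_w_shape': True,
 'v5_v6_notched_positive': True, 'st_discordance': True}
```

i.e. the tuned sinus beat has a physiological PR of 200 ms and a QRS of
86 ms; interrupting the left bundle branch broadens the QRS to 141 ms
and the 12-lead ECG shows the W-shaped S waves in V1/V2, the notched
all-positive R in V5/V6 and the ST/T discordance that define complete
LBBB. Reducing the longitudinal CV to 0.3 m/s in the blocked ventricle
(`cv_mode="reduced"`) broadens the QRS further. `run_scenario` returns
the activation map, the transmembrane traces, raw and filtered ECGs,
measured intervals and a reproducibility manifest.

The same pipeline is scriptable from the shell:

```
vheart build-anatomy --out mesh/
vheart build-hps --seed 1 --out hps.json
vheart simulate --scenario lbbb --seed 1 --out run/
vheart analyze --ecg run/ecg.csv --criteria lbbb
```

Meshes are written in the openCARP text dialect (`.pts/.elem/.lon`),
activation maps as `.dat`, ECGs as CSV.

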