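# coatkit

Growth-law modelling and quantification of clathrin-coat morphology
dynamics during clathrin-mediated endocytosis (CME).

## The problem

A clathrin-coated vesicle can form in two ways: the coat may polymerise
with constant curvature from the start, or grow as a flat lattice that
bends later at (roughly) constant surface area. Electron microscopy of
unroofed membranes shows only snapshots — per-structure morphology class
(flat, dome, pit) and projected area — while live-cell fluorescence
(AP2 adaptor + clathrin light chain, CLC) shows only per-event intensity
dynamics. `coatkit` connects the two: it fits explicit growth laws to
per-event intensity tracks, converts the fitted time courses into
predicted steady-state morphology and size distributions through
spherical-cap geometry, and compares them with EM and correlative
light–electron microscopy (CLEM) measurements. It is aimed at
quantitative cell biologists analysing CME track tables and EM/CLEM
morphometry.

## Models

A curved coat is a spherical cap of tip radius `R` and contact angle `θ`
with surface area `S = 2πR²(1 − cos θ)` and projected (silhouette) area
`πR² sin²θ` for `θ ≤ π/2`, saturating at `πR²` beyond the hemisphere. The
surface-to-projected **correction factor** rises from 1 (flat) to 2
(dome) to 4 (complete sphere).

Flat growth follows an edge-assembly/area-loss law

    dA/dt = α√A − βA   ⇒   A(t) = A_max (1 − e^{−(t−t0)/τ})²,
    A_max = (α/β)²,  τ = 2/β.

Two growth scenarios are implemented on top of it:

- **constant-area**: grow flat to `A_max`, then bend at constant surface;
- **flat-to-curved**: start bending at a fraction `f* = 0.70` of the
  final content, on a sphere of fixed tip radius with `dθ/dt = ω` until a
  maximal pit angle `θ_max` (default 160°), which stops growth
  intrinsically.

The curved phase is split dome:pit = 40:60 by duration, matching the
abundance ratio seen in EM snapshots. The AP2 plateau (fitted curve at
`(1 − ε)A_max`, `ε = 0.05`) marks the transition in the AP2-plateau
scenario; under osmotic shock, where growth stalls, the transition is
detected instead by a sustained 5% excess of normalized CLC over AP2.
CLEM calibration regresses summed fluorescence on projected area over
flat coats and infers per-class correction factors; comparing them
between channels yields the AP2/clathrin stoichiometry versus curvature.

## Worked example

Simulate 100 two-channel tracks under the AP2-plateau scenario, fit them,
and predict the snapshot ensemble — all through the pipeline front end:

```python
from coatkit import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(seed=1, n_samples=10_000,
                                      sim={"n_tracks": 100}))
```

This prints (abridged):

```
"n_fitted": 93,
"offsets": {
  "time_offset_median_s": 9.33,
  "intensity_offset_median": 0.135,
  "clc_content_at_plateau_median": 0.862
},
"ensemble": {
  "fractions_pct": {"flat": 84.6, "dome": 6.0, "pit": 9.4},
  "group_sd_pct":  {"flat": 1.7,  "dome": 0.8, "pit": 1.1},
  "n_removed_below_limit": 25, "detection_limit_nm2": 1000.0
},
"clem": {
  "clathrin": {"dome_factor": 1.36, "pit_factor": 2.70},
  "ap2_clathrin_ratio": {"flat": 1.0, "dome": 0.89, "pit": 0.64,
                         "monotone_decreasing": true}
}
```

Reading: 93/100 tracks gave convergent fits; the CLC maximum lags the
AP2 plateau by ~9.3 s (median) and overshoots it by ~13% on
plateau-normalized intensities, recovering the generator's configured
10 s / 0.15 offsets. Pooling random time points from every fitted event
predicts 84.6% flat, 6.0% dome and 9.4% pit structures (±SD across
simulated cells) after removing 25 predicted objects below the 1000 nm²
TEM detection limit. The CLEM stage recovers the embedded curvature
correction factors (true 1.4/2.8 for the clathrin channel) and shows the
AP2/clathrin density ratio falling with curvature (flat 1 → dome 0.89 →
pit 0.64).

The same steps are available as CLI subcommands operating on delimited
tables:

```bash
coatkit simulate --kind tracks --n 200 --seed 1 --out tracks.csv
coatkit fit-tracks tracks.csv --out fits.csv
coatkit predict-ensemble tracks.csv --n-samples 10000 --seed 1
coatkit clem-calibrate clem.csv
coatkit shock-analysis shock_tracks.csv
coatkit compare predicted.csv measured_em.csv
```

Track tables use columns `track_id, t_s, ap2, clc, condition,
shock_onset_s[, cell_id]`; EM tables `structure_id, membrane_id,
morphology, projected_area_nm2`; CLEM tables `structure_id, morphology,
projected_area_nm2, fluorescence_sum, channel, membrane_id`. A column map
in the YAML config adapts externally produced tables to these schemas.

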