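# emgmap

Spatial mapping of forearm muscle activity from high-density surface EMG
(sEMG) grids during cyclic wrist and finger movements.

## The problem

Controlling hand prostheses, exoskeletons and orthoses from surface EMG
requires knowing *where* on the forearm the activity of distinct muscles
appears, and how stable those locations are when the hand changes position.
With a grid of monopolar electrodes wrapped around the forearm (here 14
columns around the circumference x 8 proximal-distal rows, inter-electrode
distance IED = 15 mm), muscle activity becomes a spatial map that can be
segmented into per-movement activity areas — and those areas can then guide
targeted electrode placement.

`emgmap` implements the full analysis chain for such recordings, plus a
synthetic-data generator with planted ground truth (source positions,
temporal modules, condition shifts, gains) so that every stage can be
validated end to end:

1. **Preprocessing** — zero-phase 4th-order Butterworth band-pass
   (20–450 Hz), power-line removal by spectral interpolation (50 Hz and four
   higher harmonics), bad-contact channel detection, envelope extraction
   (rectification + zero-phase 1 Hz low-pass).
2. **Cycle analysis** — glove kinematics resampled to the EMG rate, movement
   cycles cut where the joint angle exceeds the previous extension plateau
   by 2°, range-of-motion outliers excluded (Tukey fences), envelopes
   time-normalized to 500 points per cycle, repeatability quantified by the
   coefficient of multiple correlation (CMC).
3. **Motor modules** — non-negative matrix factorization of the
   concatenated mean envelopes, `M ≈ A·S` with spatial coefficient maps `A`
   (channels x N) and temporal modules `S` (N x time); best of 100 random
   restarts; module count chosen as the least N with
   `VAF = 1 − SSE/SST ≥ 0.90` (uncentered SST = ΣM²).
4. **Map segmentation** — marker-free watershed on the equalized coefficient
   map, then the 70%-of-regional-maximum threshold defines each electrode
   activity cluster; clusters are summarized by their center of gravity
   `x̄ = Σ c_el·x_el / Σ c_el` (in IED units), pairwise overlap (normalized
   to the smaller and the larger cluster), inter-condition COG shifts and
   barycenter-weight ratios; Wilcoxon signed-rank test on paired COGs.
5. **Angle reconstruction** — per-joint multilayer perceptron (one hidden
   layer of 6 tan-sigmoid units, linear output, Levenberg–Marquardt
   training with early stopping) mapping monopolar envelopes to the joint
   angle; four-fold cycle-wise cross-validated r²; one-way ANOVA +
   Student–Newman–Keuls post-hoc to compare electrode subsets (proximal
   ring vs COG-targeted).

## Worked example

```bash
python examples/extract_motor_modules.py
```

```
cycles found: 20, kept: 20
bad channels masked: [14, 56, 97]
median CMC over active channels: 0.989
VAF by module count:
  N= 1  VAF=0.5087
  N= 2  VAF=0.8654
  N= 3  VAF=0.9994 <- selected
  ...
module 2 (extensor): temporal peak at cycle phase 0.62
module 0 (flexor): temporal peak at cycle phase 0.18
```

The generator planted three sources; the pipeline finds all 20 movement
cycles, masks exactly the three planted bad channels, measures highly
repeatable envelopes (CMC 0.989 on active channels) and selects N = 3
modules — the VAF curve crosses the 0.90 criterion exactly where the
planted dimensionality says it should.  The extensor module peaks in the
second half of the normalized cycle (the extension phase), the flexor in
the first half.

Segmenting the module maps localizes the sources
(`examples/segment_activity_maps.py`):

```
module      cluster COG (x, y)    planted center        error [IED] electrodes
extensor    ( 4.48,  4.51)      ( 4.41,  4.57)      0.10        4
flexor      (10.66,  3.72)      (10.68,  3.93)      0.20        3
```

and comparing hand positions (`examples/hand_position_shift.py`) recovers
the planted 0.8 IED ulnar-radial displacement and the planted amplitude
gains (extensor 1.4, flexor 0.5) as barycenter-weight ratios:

```
module extensor: ulnar-radial COG shift 0.96 IED (planted 0.8), weight ratio prone/neutral 1.49
module flexor:   ulnar-radial COG shift 0.83 IED (planted 0.8), weight ratio prone/neutral 0.50
```

Finally, `examples/reconstruct_joint_angle.py` shows why the maps matter
for electrode placement: three electrodes at the cluster barycenters beat a
full 14-electrode proximal ring at reconstructing the wrist angle:

```
ring  subset (14 electrodes): r^2 = 0.137 +- 0.059
cog   subset ( 3 electrodes): r^2 = 0.902 +- 0.025
ANOVA: F=423.49, p=0.0000; SNK flags ring vs cog: True
```

## Command line

```bash
emgmap simulate --kind wrist --seed 1 --out wrist.h5   # one recording to HDF5
emgmap run --out results/ --seed 1                     # full multi-subject study
```

## Layout

```
src/emgmap/        grid, recording containers, synthetic generator,
                   preprocess, cycles, nnmf, segmentation, reconstruct,
                   stats, pipeline, study, io, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and recovery tests)
docs/methods.md    model, parameters, numerical choices, limitations
```
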