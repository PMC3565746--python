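# hes1rdme

Spatial stochastic simulation of the Hes1 gene regulatory network in a
single embryonic stem (ES) cell, with wavelet-based oscillation analysis
and in-silico drug-treatment experiments.

Hes1 is a basic helix–loop–helix transcription factor whose negative
feedback on its own promoter drives noisy cyclic expression with a period of
a few hours; in ES cells the cell-to-cell variability of these oscillations
is linked to heterogeneous differentiation (sustained high Hes1 biases cells
toward mesodermal fates, low Hes1 toward neural fates).  Because copy
numbers are low and the key reactions are spatially localized — transcription
at a single promoter site in the nucleus, translation in the cytoplasm —
the natural modelling framework is the **reaction–diffusion master equation
(RDME)**: a continuous-time Markov jump process over the copy numbers
x<sub>li</sub> of each species *l* in each voxel *i* of a discretized cell,
with reactions local to voxels and diffusion as first-order jump events
S<sub>li</sub> → S<sub>lj</sub> at rate q<sub>lij</sub> = D<sub>l</sub>/h²
between face-adjacent voxels.  Trajectories are sampled *exactly* with the
**next subvolume method (NSM)**, an event-driven scheme that keeps a
per-voxel next-event time in an indexed binary heap.

## The model

The cell is two concentric spheres (cytoplasm radius 7.5 μm, nucleus radius
3 μm) voxelized on a Cartesian lattice (default edge 1 μm, ≈1 800 voxels).
The promoter occupies a single "gene voxel" at depth *r* inside the nuclear
membrane (default *r* = 3 μm: the voxel at the cell centre).  Four species —
hes1 mRNA (M), Hes1 protein (P) and the free/occupied promoter states
P<sub>f</sub>/P<sub>o</sub> — interact through seven mass-action channels:

| channel | localization | rate |
|---|---|---|
| P<sub>f</sub> + P → P<sub>o</sub> | gene voxel | k₁ = 1.00×10⁹ M⁻¹min⁻¹ |
| P<sub>o</sub> → P<sub>f</sub> + P | gene voxel | k₂ = 0.1 min⁻¹ |
| P<sub>f</sub> → P<sub>f</sub> + M | gene voxel | α<sub>m</sub> = 3.00 min⁻¹ |
| P<sub>o</sub> → P<sub>o</sub> + M | gene voxel | α<sub>m</sub>/γ, γ = 30 |
| M → M + P | cytoplasm | α<sub>p</sub> = 1.00 min⁻¹ |
| M → ∅ | everywhere | μ<sub>m</sub> = 0.015 min⁻¹ |
| P → ∅ | everywhere | μ<sub>p</sub> = 0.043 min⁻¹ |

mRNA and protein diffuse with D = 6.00×10⁻¹³ m² min⁻¹; promoter species do
not.  Simulations start from 60 proteins uniform in the cytoplasm, 10 mRNA
uniform in the nucleus and one free promoter, and run for 1200 min.

Oscillation periods are estimated with a complex **Morlet continuous
wavelet transform** (ω₀ = 6) on the whole-cell protein totals, with Gaussian
edge elimination (cone-of-influence removal) and an amplitude-calibrated
ridge.  Trajectories whose mean period exceeds 400 min, or whose oscillation
amplitude is negligible, are classified as **persistent expression (PE)**;
protein copy number above/below the trajectory mean at the 900-min decision
time predicts a mesodermal/neural fate.

## Worked example

```
$ hes1rdme simulate --seed 2 --t-end 1200 --out traj.csv
Mesh: 1791 voxels (edge 1.0 um), 123 nuclear / 1668 cytoplasmic; total volume 1791.0 um^3; gene voxel 895 at (0.00, 0.00, 0.00) um
3297877 events in 3.7 s -> traj.csv

$ hes1rdme analyze --input traj.csv --out analysis.json
{"mean_period_min": 213.35, "mean_amplitude": 114.68, "label": "oscillatory",
 "differentiation": "neural", "copy_number_at_decision": 744}
```

This trajectory oscillates with a mean period of ≈213 min (inside the
180–300 min range measured for Hes1 in ES cells) at an amplitude of ≈115
protein copies; at the 900-min transfer to differentiation medium its
protein count (744) lies below its own time mean, predicting a neural fate.
Other seeds yield persistent-expression trajectories or mesodermal calls —
the intrinsic-noise-driven heterogeneity the model is built to expose.

A small translation-inhibition experiment (α<sub>p</sub>/100 for 300 min,
five trajectories per arm):

```
$ hes1rdme drug --treatment translation --n 5 --seed 1
grand mean mRNA treated 124.8 vs wild-type 36.2 (x3.44)
```

Blocking translation removes the repressor, so mRNA rises more than
threefold — the signature of broken negative feedback.

The same functionality is available as a library:

```python
import hes1rdme as h

result = h.run_wildtype_ensemble(n=25, horizon=1200, base_seed=1)
print(result.pe_count, result.oscillatory_periods.mean())
```

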