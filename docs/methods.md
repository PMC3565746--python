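# Methods

## Model and assumptions

The package simulates the Hes1 negative-feedback loop as a reaction–
diffusion master equation (RDME): the state is the integer copy number of
each species in each voxel; reactions fire within voxels with mass-action
propensities, and diffusion is a first-order jump of one molecule to a
face-adjacent voxel.  The model deliberately avoids Hill-function promoter
kinetics: repression is an explicit bimolecular binding of one protein to
one promoter site, which is the natural description once the promoter is
spatially resolved as a single voxel.  Key structural assumptions:

- The promoter exists in exactly two states, free (transcribing at
  α_m) and occupied (α_m/γ); every channel conserves P_f + P_o = 1.
- Bound protein is sequestered: P_o neither diffuses nor degrades, and
  unbinding returns the protein intact.  Degrading bound protein would
  either break promoter conservation or add an un-modelled promoter-reset
  pathway.
- Transcribed mRNA appears in the gene voxel; translated protein appears in
  the voxel of its template mRNA (locality of the RDME); translation only
  occurs in cytoplasm voxels, degradation everywhere.
- The nuclear membrane is transparent to diffusion (continuity of flux);
  the cell membrane is zero-flux.  Nuclear import/export machinery,
  dimerization and active transport are out of scope.

## Geometry and diffusion

The cell is a ball of radius 7.5 μm with a concentric 3-μm nucleus,
voxelized on a regular Cartesian lattice aligned so one voxel is centred on
the origin.  A voxel belongs to the cell iff its centre lies strictly
inside the outer sphere, and to the nucleus iff its centre is within (or
exactly on) the inner sphere — the closed-ball rule keeps the discrete
nuclear volume within ~9% of (4/3)πR³ at the default 1-μm edge, where the
strict rule would lose the 30 lattice points sitting exactly on the
membrane and under-count the nucleus by ~18%.  Boundary voxels keep the
full h³ volume (no cut cells); total volume error is ≈1.3% at h = 1 μm and
shrinks with h.  On this mesh the exact discrete-Laplacian jump rate is
q = D/h² per shared face; boundary voxels simply have fewer faces, which
realises the zero-flux condition without special cases.  The gene voxel at
depth r is the nuclear voxel whose centre radius is nearest
(nucleus_radius − r), ties broken by lowest index for determinism.

The bimolecular binding rate is converted from molar units with the gene
voxel volume: c₁ = k₁/(N_A·V), V in litres (1 μm³ = 10⁻¹⁵ L); at h = 1 μm,
c₁ ≈ 1.661 min⁻¹ per protein–promoter pair.  This conversion — and hence
the effective repression strength — is resolution-dependent in any RDME of
a bimolecular reaction; see "Known limitations".

## Exact sampling: next subvolume method

Each voxel carries two group sums: total reaction propensity and total
outbound diffusion rate (Σ_s x_s·q_s·deg).  A per-voxel next-event time,
drawn exponentially from the group-sum total, lives in an indexed binary
min-heap; the earliest voxel fires, the event class is chosen
proportionally to the group sums, and the channel / species / destination
proportionally within the class.  After every state change the affected
voxel(s) recompute their sums and redraw a fresh exponential waiting time —
statistically exact by memorylessness and O(log V) per event.  The event
loop is compiled with numba; the Mersenne generator inside the kernel is
seeded explicitly, so a given (configuration, seed) pair reproduces a
trajectory bit for bit.  Trajectories are recorded as whole-cell totals on
a fixed grid (default 1 min — the state is piecewise constant, so grid
sampling is exact); optional per-voxel snapshots can be taken at listed
times.  A well-mixed Gillespie direct-method sampler (`ssa_wellmixed`) is
implemented independently, in plain Python, as a validation oracle: on a
single-voxel mesh with localization lifted, the two samplers target the
same process and their sampled distributions are compared by KS test in the
suite.

## Period estimation and classification

Protein totals are mean-detrended and transformed with a complex Morlet
wavelet, ψ(t) ∝ exp(iω₀t)·exp(−t²/2) with ω₀ = 6 (pywavelets
`cmor2.0-0.9549…`), on 64 geometric scales spanning periods of 60–600 min.
Two design points matter for accuracy:

- **Calibrated ridge.**  The raw CWT magnitude is not flat across scales,
  so the dominant scale is chosen on the amplitude spectrum normalised by
  the response of a unit-amplitude sinusoid at each scale (computed once
  per grid and cached).  This makes the ridge unbiased for sinusoids and
  reports amplitudes directly in copy numbers (pure test tones of 100–400
  min recover their period within ~4% and amplitude within ~2%; noisy
  tones at 20% noise recover the period within 10%).
- **Gaussian edge elimination.**  The ridge is located first over all
  scales; a time is then discarded whenever the ridge scale lies within its
  own cone of influence — within one Gaussian e-folding time (√2·s·dt) of
  either series end — where the envelope overlaps missing data.  Masking
  scales before locating the ridge instead forces edge regions onto small
  scales and biases the mean period low by tens of percent.

The mean period and mean amplitude are time-averages over the retained
support.  A broadband noise floor is measured as the median calibrated
amplitude over the sub-90-min band.

**Persistent expression (PE).**  A trajectory is PE when it does not
oscillate realistically: no retained ridge at all, mean period > 400 min,
amplitude below `amplitude_fraction × max(own level, reference_level)`, or
amplitude less than `min_contrast` (2×) above the broadband floor.  The
`reference_level` (800 copies, the typical wild-type time-mean protein
level produced by this model) ensures that a low-copy trajectory wobbling
by a large fraction of a strongly depressed level — but by only a few tens
of molecules — is not mistaken for an oscillator, while the relative clause
catches high, flat expression.  The model itself fixes no sharp
amplitude threshold, so `amplitude_fraction` was calibrated once against
the wild-type ensemble: 0.115 reproduces the observed ES-cell PE frequency
(~15%; the calibrated value sits on a plateau where 0.10–0.115 give the
same count) and is reported with every result.  **Differentiation** is
called at 900 min: protein above the trajectory's own full-horizon mean ⇒
mesodermal, at or below ⇒ neural (an ensemble-mean reference is available
via flag).  PE trajectories keep their raw copy number in the output so
callers can apply the biological reading that sustained high expression
predicts mesodermal fate.

## Experiments and problem sizes

Ensembles give trajectory i the seed base_seed + i; comparison arms use
disjoint seed blocks, and every result embeds its full configuration echo.
Headline experiments (defaults): wild-type ensembles of 100 × 1200 min;
translation inhibition α_p/100 × 300 min (statistic: average over
trajectories of the per-trajectory time-mean total mRNA, full horizon
including the transient — no burn-in, matching the literal treatment
protocol; a burn-in flag exists); proteasome inhibition μ_p/100 × 240 min
(statistic: mean over trajectories of the first time the raw total-mRNA
series attains its maximum; a 5-min moving-average variant is available
since raw count maxima are noisy).  The test suite runs scaled-down
ensembles (n = 20–30, and parameter sweeps on a 1.5-μm mesh), sizes chosen
so the qualitative contracts remain well resolved; the acceptance script
runs the full n = 100 on the default 1-μm mesh.

## Synthetic signals

`signals.generate` produces count-valued sinusoids (baseline + amplitude +
Gaussian noise, optional linear period chirp, rounded to non-negative
integers) in the simulator's trajectory container and CSV dialect.  They
validate the estimator's period/amplitude recovery, scale covariance and
edge behaviour — they do not emulate the model's spectrum (red noise,
bursting, amplitude drift), so estimator tests passing on them bounds
estimator error only, not classification accuracy on real cells.

## Known limitations

- **Mesh-scale dependence of repression.**  Converting k₁ with the gene
  voxel volume makes the binding propensity formally mesh-independent in
  the mean, but the realized occupancy retains a resolution- and
  geometry-dependent diffusion-limited correction; on the 1-μm Cartesian
  mesh the wild-type promoter occupancy is ≈0.85, giving grand-mean mRNA
  ≈38 (wild type, 300 min) and ≈133 (translation inhibition) with a robust
  >3× ratio.  Implementations on different meshes shift these absolute
  means by tens of percent while preserving the qualitative contrasts.
- **Fast-diffusion regime.**  As D grows the model approaches its
  well-mixed limit, where the spatial transport delay that reinforces
  coherent oscillation is lost; PE frequencies at D = 10⁻¹¹ m² min⁻¹ are
  therefore noticeably more variable between ensembles than at baseline.
- **Low-D gene-position sweeps** are classifier-sensitive: with slow
  diffusion a membrane-adjacent gene forms a short-delay, steadily
  repressed loop (low copy number, negligible amplitude ⇒ PE), while deep
  placement gives long transport delays with slow, large swings that the
  wavelet sometimes scores as oscillatory — so PE versus depth is not
  monotone in this implementation.
- Single cell only (no cell–cell coupling), normal diffusion only, no
  delay terms, no explicit nucleocytoplasmic transport machinery; the
  recording grid (1 min) bounds the resolution of peak-time statistics.
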