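# Methods

## Model overview

`brainflex` simulates task-driven whole-brain dynamics and measures how the
resulting functional network reconfigures over time. The chain is:

1. **Structural coupling.** A symmetric, nonnegative, zero-diagonal weight
   matrix `G` (empirically: an averaged DTI streamline-count matrix over a
   246-region parcellation) couples `N` neural-mass oscillators. Self-coupling
   is excluded — a nonzero diagonal on load is an error, since white-matter
   tractography has no self-tracts.
2. **Neural dynamics.** Each region is a FitzHugh-Nagumo (FHN) unit with
   activator `u_k` and inhibitor `w_k`:

       eps du_k/dt = u_k - u_k^3/3 - w_k + I0 - sigma * sum_l g_kl u_l + I_k(t)
       dw_k/dt     = u_k + a - b w_k

   with defaults `a = 0.45`, `b = 0.9`, `eps = 0.1`, `I0 = 0.8`,
   `sigma = 1.8`. At these values the uncoupled unit is oscillatory (the
   fixed point is unstable) and the coupling acts as an inhibitory
   activator-only interaction.
3. **Task input.** An N-back-style block design is modelled as the square
   wave `I_k(t) = -c (2 floor(f t) - floor(2 f t))`, `f = 1/T`, `c = 3`,
   `T = 60 s`: zero on `[0, T/2)` (0-back baseline block) and `c` on
   `[T/2, T)` (2-back task block), delivered to a selected set of target
   nodes only. The first block is input-off, so the simulation starts in the
   baseline condition.
4. **Hemodynamics.** Per node, the activator is z-scored over the whole run
   (population SD) and fed to the Balloon-Windkessel model
   (`tau0 = 0.98 s`, `E0 = 0.34`, `V0 = 0.02`, `tau_s = 0.65 s`,
   `tau_f = 0.41 s`), yielding the BOLD observable
   `y = V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]` with `k1 = 7 E0`, `k2 = 2`,
   `k3 = 2 E0 - 0.2`. `y` is point-sampled every `TR = 2 s`.
5. **Functional matrices.** Sliding-window Pearson correlation with
   15-volume windows and 14-volume overlap (30 s windows, 28 s overlap);
   128 volumes give 114 windows.
6. **Flexibility.** Template flexibility: per consecutive window pair, the
   fraction of nodes whose strongest affiliation to a fixed binary
   region-to-module template changes (affiliation = `|A| M` normalised by
   module size, argmax per node). Distance flexibility: one minus the
   Pearson correlation over all `N^2` elements of consecutive matrices
   (diagonal included, exactly as the defining sums are written).
7. **Ensembles.** Runs differ only in initial conditions (uniform on
   `[-2, 2]^2` per node, seeded); run `r` uses seed `base_seed + r`.
   Averaging is done on the flexibility series, not on BOLD or functional
   matrices, matching how ensemble results are reported for this pipeline.

## Numerical choices

- **Integrator.** Fixed-step classical RK4 for both the FHN network and the
  hemodynamic ODEs, default `dt = 0.01 s`; the hemodynamic stage runs at
  the neural step with the drive interpolated linearly at half-step
  substeps. The square wave's edges must fall on grid points
  (`T/(2 dt)` integer is enforced), so RK4 substeps never straddle a
  discontinuity and step-halving shows the expected ~4th-order convergence.
- **Time units.** One FHN time unit is identified with one second so the
  60 s input period and the hemodynamic constants share a clock; the
  mapping is a modelling choice, not something the dynamics dictates.
- **Flow-volume exponent.** The outflow is `f_out(v) = v^0.32`, reading the
  parameter table's "1/alpha = 0.32" literally. The common Balloon-model
  convention (`alpha ≈ 0.32`, exponent `1/alpha ≈ 3.1`) is available via
  `BalloonParams(grubb_convention=True)`.
- **Neural efficacy.** `epsilon_B = 0.5` by default; the source parameter
  table omits it, so it is exposed prominently and configurable.
- **Positivity.** Inflow, volume and deoxyhemoglobin content must stay
  positive; a violation raises an error naming node and time rather than
  clamping, so outputs are never silently biased. The resting point
  `(s, f_in, v, q) = (0, 1, 1, 1)` is kept an exact floating-point
  equilibrium by evaluating the oxygen-extraction ratio `E(f_in)/E0` as
  exactly 1 at `f_in = 1`.
- **Volume convention.** BOLD volumes sit at `k*TR` for `k*TR < duration`
  (half-open span): 256 s at TR = 2 s gives 128 volumes, hence 114 windows
  — the count the empirical protocol produces. No burn-in is discarded by
  default.
- **Degenerate windows.** A node that is exactly constant within a window
  gets zero correlations in that window (with a warning) instead of
  aborting a long ensemble; distance flexibility on a fully constant matrix
  is an error.
- **Ties.** Equal affiliation strengths resolve to the lowest module index;
  equal node strengths resolve to the lowest node index. Both make the
  selection and affiliation operators deterministic.
- **Mid-strength selection.** "Nodes around the median" is formalised as
  the contiguous ascending-rank window `ceil((N-count)/2)+1 ...
  ceil((N-count)/2)+count` of the strength-sorted node list.
- **Shuffle null.** Only the strictly-upper triangle is permuted and then
  mirrored, so the null model preserves the exact edge-weight multiset,
  symmetry and zero diagonal while destroying all placement structure. One
  fixed surrogate per battery (derived from the battery's base seed) is
  used across all runs.
- **Batched ensembles.** The pipeline advances all runs of a chunk
  (25 runs) together as `(R, N)` state arrays; the per-run arithmetic is
  the same RK4 scheme as the single-run integrator. `run_ensemble` remains
  a streaming per-run API whose runs are bit-identical to single
  `integrate` calls.
- **Periodicity score.** Spectral prominence of the task period in a
  flexibility series: direct-DFT power at the input frequency, averaged
  over a 5-point band spaced at the DFT resolution (variance control for
  the single-bin estimate), divided by the median periodogram power over
  nonzero frequencies. White noise scores ~1; a constant series scores 0.

## Synthetic data

The connectome generator produces a modular surrogate for an averaged DTI
matrix: contiguous node blocks, edge probability `density = 0.3`, weights
`scale * exp(sigma_ln * Z)` with `intra_weight_scale = 0.05`,
`inter_weight_scale = 0.01`, `sigma_ln = 0.6` — heavy-tailed, nonnegative,
symmetric. These scales put node strengths around 0.2–0.8 so that, with
`sigma = 1.8`, every node stays on its limit cycle: stronger weights push
high-strength nodes into amplitude death, whose near-constant activator
makes the z-scored hemodynamic drive spike and the Balloon model lose
inflow positivity. The surrogate reproduces the weight-distribution shape
and modularity of real connectomes but not their spatial embedding, hub
topology (rich club), or inter-subject variability; passing tests on it
demonstrates the pipeline's correctness and qualitative input-locking
behaviour, not quantitative agreement with empirical flexibility curves.

The template generator assigns each region exactly one of `P` modules
uniformly at random (each module guaranteed non-empty), standing in for an
a-priori functional-network template; multi-membership binary templates
are accepted on load.

## Experiment sizes

Desk-scale defaults are deliberately smaller than the empirical setting
the model emulates: 60-node connectomes, 20-run ensembles and 256 s of
simulated time for the structure-comparison battery (a 246-region
parcellation with 50- or 300-run ensembles is the full-scale
configuration). The 256 s duration is chosen so the window
count (114) matches the empirical protocol.

## Known limitations

- With weights weak enough that all nodes oscillate, the intact-vs-shuffled
  structural contrast is modest at N = 60: both ensembles lock strongly to
  the 60 s input, and the periodicity difference between them is not a
  reliable effect at 20 runs. A regime where structure dominates (strong,
  heavy-tailed coupling) collides with amplitude death of hub nodes under
  this activator-only inhibitory coupling, which the hemodynamic stage
  rejects by design (positivity errors on spiking z-scored drives).
- Noise-free dynamics only: run-to-run variability comes entirely from
  initial conditions.
- Single global hemodynamic parameter set; no region-specific variants.
- No data-driven community detection; the template approach deliberately
  replaces it.
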