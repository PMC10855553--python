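# Methods

## The averaging protocol

`ensavg` implements a post-processing protocol for annealing-based
comparative modeling. A modeling run is treated as a trajectory of
conformations of one target sequence; the run's last frame is its FINAL
model. The protocol pools intermediate frames across independent runs,
ranks them, averages the coordinates of the best fraction and regularizes
the average. The underlying assumptions are:

- **Redundancy**: consecutive trajectory frames are strongly correlated, so
  frames are extracted at a stride (default 34 steps, 149 frames per run)
  and may be thinned further by a gap factor (gap 2 keeps even-indexed
  frames). Nothing is lost statistically and pool handling stays cheap.
- **Fitter intermediates exist**: because the pseudo-energy landscape the
  run explores is not the true free-energy landscape, an intermediate frame
  can sit closer to the native than the endpoint. Averaging many
  top-ranked frames cancels part of their independent error.
- **Ranking is a black box**: statistical potentials are consumed as
  rankers only. Raw (non-optimized) frames are scored; the averaging uses
  each selected frame's optimized counterpart through an explicit
  raw↔optimized pairing keyed by (run, step). Pipelines without a separate
  optimized stage self-pair, which is logged, not hidden.

## Scorers

- `builtin_contact` — a self-contained stand-in pseudo-energy, **not** a
  re-implementation of any published potential: for residue pairs at
  sequence separation ≥ 3, CB–CB (CA for glycine) distances under 3.0 Å
  cost +10 (clash), distances in [3.5, 8.0] Å score −1 (native-like
  contact), all else 0; lower is better. Parameters are module constants.
- `oracle_rmsd` — CA RMSD to a known native. Only meaningful on synthetic
  benchmarks; it bounds what any real ranker could achieve and makes
  end-to-end claims about the *averaging* step rather than about a
  particular potential.
- `external_adapter` — wraps any shell command with a `{pdb}` placeholder;
  the first float matched in stdout (pattern configurable) is the score.
  Nonzero exit, timeout or unparsable output raise a scoring error carrying
  the captured output. A secondary scorer (e.g. a protein–ligand scoring
  command) can be blended as a weighted sum; the default weight 0 disables
  blending, since no canonical combination rule exists.

Selection keeps n = max(1, ⌈fraction·N⌉) frames (the ceiling-with-floor
rule guarantees a non-empty averaging set for any pool), sorted
better-first with ties broken by (run id, step index) so results do not
depend on input order.

## Averaging and regularization

Members are rigidly superposed (Kabsch, SVD-based, reflections excluded)
onto the best-ranked member before averaging; the explicit, deterministic
target makes the result independent of the order of the remaining members.
For members already expressed in a common frame the superposition can be
disabled. This matters for one exact identity: for members native ± δ in a
common frame, the mean recovers the native to machine precision *only*
without fitting — a least-squares fit absorbs part of each perturbation
into the rigid transform and leaves an O(‖δ‖²) residual. With fitting
enabled the identity holds approximately, which is the behaviour the test
suite pins down.

The regularizer minimizes

    U(x) = k_bond Σ_bonds (|x_i − x_j| − d_ij_ref)² + k_pos Σ_i |x_i − x̄_i|²

by nonlinear conjugate gradient (scipy's CG with an analytic gradient),
stopping at gradient norm < 1e−4 or 200 iterations; non-convergence
returns the best point with a warning. Bonds are atom pairs within 1.9 Å in
the reference geometry (the best-ranked member), a distance criterion that
needs no residue templates and degrades gracefully: CA-only traces have no
pairs under the cutoff, so regularization reduces to the positional anchor
and is exact. Defaults k_bond = 1.0, k_pos = 0.1 favour restoring reference
stereochemistry while staying near the average; k_bond = 0 short-circuits
to the averaged coordinates. The true reference protocol regularizes with
the modeling engine's own objective function; that objective is deliberately
out of scope here, and this simplified harmonic surrogate is documented as
such.

## Assessment conventions

- **lDDT** (on [0, 1], superposition-free): pairs of non-hetero atoms in
  different residues chosen on the *reference* with d_ref strictly below
  the 15 Å inclusion radius; per threshold t ∈ {0.5, 1, 2, 4} Å the
  fraction of pairs with |d_model − d_ref| ≤ t (inclusive); score = mean
  fraction. The published definition leaves the inequality senses open;
  ≤ on thresholds and < on the radius match common practice. No
  stereochemical penalty term; global score only.
- **GDT-HA** (on [0, 100]): per cutoff c ∈ {0.5, 1, 2, 4} Å, the largest
  fraction of mapped CA atoms whose own least-squares superposition leaves
  every subset member within c; score = 100 × mean fraction. The subset
  search is a deterministic LGA-style heuristic: every contiguous window of
  lengths 3/5/7 seeds an include-all/re-superpose iteration (≤ 10 rounds),
  followed by a fixed-cardinality trim pass (superpose on the k closest,
  recompute, iterate, for decreasing k). On chains of ≤ 12 residues every
  atom triple additionally seeds the search, making it effectively
  exhaustive at that size; an exhaustive-subset oracle in the test suite
  verifies exact agreement on 6–8-residue fixtures.
- **Binding pocket**: residues with ≥ 1 non-hetero atom within 4.0 Å
  (inclusive — "within" read as ≤) of any reference ligand atom; pocket
  RMSD is all-atom over common pocket atoms after superposing on exactly
  those atoms.
- **Δ-metric**: Δ = value(AVG) − mean(value(FINAL_r)); **global mean**: the
  arithmetic mean of a per-target feature over an analysis set.
- **Fitter fraction**: percentage of a run's intermediate frames *strictly*
  better than the run's FINAL model under the metric's direction.
- **Wilcoxon signed-rank**: two-sided; zero differences dropped; mid-ranks
  for ties; W = min(W⁺, W⁻). For ≤ 25 effective pairs the p-value comes
  from the exact distribution of W⁺ over all 2ⁿ sign assignments, computed
  by a generating-polynomial dynamic program over doubled ranks (so tied
  mid-ranks stay integral) — identical to full enumeration, verified
  against a brute-force enumeration oracle to 1e−12. Beyond 25, a normal
  approximation with continuity and tie correction. Significance threshold
  5%.

## Synthetic data

The generator emulates what matters *statistically* about annealing
trajectories, not their physics:

- **Toy natives**: self-avoiding CA random walks with 3.8 Å spacing and a
  persistent step direction (extended, protein-like); optional CB atoms at
  1.53 Å and, for pocket toys, a 4-atom HETATM ligand placed ≈ 3.2 Å from
  two mid-chain CB atoms so the 4.0 Å pocket rule selects ≥ 2 residues by
  construction.
- **Runs**: frame t = native + F·2^(−t/h) + ε_t, where F is a per-atom
  Gaussian displacement field of RMS norm `start_offset` (default 5 Å —
  each run starts from an independently perturbed configuration), h the
  bias half-life (default n_steps/5), and ε a stationary AR(1) process per
  coordinate with marginal std `noise_sigma` (default 1.0 Å) and lag-1
  correlation `noise_rho` (default 0.9), reproducing the strong
  frame-to-frame correlation of real trajectories. Frame 0 carries the full
  start offset (decay factor 2⁰ = 1); the last frame is the run's FINAL
  model. All randomness flows from a single seed through named
  `numpy.random.SeedSequence` spawn keys, so every fixture is
  bit-reproducible; a benchmark case gives run r the seed `base + r`.
- **Optimized frames**: produced by regularizing each raw frame against its
  own geometry — an exact no-op on toys already at their restraint minimum —
  purely to exercise the two-pool raw/optimized protocol end to end.

What the generator does **not** emulate: real force-field energetics,
side-chain rotamers, sequence-dependent geometry, or the distinction
between fast and slow annealing routines (run length alone stands in for
routine choice). Passing tests therefore demonstrate the correctness of the
pooling/ranking/averaging/assessment machinery and the *qualitative*
averaging effect under controlled error models — not quantitative
performance on real homology models.

## Benchmark problem sizes

The standard benchmark case uses a 30-residue CA-trace native and 15 runs
× 149 frames (2235-frame pool, 12 frames selected at fraction 0.005),
ranked by the RMSD oracle; summaries aggregate 20 independent cases.
149-step runs are simulated directly (one frame per step); the
stride-34-from-5066-steps arithmetic that yields 149 frames per run is
exercised separately in the pool tests. These sizes are large enough for
the averaging effect to be unambiguous (mean ΔlDDT ≈ +0.2 with Wilcoxon
p ≪ 0.05) while keeping a full 20-case summary to a few minutes on one
CPU.

## Numerical and degenerate-input choices

- Superposition requires ≥ 3 non-collinear mapped pairs (second singular
  value > 1e−8 relative); collinear input raises a geometry error rather
  than returning an arbitrary rotation.
- PDB coordinates round-trip bit-stably at the format's 3-decimal
  precision; alternate locations keep the first conformer; insertion codes
  are folded into the residue key as a suffix, never renumbered.
- Frames with differing atom sets are restricted to their common atoms with
  an explicit warning; an empty intersection is an error.
- Stride extraction anchors at trajectory index 0; "odd timesteps" for
  gap 2 means odd step index within the extracted sequence, which halves
  149 frames to 75.
- The selection fraction rounds up with a floor of one so the averaging set
  is never empty.

## Known limitations

- The CG regularizer is a harmonic surrogate, not a physical force field;
  it cannot rebuild side chains or repair non-bonded clashes it has no term
  for.
- The GDT-HA heuristic is exact on small chains (verified against the
  exhaustive oracle) but only a lower bound in general, as for any
  LGA-style search.
- The built-in contact scorer is a ranking stand-in for testing plumbing;
  real use should plug in an external potential through the adapter.
- lDDT is computed as a global score without stereochemistry penalties;
  per-residue profiles are not produced.
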