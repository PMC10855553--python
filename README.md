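# ensavg

Ensemble-averaging refinement for protein models built from annealing
trajectories, with a full model-quality assessment stack.

## The problem

Comparative (homology) modeling pipelines refine a starting model by
simulated-annealing molecular dynamics and return the structure at the end of
the run — the **FINAL model**. But the trajectory visits many intermediate
conformations, and a fraction of those intermediates is often *closer to the
true native structure* than the endpoint the pipeline happens to stop at.
`ensavg` exploits this: it pools the intermediate frames of many independent
runs of the same target, ranks them with a pseudo-energy scorer, averages
the atomic coordinates of the top-ranked fraction, and regularizes the
average into a stereochemically consistent structure — the **AVG model**.

The protocol, per target:

1. **Pool** — from each of *R* runs, extract intermediate (raw) frames at a
   fixed stride (every 34 timesteps, 149 frames per run in the reference
   protocol); optionally thin by a gap factor (gap = 2 keeps even-indexed
   frames); merge the runs into one configurations pool of
   *R* × ⌈149/gap⌉ frames.
2. **Rank** — score every raw frame with a statistical potential (treated as
   a black-box ranker; external binaries plug in through a shell-command
   adapter) and keep the top fraction *f* (0.3% or 0.5%), with
   n = max(1, ⌈f·N⌉). Averaging then uses each selected frame's *optimized*
   counterpart via the pool's raw↔optimized pairing.
3. **Average** — superpose the selected frames onto the best-ranked one and
   take the arithmetic mean of the atomic coordinates, x̄ᵢ = (1/n) Σₘ xᵢ⁽ᵐ⁾.
4. **Regularize** — restrained conjugate-gradient minimization of
   U(x) = k_bond Σ_bonds (|xᵢ−xⱼ| − dᵢⱼ^ref)² + k_pos Σᵢ |xᵢ − x̄ᵢ|²,
   repairing averaging artefacts while staying anchored to the mean.
5. **Assess** — against a reference structure: superposition-free **lDDT**
   (thresholds 0.5/1/2/4 Å, on [0, 1]), **GDT-HA** (cutoffs 0.5/1/2/4 Å, on
   [0, 100]), all-atom **binding-pocket RMSD** (pocket = residues within
   4.0 Å of the ligand), Δ-metrics Δ = AVG − mean(FINAL), per-target global
   means, per-run *fitter fractions* (percentage of intermediates beating
   the FINAL model), and the Wilcoxon signed-rank test (5% threshold) for
   paired comparisons.

A bundled synthetic generator produces toy natives and correlated,
bias-decaying annealing-like trajectories with known ground truth, so the
whole pipeline runs and is testable without any external modeling software.

## Worked example

`examples/01_averaging_benchmark.py` builds one synthetic benchmark case
(30-residue toy native, 15 runs × 149 frames drifting toward it), ranks the
2235-frame pool with the RMSD oracle, averages the top 0.5% and assesses the
result:

```
configurations pool: 2235 frames from 15 runs
selected top 0.5%: 12 frames (best CA-RMSD 1.35 A)
AVG model:   lDDT 0.862   GDT-HA 87.5
FINAL mean:  lDDT 0.641   GDT-HA 57.8
delta (AVG - mean FINAL): lDDT +0.221, GDT-HA +29.7
```

The positive Δ values say the averaged model is substantially closer to the
native than the typical run endpoint — the qualitative effect the protocol
is designed to produce. `examples/02_pocket_assessment.py` shows the
binding-pocket machinery and `examples/03_scorers_and_selection.py` the
three scorer kinds (built-in contact stand-in, RMSD oracle, external
command adapter).

A thin CLI wraps the same library calls:

```bash
ensavg synth --out case/ --seed 7           # generate a benchmark case
ensavg run --synthetic --scorer rmsd-oracle --out out/
ensavg assess --model out/avg_model.pdb --reference case/native.pdb
```

## Layout

- `src/ensavg/structure_io.py` — PDB reading/writing, atom correspondence
- `src/ensavg/pool.py` — stride extraction, gap subsampling, run merging, raw↔optimized pairing
- `src/ensavg/ranking.py` — scorers, ranking, top-fraction selection
- `src/ensavg/averaging.py` — Kabsch superposition, coordinate averaging, CG regularization
- `src/ensavg/assessment.py` — lDDT, GDT-HA, pocket RMSD, Δ-metrics, global means, Wilcoxon
- `src/ensavg/synthetic.py` — toy natives and annealing-like trajectory generator
- `src/ensavg/pipeline.py`, `src/ensavg/cli.py` — orchestration and the `ensavg` command

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
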