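"""Ranking a pool with different scorers.

Shows the three scorer kinds on one small pool: the built-in residue-contact
stand-in, the RMSD oracle (synthetic benchmarks only), and an external
command adapter (here a shell stub standing in for a statistical-potential
binary), plus the top-fraction selection rule.
"""

from ensavg import (ToySpec, TrajectorySpec, contact_scorer,
                    external_scorer_adapter, make_toy_native,
                    oracle_rmsd_scorer, pair_stages, score_pool, select_top,
                    simulate_run)
from ensavg.pipeline import build_pool

native = make_toy_native(ToySpec(n_residues=15, geometry="ca_cb_trace", seed=3))
runs = [simulate_run(native, TrajectorySpec(n_steps=40, seed=s)) for s in (1, 2)]
pool = pair_stages(*(build_pool(runs, stride=1, gap=1),) * 2)
print(f"pool: {len(pool)} frames")

for scorer in (contact_scorer(),
               oracle_rmsd_scorer(native),
               external_scorer_adapter("wc -c < {pdb}", name="size-stub")):
    scored = score_pool(pool, scorer)
    sel = select_top(scored, fraction=0.05)
    ids = ", ".join(f"run{r}:t{t}" for r, t, _ in sel.raw_ids)
    print(f"{scorer.name:>12}: {len(sel.raw_ids)} of {len(pool)} selected -> {ids}")

print("selection size is ceil(fraction x pool), floor one; the oracle ranks by")
print("true closeness to the native, the others only approximate that ordering")
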