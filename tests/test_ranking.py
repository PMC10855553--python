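import math

import numpy as np
import pytest

from conftest import ca_structure, cb_structure
from ensavg.pool import ConfigPool, Frame, PoolSpec, pair_stages
from ensavg.ranking import (ScoringError, Scorer, builtin_contact_score,
                            blend_scorers, contact_scorer,
                            external_scorer_adapter, oracle_rmsd_scorer,
                            score_pool, select_top)
from ensavg.synthetic import ToySpec, TrajectorySpec, make_toy_native, simulate_run


def pool_from_structures(structures):
    frames = [Frame(structure=s, run_id=1, step_index=i)
              for i, s in enumerate(structures)]
    spec = PoolSpec(n_runs=1, stride=1, frames_per_run=len(structures))
    return pair_stages(ConfigPool(frames=frames, spec=spec),
                       ConfigPool(frames=list(frames), spec=spec))


def two_residue_cb(distance):
    """Two CA+CB residues, padded by two spacers so |i-j| >= 3 holds."""
    far = 100.0
    return cb_structure([
        ([0, 0, -2], [0, 0, 0]),
        ([far, far, 0], [far, far, 2]),
        ([far, -far, 0], [far, -far, 2]),
        ([distance, 0, -2], [distance, 0, 0]),
    ])


class TestContactScore:
    @pytest.mark.parametrize("distance,expected", [
        (5.0, -1.0),    # contact well
        (2.0, 10.0),    # clash
        (12.0, 0.0),    # outside both windows
    ])
    def test_single_pair_terms(self, distance, expected):
        # spacer residues are >100 Å away: they contribute no terms
        assert builtin_contact_score(two_residue_cb(distance)) == expected

    def test_needs_two_eligible_residues(self):
        s = cb_structure([([0, 0, 0], [1.5, 0, 0])])
        with pytest.raises(ScoringError):
            builtin_contact_score(s)

    def test_gly_falls_back_to_ca(self):
        s = two_residue_cb(5.0)
        # CB distance was 5.0; GLY CA fallback shifts centres but stays scored
        atoms = [a for a in s.atoms if a.atom_name == "CA"]
        gly = ca_structure([a.coords for a in atoms], res_name="GLY")
        assert isinstance(builtin_contact_score(gly), float)


class TestScorePool:
    def test_oracle_scores_native_zero_and_minimal(self):
        native = make_toy_native(ToySpec(n_residues=10, seed=3))
        decoys = simulate_run(native, TrajectorySpec(n_steps=5, seed=4))
        pool = pool_from_structures([native] + decoys)
        scored = score_pool(pool, oracle_rmsd_scorer(native))
        native_score = scored.scores[(1, 0, "raw")]
        assert native_score == pytest.approx(0.0, abs=1e-8)
        assert all(v > native_score for fid, v in scored.scores.items()
                   if fid != (1, 0, "raw"))

    def test_constant_scorer(self):
        pool = pool_from_structures([two_residue_cb(5.0)] * 10)
        scored = score_pool(pool, Scorer("const", "lower_is_better", "custom",
                                         lambda s: 1.5))
        assert set(scored.scores.values()) == {1.5}

    def test_nonfinite_score_rejected(self):
        pool = pool_from_structures([two_residue_cb(5.0)])
        with pytest.raises(ScoringError, match="non-finite"):
            score_pool(pool, Scorer("nan", "lower_is_better", "custom",
                                    lambda s: math.nan))


class TestSelectTop:
    @pytest.mark.parametrize("n,fraction,expected", [
        (5960, 0.005, 30),
        (5960, 0.003, 18),
        (10, 0.003, 1),    # floor of one
        (10, 1.0, 10),
    ])
    def test_ceiling_rule(self, n, fraction, expected):
        assert max(1, math.ceil(fraction * n)) == expected  # arithmetic guard
        scores = {(1, i, "raw"): float(i) for i in range(n)}
        scored = _fake_scored(scores)
        sel = select_top(scored, fraction)
        assert len(sel.raw_ids) == expected
        assert sel.raw_ids == [(1, i, "raw") for i in range(expected)]

    def test_direction_respected(self):
        scores = {(1, i, "raw"): float(i) for i in range(10)}
        sel = select_top(_fake_scored(scores, direction="higher_is_better"), 0.2)
        assert sel.raw_ids == [(1, 9, "raw"), (1, 8, "raw")]

    def test_tie_break_by_provenance(self):
        scores = {(2, 0, "raw"): 1.0, (1, 5, "raw"): 1.0, (1, 2, "raw"): 1.0}
        sel = select_top(_fake_scored(scores), 1.0)
        assert sel.raw_ids == [(1, 2, "raw"), (1, 5, "raw"), (2, 0, "raw")]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        scores = {(1, i, "raw"): float(v) for i, v in enumerate(rng.normal(size=50))}
        transformed = {k: math.exp(3 * v) + 2 for k, v in scores.items()}
        a = select_top(_fake_scored(scores), 0.1)
        b = select_top(_fake_scored(transformed), 0.1)
        assert a.raw_ids == b.raw_ids

    def test_idempotent_membership(self):
        scores = {(1, i, "raw"): float(i) for i in range(40)}
        first = select_top(_fake_scored(scores), 0.25)
        again = select_top(_fake_scored({k: scores[k] for k in first.raw_ids}), 1.0)
        assert set(again.raw_ids) == set(first.raw_ids)

    def test_native_always_selected_with_oracle(self):
        native = make_toy_native(ToySpec(n_residues=10, seed=3))
        decoys = simulate_run(native, TrajectorySpec(n_steps=20, seed=4))
        pool = pool_from_structures([native] + decoys)
        scored = score_pool(pool, oracle_rmsd_scorer(native))
        for fraction in (0.01, 0.1, 0.5, 1.0):
            assert (1, 0, "raw") in select_top(scored, fraction).raw_ids


def _fake_scored(scores, direction="lower_is_better"):
    from ensavg.ranking import ScoredPool
    frames = [Frame(structure=two_residue_cb(5.0), run_id=r, step_index=s)
              for (r, s, _) in scores]
    pool = ConfigPool(frames=frames,
                      spec=PoolSpec(n_runs=max(r for r, _, _ in scores),
                                    stride=1, frames_per_run=len(scores)))
    return ScoredPool(pool=pool, scores=dict(scores),
                      scorer=Scorer("fake", direction, "custom", lambda s: 0.0))


class TestExternalAdapter:
    def test_constant_stub(self):
        scorer = external_scorer_adapter("echo 1.5 # {pdb}")
        assert scorer(two_residue_cb(5.0)) == 1.5

    def test_file_size_stub_ranks_deterministically(self):
        scorer = external_scorer_adapter("wc -c < {pdb}")
        small = two_residue_cb(5.0)
        big = make_toy_native(ToySpec(n_residues=20, seed=1))
        s_small, s_big = scorer(small), scorer(big)
        # one PDB line per atom, fixed width: size ratio follows atom counts
        assert s_big > s_small
        assert scorer(small) == s_small  # deterministic

    def test_nonzero_exit_raises(self):
        scorer = external_scorer_adapter("cat {pdb}; exit 3")
        with pytest.raises(ScoringError, match="failed"):
            scorer(two_residue_cb(5.0))

    def test_unparsable_output_raises(self):
        scorer = external_scorer_adapter("echo no-score-here # {pdb}",
                                         score_pattern=r"SCORE=\d+\.\d+")
        with pytest.raises(ScoringError, match="parsable"):
            scorer(two_residue_cb(5.0))

    def test_template_requires_placeholder(self):
        with pytest.raises(ValueError):
            external_scorer_adapter("echo 1.5")


def test_blend_weight_zero_returns_primary():
    primary = contact_scorer()
    secondary = Scorer("other", "lower_is_better", "custom", lambda s: 100.0)
    assert blend_scorers(primary, secondary, 0.0) is primary
    blended = blend_scorers(primary, secondary, 0.5)
    s = two_residue_cb(5.0)
    assert blended(s) == pytest.approx(primary(s) + 50.0)
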