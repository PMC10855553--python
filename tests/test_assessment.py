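import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import wilcoxon as scipy_wilcoxon

from conftest import ca_structure
from ensavg.assessment import (GDTParams, LDDTParams, UndefinedMetricError,
                               delta_metric, fitter_fraction, gdt_ha,
                               global_mean, lddt, lddt_many, pocket_residues,
                               pocket_rmsd, wilcoxon_signed_rank)
from ensavg.averaging import GeometryError
from ensavg.structure_io import Atom, Structure, build_atom_map
from ensavg.synthetic import ToySpec, make_toy_native
from oracles import brute_force_rmsd, exhaustive_gdt_ha, wilcoxon_enumeration_p


def rigid_move(structure, seed=0, angle=None):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix() if angle is None else \
        Rotation.from_euler("y", angle, degrees=True).as_matrix()
    return structure.with_coords(structure.coords @ rot.T + rng.uniform(-20, 20, 3))


class TestLddt:
    def test_model_equals_reference_scores_one(self, folded_structure):
        assert lddt(folded_structure, folded_structure) == 1.0

    def test_three_atom_hand_enumeration(self):
        # pair diffs {0, 1, 1}: fractions 1/3 at 0.5 Å, 1 at 1/2/4 Å -> 5/6
        ref = ca_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        mod = ca_structure([[0, 0, 0], [4, 0, 0], [9, 0, 0]])
        assert lddt(mod, ref) == pytest.approx(5.0 / 6.0, abs=1e-12)

    def test_translation_invariance(self, folded_structure, rng):
        noisy = folded_structure.with_coords(
            folded_structure.coords + rng.normal(scale=0.8, size=(8, 3)))
        base = lddt(noisy, folded_structure)
        shifted = noisy.with_coords(noisy.coords + np.array([11.0, -4.0, 7.0]))
        assert lddt(shifted, folded_structure) == pytest.approx(base, abs=1e-12)

    def test_rigid_motion_invariance(self, folded_structure, rng):
        noisy = folded_structure.with_coords(
            folded_structure.coords + rng.normal(scale=0.5, size=(8, 3)))
        base = lddt(noisy, folded_structure)
        for seed in range(20):
            moved = rigid_move(noisy, seed=seed)
            assert lddt(moved, folded_structure) == pytest.approx(base, abs=1e-12)

    def test_monotone_under_growing_noise(self):
        native = make_toy_native(ToySpec(n_residues=20, seed=11))
        sigmas = [0.1, 0.5, 1.0, 2.0]
        means = []
        for sigma in sigmas:
            vals = []
            for seed in range(20):
                g = np.random.default_rng(seed)
                noisy = native.with_coords(
                    native.coords + g.normal(scale=sigma, size=(20, 3)))
                vals.append(lddt(noisy, native))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_inclusion_radius_excludes_long_pairs(self):
        # 0-20-40 Å chain: no pair under the default 15 Å radius
        ref = ca_structure([[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        with pytest.raises(UndefinedMetricError):
            lddt(ref, ref)

    def test_lddt_many_agrees_with_scalar(self, rng):
        native = make_toy_native(ToySpec(n_residues=12, seed=4))
        frames = [native.with_coords(native.coords + rng.normal(scale=s, size=(12, 3)))
                  for s in (0.2, 0.7, 1.5)]
        batch = lddt_many(np.stack([f.coords for f in frames]), native)
        singles = [lddt(f, native) for f in frames]
        assert batch == pytest.approx(singles, abs=1e-12)


class TestGdtHa:
    def test_identity_scores_100(self, folded_structure):
        assert gdt_ha(folded_structure, folded_structure) == 100.0

    def test_one_displaced_of_four(self):
        ref = ca_structure([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 1.0]])
        mod_coords = ref.coords.copy()
        mod_coords[3] += [0, 0, 10.0]
        mod = ref.with_coords(mod_coords)
        assert gdt_ha(mod, ref) == pytest.approx(75.0)

    def test_rigid_motion_invariance(self, folded_structure, rng):
        noisy = folded_structure.with_coords(
            folded_structure.coords + rng.normal(scale=0.6, size=(8, 3)))
        base = gdt_ha(noisy, folded_structure)
        for seed in range(5):
            assert gdt_ha(rigid_move(noisy, seed=seed),
                          folded_structure) == pytest.approx(base, abs=1e-6)

    @pytest.mark.parametrize("n_res,seed,sigma", [
        (6, 0, 0.5), (6, 1, 1.2), (7, 2, 0.8), (7, 3, 2.0),
        (8, 4, 0.4), (8, 5, 1.0), (8, 6, 1.6), (6, 7, 3.0),
    ])
    def test_heuristic_equals_exhaustive_oracle(self, n_res, seed, sigma):
        native = make_toy_native(ToySpec(n_residues=n_res, seed=seed + 50))
        g = np.random.default_rng(seed)
        decoy = native.with_coords(native.coords + g.normal(scale=sigma,
                                                            size=(n_res, 3)))
        ours = gdt_ha(decoy, native)
        oracle = exhaustive_gdt_ha(decoy.coords, native.coords)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_too_few_ca_rejected(self):
        s = ca_structure([[0, 0, 0], [3.8, 0, 0]])
        with pytest.raises(GeometryError):
            gdt_ha(s, s)


def pocket_fixture():
    protein_atoms = [
        Atom("A", 1, "ALA", "CA", "C", (3.9, 0.0, 0.0)),     # residue A: in pocket
        Atom("A", 2, "ALA", "CA", "C", (4.1, 0.0, 0.0)),     # residue B: just outside
        Atom("A", 3, "ALA", "CA", "C", (0.0, 4.0, 0.0)),     # exactly at the cutoff
        Atom("A", 4, "ALA", "CA", "C", (50.0, 50.0, 50.0)),  # far away
    ]
    ligand = Structure([Atom("L", 1, "LIG", "C1", "C", (0.0, 0.0, 0.0),
                             is_hetero=True)], "lig")
    return Structure(protein_atoms, "prot"), ligand


class TestPocket:
    def test_boundary_handling(self):
        protein, ligand = pocket_fixture()
        pocket = pocket_residues(protein, ligand, 4.0)
        assert pocket == {("A", "1"), ("A", "3")}   # 3.9 in, 4.0 in, 4.1 out

    def test_far_ligand_gives_empty_set(self):
        protein, _ = pocket_fixture()
        far = Structure([Atom("L", 1, "LIG", "C1", "C", (500.0, 0.0, 0.0),
                              is_hetero=True)], "lig")
        assert pocket_residues(protein, far, 4.0) == set()

    def test_synthetic_pocket_toy_is_nonempty(self):
        toy = make_toy_native(ToySpec(n_residues=12, geometry="pocket_toy", seed=3))
        ligand = Structure([a for a in toy.atoms if a.is_hetero], "lig")
        pocket = pocket_residues(toy, ligand, 4.0)
        assert len(pocket) >= 2

    def test_pocket_rmsd_identity_and_rigid(self, rng):
        toy = make_toy_native(ToySpec(n_residues=12, geometry="pocket_toy", seed=3))
        ligand = Structure([a for a in toy.atoms if a.is_hetero], "lig")
        pocket = pocket_residues(toy, ligand, 4.0)
        assert pocket_rmsd(toy, toy, pocket) == pytest.approx(0.0, abs=1e-10)
        assert pocket_rmsd(rigid_move(toy, seed=1), toy,
                           pocket) == pytest.approx(0.0, abs=1e-8)

    def test_pocket_rmsd_matches_brute_force(self, rng):
        toy = make_toy_native(ToySpec(n_residues=12, geometry="pocket_toy", seed=3))
        ligand = Structure([a for a in toy.atoms if a.is_hetero], "lig")
        pocket = sorted(pocket_residues(toy, ligand, 4.0))[:2]
        model = toy.with_coords(toy.coords + rng.normal(scale=0.5,
                                                        size=(len(toy), 3)))
        ours = pocket_rmsd(model, toy, set(pocket))
        idx = [i for i, a in enumerate(toy.atoms)
               if not a.is_hetero and (a.chain_id, a.res_key) in set(pocket)]
        oracle = brute_force_rmsd(model.coords[idx], toy.coords[idx])
        assert ours == pytest.approx(oracle, abs=1e-6)


class TestAggregation:
    @pytest.mark.parametrize("avg,finals,expected", [
        (0.80, [0.70, 0.74], 0.08),
        (0.6, [0.6], 0.0),
        (55.0, [60.0], -5.0),
    ])
    def test_delta(self, avg, finals, expected):
        rec = delta_metric(avg, finals, "lDDT")
        assert rec.delta == pytest.approx(expected)

    def test_delta_requires_finals(self):
        with pytest.raises(ValueError):
            delta_metric(0.5, [])

    @pytest.mark.parametrize("values,expected", [
        ([5.0], 5.0),
        ([-1.0, 1.0], 0.0),
    ])
    def test_global_mean_simple(self, values, expected):
        assert global_mean(values).global_mean == pytest.approx(expected)

    def test_global_mean_linearity(self, rng):
        vals = rng.normal(size=12)
        assert global_mean(list(3.5 * vals)).global_mean == pytest.approx(
            3.5 * global_mean(list(vals)).global_mean)

    @pytest.mark.parametrize("inter,final,direction,expected", [
        ([50, 60, 70], 60, "higher_is_better", 100.0 / 3.0),
        ([60, 60, 60], 60, "higher_is_better", 0.0),
        ([70, 80, 90], 60, "higher_is_better", 100.0),
        ([1.0, 2.0, 3.0], 2.0, "lower_is_better", 100.0 / 3.0),
    ])
    def test_fitter_fraction(self, inter, final, direction, expected):
        assert fitter_fraction(inter, final, direction) == pytest.approx(expected)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 32.0, abs=1e-15)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_matches_enumeration_oracle(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(3, 13))
        a = g.normal(size=n)
        # integer-ish b forces occasional ties in |d|
        b = a + g.choice([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0], size=n)
        res = wilcoxon_signed_rank(list(a), list(b))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(a - b),
                                            abs=1e-12)

    def test_normal_approx_agrees_with_scipy(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.5, size=40) + 0.2
        res = wilcoxon_signed_rank(list(a), list(b))
        assert res.method == "normal_approx"
        ref = scipy_wilcoxon(a, b, correction=True, mode="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)
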