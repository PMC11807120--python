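import numpy as np
import pytest

from rxntree.chem import ECFP4, fingerprint, tanimoto
from rxntree.mcts import MCTSConfig, SyntheticRoute
from rxntree.metrics import (
    FilterSpec,
    filter_starting_materials,
    fraction_above_threshold,
    internal_diversity,
    ligand_efficiency,
    ligand_efficiency_from_smiles,
    reaction_step_distribution,
    scaffold_retention_rate,
    summarize_search,
    uniqueness,
    uniqueness_to_reference,
)


class TestInternalDiversity:
    def test_singleton_and_duplicates_are_zero(self):
        assert internal_diversity(["CCO"]) == pytest.approx(0.0)
        assert internal_diversity(["CCO", "CCO"]) == pytest.approx(0.0)

    def test_disjoint_pair_p1_is_half(self):
        # methane and water share no ECFP4 bits: mean similarity over the four
        # ordered pairs is (1 + 0 + 0 + 1) / 4 = 0.5
        assert tanimoto(fingerprint("C", ECFP4), fingerprint("O", ECFP4)) == 0.0
        assert internal_diversity(["C", "O"], p=1) == pytest.approx(0.5)

    def test_matches_hand_double_sum(self, rng):
        mols = ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "c1ccncc1"]
        for p in (1, 2):
            fps = [fingerprint(m, ECFP4) for m in mols]
            total = sum(
                tanimoto(a, b) ** p for a in fps for b in fps
            )
            want = 1 - (total / len(mols) ** 2) ** (1 / p)
            assert internal_diversity(mols, p=p) == pytest.approx(want, abs=1e-12)

    def test_permutation_invariant_and_duplicate_never_increases(self):
        mols = ["CCO", "c1ccccc1", "CC(=O)O"]
        base = internal_diversity(mols)
        assert internal_diversity(mols[::-1]) == pytest.approx(base)
        assert internal_diversity(mols + ["CCO"]) <= base + 1e-12

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            internal_diversity([])


class TestUniqueness:
    def test_all_distinct(self):
        assert uniqueness(["CCO", "CCN", "CCC"]) == 1.0

    def test_reference_identical_set(self):
        assert uniqueness_to_reference(["CCO", "CCN"], ["OCC", "NCC"]) == 0.0

    def test_constructed_fixture_counts(self):
        # 10 molecules with 2 duplicates -> 8 unique; 3 of the unique are in
        # the reference -> 5/8 new
        mols = ["CCO", "OCC", "CCN", "NCC", "CCC", "CCCC", "CCCCC", "c1ccccc1",
                "CC(=O)O", "CCBr"]
        ref = ["CCC", "c1ccccc1", "CC(=O)O"]
        assert uniqueness(mols) == pytest.approx(0.8)
        assert uniqueness_to_reference(mols, ref) == pytest.approx(0.625)

    def test_empty_reference_gives_one(self):
        assert uniqueness_to_reference(["CCO"], []) == 1.0


class TestFractionAboveThreshold:
    def test_all_zero(self):
        assert fraction_above_threshold({"a": 0.0, "b": 0.0}) == (0, 0.0)

    def test_half(self):
        assert fraction_above_threshold({"a": 0.6, "b": 0.4}) == (1, 0.5)

    def test_strict_inequality_at_exact_threshold(self):
        count, frac = fraction_above_threshold({"a": 0.5}, tau=0.5)
        assert count == 0 and frac == 0.0


class TestScaffoldRetention:
    def test_substituent_additions_retain(self):
        route = SyntheticRoute("Brc1ccccc1", [("Nc1ccccc1", 0), ("CC(=O)Nc1ccccc1", 5)])
        assert scaffold_retention_rate([route]) == 1.0

    def test_empty_routes_raise(self):
        with pytest.raises(ValueError):
            scaffold_retention_rate([])
        with pytest.raises(ValueError):
            scaffold_retention_rate([SyntheticRoute("C", [])])

    def test_scaffold_breaking_step_lowers_rate(self):
        # second step replaces the benzene scaffold by a pyridine: broken
        route = SyntheticRoute("Brc1ccccc1", [("Nc1ccccc1", 0), ("Nc1ccncc1", 1)])
        assert scaffold_retention_rate([route]) == pytest.approx(0.5)

    def test_search_routes_retain_scaffolds(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=20, beam_width=1, seed=1)
        )
        routes = [e.route for e in res.generated if len(e.route) > 0]
        assert scaffold_retention_rate(routes) == 1.0


class TestStepDistribution:
    def test_zero_iterations_empty(self, search_system):
        res = search_system.mcts.run_search(search_system.start, MCTSConfig(iterations=0, seed=0))
        assert reaction_step_distribution(res) == {}

    def test_histogram_conserves_generated_count(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=20, beam_width=3, seed=2)
        )
        hist = reaction_step_distribution(res)
        assert sum(hist.values()) == len(res.generated) - 1  # root excluded
        assert all(d >= 1 for d in hist)

    def test_summary_report_columns(self, search_system):
        res = search_system.mcts.run_search(
            search_system.start, MCTSConfig(iterations=20, beam_width=3, seed=2)
        )
        rep = summarize_search(res, reference=[r.reactant for r in search_system.records])
        assert rep["total"] == len(res.generated)
        assert 0 <= rep["uniqueness"] <= 1
        assert rep["reward_above_tau_pct"] == pytest.approx(
            100 * rep["reward_above_tau_num"] / rep["total"]
        )
        assert 0 <= rep["internal_diversity"] <= 1
        assert 0 <= rep["uniqueness_to_reference"] <= 1


class TestStartingMaterialFilter:
    def test_worked_fixture(self):
        mols = [
            "C1CCCCCCCC1",          # cyclononane: 9-ring
            "CCCCCCCCCCCCCCCC(=O)NCCCC",  # MW >= 300 amide
            "Brc1ccccc1",           # survivor
            "CCCCCC",               # hexane: no reactive group
        ]
        survivors, removed = filter_starting_materials(mols)
        assert survivors == ["Brc1ccccc1"]
        assert removed == {"ring_size": 1, "molecular_weight": 1, "no_reactive_group": 1}

    def test_benzene_removed_aromatic_not_unsaturation(self):
        survivors, removed = filter_starting_materials(["c1ccccc1"])
        assert survivors == [] and removed["no_reactive_group"] == 1

    def test_nonaromatic_unsaturation_kept(self):
        survivors, _ = filter_starting_materials(["C=CCCCC"])
        assert survivors == ["C=CCCCC"]

    def test_mw_boundary_inclusive_removal(self):
        # molecular weight exactly >= bound is removed
        from rxntree.chem import molecular_weight

        spec = FilterSpec(mw_bound=molecular_weight("CCO"))  # exactly at the bound
        survivors, removed = filter_starting_materials(["CCO", "CO"], spec)
        assert survivors == ["CO"]

    def test_order_preserved(self):
        mols = ["CCBr", "CCO", "CC=C", "CC(=O)C"]
        survivors, _ = filter_starting_materials(mols)
        assert survivors == mols


class TestLigandEfficiency:
    @pytest.mark.parametrize(
        "score, atoms, expected",
        [(-5.1, 7, 0.729), (-4.5, 7, 0.643), (0.0, 10, 0.0)],
    )
    def test_worked_examples(self, score, atoms, expected):
        assert round(ligand_efficiency(score, atoms), 3) == expected

    def test_from_smiles_counts_heavy_atoms(self):
        # toluene: 7 heavy atoms, hydrogens excluded
        assert ligand_efficiency_from_smiles(-5.1, "Cc1ccccc1") == pytest.approx(5.1 / 7)

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            ligand_efficiency(-5.0, 0)
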