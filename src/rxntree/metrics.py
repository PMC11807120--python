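"""Set-level and route-level evaluation of generated molecules.

Implements the standard generative-chemistry report: internal diversity
(IntDiv_p on ECFP4/2048), uniqueness and uniqueness against a reference
corpus, the fraction of molecules beating a reward threshold, the reaction
step (depth) distribution, Murcko-scaffold retention along routes, the
reactive starting-material filter, and the ligand-efficiency helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import (
    ECFP4,
    canonical_smiles,
    fingerprint,
    heavy_atom_count,
    mol_from_smiles,
    molecular_weight,
    murcko_scaffold,
    tanimoto,
)
from .mcts import SearchResult, SyntheticRoute


def internal_diversity(molecules: list[str], p: int = 1) -> float:
    """IntDiv_p(G) = 1 - (|G|^-2 Σ_{m1,m2 ∈ G} T(m1,m2)^p)^(1/p).

    The double sum runs over ordered pairs including self-pairs; T is the
    ECFP4/2048 Tanimoto similarity.  0 for a single molecule or a set of
    exact duplicates; approaches 1 for maximally dissimilar sets.
    """
    if not molecules:
        raise ValueError("empty molecule set")
    if p < 1:
        raise ValueError("p must be >= 1")
    fps = [fingerprint(m, ECFP4) for m in molecules]
    n = len(fps)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += tanimoto(fps[i], fps[j]) ** p
    return 1.0 - (total / n**2) ** (1.0 / p)


def uniqueness(molecules: list[str]) -> float:
    """|unique canonical molecules| / total generated."""
    if not molecules:
        raise ValueError("empty molecule set")
    return len({canonical_smiles(m) for m in molecules}) / len(molecules)


def uniqueness_to_reference(molecules: list[str], reference: list[str]) -> float:
    """Fraction of the unique molecules absent from the reference corpus."""
    uniq = {canonical_smiles(m) for m in molecules}
    if not uniq:
        raise ValueError("empty molecule set")
    ref = {canonical_smiles(m) for m in reference}
    return len(uniq - ref) / len(uniq)


def fraction_above_threshold(rewards: dict[str, float], tau: float = 0.5) -> tuple[int, float]:
    """(count, fraction) of unique molecules with reward strictly above tau;
    the fraction uses the set's total size as denominator."""
    if not rewards:
        raise ValueError("empty reward table")
    count = sum(1 for r in rewards.values() if r > tau)
    return count, count / len(rewards)


def scaffold_retention_rate(routes: list[SyntheticRoute]) -> float:
    """Fraction of route steps whose child contains the parent's Murcko scaffold.

    Steps whose parent is acyclic (empty scaffold) count as retained.
    """
    steps = 0
    retained = 0
    for route in routes:
        parents = route.molecules()[:-1]
        children = route.molecules()[1:]
        for par, chi in zip(parents, children):
            steps += 1
            scaf = murcko_scaffold(par)
            if not scaf:
                retained += 1
                continue
            if mol_from_smiles(chi).HasSubstructMatch(mol_from_smiles(scaf)):
                retained += 1
    if steps == 0:
        raise ValueError("no route steps to evaluate")
    return retained / steps


def reaction_step_distribution(result: SearchResult) -> dict[int, int]:
    """Histogram of generated-molecule depths (reaction step counts), root excluded."""
    return result.depth_histogram()


# ---------------------------------------------------------------------------
# Starting-material filters

@dataclass
class FilterSpec:
    """Reactive starting-material rules: no ring larger than ``max_ring_size``,
    molecular weight strictly below ``mw_bound`` (>= bound removed), and at
    least one reactive group — halogen, carbonyl, non-aromatic unsaturated
    bond, or nucleophilic substituent (-OH, -NH2/-NH-, -SH)."""

    max_ring_size: int = 8
    mw_bound: float = 300.0
    required_groups: dict[str, str] = field(
        default_factory=lambda: {
            "halogen": "[F,Cl,Br,I]",
            "carbonyl": "[CX3]=[OX1]",
            # '=' / '#' never match aromatic bonds, so aromatic rings alone
            # do not count as unsaturation
            "unsaturated_bond": "*=,#*",
            "nucleophile": "[OX2H1,SX2H1,NX3H2,NX3H1]",
        }
    )

    def __post_init__(self) -> None:
        for name, smarts in self.required_groups.items():
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"invalid SMARTS for group {name}: {smarts!r}")


def _max_ring_size(smiles: str) -> int:
    mol = mol_from_smiles(smiles)  # keep alive: RingInfo is a view into the mol
    rings = mol.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def filter_starting_materials(
    molecules: list[str], spec: FilterSpec | None = None
) -> tuple[list[str], dict[str, int]]:
    """Apply the three removal rules in order; returns survivors (order
    preserved) and per-rule removal counts."""
    spec = spec or FilterSpec()
    patterns = {n: Chem.MolFromSmarts(s) for n, s in spec.required_groups.items()}
    survivors = []
    removed = {"ring_size": 0, "molecular_weight": 0, "no_reactive_group": 0}
    for smi in molecules:
        if _max_ring_size(smi) > spec.max_ring_size:
            removed["ring_size"] += 1
            continue
        if molecular_weight(smi) >= spec.mw_bound:
            removed["molecular_weight"] += 1
            continue
        mol = mol_from_smiles(smi)
        if not any(mol.HasSubstructMatch(p) for p in patterns.values()):
            removed["no_reactive_group"] += 1
            continue
        survivors.append(smi)
    return survivors, removed


def ligand_efficiency(docking_score: float, heavy_atoms: int) -> float:
    """Absolute docking score divided by the heavy-atom count."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return abs(docking_score) / heavy_atoms


def ligand_efficiency_from_smiles(docking_score: float, smiles: str) -> float:
    return ligand_efficiency(docking_score, heavy_atom_count(smiles))


# ---------------------------------------------------------------------------
# One-call report

def summarize_search(
    result: SearchResult,
    reference: list[str] | None = None,
    tau: float = 0.5,
    p: int = 1,
) -> dict:
    """The full table-style report for one search: Total, uniqueness,
    reward > tau count and %, internal diversity, and the step distribution."""
    entries = list(result.generated)
    molecules = [e.smiles for e in entries]
    rewards = {e.smiles: e.reward for e in entries}
    count, frac = fraction_above_threshold(rewards, tau)
    report = {
        "total": len(molecules),
        "uniqueness": uniqueness(molecules),
        "reward_above_tau_num": count,
        "reward_above_tau_pct": 100.0 * frac,
        "internal_diversity": internal_diversity(molecules, p=p),
        "mean_depth": float(np.mean([e.depth for e in entries if e.depth >= 1])) if len(entries) > 1 else 0.0,
        "step_distribution": result.depth_histogram(),
        "best_reward": float(result.generated.best().reward),
    }
    if reference is not None:
        report["uniqueness_to_reference"] = uniqueness_to_reference(molecules, reference)
    return report
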