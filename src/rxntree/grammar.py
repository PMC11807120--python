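"""Synthetic reaction grammar and activity fixtures.

A desk-scale, fully deterministic stand-in for a template-labelled reaction
corpus.  Each :class:`ToyTemplate` is a named single-reactant -> single-product
transform written as reaction SMARTS; partner reactants (acyl chlorides,
sulfonyl chlorides, methylating agents...) are implicit in the transform, so a
record is exactly (reactant, product, template index).

The grammar is deliberately ambiguous: an aryl bromide can undergo amination,
methoxylation or cyanation; an acid can be amidated or esterified — so which
product follows from a reactant is undetermined without the template label.
The realized mean number of applicable templates per reactant ("ambiguity")
is steered to a configurable target, which fixes the best achievable accuracy
of any unconditional product predictor at ~1/ambiguity.

Activity labels are driven by a hidden pharmacophore substructure (default: an
N-alkylsulfonamide, reachable from an aryl bromide in two grammar steps), with
optional label noise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import canonical_smiles, mol_from_smiles
from .data import RawReaction, ReactionRecord


class TemplateApplicationError(RuntimeError):
    """A transform produced invalid chemistry — a grammar bug, not a data issue."""


@dataclass(frozen=True)
class ToyTemplate:
    """One labelled transform: a reactant-side SMARTS plus a product constructor."""

    index: int
    name: str
    match_pattern: str  # reactant-side SMARTS (also used by the GCN match filter)
    reaction_smarts: str  # full RDKit reaction SMARTS implementing the transform
    single_product: bool = False

    def pattern_mol(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.match_pattern)
        if patt is None:
            raise ValueError(f"invalid SMARTS for template {self.index}: {self.match_pattern}")
        return patt


def default_templates() -> list[ToyTemplate]:
    """The built-in 10-transform grammar (aromatic medicinal-chemistry steps)."""
    specs = [
        ("ar_amination", "[c][Br]", "[c:1][Br]>>[c:1][NH2]", False),
        ("ar_methoxylation", "[c][Br]", "[c:1][Br]>>[c:1]OC", False),
        ("ar_cyanation", "[c][Br]", "[c:1][Br]>>[c:1]C#N", False),
        ("amidation", "[CX3](=O)[OX2H1]", "[C:1](=[O:2])[OX2H1]>>[C:1](=[O:2])NC", False),
        ("esterification", "[CX3](=O)[OX2H1]", "[C:1](=[O:2])[OX2H1]>>[C:1](=[O:2])OC", False),
        ("acetylation", "[NX3;H2;!$(NC=O);!$(NS)]", "[NX3;H2;!$(NC=O);!$(NS):1]>>[N:1]C(C)=O", False),
        ("sulfonamidation", "[NX3;H2;!$(NC=O);!$(NS)]", "[NX3;H2;!$(NC=O);!$(NS):1]>>[N:1]S(C)(=O)=O", False),
        ("nitro_reduction", "[c][N+](=O)[O-]", "[c:1][N+](=O)[O-]>>[c:1][NH2]", True),
        ("o_demethylation", "[c][OX2][CH3]", "[c:1][OX2:2][CH3]>>[c:1][OX2H1:2]", True),
        ("phenol_acetylation", "[c][OX2H1]", "[c:1][OX2H1:2]>>[c:1][O:2]C(C)=O", False),
    ]
    return [
        ToyTemplate(index=i, name=n, match_pattern=m, reaction_smarts=rs, single_product=sp)
        for i, (n, m, rs, sp) in enumerate(specs)
    ]


def apply_template(smiles: str, template: ToyTemplate) -> str | None:
    """Apply a transform at the match site with the lowest canonical atom rank.

    Returns the canonical product SMILES, or ``None`` when the reactant does
    not contain the template's pattern.  The site rule makes multi-match
    molecules deterministic without any model in the loop.
    """
    mol = mol_from_smiles(smiles)
    patt = template.pattern_mol()
    matches = mol.GetSubstructMatches(patt)
    if not matches:
        return None
    rxn = AllChem.ReactionFromSmarts(template.reaction_smarts)
    product_sets = rxn.RunReactants((mol,))
    if not product_sets:
        return None
    candidates = []
    for prods in product_sets:
        if len(prods) != 1:
            raise TemplateApplicationError(
                f"template {template.name} produced {len(prods)} molecules"
            )
        try:
            out = prods[0]
            Chem.SanitizeMol(out)
            candidates.append(Chem.MolToSmiles(out))
        except Exception as exc:  # noqa: BLE001 — sanitize failures are grammar bugs
            raise TemplateApplicationError(
                f"template {template.name} on {smiles!r} gave invalid chemistry: {exc}"
            ) from exc
    # RDKit enumerates reactant hits in GetSubstructMatches order; pick the
    # hit whose first atom has the lowest canonical rank.
    ranks = list(Chem.CanonicalRankAtoms(mol))
    if len(candidates) == len(matches):
        order = sorted(range(len(matches)), key=lambda k: min(ranks[a] for a in matches[k]))
        return candidates[order[0]]
    return sorted(candidates)[0]


def applicable_templates(smiles: str, templates: list[ToyTemplate]) -> list[ToyTemplate]:
    mol = mol_from_smiles(smiles)
    return [t for t in templates if mol.HasSubstructMatch(t.pattern_mol())]


# ---------------------------------------------------------------------------
# Reactant construction

_SCAFFOLDS = [
    "{a}c1ccc({b})cc1",  # para-disubstituted benzene
    "{a}c1cccc({b})c1",  # meta-disubstituted benzene
    "{a}c1ccc({b})cn1",  # pyridine
    "{a}c1ccc({b})s1",  # thiophene
    "{a}c1ccc({b})o1",  # furan
    "{a}c1ccc(C({b})=O)cc1",  # aryl ketone linker
]

_REACTIVE = ["Br", "O=[N+]([O-])", "OC(=O)", "N", "CO", "O"]
_INERT = ["C", "CC", "F", "Cl", "C(C)C", "CC(C)C"]


@dataclass
class GrammarConfig:
    """Knobs of the synthetic grammar.

    ``ambiguity_target`` is the desired mean number of applicable templates
    per reactant; the generator steers the reactant mix until the realized
    mean is within 25% of it.
    """

    n_scaffolds: int = 5
    n_substituents: int = 4
    templates: list[ToyTemplate] = field(default_factory=default_templates)
    ambiguity_target: float = 3.0
    n_reactants: int = 120
    closure_depth: int = 0  # also emit records for molecules reachable in <= this many steps
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.templates) < 2:
            raise ValueError("need at least two templates")
        if self.ambiguity_target < 1:
            raise ValueError("ambiguity_target must be >= 1")
        if not 1 <= self.n_scaffolds <= len(_SCAFFOLDS):
            raise ValueError(f"n_scaffolds must be in [1, {len(_SCAFFOLDS)}]")
        if not 1 <= self.n_substituents <= len(_INERT):
            raise ValueError(f"n_substituents must be in [1, {len(_INERT)}]")


class GrammarConfigError(ValueError):
    """The requested grammar cannot be realized (e.g. unreachable ambiguity)."""


def _candidate_reactants(cfg: GrammarConfig) -> list[str]:
    scaffolds = _SCAFFOLDS[: cfg.n_scaffolds]
    inert = _INERT[: cfg.n_substituents]
    out: dict[str, None] = {}
    for scaf, a in itertools.product(scaffolds, _REACTIVE):
        for b in inert + [r for r in _REACTIVE if r != a]:
            smi = scaf.format(a=a, b=b)
            if Chem.MolFromSmiles(smi) is None:
                continue
            out.setdefault(canonical_smiles(smi), None)
    return list(out)


def select_reactants(cfg: GrammarConfig) -> list[str]:
    """Pick ``n_reactants`` molecules whose mean template-ambiguity hits the target."""
    pool = _candidate_reactants(cfg)
    amb = {s: len(applicable_templates(s, cfg.templates)) for s in pool}
    pool = [s for s in pool if amb[s] >= 1]
    if not pool:
        raise GrammarConfigError("no reactant matches any template")
    if cfg.ambiguity_target > max(amb.values()):
        raise GrammarConfigError(
            f"ambiguity_target {cfg.ambiguity_target} exceeds the grammar maximum {max(amb.values())}"
        )
    rng = np.random.default_rng(cfg.seed)
    order = list(rng.permutation(len(pool)))
    chosen: list[str] = []
    total = 0.0
    # greedy steering: always take the remaining candidate that keeps the
    # running mean ambiguity closest to the target (shuffle breaks ties)
    while len(chosen) < cfg.n_reactants and order:
        best_j, best_err = None, None
        for j in order:
            err = abs((total + amb[pool[j]]) / (len(chosen) + 1) - cfg.ambiguity_target)
            if best_err is None or err < best_err:
                best_j, best_err = j, err
        order.remove(best_j)
        chosen.append(pool[best_j])
        total += amb[pool[best_j]]
    realized = total / len(chosen)
    if abs(realized - cfg.ambiguity_target) > 0.25 * cfg.ambiguity_target:
        raise GrammarConfigError(
            f"realized ambiguity {realized:.2f} misses target {cfg.ambiguity_target} by >25%"
        )
    return chosen


def generate_reaction_dataset(cfg: GrammarConfig) -> list[RawReaction]:
    """One record per (reactant, applicable template); deterministic given seed.

    ``ambiguity_target`` steers the starting reactants.  With
    ``closure_depth > 0`` the grammar is additionally rolled forward: every
    molecule reachable within that many steps contributes records for its own
    applicable templates, the way a real reaction corpus contains the products
    of earlier reactions as reactants of later ones.
    """
    reactants = select_reactants(cfg)
    records = []
    seen: dict[str, None] = {}
    frontier = list(reactants)
    for level in range(cfg.closure_depth + 1):
        nxt = []
        for smi in frontier:
            if smi in seen:
                continue
            seen[smi] = None
            for t in applicable_templates(smi, cfg.templates):
                product = apply_template(smi, t)
                if product is None:
                    raise TemplateApplicationError(
                        f"template {t.name} matched but produced nothing on {smi}"
                    )
                records.append(
                    RawReaction(reactants=(smi,), products=(product,), template_index=t.index)
                )
                nxt.append(product)
        frontier = nxt
    return records


def unconditional_bayes_accuracy(records: list[ReactionRecord | RawReaction]) -> float:
    """Exact best-possible per-record accuracy of a predictor blind to templates.

    Computed by enumeration: for each reactant, an unconditional predictor can
    at best always emit that reactant's most frequent product.
    """
    by_reactant: dict[str, dict[str, int]] = {}
    for r in records:
        reactant = r.reactant if isinstance(r, ReactionRecord) else r.reactants[0]
        product = r.product if isinstance(r, ReactionRecord) else r.products[0]
        by_reactant.setdefault(reactant, {}).setdefault(product, 0)
        by_reactant[reactant][product] += 1
    total = sum(sum(d.values()) for d in by_reactant.values())
    best = sum(max(d.values()) for d in by_reactant.values())
    return best / total


def grammar_closure(
    start_molecules: list[str], templates: list[ToyTemplate], depth: int
) -> list[str]:
    """All molecules reachable from the starts in <= depth template applications."""
    seen: dict[str, None] = {canonical_smiles(s): None for s in start_molecules}
    frontier = list(seen)
    for _ in range(depth):
        nxt = []
        for smi in frontier:
            for t in applicable_templates(smi, templates):
                prod = apply_template(smi, t)
                if prod is not None and prod not in seen:
                    seen[prod] = None
                    nxt.append(prod)
        frontier = nxt
    return list(seen)


# ---------------------------------------------------------------------------
# Activity fixtures

DEFAULT_PHARMACOPHORE = "[NX3][SX4](=O)(=O)[CX4]"  # N-alkylsulfonamide


@dataclass
class ActivityRule:
    """Hidden substructure rule driving active/inactive labels."""

    pharmacophore: str = DEFAULT_PHARMACOPHORE
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")
        if Chem.MolFromSmarts(self.pharmacophore) is None:
            raise ValueError(f"invalid pharmacophore SMARTS: {self.pharmacophore}")


class ActivityConfigError(ValueError):
    """The rule yields a single-class dataset on the given molecules."""


def generate_activity_dataset(molecules: list[str], rule: ActivityRule):
    """Label molecules by pharmacophore match XOR Bernoulli(label_noise).

    Returns a DataFrame with canonical ``smiles`` and integer ``label``.
    """
    import pandas as pd

    patt = Chem.MolFromSmarts(rule.pharmacophore)
    rng = np.random.default_rng(rule.seed)
    smiles = [canonical_smiles(s) for s in molecules]
    match = np.array([mol_from_smiles(s).HasSubstructMatch(patt) for s in smiles], dtype=bool)
    flips = rng.random(len(smiles)) < rule.label_noise
    labels = (match ^ flips).astype(int)
    if match.sum() == 0:
        raise ActivityConfigError("pharmacophore matches no molecule in the set")
    if labels.sum() in (0, len(labels)):
        raise ActivityConfigError("activity labels are single-class; adjust rule or molecules")
    return pd.DataFrame({"smiles": smiles, "label": labels})
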