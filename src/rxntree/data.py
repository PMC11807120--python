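"""Reaction-dataset preparation.

Raw reactions come in as (reactants, products, template index) triples, the
reaction sides possibly holding several molecules.  Preparation mirrors the
curation of template-labelled USPTO-style data:

1. reagents/solvents on a configurable list are removed from both sides;
2. each reaction is reduced to the single (reactant, product) pair with the
   highest ECFP4 Tanimoto similarity, capturing the actual structural
   transformation;
3. the template index is prepended to the reactant token sequence as a
   condition symbol for conditional sequence-model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ECFP4, canonical_smiles, fingerprint, tanimoto
from .tokenizer import TokenSequence, Vocabulary, condition_token, tokenize_smiles

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    """Raised when a reaction has an empty reactant or product side."""


@dataclass(frozen=True)
class RawReaction:
    """One labelled reaction as read from disk (sides not yet paired)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    template_index: int
    source_id: str = ""

    @classmethod
    def from_row(cls, reactants: str, products: str, template: int, source_id: str = "") -> "RawReaction":
        return cls(
            reactants=tuple(s for s in reactants.split(".") if s),
            products=tuple(s for s in products.split(".") if s),
            template_index=int(template),
            source_id=source_id,
        )


@dataclass(frozen=True)
class ReactionRecord:
    """A single-reactant, single-product transformation — the training atom."""

    reactant: str
    product: str
    template_index: int


def remove_reagents(r: RawReaction, reagent_list: set[str]) -> RawReaction | None:
    """Drop molecules whose canonical form is on the reagent list.

    Returns ``None`` (a flagged record, to be excluded with a logged count)
    when removal empties either side.  ``reagent_list`` entries must already
    be canonical.
    """
    if not reagent_list:
        return r
    reactants = tuple(s for s in r.reactants if canonical_smiles(s) not in reagent_list)
    products = tuple(s for s in r.products if canonical_smiles(s) not in reagent_list)
    if not reactants or not products:
        return None
    return RawReaction(reactants, products, r.template_index, r.source_id)


def pair_reaction(r: RawReaction) -> ReactionRecord:
    """Keep the (reactant, product) pair with maximal ECFP4 Tanimoto similarity.

    Ties break lexicographically on canonical SMILES (reactant first, then
    product), which makes the result independent of input ordering.
    """
    if not r.reactants or not r.products:
        raise PairingError("reaction has an empty side")
    cand_r = sorted(canonical_smiles(s) for s in r.reactants)
    cand_p = sorted(canonical_smiles(s) for s in r.products)
    fps_r = {s: fingerprint(s, ECFP4) for s in cand_r}
    fps_p = {s: fingerprint(s, ECFP4) for s in cand_p}
    best = None
    best_sim = -1.0
    for sr in cand_r:
        for sp in cand_p:
            sim = tanimoto(fps_r[sr], fps_p[sp])
            if sim > best_sim:
                best, best_sim = (sr, sp), sim
    return ReactionRecord(reactant=best[0], product=best[1], template_index=r.template_index)


def prepare_records(
    raw: list[RawReaction], reagent_list: set[str] | None = None
) -> list[ReactionRecord]:
    """remove_reagents + pair_reaction over a dataset; logs the exclusion count."""
    reagent_list = reagent_list or set()
    records = []
    n_flagged = 0
    for r in raw:
        cleaned = remove_reagents(r, reagent_list)
        if cleaned is None:
            n_flagged += 1
            continue
        records.append(pair_reaction(cleaned))
    if n_flagged:
        logger.info("reagent removal emptied %d reactions; excluded", n_flagged)
    return records


def make_training_pair(
    rec: ReactionRecord, conditioned: bool, vocab: Vocabulary | None = None
) -> tuple[TokenSequence, TokenSequence]:
    """Tokenized (source, target).

    Conditioned sources get the template's ``<t_i>`` symbol as a single prefix
    token; bos/eos framing belongs to the model layer, not here.
    """
    src_tokens = tokenize_smiles(rec.reactant)
    if conditioned:
        sym = condition_token(rec.template_index)
        if vocab is not None and sym not in vocab:
            raise KeyError(f"template symbol {sym!r} not in vocabulary")
        src = TokenSequence(tuple([sym] + src_tokens), has_condition=True)
    else:
        src = TokenSequence(tuple(src_tokens))
    tgt = TokenSequence(tuple(tokenize_smiles(rec.product)))
    return src, tgt


def split_dataset(records: list, fractions=(0.8, 0.1, 0.1), seed: int = 0,
                  by_reactant: bool = False):
    """Deterministic random partition into len(fractions) parts (an exact partition).

    With ``by_reactant`` all records sharing a reactant travel together, so a
    held-out split contains no reactant seen in training — the right split for
    judging generalization (and for comparing an unconditional model against
    the per-reactant Bayes accuracy, which presumes every record of a reactant
    is scored).
    """
    fractions = tuple(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    if len(records) < len(fractions):
        raise ValueError("fewer records than splits")
    rng = np.random.default_rng(seed)
    if by_reactant:
        groups: dict[str, list] = {}
        for r in records:
            groups.setdefault(r.reactant, []).append(r)
        keys = sorted(groups)
        order = rng.permutation(len(keys))
        bounds = np.floor(np.cumsum(fractions) * len(keys)).astype(int)
        bounds[-1] = len(keys)
        parts, start = [], 0
        for b in bounds:
            part = []
            for i in order[start:b]:
                part.extend(groups[keys[i]])
            parts.append(part)
            start = b
        return tuple(parts)
    order = rng.permutation(len(records))
    bounds = np.floor(np.cumsum(fractions) * len(records)).astype(int)
    bounds[-1] = len(records)
    parts, start = [], 0
    for b in bounds:
        parts.append([records[i] for i in order[start:b]])
        start = b
    return tuple(parts)


def build_vocabulary(records: list[ReactionRecord], n_templates: int) -> Vocabulary:
    corpora = [tokenize_smiles(r.reactant) for r in records]
    corpora += [tokenize_smiles(r.product) for r in records]
    return Vocabulary.build(corpora, n_templates=n_templates)


# ---------------------------------------------------------------------------
# I/O

def read_reactions(path: str | Path) -> list[RawReaction]:
    """Read a CSV/TSV with columns reactants, products, template."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"reactants": str, "products": str})
    return [
        RawReaction.from_row(row.reactants, row.products, row.template, source_id=str(i))
        for i, row in enumerate(df.itertuples())
    ]


def write_pairs_tsv(path: str | Path, pairs: list[tuple[TokenSequence, TokenSequence]]) -> None:
    with open(path, "w") as fh:
        for src, tgt in pairs:
            fh.write(" ".join(src.tokens) + "\t" + " ".join(tgt.tokens) + "\n")


def write_records_csv(path: str | Path, records: list[ReactionRecord]) -> None:
    pd.DataFrame(
        {
            "reactants": [r.reactant for r in records],
            "products": [r.product for r in records],
            "template": [r.template_index for r in records],
        }
    ).to_csv(path, index=False)


@dataclass
class ReagentConfig:
    """Editable reagent/solvent removal list (canonical SMILES).

    Seeded with hydrochloric acid, ethyl acetate and dichloromethane; extend
    per dataset.
    """

    smiles: set[str] = field(
        default_factory=lambda: {
            canonical_smiles("Cl"),
            canonical_smiles("CCOC(C)=O"),
            canonical_smiles("ClCCl"),
        }
    )
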