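"""Canonical desk-scale experiment recipes.

Two study setups are used throughout the package:

* the **conditioning experiment** — the synthetic grammar at mean template
  ambiguity 3 (120 starting reactants, no closure), a record-level 80/10/10
  split, and a conditional/unconditional transformer twin pair.  The
  conditional model is judged on held-out perfect accuracy; the unconditional
  twin is judged dataset-wide against the exact per-reactant Bayes bound
  (~1/3 at ambiguity 3) obtained by enumeration, which is the accuracy a
  template-blind predictor can at best achieve.

* the **search system** — a smaller grammar (30 starting reactants) rolled
  forward to its full reaction closure, with the transformer trained to
  reproduce every (reactant, template) -> product record exactly, a template
  GCN, and a pharmacophore-driven QSAR reward whose optimum is reachable from
  an aryl bromide start in two reaction steps.  This is the production-style
  stack the tree search runs on.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem

from .data import (
    ReactionRecord,
    build_vocabulary,
    make_training_pair,
    prepare_records,
    split_dataset,
)
from .gcn import GCNConfig, TemplateGCN
from .grammar import (
    DEFAULT_PHARMACOPHORE,
    ActivityRule,
    GrammarConfig,
    apply_template,
    default_templates,
    generate_activity_dataset,
    generate_reaction_dataset,
    unconditional_bayes_accuracy,
)
from .mcts import MCTS, MCTSConfig
from .qsar import QSARReward, train_qsar
from .transformer import Seq2SeqTransformer, TransformerConfig

logger = logging.getLogger(__name__)

N_TEMPLATES = len(default_templates())


def ambiguous_grammar(seed: int = 0) -> GrammarConfig:
    """Grammar of the conditioning experiment: ambiguity 3, no closure."""
    return GrammarConfig(n_reactants=120, ambiguity_target=3.0, closure_depth=0, seed=seed)


def closure_grammar(seed: int = 0) -> GrammarConfig:
    """Grammar of the search system: 30 starts rolled to full closure."""
    return GrammarConfig(n_reactants=30, ambiguity_target=3.0, closure_depth=8, seed=seed)


@dataclass
class ConditioningResult:
    conditional_val_perfect: float
    unconditional_full_perfect: float
    bayes_bound: float
    conditional_history: dict
    unconditional_history: dict
    n_records: int


def conditioning_experiment(seed: int = 0, epochs: int = 200) -> ConditioningResult:
    """Train the conditional/unconditional twins and report the accuracy gap."""
    records = prepare_records(generate_reaction_dataset(ambiguous_grammar(seed)))
    vocab = build_vocabulary(records, n_templates=N_TEMPLATES)
    train, val, _test = split_dataset(records, (0.8, 0.1, 0.1), seed=seed)
    bayes = unconditional_bayes_accuracy(records)

    cond = Seq2SeqTransformer(
        vocab, TransformerConfig(epochs=epochs, patience=80), conditioned=True, seed=seed
    )
    hist_c = cond.fit(
        [make_training_pair(r, True, vocab) for r in train],
        [make_training_pair(r, True, vocab) for r in val],
        target_perfect=0.9,
        val_every=2,
    )

    uncond = Seq2SeqTransformer(
        vocab, TransformerConfig(epochs=min(epochs, 120), patience=40),
        conditioned=False, seed=seed,
    )
    hist_u = uncond.fit(
        [make_training_pair(r, False, vocab) for r in train],
        [make_training_pair(r, False, vocab) for r in val],
        val_every=2,
    )
    full_u = uncond.perfect_accuracy([make_training_pair(r, False, vocab) for r in records])
    return ConditioningResult(
        conditional_val_perfect=max(hist_c["perfect_accuracy"]),
        unconditional_full_perfect=full_u,
        bayes_bound=bayes,
        conditional_history=hist_c,
        unconditional_history=hist_u,
        n_records=len(records),
    )


@dataclass
class SearchSystem:
    """Everything a tree search needs, plus the corpus it was built from."""

    mcts: MCTS
    transformer: Seq2SeqTransformer
    gcn: TemplateGCN
    reward: QSARReward
    records: list[ReactionRecord]
    start: str
    templates: list
    qsar_auc: float
    transformer_train_perfect: float

    def template_patterns(self) -> dict[int, str]:
        return {t.index: t.match_pattern for t in self.templates}


def _pick_start(records, templates, reward, max_reward: float = 0.3) -> str:
    """An aryl-bromide starting material with a provable two-step route to the
    pharmacophore (bromide -> aniline -> sulfonamide) and a low initial reward."""
    patt = Chem.MolFromSmarts(DEFAULT_PHARMACOPHORE)
    amination = next(t for t in templates if t.name == "ar_amination")
    sulfonamidation = next(t for t in templates if t.name == "sulfonamidation")
    candidates = sorted({r.reactant for r in records})
    for smi in candidates:
        p1 = apply_template(smi, amination)
        if p1 is None:
            continue
        p2 = apply_template(p1, sulfonamidation)
        if p2 is None or not Chem.MolFromSmiles(p2).HasSubstructMatch(patt):
            continue
        if reward(smi) <= max_reward:
            return smi
    raise RuntimeError("no suitable starting material in the corpus")


def build_search_system(
    seed: int = 0,
    label_noise: float = 0.0,
    transformer_epochs: int = 260,
) -> SearchSystem:
    """Assemble the full search stack on the closure grammar.

    The transformer is trained until it reproduces the reaction corpus
    exactly (its targets are deterministic, so dropout is off and training
    stops at perfect accuracy ~1), the GCN is trained on the same records,
    and the reward forest on pharmacophore-labelled corpus molecules.
    """
    cfg = closure_grammar(seed)
    records = prepare_records(generate_reaction_dataset(cfg))
    templates = cfg.templates
    vocab = build_vocabulary(records, n_templates=N_TEMPLATES)
    pairs = [make_training_pair(r, True, vocab) for r in records]
    transformer = Seq2SeqTransformer(
        vocab,
        TransformerConfig(epochs=transformer_epochs, patience=transformer_epochs,
                          dropout=0.0, lr_decay_every=60),
        conditioned=True,
        seed=seed,
    )
    hist = transformer.fit(pairs, pairs, target_perfect=0.999, val_every=3)
    train_perfect = max(hist["perfect_accuracy"])
    logger.info("search transformer corpus accuracy: %.3f", train_perfect)

    gcn = TemplateGCN(GCNConfig.toy(n_templates=N_TEMPLATES), seed=seed)
    gcn.fit(records, records[::5])

    molecules = sorted({r.reactant for r in records} | {r.product for r in records})
    activity = generate_activity_dataset(molecules, ActivityRule(label_noise=label_noise, seed=seed))
    reward, report = train_qsar(activity, "toy", seed=seed)

    patterns = {t.index: t.match_pattern for t in templates}
    single = {t.index for t in templates if t.single_product}
    mcts = MCTS(gcn, transformer, reward, patterns,
                MCTSConfig(iterations=50, beam_width=5, seed=seed), single)
    start = _pick_start(records, templates, reward)
    return SearchSystem(
        mcts=mcts,
        transformer=transformer,
        gcn=gcn,
        reward=reward,
        records=records,
        start=start,
        templates=templates,
        qsar_auc=report.auc,
        transformer_train_perfect=train_perfect,
    )
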