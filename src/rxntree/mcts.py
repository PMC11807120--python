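"""Monte Carlo tree search over virtual reactions.

Nodes are molecules; edges are single-step virtual reactions proposed by the
template classifier (GCN + SMARTS match filter) and realized by the
conditional sequence model.  Each iteration runs the four classic phases:

selection
    descend from the root by maximal UCB score
    ``Q(s_i) + 2 C_p sqrt(ln N(s_p) / N(s_i))``; unvisited children score
    +infinity and tie-break by provenance (beam rank, template index);
expansion
    the top-k predicted templates that pass the substructure filter condition
    a beam search each; the decoded products become child nodes;
simulation
    a fixed-schedule rollout — ``sim_templates`` sampled templates per step,
    one greedy molecule each, ``sim_depth`` steps — whose best reward over the
    ≤ sim_templates**sim_depth leaf products (falling back to shallower
    products, then to the node's own reward) values the node;
backpropagation
    the value is added along the path back to the root (N += 1, W += value).

Every distinct molecule created in expansion or simulation is recorded with
its reward, depth and replayable synthetic route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import canonical_smiles, is_valid_smiles
from .gcn import TemplateGCN, TemplateRanking, filter_matching_templates
from .tokenizer import TokenSequence, condition_token, tokenize_smiles
from .transformer import Seq2SeqTransformer


@dataclass
class MCTSConfig:
    """Search knobs; simulation schedule defaults to 5 templates x 1 molecule
    x 2 steps, valuing a node by the max over its <= 25 rollout products."""

    c_p: float = 1.0 / math.sqrt(2.0)
    iterations: int = 200
    expansion_k: int = 10
    beam_width: int = 10
    sim_templates: int = 5
    sim_depth: int = 2
    sim_per_template: int = 1
    max_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("iterations", "expansion_k", "beam_width", "sim_templates",
                     "sim_depth", "sim_per_template", "max_depth"):
            if getattr(self, name) < 0 or (name not in ("iterations",) and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.c_p < 0:
            raise ValueError("c_p must be non-negative")


class SearchNode:
    """A molecule in the search tree."""

    __slots__ = ("molecule", "parent", "children", "visits", "value_sum",
                 "template_index", "beam_rank", "depth", "reward", "expanded", "terminal")

    def __init__(self, molecule: str, parent: "SearchNode | None" = None,
                 template_index: int | None = None, beam_rank: int | None = None,
                 reward: float = 0.0):
        self.molecule = molecule
        self.parent = parent
        self.children: list[SearchNode] = []
        self.visits = 0  # N(s)
        self.value_sum = 0.0  # W(s)
        self.template_index = template_index
        self.beam_rank = beam_rank
        self.depth = 0 if parent is None else parent.depth + 1
        self.reward = reward
        self.expanded = False
        self.terminal = False

    @property
    def q(self) -> float:
        return self.value_sum / self.visits if self.visits > 0 else 0.0

    def __repr__(self) -> str:
        return f"SearchNode({self.molecule!r}, N={self.visits}, Q={self.q:.3f}, depth={self.depth})"


def ucb_score(child: SearchNode, parent: SearchNode, c_p: float) -> float:
    """Q(s_i) + 2 C_p sqrt(ln N(s_p) / N(s_i)); +inf for unvisited children."""
    if child.visits < 0 or parent.visits < 1:
        raise ValueError("invalid visit counts")
    if child.visits == 0:
        return math.inf
    return child.q + 2.0 * c_p * math.sqrt(math.log(parent.visits) / child.visits)


def backpropagate(leaf: SearchNode, value: float) -> None:
    """N += 1 and W += value on every node from the leaf up to the root."""
    node = leaf
    while node is not None:
        node.visits += 1
        node.value_sum += value
        node = node.parent


@dataclass
class SyntheticRoute:
    """A replayable root-to-leaf reaction chain."""

    start: str
    steps: list[tuple[str, int]]  # (product molecule, template index) per reaction

    def __len__(self) -> int:
        return len(self.steps)

    def molecules(self) -> list[str]:
        return [self.start] + [m for m, _ in self.steps]

    def to_dict(self) -> dict:
        return {"start": self.start,
                "steps": [{"smiles": m, "template": t} for m, t in self.steps]}


def extract_route(node: SearchNode) -> SyntheticRoute:
    """Parent chain from the root; length equals node.depth."""
    chain = []
    cur = node
    while cur.parent is not None:
        chain.append((cur.molecule, cur.template_index))
        cur = cur.parent
    chain.reverse()
    return SyntheticRoute(start=cur.molecule, steps=chain)


@dataclass
class GeneratedEntry:
    smiles: str
    reward: float
    depth: int
    route: SyntheticRoute


@dataclass
class GeneratedSet:
    """All distinct molecules a search created, deduplicated by canonical
    SMILES keeping the max-reward route."""

    entries: dict[str, GeneratedEntry] = field(default_factory=dict)

    def add(self, smiles: str, reward: float, depth: int, route: SyntheticRoute) -> None:
        cur = self.entries.get(smiles)
        if cur is None or reward > cur.reward or (reward == cur.reward and depth < cur.depth):
            self.entries[smiles] = GeneratedEntry(smiles, reward, depth, route)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def smiles(self) -> list[str]:
        return list(self.entries)

    def rewards(self) -> np.ndarray:
        return np.array([e.reward for e in self.entries.values()])

    def best(self) -> GeneratedEntry:
        return max(self.entries.values(), key=lambda e: e.reward)


@dataclass
class SearchResult:
    root: SearchNode
    generated: GeneratedSet
    iterations: int
    n_reward_calls: int
    n_simulation_products: int
    counters: dict[str, int]

    def depth_histogram(self) -> dict[int, int]:
        """Counts of generated molecules (root excluded) by reaction depth."""
        hist: dict[int, int] = {}
        for e in self.generated:
            if e.depth >= 1:
                hist[e.depth] = hist.get(e.depth, 0) + 1
        return hist


class MCTS:
    """Four-phase tree search gluing the GCN, the transformer and a reward."""

    def __init__(
        self,
        gcn: TemplateGCN,
        transformer: Seq2SeqTransformer,
        reward,
        template_patterns: dict[int, str],
        config: MCTSConfig | None = None,
        single_product: set[int] | None = None,
    ):
        self.gcn = gcn
        self.transformer = transformer
        self.template_patterns = template_patterns
        self.config = config or MCTSConfig()
        self.single_product = single_product or set()
        self._raw_reward = reward
        self._reward_cache: dict[str, float] = {}
        self.last_sim_candidates = 0  # instrumentation: candidates in the last rollout max

    # reward is treated as a pure function and cached by canonical SMILES
    def reward(self, smiles: str) -> float:
        hit = self._reward_cache.get(smiles)
        if hit is None:
            hit = float(self._raw_reward(smiles))
            if not 0.0 <= hit <= 1.0:
                raise ValueError(f"reward {hit} outside [0, 1] for {smiles}")
            self._reward_cache[smiles] = hit
        return hit

    # -- phases -----------------------------------------------------------
    def select(self, root: SearchNode) -> SearchNode:
        """Descend by argmax UCB until an unexpanded or depth-capped node."""
        node = root
        while node.expanded and node.children and node.depth < self.config.max_depth:
            node = min(
                node.children,
                key=lambda c: (
                    -ucb_score(c, node, self.config.c_p),
                    c.beam_rank if c.beam_rank is not None else 0,
                    c.template_index if c.template_index is not None else -1,
                ),
            )
        return node

    def _filtered_ranking(self, smiles: str, k: int) -> TemplateRanking:
        ranking = self.gcn.predict_templates(smiles, k)
        return filter_matching_templates(smiles, ranking, self.template_patterns)

    def expand(self, node: SearchNode, generated: GeneratedSet) -> list[SearchNode]:
        """Create children from the filtered top-k templates; expand-once."""
        node.expanded = True
        ranking = self._filtered_ranking(node.molecule, self.config.expansion_k)
        if len(ranking) == 0:
            node.terminal = True
            return []
        products = self.transformer.enumerate_products(
            node.molecule, ranking, self.config.beam_width,
            single_product=self.single_product,
        )
        existing = {c.molecule for c in node.children}
        new_children = []
        for prod, t_idx, rank in sorted(products, key=lambda p: (p[2], p[1])):
            if prod in existing or prod == node.molecule:
                continue
            child = SearchNode(prod, parent=node, template_index=t_idx,
                               beam_rank=rank, reward=self.reward(prod))
            node.children.append(child)
            existing.add(prod)
            new_children.append(child)
            generated.add(prod, child.reward, child.depth, extract_route(child))
        if not new_children:
            node.terminal = True
        return new_children

    def _sample_templates(self, smiles: str, rng: np.random.Generator) -> list[int]:
        ranking = self._filtered_ranking(smiles, self.gcn.config.n_templates)
        if len(ranking) == 0:
            return []
        idx = np.array(ranking.indices())
        probs = np.array([s for _, s in ranking], dtype=float)
        probs = probs / probs.sum()
        k = min(self.config.sim_templates, len(idx))
        return [int(i) for i in rng.choice(idx, size=k, replace=False, p=probs)]

    def simulate(self, node: SearchNode, rng: np.random.Generator,
                 generated: GeneratedSet | None = None) -> float:
        """Fixed-schedule rollout; returns the node's value estimate in [0, 1]."""
        cfg = self.config
        frontier = [(node.molecule, extract_route(node))]
        last_rewards: list[float] = []
        for level in range(cfg.sim_depth):
            nxt = []
            for smiles, route in frontier:
                for t_idx in self._sample_templates(smiles, rng):
                    src = TokenSequence(
                        tuple([condition_token(t_idx)] + tokenize_smiles(smiles)),
                        has_condition=True,
                    )
                    beam = self.transformer.beam_decode(src, cfg.sim_per_template)
                    for prod in beam.smiles()[: cfg.sim_per_template]:
                        if prod == smiles:
                            continue
                        new_route = SyntheticRoute(route.start, route.steps + [(prod, t_idx)])
                        nxt.append((prod, new_route))
                        if generated is not None:
                            generated.add(prod, self.reward(prod),
                                          node.depth + level + 1, new_route)
            if not nxt:
                break
            frontier = nxt
            last_rewards = [self.reward(s) for s, _ in frontier]
        # the max is taken over the deepest non-empty rollout level
        # (<= sim_templates**sim_depth candidates; the node's own reward
        # when every rollout dead-ends)
        self.last_sim_candidates = len(last_rewards)
        if not last_rewards:
            return node.reward
        return max(last_rewards)

    # -- driver -----------------------------------------------------------
    def run_search(self, start: str, config: MCTSConfig | None = None) -> SearchResult:
        if config is not None:
            self.config = config
        cfg = self.config
        if not is_valid_smiles(start):
            raise ValueError(f"invalid starting material: {start!r}")
        start = canonical_smiles(start)
        rng = np.random.default_rng(cfg.seed)
        self._reward_cache.clear()
        root = SearchNode(start, reward=self.reward(start))
        generated = GeneratedSet()
        generated.add(start, root.reward, 0, SyntheticRoute(start, []))
        n_sim_products = 0
        for _ in range(cfg.iterations):
            node = self.select(root)
            if not node.expanded and node.depth < cfg.max_depth:
                children = self.expand(node, generated)
                if children:
                    node = children[0]  # lowest provenance rank first
            before = len(generated)
            value = self.simulate(node, rng, generated)
            n_sim_products += len(generated) - before
            backpropagate(node, value)
        counters = {
            "total_generated": len(generated),
            "n_simulation_products": n_sim_products,
            "beam_invalid": sum(b.n_invalid for b in self.transformer._beam_cache.values()),
            "beam_duplicate": sum(b.n_duplicate for b in self.transformer._beam_cache.values()),
        }
        return SearchResult(
            root=root,
            generated=generated,
            iterations=cfg.iterations,
            n_reward_calls=len(self._reward_cache),
            n_simulation_products=n_sim_products,
            counters=counters,
        )


def random_search_baseline(
    mcts: MCTS, start: str, n_unique_evaluations: int, seed: int = 0,
    max_depth: int | None = None,
) -> GeneratedSet:
    """Random-walk baseline with an equal budget of unique reward evaluations.

    Repeatedly walks from the start molecule, choosing uniformly among the
    SMARTS-applicable templates (no GCN guidance, no tree statistics) and
    taking the greedy decode, until as many distinct molecules have been
    evaluated as the tree search used.
    """
    rng = np.random.default_rng(seed)
    max_depth = max_depth or mcts.config.max_depth
    generated = GeneratedSet()
    start = canonical_smiles(start)
    generated.add(start, mcts.reward(start), 0, SyntheticRoute(start, []))
    all_templates = TemplateRanking(
        tuple((i, 0.0) for i in sorted(mcts.template_patterns))
    )
    guard = 0
    while len(generated) < n_unique_evaluations and guard < 50 * n_unique_evaluations:
        smiles, route = start, SyntheticRoute(start, [])
        for _ in range(max_depth):
            guard += 1
            applicable = filter_matching_templates(smiles, all_templates, mcts.template_patterns)
            if len(applicable) == 0:
                break
            t_idx = int(rng.choice(applicable.indices()))
            src = TokenSequence(
                tuple([condition_token(t_idx)] + tokenize_smiles(smiles)), has_condition=True
            )
            beam = mcts.transformer.beam_decode(src, 1)
            prods = beam.smiles()
            if not prods or prods[0] == smiles:
                break
            smiles = prods[0]
            route = SyntheticRoute(route.start, route.steps + [(smiles, t_idx)])
            generated.add(smiles, mcts.reward(smiles), len(route), route)
            if len(generated) >= n_unique_evaluations:
                break
    return generated
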