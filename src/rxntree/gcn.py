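"""Reaction-template prediction with a graph convolutional network.

A molecule is the pair (A, F): per-bond-type adjacency indicators
A^(t) ∈ {0,1}^{n×n} for t ∈ {single, double, triple, aromatic} and a node
feature matrix F ∈ R^{n×d}.  The network stacks

* graph convolutions  X^(l+1) = σ(Σ_t Ã^(t) X^(l) W_t^(l)),
  with Ã^(t) = D_t^{-1}(A^(t) + I) (row-normalized with self-loops),
* bias-free per-node dense layers X W,
* sum aggregation over nodes (permutation-invariant), and
* output dense layers scoring every reaction template.

Ranked template proposals are post-filtered by the reactant-side SMARTS
match: a template whose pattern has no substructure hit on the molecule is
removed before any virtual reaction is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import mol_from_smiles
from .nn.autograd import Adam, Parameter, Tensor, cross_entropy

BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I")
_MAX_DEGREE = 5
FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 1 + 1 + 1


@dataclass(frozen=True)
class MoleculeGraph:
    """(A, F) tensors: per-bond-type adjacency and node features."""

    n: int
    A: np.ndarray  # (T, n, n) uint8, symmetric, zero diagonal
    F: np.ndarray  # (n, d) float64


def featurize(smiles: str) -> MoleculeGraph:
    """Heavy-atom graph with one-hot element/degree features plus charge,
    aromaticity and ring-membership flags."""
    mol = mol_from_smiles(smiles)
    n = mol.GetNumHeavyAtoms()
    A = np.zeros((len(BOND_TYPES), n, n), dtype=np.uint8)
    for bond in mol.GetBonds():
        try:
            t = BOND_TYPES.index(bond.GetBondType())
        except ValueError:
            t = 0  # treat exotic bond orders as single
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[t, i, j] = A[t, j, i] = 1
    F = np.zeros((n, FEATURE_DIM), dtype=np.float64)
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        F[i, _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
        deg = min(atom.GetDegree(), _MAX_DEGREE)
        F[i, len(_ELEMENTS) + 1 + deg] = 1.0
        base = len(_ELEMENTS) + 1 + _MAX_DEGREE + 1
        F[i, base] = float(atom.GetFormalCharge())
        F[i, base + 1] = float(atom.GetIsAromatic())
        F[i, base + 2] = float(atom.IsInRing())
    return MoleculeGraph(n=n, A=A, F=F)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Ã^(t) = D_t^{-1}(A^(t) + I) per bond type; accepts (T,n,n) or (B,T,n,n)."""
    A = np.asarray(A, dtype=np.float64)
    eye = np.eye(A.shape[-1])
    A_hat = A + eye
    deg = A_hat.sum(axis=-1, keepdims=True)
    return A_hat / deg


def graph_convolution(X: np.ndarray | Tensor, A_norm: np.ndarray, W_t: list[Tensor]) -> Tensor:
    """σ(Σ_t Ã^(t) X W_t) for one layer; ``A_norm`` is (T, n, n) (or batched)."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    acc = None
    for t, W in enumerate(W_t):
        term = Tensor(A_norm[..., t, :, :]) @ X @ W
        acc = term if acc is None else acc + term
    return acc.relu()


def sum_aggregate(X: np.ndarray | Tensor) -> Tensor:
    """Permutation-invariant node-axis sum: graph-level representation."""
    X = X if isinstance(X, Tensor) else Tensor(X)
    return X.sum(axis=-2)


@dataclass(frozen=True)
class TemplateRanking:
    """Templates ordered by non-increasing score (ties broken by index)."""

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")
        idx = [i for i, _ in self.entries]
        if len(set(idx)) != len(idx):
            raise ValueError("template indices must be distinct")

    def indices(self) -> list[int]:
        return [i for i, _ in self.entries]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GCNConfig:
    """Defaults follow the best USPTO-scale settings (dimension 256, one
    convolution layer, three dense layers, learning rate 4e-4); the toy
    preset shrinks the width for CPU training."""

    hidden_dim: int = 256
    n_conv_layers: int = 1
    n_dense_layers: int = 3
    learning_rate: float = 4e-4
    batch_size: int = 64
    epochs: int = 120
    patience: int = 25
    n_templates: int = 1000

    @classmethod
    def toy(cls, n_templates: int) -> "GCNConfig":
        return cls(hidden_dim=64, learning_rate=2e-3, epochs=80, n_templates=n_templates)


class TemplateGCN:
    """GCN classifier over reaction templates with SMARTS post-filtering."""

    def __init__(self, config: GCNConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config
        h = c.hidden_dim
        self.conv_weights: list[list[Parameter]] = []
        d_in = FEATURE_DIM
        for _ in range(c.n_conv_layers):
            self.conv_weights.append(
                [Parameter(rng.standard_normal((d_in, h)) * np.sqrt(1.0 / d_in)) for _ in BOND_TYPES]
            )
            d_in = h
        # per-node dense layers are bias-free so padded (all-zero) nodes stay
        # zero and do not pollute the sum aggregation
        self.node_dense = [
            Parameter(rng.standard_normal((h, h)) * np.sqrt(1.0 / h))
            for _ in range(max(c.n_dense_layers - 1, 0))
        ]
        self.out_w = Parameter(rng.standard_normal((h, c.n_templates)) * np.sqrt(1.0 / h))
        self.out_b = Parameter(np.zeros(c.n_templates))
        self._graph_cache: dict[str, MoleculeGraph] = {}

    def parameters(self) -> list[Parameter]:
        ps = [w for layer in self.conv_weights for w in layer]
        ps += self.node_dense + [self.out_w, self.out_b]
        return ps

    # -- batching ---------------------------------------------------------
    def _graph(self, smiles: str) -> MoleculeGraph:
        g = self._graph_cache.get(smiles)
        if g is None:
            g = featurize(smiles)
            self._graph_cache[smiles] = g
        return g

    def _batch(self, graphs: list[MoleculeGraph]) -> tuple[np.ndarray, np.ndarray]:
        n = max(g.n for g in graphs)
        A = np.zeros((len(graphs), len(BOND_TYPES), n, n))
        F = np.zeros((len(graphs), n, FEATURE_DIM))
        for i, g in enumerate(graphs):
            A[i, :, : g.n, : g.n] = g.A
            F[i, : g.n] = g.F
        return normalize_adjacency(A), F

    def _forward(self, A_norm: np.ndarray, F: np.ndarray) -> Tensor:
        x: Tensor = Tensor(F)
        for layer in self.conv_weights:
            x = graph_convolution(x, A_norm, layer)
        for W in self.node_dense:
            x = (x @ W).relu()
        g = sum_aggregate(x)
        return g @ self.out_w + self.out_b

    def logits(self, smiles_list: list[str]) -> np.ndarray:
        A_norm, F = self._batch([self._graph(s) for s in smiles_list])
        return self._forward(A_norm, F).data

    # -- training ---------------------------------------------------------
    def fit(self, train_records, val_records=None, verbose: bool = False) -> dict:
        """Cross-entropy training on (reactant, template) records.

        Early-stops on validation top-1; returns per-epoch curves plus a
        final top-1/5/10 report on the validation split.
        """
        labels = sorted({r.template_index for r in train_records})
        if len(labels) < 2:
            raise ValueError("need at least two template classes")
        cfg = self.config
        rng = np.random.default_rng(self.seed + 1)
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        xs = [r.reactant for r in train_records]
        ys = np.array([r.template_index for r in train_records])
        history = {"epoch": [], "train_loss": [], "val_top1": []}
        best, best_epoch, best_state = -1.0, 0, None
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(xs))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                A_norm, F = self._batch([self._graph(xs[i]) for i in idx])
                logits = self._forward(A_norm, F)
                loss, _ = cross_entropy(logits, ys[idx], ignore_id=-1)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.data.item())
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(losses)))
            if val_records:
                top1 = self.top_k_accuracy(val_records, (1,))[1]
                history["val_top1"].append(top1)
                if top1 > best:
                    best, best_epoch = top1, epoch
                    best_state = [p.data.copy() for p in self.parameters()]
                if epoch - best_epoch >= cfg.patience:
                    break
        if best_state is not None:
            for p, w in zip(self.parameters(), best_state):
                p.data[...] = w
        report_split = val_records if val_records else train_records
        history["report"] = self.top_k_accuracy(report_split, (1, 5, 10))
        return history

    def top_k_accuracy(self, records, ks=(1, 5, 10)) -> dict[int, float]:
        hits = {k: 0 for k in ks}
        for start in range(0, len(records), self.config.batch_size):
            chunk = records[start : start + self.config.batch_size]
            logits = self.logits([r.reactant for r in chunk])
            # stable argsort on -score ties break toward the lower index
            order = np.argsort(-logits, axis=-1, kind="stable")
            for row, r in zip(order, chunk):
                for k in ks:
                    if r.template_index in row[:k]:
                        hits[k] += 1
        return {k: hits[k] / len(records) for k in ks}

    # -- inference --------------------------------------------------------
    def predict_templates(self, smiles: str, k: int) -> TemplateRanking:
        """Top-k templates by softmax score; deterministic index tie-break."""
        logits = self.logits([smiles])[0]
        z = logits - logits.max()
        probs = np.exp(z) / np.exp(z).sum()
        order = np.argsort(-probs, kind="stable")[:k]
        return TemplateRanking(tuple((int(i), float(probs[i])) for i in order))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(self.parameters())})
        (path / "model.json").write_text(json.dumps({"config": asdict(self.config), "seed": self.seed}))

    @classmethod
    def load(cls, path: str | Path) -> "TemplateGCN":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        model = cls(GCNConfig(**meta["config"]), seed=meta["seed"])
        arrays = np.load(path / "weights.npz")
        for i, p in enumerate(model.parameters()):
            p.data[...] = arrays[f"p{i}"]
        return model


def filter_matching_templates(
    smiles: str, ranking: TemplateRanking, template_patterns: dict[int, str]
) -> TemplateRanking:
    """Keep only ranked templates whose reactant-side SMARTS hits the molecule."""
    mol = mol_from_smiles(smiles)
    kept = []
    for idx, score in ranking:
        patt_s = template_patterns.get(idx)
        if patt_s is None:
            raise KeyError(f"template {idx} has no reactant-side SMARTS pattern")
        patt = Chem.MolFromSmarts(patt_s)
        if patt is None:
            raise ValueError(f"invalid SMARTS for template {idx}: {patt_s!r}")
        if mol.HasSubstructMatch(patt):
            kept.append((idx, score))
    return TemplateRanking(tuple(kept))
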