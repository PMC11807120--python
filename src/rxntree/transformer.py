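"""Conditional forward-synthesis sequence model.

An encoder-decoder transformer (multi-head attention, sinusoidal positions,
post-layer-norm, ReLU feed-forward) mapping a reactant token sequence to a
product token sequence.  The conditional variant receives the reaction
template as a single ``<t_i>`` prefix token on the encoder side only; the
unconditional twin sees the bare reactant and must marginalize over the
reactions the training corpus admits.

Accuracy metrics:

* partial accuracy — per-token argmax agreement under teacher forcing;
* perfect accuracy — per-molecule agreement of the canonicalized greedy
  decode with the canonical target;
* top-n accuracy — canonical target found among the top-n beam products.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chem import canonical_smiles, is_valid_smiles
from .nn.autograd import (
    Adam,
    Parameter,
    Tensor,
    cross_entropy,
    dropout,
    embedding,
    layer_norm,
)
from .tokenizer import TokenSequence, Vocabulary, condition_token, tokenize_smiles

logger = logging.getLogger(__name__)

NEG_INF = -1e9


@dataclass
class TransformerConfig:
    """Architecture and training knobs.

    Defaults are the desk-scale configuration that converges on the synthetic
    grammar; :meth:`full_scale` carries the original-architecture values used
    for USPTO-scale training (dimension 512, 6+6 layers, FFN 2048, 8 heads,
    dropout 0.1, batch 128).
    """

    d_model: int = 64
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    d_ff: int = 128
    n_heads: int = 4
    dropout: float = 0.1
    batch_size: int = 64
    activation: str = "relu"
    learning_rate: float = 1e-3
    lr_decay_every: int = 80  # halve the learning rate every this many epochs
    epochs: int = 400
    patience: int = 80

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("head count must divide model dimension")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")

    @classmethod
    def full_scale(cls) -> "TransformerConfig":
        return cls(
            d_model=512,
            n_encoder_layers=6,
            n_decoder_layers=6,
            d_ff=2048,
            n_heads=8,
            dropout=0.1,
            batch_size=128,
        )


@dataclass(frozen=True)
class BeamResult:
    """Ranked, validated, canonicalized, deduplicated beam-search products."""

    products: tuple[tuple[str, float], ...]  # (canonical SMILES, score), scores non-increasing
    beam_width: int
    n_invalid: int = 0
    n_duplicate: int = 0

    def smiles(self) -> list[str]:
        return [p for p, _ in self.products]


def _sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


class _MultiHeadAttention:
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.h = n_heads
        self.dk = d_model // n_heads
        s = np.sqrt(1.0 / d_model)
        self.wq, self.wk, self.wv, self.wo = (
            Parameter(rng.standard_normal((d_model, d_model)) * s) for _ in range(4)
        )

    def params(self):
        return [self.wq, self.wk, self.wv, self.wo]

    def __call__(self, q: Tensor, kv: Tensor, mask: np.ndarray) -> Tensor:
        B, Lq, D = q.shape
        Lk = kv.shape[1]

        def split(x: Tensor, L: int) -> Tensor:
            return x.reshape(B, L, self.h, self.dk).transpose(0, 2, 1, 3)

        Q, K, V = split(q @ self.wq, Lq), split(kv @ self.wk, Lk), split(kv @ self.wv, Lk)
        scores = (Q @ K.transpose(0, 1, 3, 2)) * Tensor(1.0 / np.sqrt(self.dk))
        scores = scores + Tensor(mask)  # additive mask: 0 allowed, NEG_INF blocked
        attn = scores.softmax()
        out = (attn @ V).transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return out @ self.wo


class _FeedForward:
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.w1 = Parameter(rng.standard_normal((d_model, d_ff)) * np.sqrt(1.0 / d_model))
        self.b1 = Parameter(np.zeros(d_ff))
        self.w2 = Parameter(rng.standard_normal((d_ff, d_model)) * np.sqrt(1.0 / d_ff))
        self.b2 = Parameter(np.zeros(d_model))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return ((x @ self.w1) + self.b1).relu() @ self.w2 + self.b2


class _AddNorm:
    def __init__(self, d_model: int):
        self.gamma = Parameter(np.ones(d_model))
        self.beta = Parameter(np.zeros(d_model))

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, sub: Tensor) -> Tensor:
        return layer_norm(x + sub, self.gamma, self.beta)


class Seq2SeqTransformer:
    """Encoder-decoder over SMILES tokens with optional template conditioning."""

    def __init__(
        self,
        vocab: Vocabulary,
        config: TransformerConfig | None = None,
        conditioned: bool = True,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.config = config or TransformerConfig()
        self.conditioned = conditioned
        self.seed = seed
        self.max_target_len = 48  # updated from the data at fit() time
        rng = np.random.default_rng(seed)
        c = self.config
        self.embed = Parameter(rng.standard_normal((len(vocab), c.d_model)) * 0.02)
        self.enc_attn = [_MultiHeadAttention(c.d_model, c.n_heads, rng) for _ in range(c.n_encoder_layers)]
        self.enc_ffn = [_FeedForward(c.d_model, c.d_ff, rng) for _ in range(c.n_encoder_layers)]
        self.enc_norm = [[_AddNorm(c.d_model) for _ in range(2)] for _ in range(c.n_encoder_layers)]
        self.dec_self = [_MultiHeadAttention(c.d_model, c.n_heads, rng) for _ in range(c.n_decoder_layers)]
        self.dec_cross = [_MultiHeadAttention(c.d_model, c.n_heads, rng) for _ in range(c.n_decoder_layers)]
        self.dec_ffn = [_FeedForward(c.d_model, c.d_ff, rng) for _ in range(c.n_decoder_layers)]
        self.dec_norm = [[_AddNorm(c.d_model) for _ in range(3)] for _ in range(c.n_decoder_layers)]
        self.out_proj = Parameter(rng.standard_normal((c.d_model, len(vocab))) * np.sqrt(1.0 / c.d_model))
        self.out_bias = Parameter(np.zeros(len(vocab)))
        self._pe = _sinusoidal_positions(512, c.d_model)
        self._drop_rng = np.random.default_rng(seed + 1)
        self._training = False
        self._beam_cache: dict[tuple, BeamResult] = {}

    # -- parameters -------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps = [self.embed, self.out_proj, self.out_bias]
        for i in range(self.config.n_encoder_layers):
            ps += self.enc_attn[i].params() + self.enc_ffn[i].params()
            for n in self.enc_norm[i]:
                ps += n.params()
        for i in range(self.config.n_decoder_layers):
            ps += self.dec_self[i].params() + self.dec_cross[i].params() + self.dec_ffn[i].params()
            for n in self.dec_norm[i]:
                ps += n.params()
        return ps

    # -- encoding of token sequences --------------------------------------
    def source_ids(self, source: TokenSequence) -> list[int]:
        return self.vocab.encode(source.tokens) + [self.vocab.eos_id]

    def target_ids(self, target: TokenSequence) -> list[int]:
        return [self.vocab.bos_id] + self.vocab.encode(target.tokens) + [self.vocab.eos_id]

    def _pad(self, seqs: list[list[int]]) -> np.ndarray:
        L = max(len(s) for s in seqs)
        out = np.full((len(seqs), L), self.vocab.pad_id, dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out

    # -- forward ----------------------------------------------------------
    def _embed(self, ids: np.ndarray) -> Tensor:
        x = embedding(self.embed, ids) * Tensor(np.sqrt(self.config.d_model))
        x = x + Tensor(self._pe[None, : ids.shape[1], :])
        return dropout(x, self.config.dropout, self._drop_rng, self._training)

    def encode(self, src: np.ndarray) -> tuple[Tensor, np.ndarray]:
        pad_mask = np.where(src == self.vocab.pad_id, NEG_INF, 0.0)[:, None, None, :]
        x = self._embed(src)
        for i in range(self.config.n_encoder_layers):
            x = self.enc_norm[i][0](x, self._sub(self.enc_attn[i](x, x, pad_mask)))
            x = self.enc_norm[i][1](x, self._sub(self.enc_ffn[i](x)))
        return x, pad_mask

    def _sub(self, x: Tensor) -> Tensor:
        return dropout(x, self.config.dropout, self._drop_rng, self._training)

    def decode(self, memory: Tensor, mem_mask: np.ndarray, tgt_in: np.ndarray) -> Tensor:
        Lt = tgt_in.shape[1]
        causal = np.triu(np.full((Lt, Lt), NEG_INF), k=1)[None, None, :, :]
        tgt_pad = np.where(tgt_in == self.vocab.pad_id, NEG_INF, 0.0)[:, None, None, :]
        self_mask = causal + tgt_pad
        x = self._embed(tgt_in)
        for i in range(self.config.n_decoder_layers):
            x = self.dec_norm[i][0](x, self._sub(self.dec_self[i](x, x, self_mask)))
            x = self.dec_norm[i][1](x, self._sub(self.dec_cross[i](x, memory, mem_mask)))
            x = self.dec_norm[i][2](x, self._sub(self.dec_ffn[i](x)))
        return x @ self.out_proj + self.out_bias  # (B, Lt, V)

    def logits(self, src: np.ndarray, tgt_in: np.ndarray) -> Tensor:
        memory, mem_mask = self.encode(src)
        return self.decode(memory, mem_mask, tgt_in)

    # -- training ---------------------------------------------------------
    def fit(
        self,
        train_pairs: list[tuple[TokenSequence, TokenSequence]],
        val_pairs: list[tuple[TokenSequence, TokenSequence]] | None = None,
        target_perfect: float | None = None,
        val_every: int = 1,
        verbose: bool = False,
    ) -> dict:
        """Train with Adam and per-epoch accuracy curves.

        Stops early when validation perfect accuracy has not improved for
        ``config.patience`` epochs, or once it reaches ``target_perfect``;
        the weights of the best validation epoch are restored at the end.
        """
        if not train_pairs:
            raise ValueError("no training pairs")
        for src, tgt in train_pairs:
            for t in src.tokens + tgt.tokens:
                if t not in self.vocab:
                    raise KeyError(f"token {t!r} outside vocabulary")
        self.max_target_len = max(len(t) for _, t in train_pairs)
        cfg = self.config
        opt = Adam(self.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(self.seed + 2)
        history = {"epoch": [], "train_loss": [], "partial_accuracy": [], "perfect_accuracy": []}
        best = -1.0
        best_epoch = 0
        src_ids = [self.source_ids(s) for s, _ in train_pairs]
        tgt_ids = [self.target_ids(t) for _, t in train_pairs]
        for epoch in range(cfg.epochs):
            self._training = True
            opt.lr = cfg.learning_rate * 0.5 ** (epoch // cfg.lr_decay_every)
            order = rng.permutation(len(train_pairs))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                src = self._pad([src_ids[i] for i in idx])
                tgt = self._pad([tgt_ids[i] for i in idx])
                logits = self.logits(src, tgt[:, :-1])
                flat = logits.reshape(-1, len(self.vocab))
                loss, _ = cross_entropy(flat, tgt[:, 1:].reshape(-1), self.vocab.pad_id)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.data.item())
            self._training = False
            history["epoch"].append(epoch)
            history["train_loss"].append(float(np.mean(losses)))
            if val_pairs and (epoch % val_every == 0 or epoch == cfg.epochs - 1):
                pa = self.partial_accuracy(val_pairs)
                pf = self.perfect_accuracy(val_pairs)
                history["partial_accuracy"].append(pa)
                history["perfect_accuracy"].append(pf)
                if verbose and epoch % 10 == 0:
                    logger.info("epoch %d loss %.4f partial %.3f perfect %.3f",
                                epoch, history["train_loss"][-1], pa, pf)
                if pf > best:
                    best, best_epoch = pf, epoch
                    best_state = [p.data.copy() for p in self.parameters()]
                if target_perfect is not None and pf >= target_perfect:
                    break
                if epoch - best_epoch >= cfg.patience:
                    break
        if val_pairs and best >= 0:
            for p, w in zip(self.parameters(), best_state):
                p.data[...] = w
            self._beam_cache.clear()
        return history

    # -- metrics ----------------------------------------------------------
    def partial_accuracy(self, pairs) -> float:
        """Token-level teacher-forced argmax accuracy over non-pad positions."""
        if not pairs:
            raise ValueError("empty pair list")
        correct = total = 0
        for start in range(0, len(pairs), self.config.batch_size):
            chunk = pairs[start : start + self.config.batch_size]
            src = self._pad([self.source_ids(s) for s, _ in chunk])
            tgt = self._pad([self.target_ids(t) for _, t in chunk])
            logits = self.logits(src, tgt[:, :-1]).data
            pred = logits.argmax(axis=-1)
            gold = tgt[:, 1:]
            keep = gold != self.vocab.pad_id
            correct += int((pred[keep] == gold[keep]).sum())
            total += int(keep.sum())
        return correct / total

    def perfect_accuracy(self, pairs) -> float:
        """Molecule-level accuracy: canonical greedy decode == canonical target."""
        if not pairs:
            raise ValueError("empty pair list")
        decoded = self.greedy_decode_batch([s for s, _ in pairs])
        n_ok = 0
        for (src, tgt), hyp in zip(pairs, decoded):
            try:
                want = canonical_smiles(tgt.smiles)
            except ValueError:
                continue
            if hyp is not None and hyp == want:
                n_ok += 1
        return n_ok / len(pairs)

    def top_n_accuracy(self, pairs, n: int, width: int) -> float:
        """Fraction of pairs whose canonical target is in the top-n beam products."""
        if n > width:
            raise ValueError("n must not exceed beam width")
        n_ok = 0
        for src, tgt in pairs:
            want = canonical_smiles(tgt.smiles)
            beam = self.beam_decode(src, width)
            if want in beam.smiles()[:n]:
                n_ok += 1
        return n_ok / len(pairs)

    # -- decoding ---------------------------------------------------------
    def _max_decode_len(self) -> int:
        return int(1.5 * self.max_target_len) + 8

    def greedy_decode_batch(self, sources: list[TokenSequence]) -> list[str | None]:
        """Greedy decode many sources at once; None for invalid products."""
        src = self._pad([self.source_ids(s) for s in sources])
        memory, mem_mask = self.encode(src)
        B = len(sources)
        ys = np.full((B, 1), self.vocab.bos_id, dtype=np.int64)
        finished = np.zeros(B, dtype=bool)
        for _ in range(self._max_decode_len()):
            logits = self.decode(memory, mem_mask, ys).data[:, -1, :]
            nxt = logits.argmax(axis=-1)
            nxt[finished] = self.vocab.pad_id
            ys = np.concatenate([ys, nxt[:, None]], axis=1)
            finished |= nxt == self.vocab.eos_id
            if finished.all():
                break
        out = []
        for row in ys:
            toks = []
            for t in row[1:]:
                if t in (self.vocab.eos_id, self.vocab.pad_id):
                    break
                toks.append(self.vocab.symbols[t])
            smi = "".join(toks)
            out.append(canonical_smiles(smi) if is_valid_smiles(smi) else None)
        return out

    def greedy_decode(self, source: TokenSequence) -> str | None:
        return self.greedy_decode_batch([source])[0]

    def beam_decode(self, source: TokenSequence, width: int) -> BeamResult:
        """Beam search with length-normalized log-probability scoring.

        Results are validity-filtered, canonicalized and deduplicated (the
        best-scoring spelling of each molecule is kept); drop counts are
        recorded on the result.  Deterministic for a fixed checkpoint.
        """
        if width < 1:
            raise ValueError("beam width must be >= 1")
        key = (tuple(source.tokens), width)
        cached = self._beam_cache.get(key)
        if cached is not None:
            return cached
        src = self._pad([self.source_ids(source)])
        memory, mem_mask = self.encode(src)
        mem_data = memory.data
        beams = [([self.vocab.bos_id], 0.0, False)]  # (ids, sum logp, finished)
        for _ in range(self._max_decode_len()):
            if all(f for _, _, f in beams):
                break
            live = [b for b in beams if not b[2]]
            done = [b for b in beams if b[2]]
            ys = np.array([b[0] for b in live], dtype=np.int64)
            mem = Tensor(np.repeat(mem_data, len(live), axis=0))
            mask = np.repeat(mem_mask, len(live), axis=0)
            logits = self.decode(mem, mask, ys).data[:, -1, :]
            z = logits - logits.max(axis=-1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
            cand = list(done)
            for bi, (ids, score, _) in enumerate(live):
                top = np.argsort(-logp[bi], kind="stable")[:width]
                for t in top:
                    cand.append((ids + [int(t)], score + float(logp[bi, t]), int(t) == self.vocab.eos_id))
            # rank by length-normalized score; stable sort keeps tie order deterministic
            cand.sort(key=lambda b: -b[1] / max(len(b[0]) - 1, 1))
            beams = cand[:width]
        ranked = sorted(beams, key=lambda b: -b[1] / max(len(b[0]) - 1, 1))
        products: dict[str, float] = {}
        n_invalid = n_duplicate = 0
        for ids, score, _ in ranked:
            toks = [self.vocab.symbols[t] for t in ids[1:] if t != self.vocab.eos_id]
            smi = "".join(toks)
            norm = score / max(len(ids) - 1, 1)
            if not is_valid_smiles(smi):
                n_invalid += 1
                continue
            can = canonical_smiles(smi)
            if can in products:
                n_duplicate += 1
                continue
            products[can] = norm
        result = BeamResult(
            products=tuple(sorted(products.items(), key=lambda kv: -kv[1])),
            beam_width=width,
            n_invalid=n_invalid,
            n_duplicate=n_duplicate,
        )
        self._beam_cache[key] = result
        return result

    # -- single-step enumeration ------------------------------------------
    def enumerate_products(
        self,
        smiles: str,
        template_ranking,
        width: int,
        per_template_cap: int | None = None,
        single_product: set[int] | None = None,
    ) -> list[tuple[str, int, int]]:
        """One virtual reaction per ranked template; the single-step move set.

        Returns (canonical product, template index, beam rank) triples,
        deduplicated across templates keeping the best (lowest) beam rank.
        Templates flagged ``single_product`` contribute only their rank-1
        product regardless of width.
        """
        single_product = single_product or set()
        src_tokens = tokenize_smiles(canonical_smiles(smiles))
        out: dict[str, tuple[str, int, int]] = {}
        for t_idx, _score in template_ranking:
            source = TokenSequence(tuple([condition_token(t_idx)] + src_tokens), has_condition=True)
            beam = self.beam_decode(source, width)
            hits = beam.smiles()
            if t_idx in single_product:
                hits = hits[:1]
            elif per_template_cap is not None:
                hits = hits[:per_template_cap]
            for rank, prod in enumerate(hits):
                prev = out.get(prod)
                if prev is None or rank < prev[2]:
                    out[prod] = (prod, t_idx, rank)
        return list(out.values())

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path / "weights.npz", **arrays)
        meta = {
            "config": asdict(self.config),
            "conditioned": self.conditioned,
            "seed": self.seed,
            "max_target_len": self.max_target_len,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=1))
        self.vocab.save(path / "vocab.json")

    @classmethod
    def load(cls, path: str | Path) -> "Seq2SeqTransformer":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        vocab = Vocabulary.load(path / "vocab.json")
        model = cls(
            vocab,
            TransformerConfig(**meta["config"]),
            conditioned=meta["conditioned"],
            seed=meta["seed"],
        )
        model.max_target_len = meta["max_target_len"]
        arrays = np.load(path / "weights.npz")
        for i, p in enumerate(model.parameters()):
            p.data[...] = arrays[f"p{i}"]
        return model
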