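"""SMILES tokenization and the sequence vocabulary.

Tokenization follows the segmentation convention of forward-synthesis
sequence models: bracket atoms, two-letter halogens and ``%nn`` ring
closures are single tokens, so detokenization is the exact inverse
(``"".join(tokens) == smiles``).

A reaction-template condition is a single prefix symbol ``<t_i>`` prepended
to the encoder-side token sequence.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#\-\+\(\)/\\\.@:~\*\$])"
)

_CONDITION_RE = re.compile(r"^<t_(\d+)>$")


class TokenizationError(ValueError):
    """Raised when a string cannot be segmented into SMILES tokens."""


def condition_token(template_index: int) -> str:
    return f"<t_{template_index}>"


def is_condition_token(token: str) -> bool:
    return _CONDITION_RE.match(token) is not None


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; joining the tokens restores it."""
    tokens = []
    pos = 0
    while pos < len(smiles):
        m = _SMILES_TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"cannot tokenize SMILES at position {pos}: {smiles[pos:pos + 10]!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def detokenize(tokens: list[str]) -> str:
    """Inverse of :func:`tokenize_smiles`; drops a leading condition token."""
    if tokens and is_condition_token(tokens[0]):
        tokens = tokens[1:]
    return "".join(tokens)


@dataclass(frozen=True)
class TokenSequence:
    tokens: tuple[str, ...]
    has_condition: bool = False

    def __post_init__(self) -> None:
        if self.has_condition:
            if not self.tokens or not is_condition_token(self.tokens[0]):
                raise ValueError("conditioned sequence must start with a <t_i> token")

    @property
    def smiles(self) -> str:
        return detokenize(list(self.tokens))

    def __len__(self) -> int:
        return len(self.tokens)


PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
RESERVED = (PAD, BOS, EOS, UNK)


@dataclass
class Vocabulary:
    """Bijective symbol <-> id map with reserved ids and condition symbols."""

    symbols: list[str] = field(default_factory=list)
    _ids: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.symbols:
            self.symbols = list(RESERVED)
        self._ids = {s: i for i, s in enumerate(self.symbols)}
        if len(self._ids) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")

    @classmethod
    def build(cls, token_lists, n_templates: int = 0) -> "Vocabulary":
        """Vocabulary over a token corpus plus ``<t_0>..<t_{n-1}>`` condition symbols."""
        seen: dict[str, None] = {}
        for toks in token_lists:
            for t in toks:
                seen.setdefault(t, None)
        symbols = list(RESERVED)
        symbols.extend(condition_token(i) for i in range(n_templates))
        symbols.extend(s for s in sorted(seen) if s not in symbols)
        return cls(symbols=symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._ids

    @property
    def pad_id(self) -> int:
        return self._ids[PAD]

    @property
    def bos_id(self) -> int:
        return self._ids[BOS]

    @property
    def eos_id(self) -> int:
        return self._ids[EOS]

    def encode(self, tokens) -> list[int]:
        try:
            return [self._ids[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    def decode(self, ids) -> list[str]:
        return [self.symbols[i] for i in ids]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"symbols": self.symbols}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls(symbols=json.loads(Path(path).read_text())["symbols"])
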