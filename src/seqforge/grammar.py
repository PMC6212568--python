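"""Context-free grammar of protein fold topology (Taylor forms).

A fold is written as an ordered list of secondary-structure elements,
each an orientation sign (+/-), a layer letter (A-D) and a signed
position token within the layer (+0..+6, -1..-6). The grammar G = (N,
Sigma, P, S) has five nonterminals and 22 productions: 2 topology rules
(recurse / terminate), 1 element rule, 2 orientation rules, 4 layer
rules and 13 position rules. A canonical leftmost derivation of a
k-element topology therefore applies exactly 5k rules, and with at most
11 elements fits in 55 rule slots. Rule sequences are one-hot encoded
with 23 slots per rule (22 productions plus a blank padding rule),
giving a flat conditioning vector of 55 x 23 = 1265 entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# ---------------------------------------------------------------------------
# Grammar definition

LAYERS = "ABCD"
POSITION_TOKENS = (
    "+0", "+1", "+2", "+3", "+4", "+5", "+6",
    "-1", "-2", "-3", "-4", "-5", "-6",
)

#: Production rules in their canonical, frozen order. Index = rule id.
#: (lhs, rhs) with nonterminals in angle brackets.
PRODUCTIONS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("<topology>", ("<element>", "<topology>")),          # 0: recurse
    ("<topology>", ("<element>",)),                        # 1: terminate
    ("<element>", ("<orientation>", "<layer>", "<position>")),  # 2
    ("<orientation>", ("+",)),                             # 3
    ("<orientation>", ("-",)),                             # 4
    ("<layer>", ("A",)),                                   # 5
    ("<layer>", ("B",)),                                   # 6
    ("<layer>", ("C",)),                                   # 7
    ("<layer>", ("D",)),                                   # 8
) + tuple(("<position>", (tok,)) for tok in POSITION_TOKENS)  # 9..21

N_RULES = len(PRODUCTIONS)           # 22
PAD_RULE = N_RULES                   # index of the blank padding rule
RULE_SLOT = N_RULES + 1              # 23 one-hot options per rule
MAX_RULES = 55                       # up to 11 elements x 5 rules
MAX_ELEMENTS = MAX_RULES // 5        # 11
ENCODING_LENGTH = MAX_RULES * RULE_SLOT  # 1265

START_SYMBOL = "<topology>"
NONTERMINALS = frozenset(
    {"<topology>", "<element>", "<orientation>", "<layer>", "<position>"}
)

_ORIENT_RULE = {"+": 3, "-": 4}
_LAYER_RULE = {layer: 5 + i for i, layer in enumerate(LAYERS)}
_POSITION_RULE = {tok: 9 + i for i, tok in enumerate(POSITION_TOKENS)}

# Typographic minus variants accepted on input; ASCII emitted on output.
_MINUS_VARIANTS = "−–—"


class TopologyParseError(ValueError):
    """Raised when a topology string cannot be parsed; carries the
    0-based character position where parsing failed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class TopologyElement:
    """One secondary-structure element: orientation, layer, position."""

    orientation: str  # '+' or '-'
    layer: str        # 'A'..'D'
    position: str     # one of the 13 position tokens

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"bad layer {self.layer!r}")
        if self.position not in POSITION_TOKENS:
            raise ValueError(f"bad position token {self.position!r}")

    def __str__(self) -> str:
        return f"{self.orientation}{self.layer}{self.position}"


@dataclass(frozen=True)
class TopologyString:
    """An ordered, non-empty tuple of topology elements."""

    elements: tuple[TopologyElement, ...]

    def __post_init__(self) -> None:
        if len(self.elements) == 0:
            raise ValueError("a topology must contain at least one element")

    def __len__(self) -> int:
        return len(self.elements)

    def __str__(self) -> str:
        return unparse_topology(self)


def _normalize(s: str) -> str:
    for ch in _MINUS_VARIANTS:
        s = s.replace(ch, "-")
    return "".join(s.split())


def parse_topology(s: str) -> TopologyString:
    """Parse a topology string such as ``"-C+0+B+0-B-1+C-1-B-2"``.

    Whitespace is ignored and typographic minus signs are accepted.
    Raises :class:`TopologyParseError` (with the failing position in the
    normalized string) on unknown layers, out-of-range positions, the
    forbidden token ``-0``, or trailing partial elements.
    """
    text = _normalize(s)
    if not text:
        raise TopologyParseError("empty topology string", 0)
    elements: list[TopologyElement] = []
    i = 0
    n = len(text)
    while i < n:
        if text[i] not in "+-":
            raise TopologyParseError(f"expected orientation sign, got {text[i]!r}", i)
        orientation = text[i]
        if i + 1 >= n:
            raise TopologyParseError("truncated element: missing layer", i + 1)
        layer = text[i + 1]
        if layer not in LAYERS:
            raise TopologyParseError(f"unknown layer letter {layer!r}", i + 1)
        if i + 3 >= n:
            raise TopologyParseError("truncated element: missing position", i + 2)
        pos = text[i + 2 : i + 4]
        if pos == "-0":
            raise TopologyParseError("position token '-0' is not in the grammar", i + 2)
        if pos not in _POSITION_RULE:
            raise TopologyParseError(f"invalid position token {pos!r}", i + 2)
        elements.append(TopologyElement(orientation, layer, pos))
        i += 4
    return TopologyString(tuple(elements))


def unparse_topology(t: TopologyString) -> str:
    """Canonical string form: elements concatenated, ASCII signs, no spaces."""
    return "".join(
        f"{e.orientation}{e.layer}{e.position}" for e in t.elements
    )


def derive_rules(t: TopologyString) -> list[int]:
    """Canonical leftmost derivation of a topology as rule indices.

    For each element before the last the recursive topology rule is
    applied, for the last the terminating rule; each element then
    contributes its element, orientation, layer and position rules in
    that order — five rules per element.
    """
    k = len(t.elements)
    if k > MAX_ELEMENTS:
        raise ValueError(
            f"topology with {k} elements needs {5 * k} rules, "
            f"exceeding the {MAX_RULES}-rule capacity"
        )
    rules: list[int] = []
    for i, e in enumerate(t.elements):
        rules.append(0 if i < k - 1 else 1)
        rules.append(2)
        rules.append(_ORIENT_RULE[e.orientation])
        rules.append(_LAYER_RULE[e.layer])
        rules.append(_POSITION_RULE[e.position])
    return rules


def replay_rules(rules: list[int]) -> TopologyString:
    """Replay a rule sequence as a leftmost derivation from the start symbol.

    Raises ``ValueError`` if the sequence is not a complete, valid
    leftmost derivation (wrong rule for the leftmost nonterminal, leftover
    rules, or unexpanded nonterminals).
    """
    sentential: list[str] = [START_SYMBOL]
    for step, r in enumerate(rules):
        if not 0 <= r < N_RULES:
            raise ValueError(f"rule index {r} out of range at step {step}")
        # leftmost nonterminal
        for j, sym in enumerate(sentential):
            if sym in NONTERMINALS:
                break
        else:
            raise ValueError(f"no nonterminal left to expand at step {step}")
        lhs, rhs = PRODUCTIONS[r]
        if sentential[j] != lhs:
            raise ValueError(
                f"rule {r} expands {lhs} but leftmost nonterminal is "
                f"{sentential[j]} at step {step}"
            )
        sentential[j : j + 1] = list(rhs)
    leftover = [sym for sym in sentential if sym in NONTERMINALS]
    if leftover:
        raise ValueError(f"incomplete derivation: {leftover} unexpanded")
    return parse_topology("".join(sentential))


def encode_rules(rules: list[int]) -> np.ndarray:
    """One-hot encode a rule sequence into the flat 1265-entry vector.

    The first ``len(rules)`` 23-wide blocks one-hot the rule indices;
    the remaining blocks one-hot the blank padding rule.
    """
    if len(rules) > MAX_RULES:
        raise ValueError(f"rule sequence of {len(rules)} exceeds {MAX_RULES}")
    out = np.zeros((MAX_RULES, RULE_SLOT), dtype=np.float64)
    for i, r in enumerate(rules):
        if not 0 <= r < N_RULES:
            raise ValueError(f"rule index {r} out of [0, {N_RULES - 1}]")
        out[i, r] = 1.0
    out[len(rules):, PAD_RULE] = 1.0
    return out.ravel()


def decode_rules(encoding: np.ndarray) -> list[int]:
    """Invert :func:`encode_rules` by per-block argmax.

    Reading stops at the first padding-rule block. The recovered sequence
    is validated by replaying it as a derivation.
    """
    arr = np.asarray(encoding, dtype=np.float64).ravel()
    if arr.size != ENCODING_LENGTH:
        raise ValueError(
            f"encoding length {arr.size} != expected {ENCODING_LENGTH}"
        )
    idx = np.argmax(arr.reshape(MAX_RULES, RULE_SLOT), axis=1)
    rules: list[int] = []
    for r in idx:
        if r == PAD_RULE:
            break
        rules.append(int(r))
    replay_rules(rules)  # raises if not a valid derivation
    return rules


def topology_encoding(t: TopologyString) -> np.ndarray:
    """Convenience: derivation + one-hot encoding of a topology."""
    return encode_rules(derive_rules(t))


def sample_topology(
    rng_seed: int,
    max_elements: int = MAX_ELEMENTS,
    min_elements: int = 1,
) -> TopologyString:
    """Draw a random topology by uniform random derivation, seeded.

    At each topology expansion the recursive and terminating rules are
    chosen uniformly, forcing termination at ``max_elements`` (and
    recursion below ``min_elements``); orientation, layer and position
    are drawn uniformly over their rules.
    """
    if not 1 <= min_elements <= max_elements <= MAX_ELEMENTS:
        raise ValueError(
            f"need 1 <= min_elements <= max_elements <= {MAX_ELEMENTS}"
        )
    rng = np.random.default_rng(rng_seed)
    elements: list[TopologyElement] = []
    while True:
        n = len(elements) + 1
        elements.append(
            TopologyElement(
                orientation="+-"[rng.integers(2)],
                layer=LAYERS[rng.integers(4)],
                position=POSITION_TOKENS[rng.integers(len(POSITION_TOKENS))],
            )
        )
        if n >= max_elements:
            break
        if n >= min_elements and rng.integers(2) == 1:
            break
    return TopologyString(tuple(elements))


def read_topology_file(path) -> list[TopologyString]:
    """Read topology strings from a plain-text file, one per line.

    Blank lines and lines starting with ``#`` are skipped.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(parse_topology(line))
    return out
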