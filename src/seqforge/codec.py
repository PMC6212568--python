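"""One-hot sequence codec.

Protein sequences are represented as flattened one-hot tensors over a
22-symbol alphabet: the 20 standard amino acids, a wildcard for any
non-standard residue (e.g. selenocysteine), and a padding symbol used to
right-pad every sequence to the model's maximum length. At the default
maximum length of 140 residues the flattened tensor has 140 x 22 = 3080
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 standard amino acids in alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Default maximum sequence length (residues).
DEFAULT_MAX_LENGTH = 140


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet: 20 standard amino acids, wildcard, padding.

    The ordering is frozen (alphabetical amino acids, then the wildcard,
    then the padding symbol) so that encodings are reproducible across
    runs and checkpoints.
    """

    symbols: str = STANDARD_AA + "X-"

    def __post_init__(self) -> None:
        if len(self.symbols) != 22:
            raise ValueError(
                f"alphabet must have exactly 22 symbols, got {len(self.symbols)}"
            )
        if len(set(self.symbols)) != 22:
            raise ValueError("alphabet symbols must be distinct")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def wildcard_index(self) -> int:
        return len(self.symbols) - 2

    @property
    def pad_index(self) -> int:
        return len(self.symbols) - 1

    @property
    def wildcard(self) -> str:
        return self.symbols[self.wildcard_index]

    @property
    def pad(self) -> str:
        return self.symbols[self.pad_index]

    def index_of(self, residue: str) -> int:
        """Index of ``residue``; unknown characters map to the wildcard."""
        i = self.symbols.find(residue.upper())
        return i if i >= 0 else self.wildcard_index


#: Module-level default alphabet instance.
DEFAULT_ALPHABET = Alphabet()


def encode_sequence(
    seq: str,
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> np.ndarray:
    """Encode an amino-acid string as a flat one-hot vector.

    Positions beyond ``len(seq)`` are one-hot encodings of the padding
    symbol, so the vector always sums to ``max_length``. Characters
    outside the standard 20 map to the wildcard symbol.

    Parameters
    ----------
    seq:
        Amino-acid string of length <= ``max_length``.
    alphabet:
        Symbol ordering; defaults to the canonical 22-symbol alphabet.
    max_length:
        Number of residue slots (140 by default, giving a 3080-vector).

    Returns
    -------
    numpy.ndarray of shape ``(max_length * 22,)``.
    """
    if len(alphabet) == 0:
        raise ValueError("empty alphabet")
    if len(seq) > max_length:
        raise ValueError(
            f"sequence of length {len(seq)} exceeds maximum {max_length}"
        )
    n_sym = len(alphabet)
    out = np.zeros((max_length, n_sym), dtype=np.float64)
    for i, ch in enumerate(seq):
        out[i, alphabet.index_of(ch)] = 1.0
    out[len(seq):, alphabet.pad_index] = 1.0
    return out.ravel()


def decode_sequence(
    tensor: np.ndarray,
    alphabet: Alphabet = DEFAULT_ALPHABET,
) -> str:
    """Decode a flat (possibly soft) sequence tensor back to a string.

    Each 22-wide block is reduced by argmax (ties break to the lowest
    symbol index). The trailing run of padding symbols is stripped;
    padding argmaxes that occur *before* a non-padding residue are mapped
    to the wildcard so positional correspondence with the input frame is
    preserved for downstream motif analysis.

    Total on any real-valued vector whose length is a multiple of 22, so
    raw decoder-network output never fails to decode.
    """
    n_sym = len(alphabet)
    arr = np.asarray(tensor, dtype=np.float64).ravel()
    if arr.size % n_sym != 0:
        raise ValueError(
            f"tensor length {arr.size} is not a multiple of alphabet size {n_sym}"
        )
    blocks = arr.reshape(-1, n_sym)
    idx = np.argmax(blocks, axis=1)
    # Strip only the trailing padding run.
    end = len(idx)
    while end > 0 and idx[end - 1] == alphabet.pad_index:
        end -= 1
    chars = []
    for i in idx[:end]:
        if i == alphabet.pad_index:  # interior padding -> wildcard
            chars.append(alphabet.wildcard)
        else:
            chars.append(alphabet.symbols[i])
    return "".join(chars)


def encode_batch(
    seqs: list[str],
    alphabet: Alphabet = DEFAULT_ALPHABET,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> np.ndarray:
    """Encode a list of sequences into an ``(n, max_length*22)`` array."""
    return np.stack([encode_sequence(s, alphabet, max_length) for s in seqs])


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    """Write an ``{id: sequence}`` mapping to a FASTA file."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
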