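"""Training-table construction from annotated sequence records.

Implements the computational dataset rules: negative training examples
(binding residues resampled from background amino-acid frequencies with
metal flags zeroed), propagation of those mutations to aligned
homologues, the homologue length filter (80-120% of the query, capped at
140 residues), and construction of the conditioning attribute vector —
either the 8 metal-binding flags or the 1265-entry one-hot grammar
encoding of a topology string.

Sequence harvesting itself (PDB / CATH / UniRef90 / MetalPDB queries) is
out of scope; this module consumes a FASTA file plus a TSV manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import grammar
from .codec import STANDARD_AA, read_fasta, write_fasta

#: Canonical metal ordering for the 8 binding flags.
METALS = ("Fe", "Zn", "Ca", "Na", "Cu", "Mg", "Cd", "Ni")

PROVENANCES = ("native", "homologue", "negative")

#: Hard cap on homologue length (residues).
MAX_HOMOLOGUE_LENGTH = 140


@dataclass(frozen=True)
class SequenceRecord:
    """One protein: sequence, metal flags, annotations, provenance."""

    id: str
    sequence: str
    metal_flags: tuple[int, ...] = (0,) * 8
    binding_positions: frozenset[int] = frozenset()
    topology: str | None = None
    family: str | None = None
    provenance: str = "native"

    def __post_init__(self) -> None:
        if len(self.metal_flags) != len(METALS):
            raise ValueError(f"need {len(METALS)} metal flags")
        if any(f not in (0, 1) for f in self.metal_flags):
            raise ValueError("metal flags must be binary")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        bad = [p for p in self.binding_positions if not 0 <= p < len(self.sequence)]
        if bad:
            raise ValueError(f"binding positions {bad} outside [0, {len(self.sequence)})")
        # freeze mutable containers passed by callers
        object.__setattr__(self, "binding_positions", frozenset(self.binding_positions))
        object.__setattr__(self, "metal_flags", tuple(self.metal_flags))

    def binds(self, metal: str) -> bool:
        return bool(self.metal_flags[METALS.index(metal)])


def amino_acid_frequencies(records: list[SequenceRecord]) -> np.ndarray:
    """Empirical frequencies of the 20 standard amino acids in a record set."""
    counts = np.zeros(20, dtype=np.float64)
    for rec in records:
        for ch in rec.sequence:
            i = STANDARD_AA.find(ch)
            if i >= 0:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no standard amino acids found in records")
    return counts / total


def make_negative_example(
    rec: SequenceRecord,
    aa_freqs: np.ndarray,
    rng_seed: int,
) -> SequenceRecord:
    """Negative training example: binding residues resampled, flags zeroed.

    Each annotated binding residue is replaced by an amino acid drawn
    from ``aa_freqs`` (the whole-training-set composition). The draw may
    return the original residue, so a "mutated" site can retain its
    native identity; everything outside ``binding_positions`` is
    untouched. Deterministic given ``rng_seed``.
    """
    if not rec.binding_positions:
        raise ValueError(f"record {rec.id} has no binding positions to mutate")
    freqs = np.asarray(aa_freqs, dtype=np.float64)
    if freqs.shape != (20,):
        raise ValueError("aa_freqs must be a 20-vector")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"aa_freqs sum to {freqs.sum()!r}, not 1")
    rng = np.random.default_rng(rng_seed)
    seq = list(rec.sequence)
    for pos in sorted(rec.binding_positions):
        seq[pos] = STANDARD_AA[rng.choice(20, p=freqs)]
    return replace(
        rec,
        id=f"{rec.id}_neg",
        sequence="".join(seq),
        metal_flags=(0,) * len(METALS),
        provenance="negative",
    )


def propagate_mutations_to_homologue(
    native: SequenceRecord,
    homologue: SequenceRecord,
    column_map: dict[int, int],
    mutated: dict[int, str],
) -> SequenceRecord:
    """Carry native binding-site mutations over to an aligned homologue.

    A homologue position aligned (via ``column_map``, native index ->
    homologue index) to a mutated native position receives the same
    replacement residue if and only if the homologue currently has the
    same amino acid as the native sequence at that column. The result is
    the homologue's negative example: flags zeroed, provenance
    ``negative``.
    """
    if len(set(column_map.values())) != len(column_map):
        raise ValueError("column_map must be injective")
    seq = list(homologue.sequence)
    for nat_pos, new_res in mutated.items():
        if nat_pos not in column_map:
            continue
        hom_pos = column_map[nat_pos]
        if not 0 <= nat_pos < len(native.sequence):
            raise ValueError(f"native index {nat_pos} out of range")
        if not 0 <= hom_pos < len(homologue.sequence):
            raise ValueError(f"homologue index {hom_pos} out of range")
        if homologue.sequence[hom_pos] == native.sequence[nat_pos]:
            seq[hom_pos] = new_res
    return replace(
        homologue,
        id=f"{homologue.id}_neg",
        sequence="".join(seq),
        metal_flags=(0,) * len(METALS),
        provenance="negative",
    )


def filter_homologue(query_len: int, hit_len: int) -> bool:
    """Length filter for homologue hits: 80-120% of the query, max 140."""
    if query_len <= 0 or hit_len <= 0:
        raise ValueError("lengths must be positive")
    return 0.8 * query_len <= hit_len <= min(1.2 * query_len, MAX_HOMOLOGUE_LENGTH)


def build_attribute(rec: SequenceRecord, mode: str) -> np.ndarray:
    """Conditioning vector for a record.

    ``mode='metal'`` gives the 8 binding flags in canonical metal order;
    ``mode='grammar'`` gives the 1265-entry one-hot rule encoding of the
    record's topology string.
    """
    if mode == "metal":
        return np.asarray(rec.metal_flags, dtype=np.float64)
    if mode == "grammar":
        if rec.topology is None:
            raise ValueError(f"record {rec.id} has no topology string")
        return grammar.topology_encoding(grammar.parse_topology(rec.topology))
    raise ValueError(f"unknown attribute mode {mode!r}")


# ---------------------------------------------------------------------------
# Manifest I/O

_MANIFEST_COLUMNS = (
    ["id"] + list(METALS) + ["binding_positions", "topology", "family", "provenance"]
)


def save_records(records: list[SequenceRecord], fasta_path, manifest_path) -> None:
    """Write records as FASTA + TSV manifest (the data_prep input format)."""
    write_fasta(fasta_path, {r.id: r.sequence for r in records})
    rows = []
    for r in records:
        row = {"id": r.id}
        row.update(dict(zip(METALS, r.metal_flags)))
        row["binding_positions"] = ",".join(str(p) for p in sorted(r.binding_positions))
        row["topology"] = r.topology or ""
        row["family"] = r.family or ""
        row["provenance"] = r.provenance
        rows.append(row)
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(
        manifest_path, sep="\t", index=False
    )


def load_records(fasta_path, manifest_path) -> list[SequenceRecord]:
    """Read records back from FASTA + TSV manifest."""
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        rid = row["id"]
        if rid not in seqs:
            raise ValueError(f"manifest id {rid!r} missing from FASTA")
        positions = frozenset(
            int(p) for p in row["binding_positions"].split(",") if p.strip()
        )
        records.append(
            SequenceRecord(
                id=rid,
                sequence=seqs[rid],
                metal_flags=tuple(int(row[m]) for m in METALS),
                binding_positions=positions,
                topology=row["topology"] or None,
                family=row["family"] or None,
                provenance=row["provenance"] or "native",
            )
        )
    return records


def build_training_arrays(
    records: list[SequenceRecord],
    mode: str,
    alphabet=None,
    max_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode records into ``(X, A)`` training matrices for the CVAE.

    ``X`` holds flattened one-hot sequences, ``A`` the conditioning
    vectors for the requested mode.
    """
    from .codec import DEFAULT_ALPHABET, DEFAULT_MAX_LENGTH, encode_sequence

    alphabet = alphabet or DEFAULT_ALPHABET
    max_length = max_length or DEFAULT_MAX_LENGTH
    X = np.stack([encode_sequence(r.sequence, alphabet, max_length) for r in records])
    A = np.stack([build_attribute(r, mode) for r in records])
    return X, A
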