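"""Synthetic protein-family fixtures.

Generates families of related sequences with the statistical structure
the models assume: a consensus per family, homologues that mutate
non-conserved positions independently (no residue covariation — a known
property of the modelling setup), planted metal-coordination motifs that
are present exactly when the family's metal flag is on, topology labels,
and paper-style negative twins in which the binding residues are
resampled from the background composition and the flags zeroed. The
output round-trips through the FASTA + TSV manifest format consumed by
the data-preparation module.

Defaults emulate a homologue harvest: up to 50 members per family and
fairly high within-family conservation (0.8 per position), with family
lengths well under the 140-residue cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import data_prep, grammar
from .codec import STANDARD_AA
from .data_prep import METALS, SequenceRecord

#: Planted coordination motifs per metal: (offset, residue) triples laid
#: down from a per-metal anchor position. The copper motif is the classic
#: His-x3-His pair plus a cysteine; the others use residues typical of
#: each metal's coordination chemistry.
METAL_MOTIFS: dict[str, tuple[tuple[int, str], ...]] = {
    "Fe": ((0, "H"), (4, "E"), (8, "H")),
    "Zn": ((0, "C"), (4, "C"), (8, "H")),
    "Ca": ((0, "D"), (4, "D"), (8, "E")),
    "Na": ((0, "D"), (4, "S"), (8, "N")),
    "Cu": ((0, "H"), (4, "H"), (8, "C")),
    "Mg": ((0, "D"), (4, "T"), (8, "D")),
    "Cd": ((0, "C"), (4, "E"), (8, "C")),
    "Ni": ((0, "H"), (4, "N"), (8, "H")),
}

#: Anchor position of each metal's motif (distinct, so signals for
#: different metals never overlap in a dataset of mixed families).
MOTIF_ANCHORS: dict[str, int] = {m: 6 + 4 * i for i, m in enumerate(METALS)}


def motif_positions(metal: str) -> tuple[int, ...]:
    """Absolute planted positions of a metal's motif."""
    anchor = MOTIF_ANCHORS[metal]
    return tuple(anchor + off for off, _ in METAL_MOTIFS[metal])


def has_motif(seq: str, metal: str) -> bool:
    """Whether the planted motif for ``metal`` is intact in ``seq``."""
    anchor = MOTIF_ANCHORS[metal]
    return all(
        anchor + off < len(seq) and seq[anchor + off] == res
        for off, res in METAL_MOTIFS[metal]
    )


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one synthetic family.

    ``conservation`` is the per-position probability that a homologue
    keeps the consensus residue; non-conserved positions are redrawn
    uniformly over the 20 amino acids (so they match the consensus by
    coincidence 1 time in 20). ``metal`` plants that metal's motif and
    sets its flag; ``topology`` attaches a grammar topology string.
    """

    family_id: str
    length: int = 60
    n_homologues: int = 30
    conservation: float = 0.8
    metal: str | None = None
    topology: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.length <= 140:
            raise ValueError("length must be in [1, 140]")
        if not 0 <= self.n_homologues <= 50:
            raise ValueError("n_homologues must be in [0, 50]")
        if not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation must be in [0, 1]")
        if self.metal is not None:
            if self.metal not in METALS:
                raise ValueError(f"unknown metal {self.metal!r}")
            if max(motif_positions(self.metal)) >= self.length:
                raise ValueError(
                    f"motif for {self.metal} does not fit in length {self.length}"
                )


def generate_family(spec: FamilySpec, rng_seed: int) -> list[SequenceRecord]:
    """Generate the native sequence and homologues of one family.

    The consensus is drawn uniformly per position; when a metal is set,
    its motif residues overwrite the planted positions and are held
    fixed in every homologue (binding sites are conserved). All other
    positions mutate independently with probability 1 - conservation.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(rng_seed)
    consensus = list(STANDARD_AA[i] for i in rng.integers(0, 20, size=spec.length))
    flags = [0] * len(METALS)
    positions: frozenset[int] = frozenset()
    if spec.metal is not None:
        anchor = MOTIF_ANCHORS[spec.metal]
        for off, res in METAL_MOTIFS[spec.metal]:
            consensus[anchor + off] = res
        flags[METALS.index(spec.metal)] = 1
        positions = frozenset(motif_positions(spec.metal))

    def record(rid: str, seq: str, provenance: str) -> SequenceRecord:
        return SequenceRecord(
            id=rid,
            sequence=seq,
            metal_flags=tuple(flags),
            binding_positions=positions,
            topology=spec.topology,
            family=spec.family_id,
            provenance=provenance,
        )

    out = [record(f"{spec.family_id}_native", "".join(consensus), "native")]
    for h in range(spec.n_homologues):
        seq = list(consensus)
        for i in range(spec.length):
            if i in positions:
                continue  # planted binding sites stay intact
            if rng.random() > spec.conservation:
                seq[i] = STANDARD_AA[rng.integers(0, 20)]
        out.append(record(f"{spec.family_id}_hom{h}", "".join(seq), "homologue"))
    return out


def generate_dataset(
    n_families: int,
    rng_seed: int = 0,
    length: int = 60,
    n_homologues: int = 30,
    conservation: float = 0.8,
    metals: tuple[str | None, ...] = METALS,
    with_topologies: bool = False,
    n_topologies: int | None = None,
    with_negatives: bool = True,
) -> list[SequenceRecord]:
    """Generate a multi-family dataset with planted attribute signals.

    Families cycle through ``metals`` (``None`` entries give non-binding
    families). Each metal-flagged record receives a negative twin with
    its binding residues resampled from the dataset's own amino-acid
    composition and flags zeroed. With ``with_topologies`` families are
    assigned grammar-sampled topology strings drawn from a pool of
    ``n_topologies`` distinct strings (default: one per family); a pool
    smaller than ``n_families`` makes several families share a fold, as
    real fold space does.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    root = np.random.default_rng(rng_seed)
    seeds = root.integers(0, 2**31 - 1, size=2 * n_families)
    pool_size = min(n_families, n_topologies or n_families)
    topology_pool = [
        str(grammar.sample_topology(int(seeds[2 * i]), max_elements=6))
        for i in range(pool_size)
    ]
    records: list[SequenceRecord] = []
    for f in range(n_families):
        metal = metals[f % len(metals)]
        topology = topology_pool[f % pool_size] if with_topologies else None
        spec = FamilySpec(
            family_id=f"fam{f:03d}",
            length=length,
            n_homologues=n_homologues,
            conservation=conservation,
            metal=metal,
            topology=topology,
        )
        records.extend(generate_family(spec, int(seeds[2 * f + 1])))

    if with_negatives:
        freqs = data_prep.amino_acid_frequencies(records)
        neg_seeds = root.integers(0, 2**31 - 1, size=len(records))
        negatives = [
            data_prep.make_negative_example(rec, freqs, int(neg_seeds[i]))
            for i, rec in enumerate(records)
            if rec.binding_positions
        ]
        records.extend(negatives)
    return records


def write_dataset(records: list[SequenceRecord], fasta_path, manifest_path) -> None:
    """Write a generated dataset in the standard FASTA + manifest form."""
    data_prep.save_records(records, fasta_path, manifest_path)
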