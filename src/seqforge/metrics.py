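"""Sequence- and structure-level evaluation of generated proteins.

Covers the copper-motif screens (His-x3-His pairs, optionally restricted
to helical positions; histidine pairs close in 3-D space on a template
structure), per-column conservation by Jensen-Shannon divergence against
a background composition, pairwise sequence identity, and residue-count
enrichment of generated pools over a native sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .codec import STANDARD_AA

#: Default distance cutoff (Angstrom) for "close in space" histidines —
#: a typical metal-coordination screening distance; configurable.
DEFAULT_CONTACT_CUTOFF = 7.0

#: Characters treated as gaps in alignment columns.
GAP_CHARS = set("-.")

#: Secondary-structure codes counted as helix.
HELIX_CODES = set("HGI")

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def find_hx3h_motifs(
    seq: str, ss: str | None = None
) -> list[tuple[int, int]]:
    """Find His-x3-His motifs: positions (i, i+4) with histidine at both.

    If a secondary-structure string ``ss`` is given (same length as
    ``seq``), only pairs whose two histidines are both helix-annotated
    (codes H/G/I) are kept — the helical copper-motif screen.
    """
    if ss is not None and len(ss) != len(seq):
        raise ValueError(
            f"secondary structure length {len(ss)} != sequence length {len(seq)}"
        )
    pairs = []
    for i in range(len(seq) - 4):
        if seq[i] == "H" and seq[i + 4] == "H":
            if ss is None or (ss[i] in HELIX_CODES and ss[i + 4] in HELIX_CODES):
                pairs.append((i, i + 4))
    return pairs


@dataclass(frozen=True)
class ResidueCoordinates:
    """Representative 3-D coordinate per residue of a template structure.

    ``positions`` maps a 0-based residue index to an (x, y, z) array in
    Angstrom — the side-chain centroid where side-chain atoms exist,
    falling back to the alpha-carbon. ``residues`` gives one-letter
    residue types at the same indices.
    """

    positions: dict[int, np.ndarray]
    residues: dict[int, str]

    @classmethod
    def from_pdb(cls, path, chain: str | None = None) -> "ResidueCoordinates":
        """Read the first model (and first or named chain) of a PDB file."""
        from Bio.PDB import PDBParser
        from Bio.PDB.Polypeptide import protein_letters_3to1

        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("template", str(path))
        model = next(structure.get_models())
        chains = list(model.get_chains())
        if chain is not None:
            chains = [c for c in chains if c.id == chain]
            if not chains:
                raise ValueError(f"chain {chain!r} not found")
        positions: dict[int, np.ndarray] = {}
        residues: dict[int, str] = {}
        idx = 0
        for res in chains[0]:
            if res.id[0] != " ":  # skip heteroatoms / waters
                continue
            side = [
                atom.coord
                for atom in res
                if atom.get_name() not in _BACKBONE_ATOMS
                and atom.element != "H"
            ]
            if side:
                coord = np.mean(side, axis=0)
            elif "CA" in res:
                coord = res["CA"].coord
            else:
                idx += 1
                continue
            positions[idx] = np.asarray(coord, dtype=np.float64)
            residues[idx] = protein_letters_3to1.get(res.get_resname(), "X")
            idx += 1
        return cls(positions, residues)


def close_histidines(
    seq: str,
    coords: ResidueCoordinates,
    cutoff_angstrom: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[int, int]]:
    """Histidine pairs close in space when ``seq`` is threaded onto the
    template coordinate frame.

    Returns pairs (i, j), i < j, with sequence separation >= 2 and
    representative-atom distance <= cutoff. Histidines without template
    coordinates are skipped with a warning.
    """
    his = [i for i, ch in enumerate(seq) if ch == "H"]
    located = []
    for i in his:
        if i in coords.positions:
            located.append(i)
        else:
            warnings.warn(f"no coordinates for residue {i}; pair skipped")
    pairs = []
    for ai in range(len(located)):
        for aj in range(ai + 1, len(located)):
            i, j = located[ai], located[aj]
            if j - i < 2:
                continue
            d = np.linalg.norm(coords.positions[i] - coords.positions[j])
            if d <= cutoff_angstrom:
                pairs.append((i, j))
    return pairs


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores in [0, 1], with a high-gap mask."""

    scores: np.ndarray
    high_gap: np.ndarray  # True where a column is >50% gaps

    def __len__(self) -> int:
        return len(self.scores)


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence with the half-mixture, log base 2."""
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log2(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def jsd_conservation(
    alignment: list[str], background: np.ndarray
) -> ConservationProfile:
    """Column conservation of an alignment as JSD against a background.

    For each column the amino-acid distribution (gaps excluded) is
    compared to the 20-vector ``background`` with the half-mixture
    Jensen-Shannon divergence in log base 2, giving scores in [0, 1]:
    0 for a column distributed exactly like the background, 1 for a
    fully conserved residue absent from the background support. Columns
    with more than 50% gaps are scored but flagged.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("ragged alignment: sequences have unequal lengths")
    bg = np.asarray(background, dtype=np.float64)
    if bg.shape != (20,):
        raise ValueError("background must be a 20-vector")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be normalized")

    scores = np.zeros(width)
    high_gap = np.zeros(width, dtype=bool)
    for col in range(width):
        counts = np.zeros(20)
        gaps = 0
        for s in alignment:
            ch = s[col]
            if ch in GAP_CHARS:
                gaps += 1
                continue
            k = STANDARD_AA.find(ch)
            if k >= 0:
                counts[k] += 1
        high_gap[col] = gaps > 0.5 * len(alignment)
        total = counts.sum()
        if total == 0:
            scores[col] = 0.0
            continue
        scores[col] = _jsd(counts / total, bg)
    return ConservationProfile(scores, high_gap)


def conservation_correlation(
    a: ConservationProfile | np.ndarray, b: ConservationProfile | np.ndarray
) -> float:
    """Pearson correlation between two conservation profiles."""
    xa = a.scores if isinstance(a, ConservationProfile) else np.asarray(a)
    xb = b.scores if isinstance(b, ConservationProfile) else np.asarray(b)
    return float(pearsonr(xa, xb).statistic)


def sequence_identity(a: str, b: str) -> float:
    """Percent identity between two sequences.

    Equal-length inputs are compared position-wise. Unequal lengths are
    globally aligned first (Needleman-Wunsch: match +1, mismatch 0, gap
    open -1, gap extend -0.5) and identity is identical pairs over
    alignment columns.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * matches / len(a)
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return 100.0 * matches / len(sa)


def count_residue_enrichment(
    generated: list[str], native: str, residue: str
) -> float:
    """Fraction of generated sequences with strictly more of ``residue``
    than the native sequence."""
    if not generated:
        raise ValueError("no generated sequences")
    native_count = native.count(residue)
    over = sum(1 for s in generated if s.count(residue) > native_count)
    return over / len(generated)
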