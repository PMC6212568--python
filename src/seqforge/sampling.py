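"""Generation procedures built on a trained conditional VAE.

Two sampling modes are provided. For metalloprotein design an input
sequence is encoded once and many latent samples are drawn from its
posterior, each decoded with a (possibly modified) metal-flag attribute
— 1000 samples by default. For the structure task, sequences for a
requested topology are drawn from the standard-normal prior, and an
iterative search alternates sampling, scoring by a pluggable scorer
(lower is better; in the full pipeline an external structure-based
scoring stage plugs in here), and re-encoding the incumbent best
sequence to sample its neighbourhood. The incumbent is always kept in
the candidate pool (elitism), so the best score never worsens across
rounds.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from . import grammar
from .codec import decode_sequence, encode_sequence
from .cvae import ConditionalVAE, LatentPosterior, reparameterize


class Scorer(Protocol):
    """Callable contract for candidate scoring: lower is better, total on
    any decodable sequence, deterministic for a fixed configuration."""

    def __call__(self, sequence: str) -> float: ...


class HammingScorer:
    """Reference mock scorer: Hamming distance to a hidden target.

    Positions beyond the shorter sequence each count as one mismatch, so
    the score is ``|len(a) - len(b)|`` plus mismatches over the overlap.
    """

    def __init__(self, target: str):
        self.target = target

    def __call__(self, sequence: str) -> float:
        overlap = sum(
            1 for a, b in zip(sequence, self.target) if a != b
        )
        return float(overlap + abs(len(sequence) - len(self.target)))


class CommandScorer:
    """Adapter for an external scoring command.

    Writes the candidate pool to FASTA, invokes ``command <fasta> <tsv>``
    and reads back a two-column TSV of id and score. Intended as the
    plug-in point for structure-based pipelines (threading, relaxation,
    fold comparison) that run outside this package.
    """

    def __init__(self, command: list[str], workdir="."):
        self.command = list(command)
        self.workdir = workdir

    def score_pool(self, sequences: list[str]) -> list[float]:
        import subprocess
        import tempfile
        from pathlib import Path

        from .codec import write_fasta

        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            fasta = Path(tmp) / "pool.fasta"
            tsv = Path(tmp) / "scores.tsv"
            names = [f"cand{i}" for i in range(len(sequences))]
            write_fasta(fasta, dict(zip(names, sequences)))
            subprocess.run(
                self.command + [str(fasta), str(tsv)], check=True
            )
            scores = {}
            with open(tsv) as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    scores[row[0]] = float(row[1])
        return [scores[n] for n in names]

    def __call__(self, sequence: str) -> float:
        return self.score_pool([sequence])[0]


@dataclass
class IterationState:
    """Record of one search round."""

    iteration: int
    best_sequence: str
    best_score: float
    shortlist: list[tuple[str, float]]
    scores: list[float] = field(repr=False, default_factory=list)
    n_failed: int = 0


def _decode_all(model: ConditionalVAE, Z: np.ndarray, attr: np.ndarray) -> list[str]:
    A = np.tile(np.asarray(attr, dtype=np.float64), (Z.shape[0], 1))
    soft = model.decode(Z, A)
    alphabet = model._alphabet()
    return [decode_sequence(row, alphabet) for row in soft]


def sample_metal_variants(
    model: ConditionalVAE,
    seq: str,
    attr: np.ndarray,
    n: int = 1000,
    rng_seed: int = 0,
) -> list[str]:
    """Posterior resampling of one input sequence.

    The sequence is encoded once with ``attr``; ``n`` latent vectors are
    drawn from the resulting Gaussian and each is decoded with the same
    attribute. To request a new property (e.g. switch a metal flag on),
    pass the modified attribute — encoding and decoding then both see
    the requested flags.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x = encode_sequence(seq, model._alphabet(), model.max_length)
    post = model.encode(x, attr)
    rng = np.random.default_rng(rng_seed)
    mu = np.tile(np.atleast_2d(post.mu), (n, 1))
    sigma2 = np.tile(np.atleast_2d(post.sigma2), (n, 1))
    Z = reparameterize(LatentPosterior(mu, sigma2), rng)
    return _decode_all(model, Z, attr)


def sample_from_topology(
    model: ConditionalVAE,
    topology: grammar.TopologyString | str,
    n: int = 1000,
    rng_seed: int = 0,
) -> list[str]:
    """Draw sequences for a topology from the standard-normal prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(topology, str):
        topology = grammar.parse_topology(topology)
    attr = grammar.topology_encoding(topology)
    rng = np.random.default_rng(rng_seed)
    Z = rng.standard_normal((n, model.latent_dim))
    return _decode_all(model, Z, attr)


def iterative_search(
    model: ConditionalVAE,
    topology: grammar.TopologyString | str,
    scorer: Callable[[str], float],
    rounds: int = 3,
    n_per_round: int = 1000,
    top_k: int = 5,
    rng_seed: int = 0,
) -> list[IterationState]:
    """Sample-analyze-resample search of the latent space (elitist).

    Round 1 samples ``n_per_round`` sequences from the prior conditioned
    on the topology. Each subsequent round encodes the incumbent best
    sequence (with the topology attribute) and samples from its
    posterior, exploring the latent neighbourhood of the best candidate
    found so far. The incumbent joins every round's pool, so the best
    score is nonincreasing. A scorer failure on a candidate skips that
    candidate with a warning rather than aborting the search.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if isinstance(topology, str):
        topology = grammar.parse_topology(topology)
    attr = grammar.topology_encoding(topology)
    rng = np.random.default_rng(rng_seed)
    alphabet = model._alphabet()

    history: list[IterationState] = []
    best_seq: str | None = None
    best_score = np.inf
    for it in range(rounds):
        if it == 0:
            Z = rng.standard_normal((n_per_round, model.latent_dim))
        else:
            x = encode_sequence(best_seq, alphabet, model.max_length)
            post = model.encode(x, attr)
            mu = np.tile(np.atleast_2d(post.mu), (n_per_round, 1))
            sigma2 = np.tile(np.atleast_2d(post.sigma2), (n_per_round, 1))
            Z = reparameterize(LatentPosterior(mu, sigma2), rng)
        pool = _decode_all(model, Z, attr)
        if best_seq is not None:
            pool.append(best_seq)  # elitism
        scored: list[tuple[str, float]] = []
        n_failed = 0
        for cand in pool:
            try:
                scored.append((cand, float(scorer(cand))))
            except Exception as exc:  # scorer failures are non-fatal
                n_failed += 1
                warnings.warn(f"scorer failed on candidate ({exc}); skipped")
        if not scored:
            raise RuntimeError(f"scorer failed on every candidate in round {it + 1}")
        scored.sort(key=lambda t: t[1])
        if scored[0][1] < best_score:
            best_seq, best_score = scored[0]
        history.append(
            IterationState(
                iteration=it + 1,
                best_sequence=best_seq,
                best_score=best_score,
                shortlist=scored[:top_k],
                scores=[s for _, s in scored],
                n_failed=n_failed,
            )
        )
    return history
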