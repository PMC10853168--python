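"""TCR beta-chain CDR3 repertoire metrics.

Clones are identified by their CDR3 amino-acid sequence; clones identical
at the amino-acid level are merged (counts summed) before any metric.
Diversity is the Shannon index H = -sum p_i ln p_i over clone frequencies
(nats); clonality is 1 - H / ln(n) for n unique clones. Repertoire
similarity uses two distances: Levenshtein edit distance for top-clone
summaries (CDR3 lengths vary), and Hamming distance with a <= 3
substitution bound for similarity-network edges.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from .errors import DataError
from .hla import STANDARD_RESIDUES


@dataclass(frozen=True)
class Clone:
    cdr3_aa: str
    count: int


@dataclass
class TCRRepertoire:
    """Clone list of one sample (patient x timepoint).

    Duplicate CDR3 amino-acid sequences are merged at construction, summing
    counts; order follows first appearance.
    """

    patient_id: str
    timepoint: str  # "baseline" | "on_treatment" (free-form accepted)
    clones: Sequence[Clone]

    def __post_init__(self) -> None:
        merged: dict[str, int] = {}
        for c in self.clones:
            if not isinstance(c, Clone):
                c = Clone(*c)
            if not c.cdr3_aa:
                raise DataError(f"patient {self.patient_id}: empty CDR3 sequence")
            bad = set(c.cdr3_aa) - STANDARD_RESIDUES
            if bad:
                raise DataError(
                    f"patient {self.patient_id}: CDR3 {c.cdr3_aa!r} has "
                    f"non-standard residues {sorted(bad)}"
                )
            if not isinstance(c.count, (int, np.integer)) or c.count < 1:
                raise DataError(
                    f"patient {self.patient_id}: clone {c.cdr3_aa} count "
                    f"{c.count!r} must be a positive integer"
                )
            merged[c.cdr3_aa] = merged.get(c.cdr3_aa, 0) + int(c.count)
        self.clones = [Clone(seq, n) for seq, n in merged.items()]

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clones)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def frequencies(self) -> np.ndarray:
        counts = np.array([c.count for c in self.clones], dtype=float)
        return counts / counts.sum()


def downsample(rep: TCRRepertoire, n: int, seed: int) -> TCRRepertoire:
    """Draw exactly ``n`` reads without replacement from a repertoire.

    Sampling is multivariate hypergeometric over clone counts (each read is
    equally likely to be kept), seeded and reproducible. Clones that lose
    all reads are dropped. Upsampling is refused.
    """
    if rep.n_clones == 0:
        raise DataError("cannot downsample an empty repertoire")
    if n > rep.total_reads:
        raise DataError(
            f"cannot draw {n} reads from {rep.total_reads} (no upsampling)"
        )
    if n < 1:
        raise DataError(f"target read count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    counts = np.array([c.count for c in rep.clones], dtype=np.int64)
    new_counts = rng.multivariate_hypergeometric(counts, n)
    clones = [
        Clone(c.cdr3_aa, int(k))
        for c, k in zip(rep.clones, new_counts)
        if k > 0
    ]
    return TCRRepertoire(rep.patient_id, rep.timepoint, clones)


def shannon_diversity(rep: TCRRepertoire) -> float:
    """Shannon index H = -sum p_i ln p_i (nats) over clone frequencies."""
    if rep.n_clones == 0:
        raise DataError("empty repertoire")
    p = rep.frequencies()
    return float(-(p * np.log(p)).sum())


def clonality(rep: TCRRepertoire) -> float:
    """Clonality = 1 - H / ln(n unique clones); a monoclonal sample scores 1.

    n = 1 makes the ratio 0/0; the limit convention is maximal clonality.
    """
    if rep.n_clones == 0:
        raise DataError("empty repertoire")
    if rep.n_clones == 1:
        return 1.0
    return 1.0 - shannon_diversity(rep) / math.log(rep.n_clones)


def clonality_delta(baseline: TCRRepertoire, followup: TCRRepertoire) -> float:
    """Signed clonality change, follow-up minus baseline, for one patient."""
    if baseline.patient_id != followup.patient_id:
        raise DataError(
            f"patient mismatch: baseline {baseline.patient_id!r} vs "
            f"follow-up {followup.patient_id!r}"
        )
    return clonality(followup) - clonality(baseline)


def levenshtein(a: str, b: str) -> int:
    """Levenshtein edit distance between two CDR3 amino-acid sequences."""
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass(frozen=True)
class EditDistanceSummary:
    clones: list
    matrix: np.ndarray  # symmetric, zero diagonal, integer distances
    mean: float
    median: float


def top_clones(rep: TCRRepertoire, n: int) -> list[Clone]:
    """Top-n clones by count; ties broken lexicographically by sequence."""
    ranked = sorted(rep.clones, key=lambda c: (-c.count, c.cdr3_aa))
    return ranked[:n]


def top_clone_edit_distance(
    rep: TCRRepertoire, n: int = 30, pair_mode: str = "all_pairs"
) -> EditDistanceSummary:
    """Pairwise Levenshtein distances among the top-n clones.

    ``pair_mode="all_pairs"`` summarizes every unordered pair;
    ``"nearest"`` summarizes each clone's nearest-neighbor distance.
    """
    if pair_mode not in ("all_pairs", "nearest"):
        raise DataError(f"pair_mode must be 'all_pairs' or 'nearest', got {pair_mode!r}")
    if rep.n_clones < 2:
        raise DataError("edit-distance summary needs >= 2 clones")
    chosen = top_clones(rep, n)
    k = len(chosen)
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = levenshtein(chosen[i].cdr3_aa, chosen[j].cdr3_aa)
            mat[i, j] = mat[j, i] = d
    if pair_mode == "all_pairs":
        vals = mat[np.triu_indices(k, 1)]
    else:
        vals = np.array([
            mat[i, [j for j in range(k) if j != i]].min() for i in range(k)
        ])
    return EditDistanceSummary(
        clones=chosen,
        matrix=mat,
        mean=float(vals.mean()),
        median=float(statistics.median(vals.tolist())),
    )


def hamming(a: str, b: str) -> int:
    """Hamming distance; sequences must have equal length."""
    if len(a) != len(b):
        raise DataError("Hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def similarity_network(
    clones: Sequence[str], max_subs: int = 3
) -> list[tuple[int, int]]:
    """Undirected similarity edges between CDR3 sequences.

    An edge connects two sequences of equal length differing by at most
    ``max_subs`` amino-acid substitutions (Hamming distance); unequal-length
    pairs are never connected. Returns index pairs (i, j), i < j.
    """
    if len(clones) < 2:
        raise DataError("similarity network needs >= 2 sequences")
    edges = []
    for i in range(len(clones)):
        for j in range(i + 1, len(clones)):
            a, b = clones[i], clones[j]
            if len(a) == len(b) and hamming(a, b) <= max_subs:
                edges.append((i, j))
    return edges
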