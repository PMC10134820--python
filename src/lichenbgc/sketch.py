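"""MinHash genome sketching, Mash distance, and distance-based clustering.

Genomes are reduced to bottom-``s`` MinHash sketches of their canonical
k-mers (the lexicographic minimum of each k-mer and its reverse
complement).  The Jaccard index estimated from two sketches is converted
to an evolutionary distance with the Mash formula

    d = -(1/k) * ln(2j / (1 + j)),

which approximates the per-site substitution rate between the two
genomes; ``1 - d`` approximates average nucleotide identity (ANI).
Average-linkage hierarchical clustering of the all-pairs distance matrix
supports strain dereplication (default cutoff 0.005, i.e. 99.5% ANI) and
putative-species delineation (default cutoff 0.04, i.e. 96% ANI).

k-mers are packed two bits per base into 64-bit integers (which limits k
to 32) and scrambled with a SplitMix64 finalizer, a fixed platform-stable
hash, so sketches are reproducible across runs and machines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .synthetic import GenomeRecord

HASH_SEED = 42
DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


class EmptySketchError(ValueError):
    """No contig long enough to yield a single k-mer."""


@dataclass(frozen=True)
class KmerSketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mer set."""

    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted uint64, size <= s

    def __post_init__(self):
        if self.k < 11 or self.k > 32:
            raise ValueError(f"k must be in [11, 32], got {self.k}")
        if len(self.hashes) > self.s:
            raise ValueError("sketch holds more than s hashes")

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "k": self.k,
            "s": self.s,
            "hashes": [int(h) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KmerSketch":
        return cls(
            genome_id=d["genome_id"],
            k=int(d["k"]),
            s=int(d["s"]),
            hashes=np.asarray(sorted(d["hashes"]), dtype=np.uint64),
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric all-pairs Mash distance matrix."""

    ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match id list")
        if not np.allclose(self.D, self.D.T) or np.any(np.diag(self.D) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if np.any(self.D < 0) or np.any(self.D > 1):
            raise ValueError("distances must lie in [0, 1]")


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering of genomes at a fixed linkage cutoff.

    Cluster ids are contiguous integers from 0, numbered in order of the
    first member's appearance in the input id list.
    """

    assignments: Mapping[str, int]
    cutoff: float
    linkage: str = field(default="average")

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gid, cid in self.assignments.items():
            out.setdefault(cid, []).append(gid)
        return out


_SEED_OFFSET = np.uint64((HASH_SEED * 0x9E3779B97F4A7C15) % 2**64)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer; fixed-seed, vectorized over uint64 arrays."""
    z = x + _SEED_OFFSET
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _canonical_kmer_values(sequence: str, k: int) -> np.ndarray:
    """Packed integer values of the canonical k-mers of one contig.

    Windows containing N (or any non-ACGT symbol) are skipped.
    """
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64)
    win = sliding_window_view(codes, k)
    valid = (win != 4).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    win = win[valid].astype(np.uint64)
    pw_desc = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    pw_asc = pw_desc[::-1]
    fwd = (win * pw_desc).sum(axis=1)
    rev = ((np.uint64(3) - win) * pw_asc).sum(axis=1)
    return np.minimum(fwd, rev)


def sketch(genome: GenomeRecord, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH_SIZE) -> KmerSketch:
    """Bottom-s MinHash sketch over the genome's canonical k-mers.

    k-mers never span contig boundaries; contigs shorter than k are
    ignored.  Raises :class:`EmptySketchError` when no contig yields a
    single valid k-mer.
    """
    if s < 1:
        raise ValueError("sketch size s must be positive")
    values = [_canonical_kmer_values(seq, k) for _, seq in genome.contigs]
    values = [v for v in values if len(v)]
    if not values:
        raise EmptySketchError(
            f"genome {genome.genome_id!r}: no contig yields a k-mer at k={k}"
        )
    distinct = np.unique(np.concatenate(values))
    hashes = np.sort(_splitmix64(distinct))[:s]
    return KmerSketch(genome_id=genome.genome_id, k=k, s=s, hashes=hashes)


def jaccard(a: KmerSketch, b: KmerSketch) -> float:
    """Mash-style Jaccard estimate from two bottom-s sketches.

    Among the s smallest hashes of the union of the two sketches, the
    fraction present in both.
    """
    if a.k != b.k or a.s != b.s:
        raise ValueError("sketches must share k and s")
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(a.s, len(union))]
    shared = int(np.count_nonzero(np.isin(bottom, a.hashes) & np.isin(bottom, b.hashes)))
    return shared / len(bottom)


def mash_distance(j: float, k: int) -> float:
    """Mash distance d = -(1/k) ln(2j/(1+j)), capped at 1; j=0 maps to the cap."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate must lie in [0, 1], got {j}")
    if j == 0.0:
        return 1.0
    d = -np.log(2.0 * j / (1.0 + j)) / k
    return float(min(max(d, 0.0), 1.0))


def distance_matrix(sketches: Sequence[KmerSketch]) -> DistanceMatrix:
    """All-pairs Mash distances for a consistent set of sketches."""
    if len(sketches) < 2:
        raise ValueError("need at least two sketches")
    k0, s0 = sketches[0].k, sketches[0].s
    if any(sk.k != k0 or sk.s != s0 for sk in sketches):
        raise ValueError("all sketches must share k and s")
    ids = tuple(sk.genome_id for sk in sketches)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids in sketch list")
    n = len(sketches)
    D = np.zeros((n, n))
    for i, jdx in combinations(range(n), 2):
        d = mash_distance(jaccard(sketches[i], sketches[jdx]), k0)
        D[i, jdx] = D[jdx, i] = d
    return DistanceMatrix(ids=ids, D=D)


def average_linkage_clusters(D: DistanceMatrix, cutoff: float) -> ClusterAssignment:
    """Agglomerative average-linkage clustering cut at ``cutoff``.

    Merges with linkage distance <= cutoff are kept, so two genomes land
    in one cluster iff they are joined at or below the cutoff.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    Z = linkage(squareform(D.D, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    remap: dict[int, int] = {}
    assignments: dict[str, int] = {}
    for gid, lab in zip(D.ids, labels):
        if lab not in remap:
            remap[lab] = len(remap)
        assignments[gid] = remap[lab]
    return ClusterAssignment(assignments=assignments, cutoff=cutoff)


def dereplicate(D: DistanceMatrix, cutoff: float = 0.005) -> list[str]:
    """Collapse near-identical genomes; one representative per cluster.

    The representative is the lexicographically smallest genome id in
    each cluster; the default cutoff 0.005 corresponds to 99.5% ANI.
    """
    clusters = average_linkage_clusters(D, cutoff)
    return sorted(min(members) for members in clusters.members().values())


def delineate_species(D: DistanceMatrix, cutoff: float = 0.04) -> ClusterAssignment:
    """Cluster genomes into putative species at 4% Mash distance (96% ANI)."""
    return average_linkage_clusters(D, cutoff)


# ---------------------------------------------------------------------------
# I/O


def write_sketches(sketches: Iterable[KmerSketch], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([sk.to_dict() for sk in sketches], indent=1) + "\n"
    )


def read_sketches(path: str | Path) -> list[KmerSketch]:
    return [KmerSketch.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-like square TSV: header row of ids, one labelled row per genome."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for gid, row in zip(dm.ids, dm.D):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        ids = tuple(fh.readline().rstrip("\n").split("\t")[1:])
        rows = []
        for line in fh:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return DistanceMatrix(ids=ids, D=np.asarray(rows))


def write_clusters(ca: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tcluster_id\n")
        for gid, cid in ca.assignments.items():
            fh.write(f"{gid}\t{cid}\n")
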