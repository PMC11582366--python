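"""MinHash sketch ANI estimation and greedy species clustering.

Average nucleotide identity (ANI) between two genomes is estimated from the
Jaccard similarity of their canonical k-mer sets, subsampled by a bottom
sketch (the smallest ``sketch_size`` distinct 64-bit k-mer hashes). Under a
Poisson substitution model the fraction of shared k-mers w relates to the
per-site divergence d by w ~= e^(-kd); with the Jaccard estimate J,
w = 2J/(1+J), so d ~= -(1/k) ln(2J/(1+J)) and ANI = 100(1-d). Sketches use
canonical k-mers (lexicographic min of a k-mer and its reverse complement)
so strand is irrelevant. Disjoint sketches (J = 0) are reported as ANI 0
with a ``saturated`` flag: the true distance is merely beyond resolution.

Species clustering is greedy centroid clustering: repeatedly promote the
best-quality unassigned genome to representative and absorb every
unassigned genome with ANI >= the species threshold (default 93%). The
expanded set keeps, besides the representatives, every member strictly
below the dereplication threshold (default 99%) to its representative —
near-identical duplicates are dropped, distinct within-species diversity
is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 5000
DEFAULT_SPECIES_THRESHOLD = 93.0
DEFAULT_DEREP_THRESHOLD = 99.0

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i  # lowercase


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: a cheap, well-mixed 64-bit hash."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x = (x * np.uint64(0xBF58476D1CE4E5B9)).astype(np.uint64)
    x ^= x >> np.uint64(27)
    x = (x * np.uint64(0x94D049BB133111EB)).astype(np.uint64)
    x ^= x >> np.uint64(31)
    return x


def _canonical_kmer_hashes(sequence: str, k: int, seed: int) -> np.ndarray:
    """Hashes of all canonical k-mers of one sequence (k-mers with N skipped)."""
    if len(sequence) < k:
        raise ValidationError(f"sequence length {len(sequence)} < k = {k}")
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes <= 3
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.uint64)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    win = win[ok]
    if win.size == 0:
        return np.empty(0, dtype=np.uint64)
    shifts = (np.uint64(2) * np.arange(k - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
    fwd = (win << shifts).sum(axis=1, dtype=np.uint64)
    rc_win = (np.uint64(3) - win)[:, ::-1]
    rev = (rc_win << shifts).sum(axis=1, dtype=np.uint64)
    canon = np.minimum(fwd, rev)
    return _mix64(canon ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF))


def kmer_sketch(
    sequences: str | Iterable[str],
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    seed: int = 0,
) -> np.ndarray:
    """Bottom sketch: the smallest ``sketch_size`` distinct canonical k-mer hashes.

    ``sequences`` may be a single string or an iterable of contigs; contigs
    contribute to one pooled k-mer set (k-mers never span contig joins).
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_canonical_kmer_hashes(s, k, seed) for s in sequences]
    hashes = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
    return hashes[:sketch_size]


@dataclass(frozen=True)
class ANIEstimate:
    """A sketch-based ANI estimate with its underlying Jaccard similarity."""

    ani: float
    jaccard: float
    saturated: bool

    def __float__(self) -> float:
        return self.ani


def ani_from_sketches(
    sketch_a: np.ndarray, sketch_b: np.ndarray, k: int = DEFAULT_K
) -> ANIEstimate:
    """Mash-style ANI from two bottom sketches built with the same k and seed."""
    s = min(len(sketch_a), len(sketch_b))
    if s == 0:
        raise ValidationError("empty sketch")
    union = np.union1d(sketch_a, sketch_b)[:s]
    shared = np.intersect1d(union, np.intersect1d(sketch_a, sketch_b)).size
    j = shared / s
    if j <= 0:
        return ANIEstimate(0.0, 0.0, saturated=True)
    d = -math.log(2 * j / (1 + j)) / k
    return ANIEstimate(max(0.0, min(100.0, 100.0 * (1.0 - d))), j, saturated=False)


def sketch_ani(
    seq_a: str,
    seq_b: str,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    seed: int = 0,
) -> ANIEstimate:
    """Estimate ANI (percent) between two nucleotide sequences."""
    sa = kmer_sketch(seq_a, k, sketch_size, seed)
    sb = kmer_sketch(seq_b, k, sketch_size, seed)
    return ani_from_sketches(sa, sb, k)


@dataclass(frozen=True)
class ANIMatrix:
    """Symmetric ANI percent matrix; NaN marks pairs below any threshold."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("ANI matrix shape does not match ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate genome ids in ANI matrix")
        with np.errstate(invalid="ignore"):
            if np.any((v < 0) | (v > 100)):
                raise ValidationError("ANI values must lie in [0, 100]")
        mask = ~np.isnan(v)
        if not np.array_equal(mask, mask.T) or not np.allclose(
            v[mask & mask.T], v.T[mask & mask.T]
        ):
            raise ValidationError("ANI matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValidationError("self-ANI must be 100")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    @classmethod
    def from_pairs(
        cls, ids: Sequence[str], pairs: Mapping[tuple[str, str], float]
    ) -> "ANIMatrix":
        idx = {g: i for i, g in enumerate(ids)}
        v = np.full((len(ids), len(ids)), np.nan)
        np.fill_diagonal(v, 100.0)
        for (a, b), ani in pairs.items():
            v[idx[a], idx[b]] = ani
            v[idx[b], idx[a]] = ani
        return cls(tuple(ids), v)

    @classmethod
    def from_sketches(
        cls, sketches: Mapping[str, np.ndarray], k: int = DEFAULT_K
    ) -> "ANIMatrix":
        ids = tuple(sketches)
        v = np.full((len(ids), len(ids)), np.nan)
        np.fill_diagonal(v, 100.0)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                est = ani_from_sketches(sketches[ids[i]], sketches[ids[j]], k)
                v[i, j] = v[j, i] = np.nan if est.saturated else est.ani
        return cls(ids, v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ANIMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in frame.columns), frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class Cluster:
    representative: str
    members: tuple[str, ...]

    def __post_init__(self):
        if self.representative not in self.members:
            raise ValidationError("representative must be a cluster member")


@dataclass(frozen=True)
class SpeciesClustering:
    clusters: tuple[Cluster, ...]
    threshold: float
    expanded_set: tuple[str, ...] | None = None

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(c.representative for c in self.clusters)

    def assignments(self) -> dict[str, str]:
        """genome -> its cluster representative."""
        return {m: c.representative for c in self.clusters for m in c.members}

    def to_frame(self) -> pd.DataFrame:
        expanded = set(self.expanded_set or ())
        rows = [
            (m, c.representative, m in expanded)
            for c in self.clusters
            for m in c.members
        ]
        return pd.DataFrame(
            rows, columns=["genome_id", "representative_id", "in_expanded_set"]
        )


def quality_priority(
    qc_results: Iterable, records: Mapping[str, "object"] | None = None
) -> dict[str, tuple]:
    """dRep-style representative priority: completeness - 5 x contamination,
    then assembly length, then genome id (all descending except the id)."""
    priority = {}
    for r in qc_results:
        length = 0.0
        if records is not None and r.genome_id in records:
            length = float(records[r.genome_id].assembly_length)
        score = r.completeness_percent - 5.0 * r.contamination_percent
        priority[r.genome_id] = (score, length)
    return priority


def cluster_species(
    ani: ANIMatrix,
    priority: Mapping[str, tuple],
    threshold: float = DEFAULT_SPECIES_THRESHOLD,
) -> SpeciesClustering:
    """Greedy centroid clustering at an ANI threshold.

    Deterministic: genomes are visited by descending priority with the
    genome id as the final tie-break; each new representative absorbs every
    unassigned genome at ANI >= threshold (missing ANI counts as below).
    """
    if set(priority) != set(ani.ids):
        raise ValidationError("priority keys must match ANI matrix ids exactly")
    order = sorted(ani.ids, key=lambda g: (tuple(-x for x in priority[g]), g))
    idx = {g: i for i, g in enumerate(ani.ids)}
    unassigned = set(ani.ids)
    clusters = []
    for rep in order:
        if rep not in unassigned:
            continue
        unassigned.discard(rep)
        members = [rep]
        row = ani.values[idx[rep]]
        for g in sorted(unassigned):
            val = row[idx[g]]
            if not np.isnan(val) and val >= threshold:
                members.append(g)
        for g in members[1:]:
            unassigned.discard(g)
        clusters.append(Cluster(rep, tuple(sorted(members))))
    return SpeciesClustering(tuple(clusters), threshold)


def expand_dataset(
    clustering: SpeciesClustering,
    ani: ANIMatrix,
    dereplication_threshold: float = DEFAULT_DEREP_THRESHOLD,
) -> tuple[str, ...]:
    """Representatives plus members strictly below the dereplication ANI.

    A member at ANI 98.9 to its representative is distinct enough to keep;
    one at 99.0 or above is treated as a near-duplicate and dropped.
    """
    idx = {g: i for i, g in enumerate(ani.ids)}
    expanded = []
    for cluster in clustering.clusters:
        for g in cluster.members:
            if g == cluster.representative:
                expanded.append(g)
                continue
            val = ani.values[idx[g], idx[cluster.representative]]
            if np.isnan(val) or val < dereplication_threshold:
                expanded.append(g)
    return tuple(sorted(expanded))
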