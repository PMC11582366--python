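"""Marker-gene inventories and anchored / family-specific marker-set derivation.

A marker set is a collection of genes expected in single copy across a
taxonomic group; the fraction of them observed in a draft genome is the
standard completeness estimate. That estimate is only as good as the set it
is scored against: genes genuinely absent from an entire lineage deflate
completeness and inflate genome-size estimates for every member of that
lineage. This module recalibrates a reference marker set against a closed
"anchor" isolate genome (removing markers the anchor demonstrably lacks),
screens a genome collection for additional lineage-wide ("systematic")
absences, and derives family-specific marker sets from them.

Absence semantics: a copy count of zero and a missing key are treated
identically — the hit tables this module consumes do not distinguish
"not searched" from "absent".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ParseError, ValidationError

ABSENT_FROM_ANCHOR = "absent-from-anchor"
SYSTEMATIC_ABSENCE = "systematic-absence(family)"

#: Default prevalence below which a marker is called systematically absent.
#: Strict '<'; tolerates rare spurious hits in incomplete genomes while
#: rejecting genuinely retained markers.
DEFAULT_PREVALENCE_THRESHOLD = 0.10


@dataclass(frozen=True)
class MarkerSet:
    """An ordered set of single-copy marker gene identifiers.

    ``excluded`` records every marker removed from ``parent_set_id`` together
    with the reason, so the provenance of a derived set is auditable.
    """

    set_id: str
    markers: tuple[str, ...]
    parent_set_id: str | None = None
    excluded: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError(f"marker set {self.set_id!r}: duplicate marker ids")
        overlap = set(self.markers) & {m for m, _ in self.excluded}
        if overlap:
            raise ValidationError(
                f"marker set {self.set_id!r}: markers also listed as excluded: {sorted(overlap)}"
            )

    def __len__(self) -> int:
        return len(self.markers)

    def __contains__(self, marker: str) -> bool:
        return marker in set(self.markers)

    def __iter__(self) -> Iterator[str]:
        return iter(self.markers)

    @property
    def excluded_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.excluded)

    @property
    def all_ids(self) -> frozenset[str]:
        """Markers plus excluded ids (the parent universe, when derived)."""
        return frozenset(self.markers) | frozenset(self.excluded_ids)


@dataclass(frozen=True)
class MarkerProfile:
    """Per-genome marker copy counts. Zero-copy entries are dropped."""

    genome_id: str
    copies: Mapping[str, int]

    def __post_init__(self):
        for marker, n in self.copies.items():
            if n < 0:
                raise ValidationError(
                    f"genome {self.genome_id!r}: negative copy count for {marker!r}"
                )
        cleaned = {m: int(n) for m, n in self.copies.items() if n > 0}
        object.__setattr__(self, "copies", cleaned)

    def count(self, marker: str) -> int:
        return self.copies.get(marker, 0)

    @property
    def present(self) -> frozenset[str]:
        return frozenset(self.copies)


@dataclass(frozen=True)
class MarkerMatrix:
    """A genome x marker copy-number inventory over a shared marker universe."""

    profiles: Mapping[str, MarkerProfile]
    marker_universe: MarkerSet

    def __post_init__(self):
        universe = self.marker_universe.all_ids
        for gid, profile in self.profiles.items():
            if gid != profile.genome_id:
                raise ValidationError(f"profile key {gid!r} != genome_id {profile.genome_id!r}")
            unknown = profile.present - universe
            if unknown:
                raise ValidationError(
                    f"genome {gid!r}: markers outside the universe: {sorted(unknown)[:5]}"
                )

    @classmethod
    def from_profiles(
        cls, profiles: Iterable[MarkerProfile], universe: MarkerSet | None = None
    ) -> "MarkerMatrix":
        plist = list(profiles)
        ids = [p.genome_id for p in plist]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate genome ids in profiles")
        if universe is None:
            seen = sorted(set().union(*(p.present for p in plist)) if plist else set())
            universe = MarkerSet("observed", tuple(seen))
        return cls({p.genome_id: p for p in plist}, universe)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    @property
    def n_genomes(self) -> int:
        return len(self.profiles)

    def __getitem__(self, genome_id: str) -> MarkerProfile:
        return self.profiles[genome_id]

    def subset(self, genome_ids: Iterable[str]) -> "MarkerMatrix":
        wanted = list(genome_ids)
        missing = [g for g in wanted if g not in self.profiles]
        if missing:
            raise ValidationError(f"unknown genome ids: {missing}")
        return MarkerMatrix({g: self.profiles[g] for g in wanted}, self.marker_universe)


@dataclass(frozen=True)
class PrevalenceRecord:
    marker_id: str
    n_genomes_present: int
    prevalence: float
    flagged_systematic: bool


@dataclass(frozen=True)
class PrevalenceReport:
    """Per-marker presence across a genome collection, with systematic flags."""

    records: tuple[PrevalenceRecord, ...]
    n_genomes: int
    threshold: float

    @property
    def flagged_markers(self) -> tuple[str, ...]:
        return tuple(r.marker_id for r in self.records if r.flagged_systematic)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.marker_id, r.n_genomes_present, r.prevalence, r.flagged_systematic)
                for r in self.records
            ],
            columns=["marker_id", "n_genomes_present", "prevalence", "flagged_systematic"],
        )


def load_marker_hits(path: str | Path, universe: MarkerSet | None = None) -> MarkerMatrix:
    """Read a marker-hit TSV (genome_id, marker_id, copies) into a matrix.

    Duplicate (genome, marker) rows are summed, matching common hit-table
    dialects. Raises :class:`ParseError` with the 1-based line number for
    malformed rows and :class:`ValidationError` for negative copy counts.
    """
    counts: dict[str, dict[str, int]] = {}
    order: list[str] = []
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file, expected a header row", line=1)
        expected = ["genome_id", "marker_id", "copies"]
        if [h.strip() for h in header[:3]] != expected:
            raise ParseError(f"expected header columns {expected}, got {header[:3]}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ParseError(f"expected 3 columns, got {len(row)}", line=lineno)
            gid, marker = row[0].strip(), row[1].strip()
            if not gid or not marker:
                raise ParseError("empty genome_id or marker_id", line=lineno)
            try:
                n = int(row[2])
            except ValueError:
                raise ParseError(f"copies {row[2]!r} is not an integer", line=lineno)
            if n < 0:
                raise ValidationError(f"line {lineno}: negative copies for {gid}/{marker}")
            if gid not in counts:
                counts[gid] = {}
                order.append(gid)
            counts[gid][marker] = counts[gid].get(marker, 0) + n
    profiles = [MarkerProfile(g, counts[g]) for g in order]
    return MarkerMatrix.from_profiles(profiles, universe)


def write_marker_set(marker_set: MarkerSet, path: str | Path) -> None:
    """Write a marker set as TSV (set_id, marker_id); excluded markers get a reason column."""
    rows = [(marker_set.set_id, m, "") for m in marker_set.markers]
    rows += [(marker_set.set_id, m, reason) for m, reason in marker_set.excluded]
    pd.DataFrame(rows, columns=["set_id", "marker_id", "excluded_reason"]).to_csv(
        path, sep="\t", index=False
    )


def read_marker_set(path: str | Path) -> MarkerSet:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"set_id", "marker_id"} <= set(frame.columns):
        raise ParseError("marker-set TSV needs columns set_id, marker_id", line=1)
    set_ids = frame["set_id"].unique()
    if len(set_ids) != 1:
        raise ValidationError(f"expected a single set_id, got {list(set_ids)}")
    if "excluded_reason" not in frame.columns:
        frame["excluded_reason"] = ""
    kept = frame[frame["excluded_reason"] == ""]["marker_id"]
    excl = frame[frame["excluded_reason"] != ""][["marker_id", "excluded_reason"]]
    return MarkerSet(
        str(set_ids[0]),
        tuple(kept),
        excluded=tuple(excl.itertuples(index=False, name=None)),
    )


def derive_anchored_set(
    base: MarkerSet, anchor: MarkerProfile, set_id: str | None = None
) -> MarkerSet:
    """Restrict ``base`` to markers present (copy >= 1) in the anchor genome.

    Markers the closed anchor genome lacks cannot be expected in any member
    of its lineage; they are excluded with reason ``absent-from-anchor``.
    Idempotent: anchoring an anchored set on the same anchor is a no-op.
    """
    present = anchor.present
    if not (set(base.markers) & present):
        raise ValidationError(
            f"anchor {anchor.genome_id!r} shares no marker with set {base.set_id!r}"
        )
    kept = tuple(m for m in base.markers if m in present)
    dropped = tuple((m, ABSENT_FROM_ANCHOR) for m in base.markers if m not in present)
    return MarkerSet(
        set_id or f"{base.set_id}-anchored-{anchor.genome_id}",
        kept,
        parent_set_id=base.set_id,
        excluded=dropped,
    )


def prevalence_screen(
    matrix: MarkerMatrix,
    markers: Iterable[str],
    threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
    completeness: Mapping[str, float] | None = None,
) -> PrevalenceReport:
    """Fraction of genomes carrying each marker; flag those below ``threshold``.

    Flagging is strict (< threshold), so a threshold of 0 flags nothing.
    When ``completeness`` (per-genome fractions in (0, 1]) is given, raw
    prevalence is divided by the mean completeness (capped at 1) to correct
    for dropout in incomplete genomes; the default is the uncorrected count.
    """
    if matrix.n_genomes < 1:
        raise ValidationError("prevalence_screen needs at least one genome")
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    wanted = list(markers)
    unknown = [m for m in wanted if m not in matrix.marker_universe.all_ids]
    if unknown:
        raise ValidationError(f"markers outside the matrix universe: {unknown}")
    scale = 1.0
    if completeness is not None:
        vals = [completeness[g] for g in matrix.genome_ids]
        mean_c = sum(vals) / len(vals)
        if mean_c <= 0:
            raise ValidationError("mean completeness must be positive")
        scale = 1.0 / mean_c
    records = []
    n = matrix.n_genomes
    for m in wanted:
        hits = sum(1 for p in matrix.profiles.values() if p.count(m) >= 1)
        prev = min(1.0, (hits / n) * scale)
        records.append(PrevalenceRecord(m, hits, prev, prev < threshold))
    return PrevalenceReport(tuple(records), n, threshold)


def derive_family_set(
    base: MarkerSet,
    family_matrix: MarkerMatrix,
    threshold: float = DEFAULT_PREVALENCE_THRESHOLD,
    set_id: str | None = None,
    completeness: Mapping[str, float] | None = None,
) -> MarkerSet:
    """Drop markers systematically absent from a family's genomes.

    Screens every marker of ``base`` (not only anchor-absent ones): lineages
    typically lose more markers than their anchor alone reveals. Exclusions
    are recorded with reason ``systematic-absence(family)``.
    """
    if family_matrix.n_genomes == 0:
        raise ValidationError("family matrix is empty")
    report = prevalence_screen(family_matrix, base.markers, threshold, completeness)
    flagged = set(report.flagged_markers)
    kept = tuple(m for m in base.markers if m not in flagged)
    dropped = tuple((m, SYSTEMATIC_ABSENCE) for m in base.markers if m in flagged)
    return MarkerSet(
        set_id or f"{base.set_id}-family",
        kept,
        parent_set_id=base.set_id,
        excluded=dropped,
    )


def aggregate_copy_number(
    matrix: MarkerMatrix, taxon_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Mean copies per genome of each marker within each taxon.

    Returns a taxon x marker DataFrame; absent markers count as zero, so
    cell (t, m) = sum of copies over the taxon's genomes / taxon size.
    """
    unlabeled = [g for g in matrix.genome_ids if g not in taxon_labels]
    if unlabeled:
        raise ValidationError(f"genomes without a taxon label: {unlabeled}")
    cols = list(matrix.marker_universe.markers)
    groups: dict[str, list[str]] = {}
    for g in matrix.genome_ids:
        groups.setdefault(taxon_labels[g], []).append(g)
    data = {
        taxon: [
            sum(matrix[g].count(m) for g in members) / len(members) for m in cols
        ]
        for taxon, members in sorted(groups.items())
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
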