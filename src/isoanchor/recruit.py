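"""Detection-thresholded relative abundances from read-recruitment summaries.

The input boundary is a per-sample, per-genome mapping summary (mapped
reads, covered reference positions, genome length, total sample reads);
competitive read mapping itself happens upstream. Two quantities are
derived per cell:

* detection — the fraction of the genome's positions covered by at least
  one read (breadth of coverage). Low breadth with non-trivial read counts
  is the signature of spurious recruitment to conserved regions, so
  abundance is zeroed wherever detection falls below a threshold
  (default 0.25).
* relative abundance — the percent of the sample's total reads recruited
  to the genome. A coverage-normalized mode (mean depth) is available
  behind a flag for users who prefer length-corrected values.

Genome abundances roll up additively to genus, family, and order, and are
averaged over depth bins (left-closed, right-open, last bin closed) and
ocean regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_DETECTION = 0.25
DEFAULT_DEPTH_BINS = (0.0, 100.0, 200.0, 300.0)

SUMMARY_COLUMNS = [
    "sample_id",
    "genome_id",
    "mapped_reads",
    "covered_positions",
    "genome_length",
    "total_sample_reads",
    "depth_m",
    "region",
]


@dataclass(frozen=True)
class MappingSummary:
    """One sample x genome read-recruitment record."""

    sample_id: str
    genome_id: str
    mapped_reads: int
    covered_positions: int
    genome_length: int
    total_sample_reads: int
    depth_m: float | None = None
    region: str | None = None

    def __post_init__(self):
        if self.covered_positions > self.genome_length:
            raise ValidationError(
                f"{self.sample_id}/{self.genome_id}: covered positions exceed genome length"
            )
        if self.mapped_reads > self.total_sample_reads:
            raise ValidationError(
                f"{self.sample_id}/{self.genome_id}: mapped reads exceed total sample reads"
            )
        if min(self.mapped_reads, self.covered_positions, self.total_sample_reads) < 0:
            raise ValidationError("counts must be non-negative")
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")


def detection(covered_positions: int, genome_length: int) -> float:
    """Breadth of coverage: fraction of genome positions covered at least once."""
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    if covered_positions > genome_length:
        raise ValidationError("covered positions exceed genome length")
    if covered_positions < 0:
        raise ValidationError("covered positions must be non-negative")
    return covered_positions / genome_length


def relative_abundance(
    summary: MappingSummary,
    min_detection: float = DEFAULT_MIN_DETECTION,
    mode: str = "percent_reads",
) -> float:
    """Percent of sample reads recruited, zeroed below the detection threshold.

    ``mode="coverage"`` returns mean depth (mapped bases are approximated as
    reads x genome-length-normalized units, i.e. reads / genome length,
    scaled by 100) instead; the detection gate applies in both modes.
    Set ``min_detection=0`` to report raw (ungated) values.
    """
    if summary.total_sample_reads <= 0:
        raise ValidationError("total_sample_reads must be positive")
    det = detection(summary.covered_positions, summary.genome_length)
    if det < min_detection:
        return 0.0
    if mode == "percent_reads":
        return 100.0 * summary.mapped_reads / summary.total_sample_reads
    if mode == "coverage":
        return 100.0 * summary.mapped_reads / summary.genome_length
    raise ValidationError(f"unknown abundance mode {mode!r}")


@dataclass(frozen=True)
class AbundanceTable:
    """Per-sample per-genome relative abundances with detection fractions."""

    abundance: pd.DataFrame  # index samples, columns genomes, percent
    detection: pd.DataFrame  # same shape, fractions in [0, 1]
    min_detection: float

    def __post_init__(self):
        if not self.abundance.index.equals(self.detection.index) or not (
            self.abundance.columns.equals(self.detection.columns)
        ):
            raise ValidationError("abundance and detection frames must align")
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("abundances must be non-negative")
        if (self.abundance.sum(axis=1) > 100.0 + 1e-9).any():
            raise ValidationError("abundances exceed 100% in some sample")


def abundance_table(
    summaries: Iterable[MappingSummary],
    min_detection: float = DEFAULT_MIN_DETECTION,
    mode: str = "percent_reads",
) -> AbundanceTable:
    """Build the sample x genome abundance/detection matrices."""
    rows = []
    for s in summaries:
        rows.append(
            (
                s.sample_id,
                s.genome_id,
                relative_abundance(s, min_detection, mode),
                detection(s.covered_positions, s.genome_length),
            )
        )
    frame = pd.DataFrame(rows, columns=["sample_id", "genome_id", "abundance", "detection"])
    ab = frame.pivot_table(
        index="sample_id", columns="genome_id", values="abundance", fill_value=0.0
    )
    det = frame.pivot_table(
        index="sample_id", columns="genome_id", values="detection", fill_value=0.0
    )
    return AbundanceTable(ab, det.reindex_like(ab), min_detection)


def aggregate_taxa(
    table: AbundanceTable,
    taxonomy: Mapping[str, tuple[str, str, str]],
) -> pd.DataFrame:
    """Sum genome abundances up to genus, family, and order per sample.

    ``taxonomy`` maps genome -> (genus, family, order). Order abundance is
    the sum over family abundances, which is the sum over genus abundances,
    so the rollup is additively consistent by construction. Returns a tidy
    frame (sample_id, level, taxon, abundance).
    """
    unlabeled = [g for g in table.abundance.columns if g not in taxonomy]
    if unlabeled:
        raise ValidationError(f"genomes without taxonomy labels: {unlabeled}")
    tidy = []
    for level, pick in (("genus", 0), ("family", 1), ("order", 2)):
        groups = table.abundance.T.groupby(
            lambda g: taxonomy[g][pick]
        ).sum().T  # samples x taxa
        for taxon in groups.columns:
            for sample, value in groups[taxon].items():
                tidy.append((sample, level, taxon, float(value)))
    return pd.DataFrame(tidy, columns=["sample_id", "level", "taxon", "abundance"])


def _bin_label(lo: float, hi: float, last: bool) -> str:
    close = "]" if last else ")"
    return f"[{lo:g},{hi:g}{close}"


def assign_depth_bin(depth: float, bins: Sequence[float]) -> str | None:
    """Half-open [lo, hi) bins; the last bin is closed on the right."""
    edges = list(bins)
    for i in range(len(edges) - 1):
        last = i == len(edges) - 2
        if edges[i] <= depth < edges[i + 1] or (last and depth == edges[i + 1]):
            return _bin_label(edges[i], edges[i + 1], last)
    return None


def depth_region_summary(
    taxon_table: pd.DataFrame,
    sample_metadata: pd.DataFrame,
    depth_bins: Sequence[float] = DEFAULT_DEPTH_BINS,
    by_region: bool = False,
) -> pd.DataFrame:
    """Mean taxon abundance per depth bin (and per region), with per-cell n.

    ``taxon_table`` is the tidy output of :func:`aggregate_taxa`;
    ``sample_metadata`` needs columns sample_id, depth_m (and region when
    ``by_region``). Samples lacking a depth (or falling outside the bins)
    are excluded with a logged warning, not an error.
    """
    edges = list(depth_bins)
    if len(edges) < 2 or any(lo >= hi for lo, hi in zip(edges, edges[1:])):
        raise ValidationError("depth bins must be strictly increasing edges")
    meta = sample_metadata.set_index("sample_id")
    if by_region and "region" not in meta.columns:
        raise ValidationError("by_region requires a 'region' column")
    assignments = {}
    for sample in taxon_table["sample_id"].unique():
        if sample not in meta.index or pd.isna(meta.loc[sample, "depth_m"]):
            logger.warning("sample %s has no depth; excluded from depth summary", sample)
            continue
        label = assign_depth_bin(float(meta.loc[sample, "depth_m"]), edges)
        if label is None:
            logger.warning("sample %s depth outside bins; excluded", sample)
            continue
        assignments[sample] = label
    frame = taxon_table[taxon_table["sample_id"].isin(assignments)].copy()
    frame["depth_bin"] = frame["sample_id"].map(assignments)
    keys = ["depth_bin", "level", "taxon"]
    if by_region:
        frame["region"] = frame["sample_id"].map(meta["region"])
        keys = ["region"] + keys
    out = (
        frame.groupby(keys)["abundance"]
        .agg(mean_abundance="mean", n="count")
        .reset_index()
    )
    return out


def read_mapping_summaries(path: str | Path) -> list[MappingSummary]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        depth = d.get("depth_m")
        region = d.get("region")
        out.append(
            MappingSummary(
                sample_id=str(d["sample_id"]),
                genome_id=str(d["genome_id"]),
                mapped_reads=int(d["mapped_reads"]),
                covered_positions=int(d["covered_positions"]),
                genome_length=int(d["genome_length"]),
                total_sample_reads=int(d["total_sample_reads"]),
                depth_m=None if depth is None or (isinstance(depth, float) and math.isnan(depth)) else float(depth),
                region=None if region is None or (isinstance(region, float) and math.isnan(region)) else str(region),
            )
        )
    return out


def write_mapping_summaries(summaries: Iterable[MappingSummary], path: str | Path) -> None:
    rows = [
        (
            s.sample_id,
            s.genome_id,
            s.mapped_reads,
            s.covered_positions,
            s.genome_length,
            s.total_sample_reads,
            s.depth_m,
            s.region,
        )
        for s in summaries
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def summaries_from_sam(
    sam_path: str | Path,
    sample_id: str,
    total_sample_reads: int,
    depth_m: float | None = None,
    region: str | None = None,
) -> list[MappingSummary]:
    """Derive mapping summaries from a SAM text file (header required).

    Counts primary alignments only (secondary/supplementary flags skipped);
    covered positions come from the union of aligned reference spans per
    reference sequence.
    """
    import pysam

    covered: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for ref, length in zip(sam.references, sam.lengths):
            lengths[ref] = length
            covered[ref] = np.zeros(length, dtype=bool)
            counts[ref] = 0
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            ref = read.reference_name
            counts[ref] += 1
            covered[ref][read.reference_start : read.reference_end] = True
    return [
        MappingSummary(
            sample_id=sample_id,
            genome_id=ref,
            mapped_reads=counts[ref],
            covered_positions=int(covered[ref].sum()),
            genome_length=lengths[ref],
            total_sample_reads=total_sample_reads,
            depth_m=depth_m,
            region=region,
        )
        for ref in lengths
    ]
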