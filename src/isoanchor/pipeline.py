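"""End-to-end analysis pipeline over a genome-collection input bundle.

Stages, in order (later stages are skipped when their inputs are absent):

1. markers — anchor the base marker set on the closed isolate, then derive
   a corrected set per family by prevalence-screening the family's
   *environmental* genomes (the anchor is excluded from screening: a single
   closed genome would mask genuine lineage-wide absences).
2. qc — completeness/contamination per genome against its family's
   corrected set (the anchored set when a genome has no family label),
   completeness-corrected size estimates, and pass/fail filtering.
3. cluster — sketch-ANI matrix over QC-passing genomes, greedy species
   clustering, and the dereplication-expanded genome set.
4. red — relative evolutionary distance on the full input tree (computed
   before any QC pruning, so deep-node depth normalization is unaffected by
   which genomes pass) and RED-interval rank assignment.
5. recruit — detection-gated relative abundances, taxon rollups, and
   depth-bin summaries from read-mapping summaries.
6. stats — Kruskal-Wallis plus Dunn post-hoc comparisons of estimated
   genome size and %GC across families (QC-passing genomes only).

Every run writes a ``manifest.yaml`` listing inputs, parameters, stages
run, and output files. The manifest contains no timestamps or hostnames:
two runs on identical inputs produce identical output trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ani as ani_mod
from . import markers as mk
from . import qc as qc_mod
from . import recruit as rc
from . import red as red_mod
from . import stats as st
from .errors import IsoanchorError, StageError, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("markers", "qc", "cluster", "red", "recruit", "stats")


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Required inputs: ``marker_hits``, ``marker_universe``, ``metadata``.
    ``sequences`` (FASTA) enables the cluster stage, ``tree`` the red stage,
    and ``mapping_summaries`` the recruit stage. The anchor genome is named
    explicitly or found via an ``is_anchor`` column in the metadata.
    """

    marker_hits: Path
    marker_universe: Path
    metadata: Path
    out_dir: Path
    sequences: Path | None = None
    tree: Path | None = None
    mapping_summaries: Path | None = None
    anchor_id: str | None = None
    prevalence_threshold: float = mk.DEFAULT_PREVALENCE_THRESHOLD
    min_completeness: float = qc_mod.DEFAULT_MIN_COMPLETENESS
    max_contamination: float = qc_mod.DEFAULT_MAX_CONTAMINATION
    kmer_size: int = ani_mod.DEFAULT_K
    sketch_size: int = ani_mod.DEFAULT_SKETCH_SIZE
    species_threshold: float = ani_mod.DEFAULT_SPECIES_THRESHOLD
    derep_threshold: float = ani_mod.DEFAULT_DEREP_THRESHOLD
    rank_intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(red_mod.DEFAULT_RANK_INTERVALS)
    )
    min_detection: float = rc.DEFAULT_MIN_DETECTION
    depth_bins: tuple[float, ...] = rc.DEFAULT_DEPTH_BINS
    order_label: str = "order"
    alpha: float = 0.05

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, out_dir: str | Path, **overrides) -> "RunConfig":
        """Point a run at a directory produced by :func:`isoanchor.simulate.simulate_bundle`."""
        b = Path(bundle_dir)

        def _opt(name: str) -> Path | None:
            p = b / name
            return p if p.exists() else None

        return cls(
            marker_hits=b / "marker_hits.tsv",
            marker_universe=b / "marker_universe.tsv",
            metadata=b / "metadata.tsv",
            out_dir=Path(out_dir),
            sequences=_opt("sequences.fasta"),
            tree=_opt("tree.nwk"),
            mapping_summaries=_opt("mapping_summaries.tsv"),
            **overrides,
        )

    def parameters(self) -> dict:
        return {
            "anchor_id": self.anchor_id,
            "prevalence_threshold": self.prevalence_threshold,
            "min_completeness": self.min_completeness,
            "max_contamination": self.max_contamination,
            "kmer_size": self.kmer_size,
            "sketch_size": self.sketch_size,
            "species_threshold": self.species_threshold,
            "derep_threshold": self.derep_threshold,
            "rank_intervals": {r: list(v) for r, v in self.rank_intervals.items()},
            "min_detection": self.min_detection,
            "depth_bins": list(self.depth_bins),
            "order_label": self.order_label,
            "alpha": self.alpha,
        }


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    stages_run: list[str]
    anchored_set: mk.MarkerSet | None = None
    family_sets: dict[str, mk.MarkerSet] | None = None
    qc_results: list[qc_mod.QCResult] | None = None
    passed_ids: list[str] | None = None
    ani_matrix: ani_mod.ANIMatrix | None = None
    clustering: ani_mod.SpeciesClustering | None = None
    red_table: red_mod.REDTable | None = None
    rank_assignment: red_mod.RankAssignment | None = None
    abundance: rc.AbundanceTable | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _find_anchor(config: RunConfig, meta_frame: pd.DataFrame) -> str:
    if config.anchor_id is not None:
        if config.anchor_id not in set(meta_frame["genome_id"].astype(str)):
            raise ValidationError(f"anchor {config.anchor_id!r} not in metadata")
        return config.anchor_id
    if "is_anchor" in meta_frame.columns:
        anchors = meta_frame.loc[meta_frame["is_anchor"].astype(bool), "genome_id"]
        if len(anchors) == 1:
            return str(anchors.iloc[0])
        raise ValidationError(
            f"metadata marks {len(anchors)} anchor genomes; expected exactly 1"
        )
    raise ValidationError("no anchor_id given and metadata has no is_anchor column")


def run_pipeline(config: RunConfig) -> RunResult:
    """Run all applicable stages; raise :class:`StageError` on the first failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(out_dir=out, stages_run=[])

    # ---- stage: markers -------------------------------------------------
    stage = "markers"
    try:
        logger.info("stage markers: loading inputs")
        universe = mk.read_marker_set(config.marker_universe)
        matrix = mk.load_marker_hits(config.marker_hits, universe)
        records = qc_mod.read_metadata(config.metadata)
        meta_frame = pd.read_csv(config.metadata, sep="\t")
        anchor_id = _find_anchor(config, meta_frame)
        if anchor_id not in matrix.profiles:
            raise ValidationError(f"anchor {anchor_id!r} has no marker profile")
        anchored = mk.derive_anchored_set(universe, matrix[anchor_id], set_id="anchored")
        families = sorted(
            {r.family for r in records.values() if r.family is not None}
        )
        family_sets: dict[str, mk.MarkerSet] = {}
        for fam in families:
            env_ids = [
                g
                for g, r in records.items()
                if r.family == fam and g != anchor_id and g in matrix.profiles
            ]
            if not env_ids:
                logger.info("family %s has no environmental genomes; using anchored set", fam)
                family_sets[fam] = anchored
                continue
            family_sets[fam] = mk.derive_family_set(
                anchored,
                matrix.subset(env_ids),
                threshold=config.prevalence_threshold,
                set_id=f"anchored-{fam}",
            )
        mk.write_marker_set(anchored, out / "anchored_set.tsv")
        for fam, fset in family_sets.items():
            mk.write_marker_set(fset, out / f"marker_set_{fam}.tsv")
        result.anchored_set = anchored
        result.family_sets = family_sets
        result.outputs["anchored_set"] = out / "anchored_set.tsv"
        result.stages_run.append(stage)
        logger.info(
            "anchored set: %d of %d markers kept; %d family sets derived",
            len(anchored), len(universe), len(family_sets),
        )
    except IsoanchorError as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: qc -------------------------------------------------------
    stage = "qc"
    try:
        qc_results: list[qc_mod.QCResult] = []
        for gid in matrix.genome_ids:
            rec = records.get(gid)
            fam = rec.family if rec is not None else None
            marker_set = family_sets.get(fam, anchored)
            qc_results.extend(
                qc_mod.evaluate_qc(
                    matrix.subset([gid]),
                    marker_set,
                    records,
                    config.min_completeness,
                    config.max_contamination,
                )
            )
        passed, failed = qc_mod.qc_filter(
            qc_results, config.min_completeness, config.max_contamination
        )
        frame = qc_mod.qc_results_to_frame(qc_results)
        frame.to_csv(out / "qc.tsv", sep="\t", index=False)
        qc_mod.summarize_by_taxon(records, qc_results, level="family").to_csv(
            out / "family_summary.tsv", sep="\t"
        )
        result.qc_results = qc_results
        result.passed_ids = [r.genome_id for r in passed]
        result.outputs["qc"] = out / "qc.tsv"
        result.outputs["family_summary"] = out / "family_summary.tsv"
        result.stages_run.append(stage)
        logger.info("qc: %d passed, %d failed", len(passed), len(failed))
    except IsoanchorError as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: cluster --------------------------------------------------
    if config.sequences is not None:
        stage = "cluster"
        try:
            seqs = qc_mod.read_fasta(config.sequences)
            usable = [g for g in result.passed_ids if g in seqs]
            if len(usable) < 2:
                raise ValidationError("cluster stage needs >= 2 QC-passing genomes with sequences")
            sketches = {
                g: ani_mod.kmer_sketch(seqs[g], config.kmer_size, config.sketch_size)
                for g in usable
            }
            ani_matrix = ani_mod.ANIMatrix.from_sketches(sketches, config.kmer_size)
            priority = ani_mod.quality_priority(
                [r for r in qc_results if r.genome_id in set(usable)], records
            )
            clustering = ani_mod.cluster_species(
                ani_matrix, priority, config.species_threshold
            )
            expanded = ani_mod.expand_dataset(clustering, ani_matrix, config.derep_threshold)
            clustering = ani_mod.SpeciesClustering(
                clustering.clusters, clustering.threshold, expanded
            )
            ani_matrix.write_tsv(out / "ani.tsv")
            clustering.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
            result.ani_matrix = ani_matrix
            result.clustering = clustering
            result.outputs["ani"] = out / "ani.tsv"
            result.outputs["clusters"] = out / "clusters.tsv"
            result.stages_run.append(stage)
            logger.info(
                "cluster: %d species clusters, %d genomes in expanded set",
                len(clustering.clusters), len(expanded),
            )
        except IsoanchorError as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- stage: red --------------------------------------------------------
    if config.tree is not None:
        stage = "red"
        try:
            tree = red_mod.read_newick(config.tree)
            red_table = red_mod.compute_red(tree)
            ranks = red_mod.assign_ranks(red_table, tree, config.rank_intervals)
            red_table.to_frame().to_csv(out / "red.tsv", sep="\t", index=False)
            ranks.to_frame().to_csv(out / "ranks.tsv", sep="\t", index=False)
            result.red_table = red_table
            result.rank_assignment = ranks
            result.outputs["red"] = out / "red.tsv"
            result.outputs["ranks"] = out / "ranks.tsv"
            result.stages_run.append(stage)
            logger.info("red: rank counts %s", ranks.counts)
        except IsoanchorError as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- stage: recruit ----------------------------------------------------
    if config.mapping_summaries is not None:
        stage = "recruit"
        try:
            summaries = rc.read_mapping_summaries(config.mapping_summaries)
            table = rc.abundance_table(summaries, config.min_detection)
            taxonomy = {}
            for gid in table.abundance.columns:
                rec = records.get(gid)
                if rec is None or rec.genus is None or rec.family is None:
                    raise ValidationError(f"genome {gid!r} lacks genus/family labels")
                taxonomy[gid] = (rec.genus, rec.family, config.order_label)
            tidy = rc.aggregate_taxa(table, taxonomy)
            sample_meta = (
                pd.DataFrame(
                    [
                        (s.sample_id, s.depth_m, s.region)
                        for s in summaries
                    ],
                    columns=["sample_id", "depth_m", "region"],
                )
                .drop_duplicates("sample_id")
            )
            depth_summary = rc.depth_region_summary(
                tidy, sample_meta, config.depth_bins, by_region=True
            )
            table.abundance.to_csv(out / "abundance.tsv", sep="\t")
            tidy.to_csv(out / "taxon_abundance.tsv", sep="\t", index=False)
            depth_summary.to_csv(out / "depth_summary.tsv", sep="\t", index=False)
            result.abundance = table
            result.outputs["abundance"] = out / "abundance.tsv"
            result.outputs["taxon_abundance"] = out / "taxon_abundance.tsv"
            result.outputs["depth_summary"] = out / "depth_summary.tsv"
            result.stages_run.append(stage)
            logger.info("recruit: %d samples", table.abundance.shape[0])
        except IsoanchorError as exc:
            raise StageError(stage, str(exc)) from exc

    # ---- stage: stats ------------------------------------------------------
    stage = "stats"
    try:
        by_family_size: dict[str, list[float]] = {}
        by_family_gc: dict[str, list[float]] = {}
        for r in qc_results:
            if not r.passed or r.estimated_size_bp is None:
                continue
            rec = records.get(r.genome_id)
            if rec is None or rec.family is None:
                continue
            by_family_size.setdefault(rec.family, []).append(r.estimated_size_bp)
            by_family_gc.setdefault(rec.family, []).append(rec.gc_percent)
        stats_out = {}
        if len(by_family_size) >= 2:
            for name, data in (("estimated_size_bp", by_family_size), ("gc_percent", by_family_gc)):
                omnibus, pairwise = st.compare_groups(data, config.alpha)
                stats_out[name] = {
                    "H": omnibus.H,
                    "df": omnibus.df,
                    "p": omnibus.p,
                }
                if pairwise is not None:
                    pairwise.to_csv(out / f"dunn_{name}.tsv", sep="\t", index=False)
                    result.outputs[f"dunn_{name}"] = out / f"dunn_{name}.tsv"
            with open(out / "stats.yaml", "w") as fh:
                yaml.safe_dump(stats_out, fh, sort_keys=True)
            result.outputs["stats"] = out / "stats.yaml"
            result.stages_run.append(stage)
            logger.info("stats: %s", {k: round(v["p"], 4) for k, v in stats_out.items()})
        else:
            logger.info("stats: fewer than 2 labeled families; skipped")
    except IsoanchorError as exc:
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "pipeline": "isoanchor",
        "stages_run": result.stages_run,
        "inputs": {
            "marker_hits": str(config.marker_hits),
            "marker_universe": str(config.marker_universe),
            "metadata": str(config.metadata),
            "sequences": None if config.sequences is None else str(config.sequences),
            "tree": None if config.tree is None else str(config.tree),
            "mapping_summaries": (
                None if config.mapping_summaries is None else str(config.mapping_summaries)
            ),
        },
        "parameters": {**config.parameters(), "anchor_id": anchor_id},
        "outputs": {k: str(v) for k, v in sorted(result.outputs.items())},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    result.outputs["manifest"] = out / "manifest.yaml"
    return result
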