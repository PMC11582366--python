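"""Synthetic genome-collection generator with fully known ground truth.

Every input the analysis pipeline consumes can be generated here with the
answers recorded: a rooted taxonomy tree whose family- and genus-level
nodes sit in disjoint relative-depth bands; marker inventories with an
anchor-absent loss set plus additional family-conserved losses; incomplete
genomes produced by subsampling markers and genes at a known completeness;
genome sequences diverged along the tree at a planted per-site divergence
ladder; and read-recruitment tables with planted taxon abundances and a
depth gradient (three surface-enriched families and one deep-enriched one).

All generators are pure functions of (config, seed): the same seed yields
byte-identical outputs. Independent random streams are derived per stage so
changing one stage's parameters does not reshuffle another's draws.

What this emulates — and what it does not: marker dropout is i.i.d. per
marker (an optional "block" mode drops a contiguous chromosomal arc
instead, closer to single-cell assembly dropout); sequence evolution is
i.i.d. substitution with no indels, rate heterogeneity or recombination;
read recruitment is multinomial with Poisson-breadth coverage, with no
read-level errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .markers import MarkerMatrix, MarkerProfile, MarkerSet, write_marker_set
from .qc import GenomeRecord, METADATA_COLUMNS
from .recruit import MappingSummary, write_mapping_summaries
from .red import parse_newick

_STREAMS = ("taxonomy", "markers", "completeness", "sequences", "recruitment")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator. Defaults mirror the study structure:

    a 280-marker universe with 28 anchor-absent markers (so the anchored set
    has 252), four families with (10, 4, 4, 4) genera (22 in total), family
    loss totals of 28 + extra in the 29-52 range, completeness concentrated
    around ~89%, one higher-GC family, and recruitment totals in the
    2-6 percent range with one family enriched at depth.
    """

    seed: int = 0
    n_families: int = 4
    genera_per_family: tuple[int, ...] = (10, 4, 4, 4)
    genomes_per_genus: int = 3
    marker_universe_size: int = 280
    anchor_missing: int = 28
    family_extra_losses: tuple[int, ...] = (12, 24, 11, 1)
    duplication_rate: float = 0.005
    # completeness: Beta(alpha, beta) rescaled onto [min, max]
    completeness_alpha: float = 5.0
    completeness_beta: float = 2.0
    completeness_min: float = 0.6
    completeness_max: float = 1.0
    dropout_mode: str = "iid"  # or "block": drop a contiguous chromosomal arc
    true_length_mean: float = 1.3e6
    true_length_sd: float = 0.15e6
    gc_anchor_family_mean: float = 36.3
    gc_anchor_family_sd: float = 0.5
    gc_other_mean: float = 34.5
    gc_other_sd: float = 1.0
    # ultrametric node-depth bands; on an ultrametric tree RED equals
    # relative depth, so these bands are also the planted RED bands
    family_depth_band: tuple[float, float] = (0.30, 0.50)
    genus_depth_band: tuple[float, float] = (0.70, 0.85)
    # per-site divergence ladder (total pairwise, per pair class)
    within_genus_divergence: float = 0.02
    within_family_divergence: float = 0.10
    between_family_divergence: float = 0.25
    sequence_length: int = 30000
    # recruitment design
    regions: tuple[str, ...] = ("NorthAtlantic", "SouthPacific", "Mediterranean")
    sample_depths: tuple[float, ...] = (5.0, 50.0, 90.0, 150.0, 250.0)
    samples_per_condition: int = 3
    total_sample_reads: int = 10_000_000
    read_length: int = 150
    surface_total_percent: float = 4.5
    deep_total_percent: float = 2.5  # at 300 m
    mediterranean_boost: float = 1.3
    family_surface_shares: tuple[float, ...] = (0.50, 0.12, 0.25, 0.13)
    family_depth_gradients: tuple[float, ...] = (-0.8, -0.7, -0.6, 1.2)  # per 100 m
    genus_dirichlet_concentration: float = 1.0

    def __post_init__(self):
        if self.n_families < 1:
            raise ValidationError("need at least one family")
        for name in ("genera_per_family", "family_extra_losses",
                     "family_surface_shares", "family_depth_gradients"):
            if len(getattr(self, name)) != self.n_families:
                raise ValidationError(f"{name} must have {self.n_families} entries")
        if any(g < 1 for g in self.genera_per_family):
            raise ValidationError("every family needs at least one genus")
        if self.n_families >= 2 and any(g < 2 for g in self.genera_per_family[:-1]):
            raise ValidationError(
                "families without the anchor need >= 2 genera (no unary tree nodes)"
            )
        if self.genomes_per_genus < 2:
            raise ValidationError("genomes_per_genus must be >= 2 (no unary tree nodes)")
        if self.anchor_missing >= self.marker_universe_size:
            raise ValidationError("anchor_missing must be below the universe size")
        if any(x < 0 for x in self.family_extra_losses):
            raise ValidationError("family extra losses must be >= 0")
        if self.anchor_missing + max(self.family_extra_losses) > self.marker_universe_size:
            raise ValidationError("family losses exceed the marker universe")
        if not 0 < self.completeness_min <= self.completeness_max <= 1:
            raise ValidationError("completeness range must satisfy 0 < min <= max <= 1")
        if self.dropout_mode not in ("iid", "block"):
            raise ValidationError("dropout_mode must be 'iid' or 'block'")
        fb, gb = self.family_depth_band, self.genus_depth_band
        if not (0 < fb[0] < fb[1] <= gb[0] < gb[1] < 1):
            raise ValidationError("depth bands must be ordered and disjoint within (0,1)")
        if not (0 <= self.within_genus_divergence
                < self.within_family_divergence
                < self.between_family_divergence < 0.75):
            raise ValidationError("divergence ladder must be strictly increasing below 0.75")
        if self.sequence_length < 1:
            raise ValidationError("sequence length must be positive")

    @property
    def family_names(self) -> tuple[str, ...]:
        return tuple(f"F{i + 1}" for i in range(self.n_families))

    @property
    def anchor_family(self) -> str:
        return self.family_names[-1]

    @property
    def anchor_genus(self) -> str:
        return f"{self.anchor_family}G00"


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


ANCHOR_ID = "anchor"


def simulate_taxonomy(config: SimulationConfig) -> tuple["object", pd.DataFrame]:
    """Rooted ultrametric tree with planted family/genus nodes, plus labels.

    Family nodes sit at depths in ``family_depth_band`` and genus nodes in
    ``genus_depth_band`` with all leaves at depth 1, so node RED equals node
    depth exactly and the planted ranks occupy disjoint RED bands. The
    anchor genome is a basal leaf of the last family. With a single family
    the root stands in for its (otherwise unary) family node, so the minimal
    1-family/1-genus/2-genome tree is root -> (genus node, anchor leaf).
    """
    rng = _rng(config, "taxonomy")
    label_rows = []
    family_clauses = []
    for fi, fam in enumerate(config.family_names):
        fam_depth = rng.uniform(*config.family_depth_band)
        genus_clauses = []
        for gi in range(config.genera_per_family[fi]):
            genus = f"{fam}G{gi + 1:02d}"
            genus_depth = rng.uniform(*config.genus_depth_band)
            leaves = []
            for si in range(config.genomes_per_genus):
                gid = f"{genus}S{si + 1}"
                leaves.append(f"{gid}:{1.0 - genus_depth:.10f}")
                label_rows.append((gid, genus, fam, False))
            genus_bl = genus_depth - (fam_depth if config.n_families > 1 else 0.0)
            genus_clauses.append(f"({','.join(leaves)}){genus}:{genus_bl:.10f}")
        if fi == config.n_families - 1:
            anchor_bl = 1.0 - (fam_depth if config.n_families > 1 else 0.0)
            genus_clauses.append(f"{ANCHOR_ID}:{anchor_bl:.10f}")
            label_rows.append((ANCHOR_ID, config.anchor_genus, fam, True))
        if config.n_families > 1:
            family_clauses.append(f"({','.join(genus_clauses)}){fam}:{fam_depth:.10f}")
        else:
            # single family: the root stands in for the family node
            family_clauses.append(",".join(genus_clauses))
    newick = f"({','.join(family_clauses)})root;"
    tree = parse_newick(newick)
    labels = pd.DataFrame(
        label_rows, columns=["genome_id", "genus", "family", "is_anchor"]
    )
    return tree, labels


def planted_rank_counts(config: SimulationConfig) -> dict[str, int]:
    """Number of family and genus internal nodes the taxonomy tree contains."""
    n_fam = config.n_families if config.n_families > 1 else 0
    return {"family": n_fam, "genus": sum(config.genera_per_family)}


def simulate_marker_inventories(
    labels: pd.DataFrame, config: SimulationConfig
) -> tuple[MarkerMatrix, dict]:
    """Complete ("true") marker inventories with planted lineage losses.

    One fixed anchor-absent set is lost from every genome including the
    anchor; each family additionally loses ``family_extra_losses`` markers
    in all its environmental genomes (the anchor, being a basal closed
    genome, retains them). Retained markers are single copy, with a small
    duplication rate planting copy-2 entries.
    """
    rng = _rng(config, "markers")
    universe_ids = tuple(f"M{i + 1:04d}" for i in range(config.marker_universe_size))
    universe = MarkerSet(f"base-{config.marker_universe_size}", universe_ids)
    anchor_absent = sorted(
        universe_ids[i]
        for i in rng.choice(config.marker_universe_size, config.anchor_missing, replace=False)
    )
    retained_pool = [m for m in universe_ids if m not in set(anchor_absent)]
    family_extra: dict[str, list[str]] = {}
    for fi, fam in enumerate(config.family_names):
        k = config.family_extra_losses[fi]
        extra = sorted(
            retained_pool[i] for i in rng.choice(len(retained_pool), k, replace=False)
        )
        family_extra[fam] = extra
    family_losses = {
        fam: sorted(set(anchor_absent) | set(family_extra[fam]))
        for fam in config.family_names
    }
    profiles = []
    for row in labels.itertuples(index=False):
        if row.is_anchor:
            present = [m for m in universe_ids if m not in set(anchor_absent)]
            profiles.append(MarkerProfile(row.genome_id, {m: 1 for m in present}))
            continue
        lost = set(family_losses[row.family])
        present = [m for m in universe_ids if m not in lost]
        dup = rng.random(len(present)) < config.duplication_rate
        profiles.append(
            MarkerProfile(
                row.genome_id,
                {m: (2 if d else 1) for m, d in zip(present, dup)},
            )
        )
    matrix = MarkerMatrix.from_profiles(profiles, universe)
    losses = {
        "anchor_absent": anchor_absent,
        "family_extra": family_extra,
        "family_losses": family_losses,
    }
    return matrix, losses


def simulate_incomplete_genomes(
    true_matrix: MarkerMatrix,
    labels: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[MarkerMatrix, dict[str, GenomeRecord], dict[str, float], dict[str, float]]:
    """Subsample each genome to a drawn completeness; emit observed inventories.

    For each environmental genome a completeness c is drawn from the
    configured Beta rescaled onto [min, max]; markers are retained i.i.d.
    with probability c (or within a contiguous arc of length c in "block"
    mode), genes binomially, and the assembly length is the true length
    times the retained gene fraction. The anchor stays complete (closed).
    Returns (observed matrix, metadata records, planted completeness,
    planted true lengths).
    """
    rng = _rng(config, "completeness")
    universe_ids = true_matrix.marker_universe.markers
    marker_pos = {m: p for m, p in zip(universe_ids, rng.random(len(universe_ids)))}
    profiles = []
    records: dict[str, GenomeRecord] = {}
    completeness: dict[str, float] = {}
    true_length: dict[str, float] = {}
    for row in labels.itertuples(index=False):
        gid = row.genome_id
        tlen = float(np.clip(rng.normal(config.true_length_mean, config.true_length_sd),
                             0.4e6, None))
        n_genes = max(1, int(round(tlen / 1000.0)))
        if row.is_anchor:
            c = 1.0
        else:
            span = config.completeness_max - config.completeness_min
            c = config.completeness_min + span * float(
                rng.beta(config.completeness_alpha, config.completeness_beta)
            )
        true_profile = true_matrix[gid]
        if c >= 1.0:
            kept = dict(true_profile.copies)
            retained_genes = n_genes
        else:
            markers = sorted(true_profile.copies)
            if config.dropout_mode == "iid":
                keep_mask = rng.random(len(markers)) < c
            else:
                offset = rng.random()
                keep_mask = np.array(
                    [((marker_pos[m] - offset) % 1.0) < c for m in markers]
                )
            kept = {m: true_profile.copies[m] for m, k in zip(markers, keep_mask) if k}
            retained_genes = int(rng.binomial(n_genes, c))
            retained_genes = max(retained_genes, 1)
        assembly_length = tlen * retained_genes / n_genes
        is_anchor_family = row.family == config.anchor_family
        gc_mean = config.gc_anchor_family_mean if is_anchor_family else config.gc_other_mean
        gc_sd = config.gc_anchor_family_sd if is_anchor_family else config.gc_other_sd
        gc = float(np.clip(rng.normal(gc_mean, gc_sd), 0.0, 100.0))
        profiles.append(MarkerProfile(gid, kept))
        records[gid] = GenomeRecord(
            genome_id=gid,
            assembly_length=assembly_length,
            gc_percent=gc,
            n_genes=retained_genes,
            family=row.family,
            genus=row.genus,
        )
        completeness[gid] = c
        true_length[gid] = tlen
    observed = MarkerMatrix.from_profiles(profiles, true_matrix.marker_universe)
    return observed, records, completeness, true_length


def compose_divergence(p: float, q: float) -> float:
    """Per-site difference probability after two independent branches.

    Mutations go to one of the three other bases uniformly, so two branch
    difference probabilities p and q compose to p + q - (4/3) p q.
    """
    return p + q - (4.0 / 3.0) * p * q


def mutate_sequence(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p to a uniformly chosen other base."""
    mask = rng.random(codes.size) < p
    out = codes.copy()
    out[mask] = (codes[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return out


def decode_sequence(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode_sequence(rng.integers(0, 4, length, dtype=np.uint8))


def _branch_rates(config: SimulationConfig) -> tuple[float, float, float]:
    """Per-branch substitution probabilities (leaf, genus, family) such that
    the three pair classes reach the configured total divergences
    approximately (small-rate additive inversion)."""
    r_leaf = config.within_genus_divergence / 2.0
    r_genus = config.within_family_divergence / 2.0 - r_leaf
    r_family = config.between_family_divergence / 2.0 - r_leaf - r_genus
    if min(r_leaf, r_genus, r_family) < 0:
        raise ValidationError("divergence ladder yields a negative branch rate")
    return r_leaf, r_genus, r_family


def expected_ani_classes(config: SimulationConfig) -> dict[str, float]:
    """Planted expected ANI (percent) for the three pair classes."""
    r_l, r_g, r_f = _branch_rates(config)
    wg = compose_divergence(r_l, r_l)
    wf = compose_divergence(compose_divergence(r_l, r_g), compose_divergence(r_g, r_l))
    bf = compose_divergence(
        compose_divergence(compose_divergence(r_l, r_g), r_f),
        compose_divergence(r_f, compose_divergence(r_g, r_l)),
    )
    return {
        "within_genus": 100.0 * (1.0 - wg),
        "within_family": 100.0 * (1.0 - wf),
        "between_family": 100.0 * (1.0 - bf),
    }


def expected_pair_ani(labels: pd.DataFrame, config: SimulationConfig, a: str, b: str) -> float:
    """Planted expected ANI between two named genomes."""
    classes = expected_ani_classes(config)
    row = labels.set_index("genome_id")
    if a == b:
        return 100.0
    if row.loc[a, "genus"] == row.loc[b, "genus"]:
        return classes["within_genus"]
    if row.loc[a, "family"] == row.loc[b, "family"]:
        return classes["within_family"]
    return classes["between_family"]


def simulate_sequences(
    labels: pd.DataFrame, config: SimulationConfig
) -> tuple[dict[str, str], dict[str, float]]:
    """Evolve one sequence per genome along the family/genus/leaf hierarchy.

    A root sequence accumulates i.i.d. substitutions along family, genus,
    and leaf branches at rates inverted from the configured divergence
    ladder. The anchor evolves from its family ancestor over a genus- plus
    leaf-rate path, like any other genome. Returns the sequences and the
    planted expected ANI per pair class.
    """
    rng = _rng(config, "sequences")
    r_leaf, r_genus, r_family = _branch_rates(config)
    root = rng.integers(0, 4, config.sequence_length, dtype=np.uint8)
    sequences: dict[str, str] = {}
    for fam in config.family_names:
        fam_codes = mutate_sequence(root, r_family, rng)
        fam_rows = labels[labels["family"] == fam]
        for genus in sorted(fam_rows["genus"].unique()):
            genus_rows = fam_rows[fam_rows["genus"] == genus]
            if genus_rows["is_anchor"].all():
                # the anchor hangs off the family node directly
                anchor_codes = mutate_sequence(
                    mutate_sequence(fam_codes, r_genus, rng), r_leaf, rng
                )
                sequences[ANCHOR_ID] = decode_sequence(anchor_codes)
                continue
            genus_codes = mutate_sequence(fam_codes, r_genus, rng)
            for gid in genus_rows["genome_id"]:
                sequences[gid] = decode_sequence(mutate_sequence(genus_codes, r_leaf, rng))
    return sequences, expected_ani_classes(config)


def simulate_recruitment(
    labels: pd.DataFrame,
    records: Mapping[str, GenomeRecord],
    config: SimulationConfig,
) -> tuple[list[MappingSummary], dict]:
    """Multinomial read recruitment over a depth x region sample grid.

    Per sample, the order-level total declines linearly from the surface
    value to the deep value at 300 m (boosted in the Mediterranean);
    family shares follow share_f * exp(gradient_f * depth / 100 m),
    renormalized; genus shares within a family are one Dirichlet draw
    (shared across samples, so some genera dominate); genomes split a genus
    evenly. Mapped reads are multinomial and covered positions follow the
    Poisson breadth L (1 - exp(-coverage)).
    """
    rng = _rng(config, "recruitment")
    genus_share: dict[str, float] = {}
    fam_genera: dict[str, list[str]] = {}
    for fam in config.family_names:
        genera = sorted(labels.loc[labels["family"] == fam, "genus"].unique())
        fam_genera[fam] = genera
        shares = rng.dirichlet(
            np.full(len(genera), config.genus_dirichlet_concentration)
        )
        for genus, s in zip(genera, shares):
            genus_share[genus] = float(s)
    genus_members = {
        genus: list(labels.loc[labels["genus"] == genus, "genome_id"])
        for genus in genus_share
    }
    genomes = list(labels["genome_id"])
    lengths = np.array([int(round(records[g].assembly_length)) for g in genomes])
    summaries: list[MappingSummary] = []
    expected_family: dict[str, dict[str, float]] = {}
    for region in config.regions:
        boost = config.mediterranean_boost if "editerranean" in region else 1.0
        for depth in config.sample_depths:
            frac = min(depth / 300.0, 1.0)
            total_pct = boost * (
                config.surface_total_percent
                + (config.deep_total_percent - config.surface_total_percent) * frac
            )
            weights = np.array(
                [
                    share * np.exp(grad * depth / 100.0)
                    for share, grad in zip(
                        config.family_surface_shares, config.family_depth_gradients
                    )
                ]
            )
            if weights.sum() > 0:
                fam_pct = total_pct * weights / weights.sum()
            else:
                fam_pct = np.zeros_like(weights)
            genome_pct = {}
            for fam, pct in zip(config.family_names, fam_pct):
                for genus in fam_genera[fam]:
                    members = genus_members[genus]
                    for gid in members:
                        genome_pct[gid] = pct * genus_share[genus] / len(members)
            probs = np.array([genome_pct[g] / 100.0 for g in genomes])
            rest = max(0.0, 1.0 - probs.sum())
            for rep in range(config.samples_per_condition):
                sample_id = f"{region}-{int(depth)}m-r{rep + 1}"
                draws = rng.multinomial(
                    config.total_sample_reads, np.append(probs, rest)
                )[: len(genomes)]
                coverage = draws * config.read_length / lengths
                covered = np.minimum(
                    lengths, np.round(lengths * (1.0 - np.exp(-coverage)))
                ).astype(int)
                expected_family[sample_id] = {
                    fam: float(p) for fam, p in zip(config.family_names, fam_pct)
                }
                for gid, n_reads, cov_pos, length in zip(
                    genomes, draws, covered, lengths
                ):
                    summaries.append(
                        MappingSummary(
                            sample_id=sample_id,
                            genome_id=gid,
                            mapped_reads=int(n_reads),
                            covered_positions=int(cov_pos),
                            genome_length=int(length),
                            total_sample_reads=config.total_sample_reads,
                            depth_m=float(depth),
                            region=region,
                        )
                    )
    truth = {
        "genus_share": genus_share,
        "expected_family_abundance": expected_family,
        "gradients": {
            fam: g
            for fam, g in zip(config.family_names, config.family_depth_gradients)
        },
    }
    return summaries, truth


def _pyify(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {_pyify(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def simulate_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full input bundle plus its ground truth.

    Emits tree.nwk, marker_universe.tsv, marker_hits.tsv, metadata.tsv,
    sequences.fasta, mapping_summaries.tsv, and ground_truth.yaml under
    ``out_dir`` and returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree, labels = simulate_taxonomy(config)
    true_matrix, losses = simulate_marker_inventories(labels, config)
    observed, records, completeness, true_length = simulate_incomplete_genomes(
        true_matrix, labels, config
    )
    sequences, ani_classes = simulate_sequences(labels, config)
    summaries, recruit_truth = simulate_recruitment(labels, records, config)

    paths = {name: out / fname for name, fname in [
        ("tree", "tree.nwk"),
        ("marker_universe", "marker_universe.tsv"),
        ("marker_hits", "marker_hits.tsv"),
        ("metadata", "metadata.tsv"),
        ("sequences", "sequences.fasta"),
        ("mapping_summaries", "mapping_summaries.tsv"),
        ("ground_truth", "ground_truth.yaml"),
    ]}
    from .red import write_newick

    paths["tree"].write_text(write_newick(tree) + "\n")
    write_marker_set(observed.marker_universe, paths["marker_universe"])
    hit_rows = [
        (gid, m, n)
        for gid in observed.genome_ids
        for m, n in sorted(observed[gid].copies.items())
    ]
    pd.DataFrame(hit_rows, columns=["genome_id", "marker_id", "copies"]).to_csv(
        paths["marker_hits"], sep="\t", index=False
    )
    meta = pd.DataFrame(
        [
            (
                r.genome_id, r.assembly_length, r.gc_percent, r.n_genes,
                r.family, r.genus, r.depth_m, r.region,
            )
            for r in records.values()
        ],
        columns=METADATA_COLUMNS,
    )
    meta["is_anchor"] = [gid == ANCHOR_ID for gid in records]
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    with open(paths["sequences"], "w") as fh:
        for gid in sorted(sequences):
            fh.write(f">{gid}\n")
            seq = sequences[gid]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_mapping_summaries(summaries, paths["mapping_summaries"])
    truth = {
        "anchor_id": ANCHOR_ID,
        "planted_rank_counts": planted_rank_counts(config),
        "taxonomy": {
            row.genome_id: {"genus": row.genus, "family": row.family}
            for row in labels.itertuples(index=False)
        },
        "anchor_absent": losses["anchor_absent"],
        "family_extra": losses["family_extra"],
        "family_losses": losses["family_losses"],
        "completeness": completeness,
        "true_length": true_length,
        "expected_ani": ani_classes,
        "genus_share": recruit_truth["genus_share"],
        "expected_family_abundance": recruit_truth["expected_family_abundance"],
        "gradients": recruit_truth["gradients"],
        "config": asdict(config),
    }
    with open(paths["ground_truth"], "w") as fh:
        yaml.safe_dump(_pyify(truth), fh, sort_keys=True)
    return paths


def load_ground_truth(bundle_dir: str | Path) -> dict:
    with open(Path(bundle_dir) / "ground_truth.yaml") as fh:
        return yaml.safe_load(fh)


def validate_bundle(bundle_dir: str | Path) -> bool:
    """Re-check that emitted files agree with the emitted ground truth."""
    from .markers import load_marker_hits, read_marker_set
    from .qc import read_metadata
    from .recruit import read_mapping_summaries

    bundle = Path(bundle_dir)
    truth = load_ground_truth(bundle)
    universe = read_marker_set(bundle / "marker_universe.tsv")
    matrix = load_marker_hits(bundle / "marker_hits.tsv", universe)
    records = read_metadata(bundle / "metadata.tsv")
    anchor_id = truth["anchor_id"]
    expected_anchor = set(universe.markers) - set(truth["anchor_absent"])
    if set(matrix[anchor_id].present) != expected_anchor:
        raise ValidationError("anchor profile disagrees with planted anchor-absent set")
    for gid, tax in truth["taxonomy"].items():
        if gid not in records:
            raise ValidationError(f"genome {gid} missing from metadata")
        if records[gid].family != tax["family"] or records[gid].genus != tax["genus"]:
            raise ValidationError(f"taxonomy mismatch for {gid}")
        if gid == anchor_id:
            continue
        losses = set(truth["family_losses"][tax["family"]])
        if matrix[gid].present & losses:
            raise ValidationError(f"{gid} carries a marker planted as lost")
    summaries = read_mapping_summaries(bundle / "mapping_summaries.tsv")
    sample_totals: dict[str, float] = {}
    for s in summaries:
        sample_totals[s.sample_id] = (
            sample_totals.get(s.sample_id, 0.0)
            + 100.0 * s.mapped_reads / s.total_sample_reads
        )
    if any(v > 100.0 + 1e-9 for v in sample_totals.values()):
        raise ValidationError("recruitment exceeds 100% of a sample's reads")
    if set(sample_totals) != set(truth["expected_family_abundance"]):
        raise ValidationError("sample grid disagrees with ground truth")
    return True
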