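"""Sketch-ANI species clustering and dataset expansion.

Genome sequences are reduced to MinHash bottom sketches, pairwise ANI is
estimated from sketch Jaccard similarity, and genomes are greedily
clustered into species at ANI >= 93% with the best-quality genome of each
cluster as representative. The expanded set then adds back members below
99% ANI to their representative: near-duplicates are dropped, distinct
within-species diversity is retained.

Run: python examples/02_species_clustering.py
"""

import tempfile
from pathlib import Path

import isoanchor as ia
from isoanchor.ani import ANIMatrix, cluster_species, expand_dataset, kmer_sketch, quality_priority
from isoanchor.markers import load_marker_hits, read_marker_set
from isoanchor.qc import evaluate_qc, read_fasta, read_metadata

workdir = Path(tempfile.mkdtemp(prefix="isoanchor-example-"))
bundle = workdir / "bundle"
ia.simulate_bundle(ia.SimulationConfig(seed=0), bundle)

seqs = read_fasta(bundle / "sequences.fasta")
records = read_metadata(bundle / "metadata.tsv")
universe = read_marker_set(bundle / "marker_universe.tsv")
matrix = load_marker_hits(bundle / "marker_hits.tsv", universe)

print(f"sketching {len(seqs)} genomes ...")
sketches = {g: kmer_sketch(s) for g, s in seqs.items()}
ani = ANIMatrix.from_sketches(sketches)

qc = evaluate_qc(matrix, universe, records)
clustering = cluster_species(ani, quality_priority(qc, records))
expanded = expand_dataset(clustering, ani)

print(f"{len(clustering.clusters)} species clusters from {len(seqs)} genomes")
for cluster in clustering.clusters[:5]:
    genus = records[cluster.representative].genus
    print(f"  rep {cluster.representative} (genus {genus}): "
          f"{len(cluster.members)} members")
print(f"expanded set keeps {len(expanded)} genomes "
      f"(members < 99% ANI to their representative)")
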