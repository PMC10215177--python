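"""mitophylo: mitogenome characterization and distance-based phylogenetics.

Parse annotated mitochondrial genomes, compute base composition and AT/GC
skews, codon usage and RSCU under the vertebrate mitochondrial code, build
p / TN93 / maximum-composite-likelihood distance matrices with
neighbor-joining trees and bootstrap support, and compare specimen
morphometrics against species reference ranges — with a synthetic-data
module providing ground-truthed inputs for every stage.
"""

from importlib.resources import files
from pathlib import Path

__version__ = "0.1.0"

from .annotation import (  # noqa: F401
    GeneFeature, MitoGenome, extract_gene, read_feature_table, read_genbank,
)
from .composition import (  # noqa: F401
    CompositionReport, at_skew, class_totals, composition, gc_skew,
)
from .codons import count_codons, identify_codons, rscu  # noqa: F401
from .alignment import Alignment, concatenate, read_fasta_alignment  # noqa: F401
from .distances import (  # noqa: F401
    DistanceMatrix, mcl_distances, p_distance, p_distances, tn93_distance,
    tn93_distances,
)
from .njtree import PhyloTree, bootstrap_support, neighbor_joining  # noqa: F401
from .simulate import SimConfig, evolve_sequences, simulate_tree, synth_genome  # noqa: F401
from .morpho import MorphoRecord, ReferenceRange, range_check  # noqa: F401


def bundled_annotation_path() -> Path:
    """Packaged genome-organization table of the steppe whiskered bat
    mitogenome (GenBank OK053029), sequence-free with published per-gene
    base compositions."""
    return Path(str(files("mitophylo.data") / "aurascens_mitogenome_features.tsv"))
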