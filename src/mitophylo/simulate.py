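"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all driven by one seed through independent child streams
(adding a stage never perturbs the draws of an earlier one):

* :func:`simulate_tree` — random unrooted binary topologies, uniform over
  the (2n-5)!! labelled topologies, with branch lengths drawn uniformly
  from a configured range;
* :func:`evolve_sequences` — gap-free alignments evolved along a tree under
  TN93 (root drawn from the stationary frequencies, per-edge substitution
  via the closed-form transition matrices), with optional post-hoc gap
  masking to exercise pairwise deletion;
* :func:`synth_genome` — an annotated circular mitogenome with the canonical
  gene inventory (13 PCGs, 22 tRNAs, 2 rRNAs, 1 control region), both
  strands, and PCGs whose declared start/stop codons — including truncated
  ``TA-``/``T--`` stops — are consistent with their sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .annotation import GeneFeature, MitoGenome, PCG_NAMES, reverse_complement
from .codons import VERTEBRATE_MITO_TABLE_ID
from .model import BASE_ORDER, TN93Model
from .njtree import PhyloTree, _quote

__all__ = ["SimConfig", "simulate_tree", "evolve_sequences", "synth_genome",
           "mask_gaps"]

_TRNA_AAS = (
    "Phe", "Val", "Leu1", "Leu2", "Ile", "Gln", "Met", "Trp", "Ala", "Asn",
    "Cys", "Tyr", "Ser1", "Ser2", "Asp", "Lys", "Gly", "Arg", "His", "Glu",
    "Thr", "Pro",
)
# non-stop codons under the vertebrate mitochondrial code (DNA alphabet)
_STOPS_DNA = ("TAA", "TAG", "AGA", "AGG")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in _STOPS_DNA
)
_START_CODONS = ("ATG", "ATA", "ATT")


@dataclass(frozen=True)
class SimConfig:
    """Shared configuration for the synthetic generators.

    Branch lengths are in expected substitutions per site.  The TN93
    parameters default to mammalian-mitogenome-like values: AT-rich,
    G-poor frequencies and strong transition bias.
    """

    seed: int = 0
    n_taxa: int = 6
    branch_length_range: tuple[float, float] = (0.02, 0.2)
    seq_length: int = 10_000
    pi: tuple[float, float, float, float] = (0.34, 0.22, 0.13, 0.31)
    kappa1: float = 8.0
    kappa2: float = 8.0
    gap_rate: float = 0.0
    # genome layout
    n_pcg: int = 13
    n_trna: int = 22
    n_rrna: int = 2
    n_control: int = 1
    l_strand_trna: int = 8
    incomplete_stop_fraction: float = 0.3
    genetic_code: int = VERTEBRATE_MITO_TABLE_ID

    def __post_init__(self):
        lo, hi = self.branch_length_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid branch length range")
        if abs(sum(self.pi) - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ValueError("rates must be positive")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")

    def model(self) -> TN93Model:
        return TN93Model(pi=self.pi, kappa1=self.kappa1, kappa2=self.kappa2)

    def streams(self) -> dict[str, np.random.Generator]:
        """Named child RNG streams off the root seed, one per stage."""
        root = np.random.SeedSequence(self.seed)
        tree_ss, seq_ss, genome_ss, gap_ss = root.spawn(4)
        return {
            "tree": np.random.default_rng(tree_ss),
            "sequences": np.random.default_rng(seq_ss),
            "genome": np.random.default_rng(genome_ss),
            "gaps": np.random.default_rng(gap_ss),
        }


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "label", "length")

    def __init__(self, label=None):
        self.children: list[_Node] = []
        self.label = label
        self.length: float = 0.0

    def newick(self) -> str:
        if not self.children:
            return f"{_quote(self.label)}:{self.length:.10g}"
        inner = ",".join(c.newick() for c in self.children)
        return (f"({inner}):{self.length:.10g}" if self.label is None
                else f"({inner}){self.label}:{self.length:.10g}")


def _random_topology(
    n_taxa: int, rng: np.random.Generator
) -> tuple[_Node, list[tuple[_Node, _Node]]]:
    """Uniform random unrooted binary topology via sequential edge insertion.

    Returns the basal trifurcation node and the (parent, child) edge list.
    Inserting each new leaf into a uniformly chosen existing edge makes every
    one of the (2n-5)!! labelled topologies equally likely.
    """
    root = _Node()
    leaves = [_Node(f"t{i + 1}") for i in range(n_taxa)]
    root.children = leaves[:3]
    edges: list[tuple[_Node, _Node]] = [(root, c) for c in root.children]
    for leaf in leaves[3:]:
        parent, child = edges[rng.integers(0, len(edges))]
        mid = _Node()
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, leaf]
        edges.remove((parent, child))
        edges.extend([(parent, mid), (mid, child), (mid, leaf)])
    return root, edges


def topology_signature(root: _Node) -> frozenset:
    """Canonical label of an unrooted topology: its set of non-trivial splits."""
    all_leaves: set[str] = set()

    def leafset(node: _Node) -> frozenset:
        if not node.children:
            all_leaves.add(node.label)
            return frozenset([node.label])
        return frozenset().union(*(leafset(c) for c in node.children))

    below = {}

    def collect(node: _Node):
        sets = []
        for c in node.children:
            s = leafset(c) if not c.children else collect(c)
            below[id(c)] = s
            sets.append(s)
        return frozenset().union(*sets) if sets else frozenset()

    collect(root)
    total = leafset(root)
    ref = min(total)
    splits = set()
    for s in below.values():
        side = total - s if ref in s else s
        if 2 <= len(side) <= len(total) - 2:
            splits.add(side)
    return frozenset(splits)


def simulate_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Random unrooted binary tree on ``cfg.n_taxa`` labelled leaves.

    Topology uniform over the (2n-5)!! unrooted labelled topologies (random
    edge insertion); every edge length an independent uniform draw from
    ``cfg.branch_length_range``.  Leaf labels are ``t1 .. tn``.
    """
    if cfg.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = rng if rng is not None else cfg.streams()["tree"]
    root, edges = _random_topology(cfg.n_taxa, rng)
    lo, hi = cfg.branch_length_range
    for _, child in edges:
        child.length = float(rng.uniform(lo, hi))
    inner = ",".join(c.newick() for c in root.children)
    return PhyloTree.from_newick(f"({inner});")


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequences(
    tree: PhyloTree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> Alignment:
    """Evolve a gap-free alignment along ``tree`` under the TN93 model.

    The root sequence is drawn from the stationary frequencies; each edge
    applies the closed-form transition matrix for its length, site by site
    (sites are iid — no rate heterogeneity, no indels).  Set
    ``cfg.gap_rate > 0`` and call :func:`mask_gaps` to exercise
    pairwise-deletion code paths.
    """
    rng = rng if rng is not None else cfg.streams()["sequences"]
    model = cfg.model()
    L = cfg.seq_length
    states: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    states[id(root)] = rng.choice(4, size=L, p=model.pi_array)
    rows: dict[str, str] = {}
    decode = np.array(list(BASE_ORDER))
    for node in tree.tree.preorder_node_iter():
        if node is root:
            parent_state = states[id(root)]
        else:
            P = model.transition_matrix(node.edge.length or 0.0)
            parent_state = states[id(node.parent_node)]
            child = np.empty(L, dtype=np.int64)
            for s in range(4):
                mask = parent_state == s
                k = int(mask.sum())
                if k:
                    child[mask] = rng.choice(4, size=k, p=P[s])
            states[id(node)] = child
            parent_state = child
        if node.is_leaf():
            rows[node.taxon.label] = "".join(decode[parent_state])
    labels = sorted(rows, key=lambda s: (len(s), s))
    return Alignment(labels=labels, rows=[rows[l] for l in labels])


def mask_gaps(
    aln: Alignment, gap_rate: float, rng: np.random.Generator
) -> Alignment:
    """Replace a random fraction of cells with gaps (post-hoc masking)."""
    if not 0 <= gap_rate < 1:
        raise ValueError("gap_rate must be in [0, 1)")
    mat = aln.matrix.copy()
    mask = rng.random(mat.shape) < gap_rate
    rows = []
    for r, m in zip(aln.rows, mask):
        chars = np.array(list(r))
        chars[m] = "-"
        rows.append("".join(chars))
    return Alignment(labels=list(aln.labels), rows=rows)


# ---------------------------------------------------------------------------
# synthetic annotated genomes
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, pi) -> str:
    return "".join(np.array(list(BASE_ORDER))[rng.choice(4, size=n, p=np.asarray(pi))])


def _random_cds(rng: np.random.Generator, n_codons: int,
                incomplete_stop: bool) -> tuple[str, str, str]:
    """(cds, declared_start, declared_stop_token) for one synthetic PCG."""
    start = _START_CODONS[rng.integers(0, len(_START_CODONS))]
    body = "".join(
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    )
    if incomplete_stop:
        if rng.random() < 0.5:
            return start + body + "TA", start, "TA-"
        return start + body + "T", start, "T--"
    stop = ("TAA", "TAG", "AGA")[rng.integers(0, 3)]
    return start + body + stop, start, stop


def synth_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> MitoGenome:
    """Generate an annotated circular mitogenome emulating the mammalian plan.

    The default layout is 13 PCGs + 22 tRNAs + 2 rRNAs + 1 control region;
    ND6 and ``cfg.l_strand_trna`` tRNAs sit on the L strand (their reverse
    complement is what appears in the genome, so extraction returns the
    coding sense).  PCG start/stop declarations — including truncated stops
    at ``cfg.incomplete_stop_fraction`` — match the embedded sequences.
    """
    rng = rng if rng is not None else cfg.streams()["genome"]
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 1

    def _append(name, fclass, strand, payload, start_codon=None, stop_codon=None):
        nonlocal pos
        genome_piece = (
            reverse_complement(payload) if strand == "L" else payload
        )
        parts.append(genome_piece)
        features.append(GeneFeature(
            name=name, feature_class=fclass, strand=strand,
            start=pos, end=pos + len(payload) - 1,
            declared_start_codon=start_codon, declared_stop_codon=stop_codon,
        ))
        pos += len(payload)
        spacer = int(rng.integers(0, 6))
        if spacer:
            parts.append(_random_bases(rng, spacer, cfg.pi))
            pos += spacer

    l_trna_idx = set(
        rng.choice(cfg.n_trna, size=min(cfg.l_strand_trna, cfg.n_trna),
                   replace=False).tolist()
    )
    trna_names = [f"tRNA-{aa}" for aa in _TRNA_AAS[:cfg.n_trna]]
    pcg_names = list(PCG_NAMES[:cfg.n_pcg])
    rrna_names = ["12S-rRNA", "16S-rRNA"][:cfg.n_rrna]

    # interleave: rRNAs first, then alternate PCGs and tRNAs, control region last
    for name in rrna_names:
        _append(name, "rRNA", "H", _random_bases(rng, int(rng.integers(900, 1650)), cfg.pi))
    ti = 0
    for k, name in enumerate(pcg_names):
        if ti < len(trna_names):
            strand = "L" if ti in l_trna_idx else "H"
            _append(trna_names[ti], "tRNA", strand,
                    _random_bases(rng, int(rng.integers(59, 76)), cfg.pi))
            ti += 1
        n_codons = int(rng.integers(60, 620))
        incomplete = bool(rng.random() < cfg.incomplete_stop_fraction)
        cds, start, stop = _random_cds(rng, n_codons, incomplete)
        strand = "L" if name == "ND6" else "H"
        _append(name, "PCG", strand, cds, start_codon=start, stop_codon=stop)
    while ti < len(trna_names):
        strand = "L" if ti in l_trna_idx else "H"
        _append(trna_names[ti], "tRNA", strand,
                _random_bases(rng, int(rng.integers(59, 76)), cfg.pi))
        ti += 1
    for _ in range(cfg.n_control):
        _append("D-loop", "control_region", "H",
                _random_bases(rng, int(rng.integers(900, 1400)), cfg.pi))

    return MitoGenome(
        identifier=f"synthetic-mitogenome-seed{cfg.seed}",
        sequence="".join(parts),
        is_circular=True,
        features=features,
    )
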