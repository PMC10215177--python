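"""End-to-end orchestration: characterize a genome; distances + NJ over a set.

Thin drivers over the library modules: each run validates its configuration,
executes the stages in order, writes machine-readable reports (TSV, PHYLIP,
Newick) into an output directory, and returns the in-memory results.  Stage
failures are re-raised with the stage name attached so callers (and the CLI)
can report where a run died.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .alignment import Alignment, concatenate, read_fasta_alignment
from .annotation import MitoGenome, PCG_NAMES, extract_gene, read_feature_table, read_genbank
from .codons import count_codons, usage_table
from .composition import class_totals, genome_composition_table
from .distances import combined_triangle_table, write_phylip
from .njtree import ESTIMATORS, bootstrap_support, neighbor_joining

__all__ = ["RunConfig", "PipelineError", "run_characterize", "run_distances"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    ``exclude_genes`` defaults to dropping ND6 from supermatrices — the one
    L-strand protein-coding gene, conventionally excluded from concatenated
    nucleotide analyses for its deviant composition.
    """

    annotation: Optional[Path] = None
    fasta: Optional[Path] = None
    genbank: Optional[Path] = None
    gene_alignments: dict[str, Path] = field(default_factory=dict)
    exclude_genes: set[str] = field(default_factory=lambda: {"ND6"})
    estimators: tuple[str, ...] = ("p", "mcl")
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: Path = Path("results")

    def validate(self) -> None:
        for p in [self.annotation, self.fasta, self.genbank,
                  *self.gene_alignments.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        known = set(PCG_NAMES) | {"12S-rRNA", "16S-rRNA", "D-loop"}
        unknown = {
            g for g in self.exclude_genes
            if g not in known and not g.startswith("tRNA-")
        }
        if unknown:
            raise ValueError(f"excluded genes outside known vocabulary: {unknown}")
        for est in self.estimators:
            if est not in ESTIMATORS:
                raise ValueError(f"unknown estimator {est!r}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("load-genome")
def _load_genome(cfg: RunConfig) -> MitoGenome:
    if cfg.genbank is not None:
        return read_genbank(cfg.genbank)
    if cfg.annotation is not None:
        return read_feature_table(cfg.annotation, fasta=cfg.fasta)
    raise ValueError("config supplies neither an annotation table nor GenBank")


def run_characterize(cfg: RunConfig) -> dict:
    """Characterize one genome: composition table, class totals, codon/RSCU.

    Writes ``composition.tsv``, ``class_totals.tsv`` and (when sequence is
    available) ``codon_usage.tsv`` under ``cfg.out_dir``; returns the frames.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = _load_genome(cfg)

    results: dict = {"genome": genome}
    try:
        comp = genome_composition_table(genome)
        comp.to_csv(out / "composition.tsv", sep="\t", index=False)
        totals = class_totals(genome)
        totals.to_csv(out / "class_totals.tsv", sep="\t")
        results["composition"] = comp
        results["class_totals"] = totals
    except Exception as exc:
        raise PipelineError("composition", exc) from exc

    if genome.sequence is not None:
        try:
            cds = [
                extract_gene(genome, f)
                for f in genome.features_by_class("PCG")
            ]
            usage = count_codons(cds, table_id=2)
            table = usage_table(usage)
            table.to_csv(out / "codon_usage.tsv", sep="\t", index=False)
            results["codon_usage"] = table
        except Exception as exc:
            raise PipelineError("codon-usage", exc) from exc
    logger.info("characterize run complete: %s", out)
    return results


def run_distances(cfg: RunConfig) -> dict:
    """Distances + NJ over per-gene alignments.

    Concatenates the configured gene alignments (honoring exclusions),
    computes one distance matrix per estimator, writes PHYLIP matrices, a
    combined upper/lower-triangle table when exactly two estimators are
    configured, and — for >= 3 taxa — a bootstrapped NJ tree in Newick.
    With only two taxa the tree stage is skipped with a warning.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        genes = {
            name: read_fasta_alignment(path)
            for name, path in cfg.gene_alignments.items()
        }
        supermatrix = concatenate(genes, exclude=cfg.exclude_genes)
    except Exception as exc:
        raise PipelineError("concatenate", exc) from exc

    results: dict = {"alignment": supermatrix}
    matrices = {}
    try:
        for est in cfg.estimators:
            dm = ESTIMATORS[est](supermatrix)
            write_phylip(dm, out / f"distances_{est}.phy")
            matrices[est] = dm
        results["distances"] = matrices
        if len(cfg.estimators) == 2:
            first, second = cfg.estimators
            combined = combined_triangle_table(
                upper=matrices[second], lower=matrices[first]
            )
            combined.to_csv(out / "distances_combined.tsv", sep="\t")
            results["combined_table"] = combined
    except Exception as exc:
        raise PipelineError("distances", exc) from exc

    if supermatrix.n_taxa < 3:
        logger.warning("fewer than 3 taxa: tree stage skipped")
        return results
    try:
        tree = bootstrap_support(
            supermatrix,
            estimator=cfg.estimators[0],
            n_reps=cfg.bootstrap_reps,
            seed=cfg.seed,
        )
        (out / "nj_tree.nwk").write_text(tree.to_newick() + "\n")
        results["tree"] = tree
    except Exception as exc:
        raise PipelineError("nj-bootstrap", exc) from exc
    logger.info("distance run complete: %s", out)
    return results
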