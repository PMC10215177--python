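"""Multiple sequence alignments and gene concatenation (supermatrices)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from .model import BASE_ORDER

__all__ = ["Alignment", "read_fasta_alignment", "concatenate"]

logger = logging.getLogger(__name__)

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("U")] = _ENCODE[ord("u")] = 3


@dataclass
class Alignment:
    """Equal-length gapped nucleotide rows with unique taxon labels.

    ``partition_map`` optionally records, for a concatenated supermatrix, the
    1-based inclusive column range contributed by each gene.
    """

    labels: list[str]
    rows: list[str]
    partition_map: Optional[dict[str, tuple[int, int]]] = None
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 codes: A,C,G,T -> 0..3, anything else 4."""
        if self._matrix is None:
            buf = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_taxa, self.n_sites)
            self._matrix = _ENCODE[buf]
        return self._matrix

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]

    def subsample_columns(self, columns: np.ndarray) -> "Alignment":
        """New alignment from the given column indices (bootstrap resampling)."""
        mat = self.matrix[:, columns]
        decode = np.frombuffer((BASE_ORDER + "-").encode(), dtype=np.uint8)
        rows = [bytes(decode[r]).decode("ascii") for r in mat]
        return Alignment(labels=list(self.labels), rows=rows)

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for label, row in zip(self.labels, self.rows):
                fh.write(f">{label}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i:i + width] + "\n")


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned multi-FASTA file."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not labels:
        raise ValueError(f"{path}: no sequences")
    return Alignment(labels=labels, rows=rows)


def concatenate(
    genes: dict[str, Alignment], exclude: Optional[set[str]] = None
) -> Alignment:
    """Concatenate per-gene alignments into a supermatrix.

    Gene blocks are appended in the given order; taxa missing from a gene are
    filled with gaps (logged).  ``partition_map`` records each gene's 1-based
    inclusive column range.  Pairwise-deletion distance estimators are
    unaffected by the gap fill.
    """
    exclude = exclude or set()
    kept = {name: aln for name, aln in genes.items() if name not in exclude}
    if not kept:
        raise ValueError("no genes left after exclusion")
    all_taxa: list[str] = []
    for aln in kept.values():
        for label in aln.labels:
            if label not in all_taxa:
                all_taxa.append(label)
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in all_taxa}
    pos = 1
    for name, aln in kept.items():
        index = dict(zip(aln.labels, aln.rows))
        for taxon in all_taxa:
            if taxon in index:
                chunks[taxon].append(index[taxon])
            else:
                logger.info("taxon %s missing gene %s: gap-filled", taxon, name)
                chunks[taxon].append("-" * aln.n_sites)
        parts[name] = (pos, pos + aln.n_sites - 1)
        pos += aln.n_sites
    return Alignment(
        labels=all_taxa,
        rows=["".join(chunks[t]) for t in all_taxa],
        partition_map=parts,
    )
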