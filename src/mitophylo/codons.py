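"""Codon iteration, incomplete-stop identification, usage counts and RSCU.

Everything here runs under the vertebrate mitochondrial genetic code (NCBI
translation table 2: AGA/AGG are stops, AUA codes Met, UGA codes Trp), which
explains the ``AGA`` stop printed for Cytb in mammalian mitogenome tables and
the truncated stops (``TA-``, ``T--``) completed by polyadenylation of the
mRNA.

RSCU (relative synonymous codon usage) for codon ``c`` in a synonymous family
of size ``k`` with counts ``n_j``:

    RSCU_c = n_c / ((1/k) * sum_j n_j)

so RSCU = 1 for every member of a uniformly used family and family RSCU
values always sum to ``k`` when the family is used at all.  Following CodonW
conventions, termination codons are excluded from usage counts and trailing
partial codons are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

__all__ = [
    "VERTEBRATE_MITO_TABLE_ID",
    "codon_to_aa",
    "synonymous_families",
    "identify_codons",
    "count_codons",
    "rscu",
    "CodonUsage",
    "RSCUTable",
]

VERTEBRATE_MITO_TABLE_ID = 2

_BASES_RNA = "UCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES_RNA for b in _BASES_RNA
                   for c in _BASES_RNA)


def _dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def codon_to_aa(table_id: int = VERTEBRATE_MITO_TABLE_ID) -> dict[str, str]:
    """Codon (RNA alphabet) -> one-letter amino acid; stops map to ``*``."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = {}
    for codon in ALL_CODONS:
        dna = _dna(codon)
        out[codon] = "*" if dna in table.stop_codons else table.forward_table[dna]
    return out


def synonymous_families(
    table_id: int = VERTEBRATE_MITO_TABLE_ID,
) -> dict[str, tuple[str, ...]]:
    """Amino acid -> tuple of synonymous codons (RNA alphabet), stops under ``*``."""
    fams: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa(table_id).items():
        fams.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(codons)) for aa, codons in fams.items()}


def is_stop(codon: str, table_id: int = VERTEBRATE_MITO_TABLE_ID) -> bool:
    return _dna(codon) in CodonTable.unambiguous_dna_by_id[table_id].stop_codons


@dataclass(frozen=True)
class CodonIdentity:
    """Start/stop identification for one CDS."""

    start_codon: str
    stop_codon_token: str  # "TAA"-style, or "TA-"/"T--" for truncated stops
    n_complete_codons: int
    n_trailing_bases: int


def identify_codons(cds: str) -> CodonIdentity:
    """Identify start codon and (possibly truncated) stop token of a sense CDS.

    The CDS must already read 5'->3' on the coding sense (L-strand genes are
    reverse-complemented upstream).  A length = 0 (mod 3) CDS reports its
    final codon as the stop token; remainders of 2 and 1 report the trailing
    bases padded with dashes (``TA-``, ``T--``), the standard rendering of
    stops completed by polyadenylation.
    """
    cds = _dna(cds)
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon (length {len(cds)})")
    n_complete, trailing = divmod(len(cds), 3)
    if trailing == 0:
        token = cds[-3:]
    else:
        token = cds[n_complete * 3:] + "-" * (3 - trailing)
    return CodonIdentity(
        start_codon=cds[:3],
        stop_codon_token=token,
        n_complete_codons=n_complete,
        n_trailing_bases=trailing,
    )


@dataclass
class CodonUsage:
    """Codon counts (RNA alphabet, all 64 keys) over a set of CDSs."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS}
    )
    genetic_code: int = VERTEBRATE_MITO_TABLE_ID
    n_incomplete: int = 0   # trailing partial codons dropped
    n_stops_excluded: int = 0

    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonUsage") -> "CodonUsage":
        if self.genetic_code != other.genetic_code:
            raise ValueError("cannot add usages under different genetic codes")
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonUsage(
            counts=merged,
            genetic_code=self.genetic_code,
            n_incomplete=self.n_incomplete + other.n_incomplete,
            n_stops_excluded=self.n_stops_excluded + other.n_stops_excluded,
        )


def count_codons(
    genes: list[str], table_id: int = VERTEBRATE_MITO_TABLE_ID
) -> CodonUsage:
    """Count codon usage over sense-strand CDSs.

    Only complete codons are read; a trailing partial codon is dropped and
    tallied in ``n_incomplete``.  A terminal complete stop codon is excluded
    from the usage counts (and tallied separately) — internal codons that
    happen to spell a stop are counted as read.
    """
    usage = CodonUsage(genetic_code=table_id)
    for gene in genes:
        ident = identify_codons(gene)
        dna = _dna(gene)
        codons = [dna[i:i + 3] for i in range(0, ident.n_complete_codons * 3, 3)]
        if ident.n_trailing_bases:
            usage.n_incomplete += 1
        elif codons and is_stop(codons[-1], table_id):
            codons.pop()
            usage.n_stops_excluded += 1
        for codon in codons:
            usage.counts[_rna(codon)] += 1
    return usage


@dataclass(frozen=True)
class RSCUTable:
    """RSCU values plus family assignment per codon."""

    rscu: dict[str, float]
    amino_acid: dict[str, str]
    family_size: dict[str, int]

    def n_preferred(self, threshold: float = 1.0) -> int:
        """Number of codons used more than expected (RSCU > threshold)."""
        return sum(1 for v in self.rscu.values() if v > threshold)


def rscu(usage: CodonUsage) -> RSCUTable:
    """Relative synonymous codon usage of a :class:`CodonUsage`.

    Stop codons are excluded.  A family whose total count is zero has RSCU 0
    for all members (the undefined 0/0 case, by convention).
    """
    fams = synonymous_families(usage.genetic_code)
    aa_of = codon_to_aa(usage.genetic_code)
    values: dict[str, float] = {}
    family_size: dict[str, int] = {}
    for aa, codons in fams.items():
        if aa == "*":
            continue
        k = len(codons)
        total = sum(usage.counts[c] for c in codons)
        for c in codons:
            family_size[c] = k
            values[c] = (usage.counts[c] * k / total) if total > 0 else 0.0
    return RSCUTable(
        rscu=values,
        amino_acid={c: aa_of[c] for c in values},
        family_size=family_size,
    )


def usage_table(usage: CodonUsage):
    """Long-form DataFrame ``codon aa count rscu`` (stops carry rscu = NaN)."""
    import pandas as pd

    table = rscu(usage)
    aa_of = codon_to_aa(usage.genetic_code)
    rows = [
        {
            "codon": c,
            "aa": aa_of[c],
            "count": usage.counts[c],
            "rscu": round(table.rscu[c], 4) if c in table.rscu else float("nan"),
        }
        for c in ALL_CODONS
    ]
    return pd.DataFrame(rows)
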