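"""Annotated mitochondrial genomes: data model, parsers, and gene extraction.

The central object is :class:`MitoGenome` — a (usually circular) nucleotide
sequence plus an ordered list of :class:`GeneFeature` annotations in the
1-based inclusive coordinate convention used by GenBank and by published
genome-organization tables.  Genomes can be loaded from GenBank flat files
(via Biopython) or from a plain tab-separated feature table, optionally
accompanied by a FASTA sequence; a sequence-free mode carries per-feature
base-composition percentages instead, so published annotation tables can be
analyzed without the underlying record.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneFeature",
    "MitoGenome",
    "FeatureTableError",
    "CoordinateError",
    "read_feature_table",
    "read_genbank",
    "write_feature_table",
    "extract_gene",
    "normalize_gene_name",
    "PCG_NAMES",
]

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

#: The 13 protein-coding genes of a vertebrate mitogenome, canonical spelling.
PCG_NAMES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COX1", "COX2", "COX3", "ATP6", "ATP8", "Cytb",
)

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


class FeatureTableError(ValueError):
    """Malformed feature-table input."""


class CoordinateError(ValueError):
    """Feature coordinates inconsistent with the genome they annotate."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Alternate spellings seen in GenBank records and published tables, mapped to
# the canonical vocabulary (three-letter amino acids for tRNAs, Leu1/Leu2 and
# Ser1/Ser2 disambiguated by anticodon where the source provides one).
_AA3 = {
    "ala": "Ala", "arg": "Arg", "asn": "Asn", "asp": "Asp", "cys": "Cys",
    "gln": "Gln", "glu": "Glu", "gly": "Gly", "his": "His", "ile": "Ile",
    "leu": "Leu", "lys": "Lys", "met": "Met", "phe": "Phe", "pro": "Pro",
    "ser": "Ser", "thr": "Thr", "trp": "Trp", "tyr": "Tyr", "val": "Val",
}
_GENE_ALIASES = {
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
    "nad4l": "ND4L", "nad5": "ND5", "nad6": "ND6",
    "nd1": "ND1", "nd2": "ND2", "nd3": "ND3", "nd4": "ND4", "nd4l": "ND4L",
    "nd5": "ND5", "nd6": "ND6",
    "cox1": "COX1", "cox2": "COX2", "cox3": "COX3",
    "coi": "COX1", "coii": "COX2", "coiii": "COX3",
    "co1": "COX1", "co2": "COX2", "co3": "COX3",
    "atp6": "ATP6", "atp8": "ATP8", "atpase6": "ATP6", "atpase8": "ATP8",
    "cytb": "Cytb", "cob": "Cytb", "mt-cyb": "Cytb",
    "12srrna": "12S-rRNA", "12s": "12S-rRNA", "rrns": "12S-rRNA",
    "s-rrna": "12S-rRNA", "12sribosomalrna": "12S-rRNA",
    "16srrna": "16S-rRNA", "16s": "16S-rRNA", "rrnl": "16S-rRNA",
    "l-rrna": "16S-rRNA", "16sribosomalrna": "16S-rRNA",
    "dloop": "D-loop", "d-loop": "D-loop", "controlregion": "D-loop",
    "cr": "D-loop",
}
# tRNA-Leu(UUR)/tRNA-Leu(CUN) and tRNA-Ser(UCN)/tRNA-Ser(AGY): the standard
# numbering calls the UUR/AGY isotypes Leu2/Ser2 in mammalian mitogenomes
# (Leu1 = CUN, Ser1 = AGY in some tables; here we follow the anticodon order
# of the reference table: Leu2 precedes ND1, Ser1 follows ND4).
_TRNA_CODON_SUFFIX = {
    ("leu", "uur"): "Leu2", ("leu", "uua"): "Leu2", ("leu", "taa"): "Leu2",
    ("leu", "cun"): "Leu1", ("leu", "tag"): "Leu1",
    ("ser", "ucn"): "Ser2", ("ser", "tga"): "Ser2",
    ("ser", "agy"): "Ser1", ("ser", "gct"): "Ser1",
}


def normalize_gene_name(raw: str) -> str:
    """Map a gene/feature name to the canonical vocabulary.

    Handles GenBank-style names (``nad4L``, ``COIII``, ``trnF``,
    ``tRNA-Leu(UUR)``), rRNA aliases, and control-region spellings.  Unknown
    names are returned stripped but otherwise untouched.
    """
    name = raw.strip()
    key = re.sub(r"[\s_*]", "", name).lower()
    if key in _GENE_ALIASES:
        return _GENE_ALIASES[key]
    m = re.match(r"^trna[-]?([a-z]{3})(\d?)(?:\((\w+)\))?$", key)
    if m:
        aa, num, anticodon = m.groups()
        if aa in _AA3:
            if num:
                return f"tRNA-{_AA3[aa]}{num}"
            if anticodon and (aa, anticodon.lower()) in _TRNA_CODON_SUFFIX:
                return "tRNA-" + _TRNA_CODON_SUFFIX[(aa, anticodon.lower())]
            return f"tRNA-{_AA3[aa]}"
    m = re.match(r"^trn([a-z])\d?$", key)
    if m:
        one_to_three = {
            "a": "Ala", "r": "Arg", "n": "Asn", "d": "Asp", "c": "Cys",
            "q": "Gln", "e": "Glu", "g": "Gly", "h": "His", "i": "Ile",
            "l": "Leu", "k": "Lys", "m": "Met", "f": "Phe", "p": "Pro",
            "s": "Ser", "t": "Thr", "w": "Trp", "y": "Tyr", "v": "Val",
        }
        if m.group(1) in one_to_three:
            return f"tRNA-{one_to_three[m.group(1)]}"
    return name


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a mitogenome.

    Coordinates are 1-based inclusive.  A feature with ``end < start`` wraps
    around the origin of a circular genome.  ``declared_start_codon`` /
    ``declared_stop_codon`` carry the annotation-table tokens (a stop of
    ``TA-`` or ``T--`` denotes a truncated codon completed by mRNA
    polyadenylation); ``composition`` optionally carries published per-gene
    base percentages for sequence-free tables.
    """

    name: str
    feature_class: str
    strand: str
    start: int
    end: int
    declared_start_codon: Optional[str] = None
    declared_stop_codon: Optional[str] = None
    composition: Optional[dict] = None  # {"A": %, "C": %, "G": %, "T": %}

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, "
                f"got {self.feature_class!r}"
            )
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.name}: coordinates are 1-based, got {self.start}-{self.end}"
            )

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start

    def size(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp (requires ``genome_length`` when wrapping)."""
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError(
                f"{self.name} wraps the origin; genome length required for size"
            )
        return (genome_length - self.start + 1) + self.end


@dataclass
class MitoGenome:
    """A mitogenome: sequence (optional), circularity flag, ordered features.

    ``sequence`` may be ``None`` in sequence-free mode, where analyses fall
    back on the per-feature ``composition`` percentages.  ``total_composition``
    optionally stores published whole-genome base percentages; ``length`` is
    the declared genome length (equal to ``len(sequence)`` when present).
    """

    identifier: str
    sequence: Optional[str]
    is_circular: bool
    features: list[GeneFeature] = field(default_factory=list)
    declared_length: Optional[int] = None
    total_composition: Optional[dict] = None

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            if len(self.sequence) < 1:
                raise ValueError("sequence must be non-empty")
            if self.declared_length is None:
                self.declared_length = len(self.sequence)
            elif self.declared_length != len(self.sequence):
                raise ValueError(
                    f"declared length {self.declared_length} != sequence "
                    f"length {len(self.sequence)}"
                )
        self._validate_coordinates()

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        if self.declared_length is not None:
            return self.declared_length
        return max((f.end for f in self.features), default=0)

    def _validate_coordinates(self) -> None:
        n = self.length
        for f in self.features:
            if f.start > n or f.end > n:
                raise CoordinateError(
                    f"{f.name}: coordinates {f.start}-{f.end} exceed genome "
                    f"length {n}"
                )
            if f.wraps_origin and not self.is_circular:
                raise CoordinateError(
                    f"{f.name}: end < start ({f.end} < {f.start}) on a linear genome"
                )

    def features_by_class(self, feature_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


def extract_gene(genome: MitoGenome, feat: GeneFeature) -> str:
    """Return the sense-strand (5'->3') sequence of a feature.

    H-strand features are the plain [start, end] substring; L-strand features
    are reverse-complemented so that downstream codon logic always reads the
    coding sense.  Wrap-around features on circular genomes splice
    ``[start..L] + [1..end]``.
    """
    if genome.sequence is None:
        raise ValueError("genome has no sequence (sequence-free mode)")
    n = len(genome.sequence)
    if feat.start > n or feat.end > n:
        raise CoordinateError(
            f"{feat.name}: {feat.start}-{feat.end} out of range for length {n}"
        )
    if feat.wraps_origin:
        if not genome.is_circular:
            raise CoordinateError(
                f"{feat.name}: wrap-around feature on a linear genome"
            )
        sub = genome.sequence[feat.start - 1:] + genome.sequence[:feat.end]
    else:
        sub = genome.sequence[feat.start - 1:feat.end]
    return reverse_complement(sub) if feat.strand == "L" else sub


# ---------------------------------------------------------------------------
# Feature-table TSV  (columns: name class strand start end start_codon
# stop_codon [pct_a pct_c pct_g pct_t]; '#key=value' headers carry genome
# metadata; '-' or empty marks a missing codon)
# ---------------------------------------------------------------------------

def _parse_coord(token: str, row_desc: str) -> int:
    try:
        return int(token.replace(",", "").strip())
    except ValueError:
        raise FeatureTableError(f"malformed coordinate {token!r} in {row_desc}")


def read_feature_table(
    path: str | Path, fasta: Optional[str | Path] = None
) -> MitoGenome:
    """Load a MitoGenome from a tab-separated feature table.

    ``fasta`` optionally supplies the genome sequence; otherwise the genome is
    sequence-free and statistics columns (``pct_a``..``pct_t``), if present,
    populate per-feature compositions.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(.*)$", line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip().lower() for c in cells]
                required = {"name", "class", "strand", "start", "end"}
                if not required.issubset(header):
                    raise FeatureTableError(
                        f"{path}: header must contain {sorted(required)}"
                    )
                continue
            row = dict(zip(header, (c.strip() for c in cells)))
            desc = f"{path.name} line {lineno} ({row.get('name', '?')})"
            start = _parse_coord(row["start"], desc)
            end = _parse_coord(row["end"], desc)
            codon = lambda key: (
                row.get(key) if row.get(key) not in (None, "", "-") else None
            )
            comp = None
            if all(f"pct_{b}" in row and row[f"pct_{b}"] not in ("", "-")
                   for b in "acgt"):
                comp = {b.upper(): float(row[f"pct_{b}"]) for b in "acgt"}
            try:
                feat = GeneFeature(
                    name=normalize_gene_name(row["name"]),
                    feature_class=row["class"],
                    strand=row["strand"],
                    start=start,
                    end=end,
                    declared_start_codon=codon("start_codon"),
                    declared_stop_codon=codon("stop_codon"),
                    composition=comp,
                )
            except ValueError as exc:
                raise FeatureTableError(f"{desc}: {exc}") from exc
            features.append(feat)
    if header is None:
        raise FeatureTableError(f"{path}: empty feature table")
    if not features:
        raise FeatureTableError(f"{path}: no feature rows")

    sequence = None
    if fasta is not None:
        record = next(SeqIO.parse(str(fasta), "fasta"))
        sequence = str(record.seq)

    total = None
    if all(f"total_pct_{b}" in meta for b in "acgt"):
        total = {b.upper(): float(meta[f"total_pct_{b}"]) for b in "acgt"}

    genome = MitoGenome(
        identifier=meta.get("identifier", path.stem),
        sequence=sequence,
        is_circular=meta.get("circular", "true").lower() in ("1", "true", "yes"),
        features=features,
        declared_length=int(meta["length"]) if "length" in meta else None,
        total_composition=total,
    )
    logger.info(
        "read %d features from %s (length %s, %s)",
        len(features), path, genome.length,
        "with sequence" if sequence else "sequence-free",
    )
    return genome


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    """Serialize a genome's annotations (and metadata) to the TSV format."""
    cols = ["name", "class", "strand", "start", "end", "start_codon", "stop_codon"]
    with_comp = any(f.composition for f in genome.features)
    if with_comp:
        cols += ["pct_a", "pct_c", "pct_g", "pct_t"]
    with open(path, "w") as fh:
        fh.write(f"#identifier={genome.identifier}\n")
        fh.write(f"#circular={'true' if genome.is_circular else 'false'}\n")
        fh.write(f"#length={genome.length}\n")
        if genome.total_composition:
            for b in "ACGT":
                fh.write(f"#total_pct_{b.lower()}={genome.total_composition[b]}\n")
        fh.write("\t".join(cols) + "\n")
        for f in genome.features:
            row = [
                f.name, f.feature_class, f.strand, str(f.start), str(f.end),
                f.declared_start_codon or "-", f.declared_stop_codon or "-",
            ]
            if with_comp:
                if f.composition:
                    row += [f"{f.composition[b]:.2f}" for b in "ACGT"]
                else:
                    row += ["-"] * 4
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D-loop": "control_region"}


def read_genbank(path: str | Path) -> MitoGenome:
    """Load a MitoGenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features are kept (plain ``gene`` features duplicate
    them and are folded in only when no typed feature covers the same span);
    ``misc_feature`` annotated as a control region is honored.  Complement
    locations map to the L strand.  Unknown feature keys are skipped with a
    warning.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: not a readable GenBank record: {exc}") from exc
    try:
        sequence = str(record.seq)
    except Exception as exc:  # UndefinedSequenceError on records lacking ORIGIN
        raise ValueError(f"{path}: GenBank record has no sequence") from exc
    if not sequence:
        raise ValueError(f"{path}: GenBank record has no sequence")
    is_circular = record.annotations.get("topology", "linear") == "circular"
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type in ("source", "gene"):
            continue
        fclass = _GENBANK_CLASS.get(feat.type)
        if fclass is None:
            if feat.type == "misc_feature" and "control" in str(
                feat.qualifiers.get("note", "")
            ).lower():
                fclass = "control_region"
            else:
                logger.warning("skipping feature with unknown key %r", feat.type)
                continue
        loc = feat.location
        strand = "L" if loc.strand == -1 else "H"
        # for a join() wrapping the origin of a circular genome this yields
        # start > end, which MitoGenome treats as a wrap-around feature
        parts = list(loc.parts)
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        qual = feat.qualifiers
        name = (
            qual.get("gene", [None])[0]
            or qual.get("product", [None])[0]
            or feat.type
        )
        if fclass == "control_region":
            name = "D-loop"
        features.append(
            GeneFeature(
                name=normalize_gene_name(name),
                feature_class=fclass,
                strand=strand,
                start=start,
                end=end,
            )
        )
    genome = MitoGenome(
        identifier=record.id or record.name,
        sequence=sequence,
        is_circular=is_circular,
        features=features,
    )
    logger.info("read %d features from GenBank %s", len(features), path)
    return genome


def write_fasta(genome: MitoGenome, path: str | Path, width: int = 70) -> None:
    if genome.sequence is None:
        raise ValueError("cannot write FASTA for a sequence-free genome")
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i:i + width] + "\n")
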