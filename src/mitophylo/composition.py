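"""Base composition, AT/GC skew, and feature-class length roll-ups.

Skews quantify strand-compositional asymmetry:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

Both are scale-invariant, so they accept raw counts or percentages
interchangeably.  Composition excludes IUPAC ambiguity codes and gaps from
all denominators; U is treated as T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .annotation import MitoGenome

__all__ = [
    "CompositionReport",
    "composition",
    "at_skew",
    "gc_skew",
    "class_totals",
    "genome_composition_table",
]


@dataclass(frozen=True)
class CompositionReport:
    """Base counts, percentages, AT/GC content and skews for one sequence."""

    counts: dict          # {"A": int, "C": int, "G": int, "T": int}
    fractions: dict       # percent of counted bases, same keys
    at_content: float     # percent
    gc_content: float     # percent
    at_skew: Optional[float]
    gc_skew: Optional[float]
    n_excluded: int       # ambiguous/gap positions left out of denominators

    def rounded(self) -> dict:
        """Render at the conventional precision: percents to 2 d.p., skews to 3."""
        out = {b: round(self.fractions[b], 2) for b in "ACGT"}
        out["AT"] = round(self.at_content, 2)
        out["GC"] = round(self.gc_content, 2)
        out["at_skew"] = None if self.at_skew is None else round(self.at_skew, 3)
        out["gc_skew"] = None if self.gc_skew is None else round(self.gc_skew, 3)
        return out


def at_skew(a: float, t: float) -> Optional[float]:
    """(A - T) / (A + T); ``None`` when A + T = 0 (undefined, never 0)."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> Optional[float]:
    """(G - C) / (G + C); ``None`` when G + C = 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


def composition(seq: str) -> CompositionReport:
    """Base composition of a nucleotide sequence.

    Ambiguity codes, Ns and gap characters are excluded from all denominators
    (tallied in ``n_excluded``); the sequence must contain at least one
    unambiguous base.
    """
    tally = Counter(seq.upper().replace("U", "T"))
    counts = {b: tally.get(b, 0) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous A/C/G/T bases in sequence")
    n_excluded = sum(tally.values()) - total
    fractions = {b: 100.0 * counts[b] / total for b in "ACGT"}
    return CompositionReport(
        counts=counts,
        fractions=fractions,
        at_content=fractions["A"] + fractions["T"],
        gc_content=fractions["G"] + fractions["C"],
        at_skew=at_skew(counts["A"], counts["T"]),
        gc_skew=gc_skew(counts["G"], counts["C"]),
        n_excluded=n_excluded,
    )


def report_from_percentages(pct: dict) -> CompositionReport:
    """Build a report from published percentages (sequence-free mode)."""
    fractions = {b: float(pct[b]) for b in "ACGT"}
    return CompositionReport(
        counts={},
        fractions=fractions,
        at_content=fractions["A"] + fractions["T"],
        gc_content=fractions["G"] + fractions["C"],
        at_skew=at_skew(fractions["A"], fractions["T"]),
        gc_skew=gc_skew(fractions["G"], fractions["C"]),
        n_excluded=0,
    )


def class_totals(genome: MitoGenome) -> pd.DataFrame:
    """Total bp and percent-of-genome per feature class.

    Totals are plain sums of declared sizes — overlapping features are not
    de-duplicated, matching how genome-organization tables roll up.
    """
    if not genome.features:
        raise ValueError("genome has no features")
    length = genome.length
    rows = {}
    for f in genome.features:
        rows.setdefault(f.feature_class, {"n_features": 0, "total_bp": 0})
        rows[f.feature_class]["n_features"] += 1
        rows[f.feature_class]["total_bp"] += f.size(length)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature_class"
    df["percent_of_genome"] = 100.0 * df["total_bp"] / length
    return df.sort_index()


def genome_composition_table(genome: MitoGenome) -> pd.DataFrame:
    """Per-feature composition table (plus a Total row when available).

    Uses extracted sequences when the genome carries one, otherwise the
    published per-feature percentages of a sequence-free table.
    """
    from .annotation import extract_gene

    rows = []
    for f in genome.features:
        if genome.sequence is not None:
            rep = composition(extract_gene(genome, f))
        elif f.composition is not None:
            rep = report_from_percentages(f.composition)
        else:
            continue
        r = rep.rounded()
        rows.append({
            "name": f.name, "class": f.feature_class, "strand": f.strand,
            "start": f.start, "end": f.end, "size": f.size(genome.length),
            "pct_a": r["A"], "pct_c": r["C"], "pct_g": r["G"], "pct_t": r["T"],
            "pct_at": r["AT"], "pct_gc": r["GC"],
            "at_skew": r["at_skew"], "gc_skew": r["gc_skew"],
        })
    if genome.sequence is not None:
        rep = composition(genome.sequence)
    elif genome.total_composition is not None:
        rep = report_from_percentages(genome.total_composition)
    else:
        rep = None
    if rep is not None:
        r = rep.rounded()
        rows.append({
            "name": "Total", "class": "-", "strand": "-",
            "start": 1, "end": genome.length, "size": genome.length,
            "pct_a": r["A"], "pct_c": r["C"], "pct_g": r["G"], "pct_t": r["T"],
            "pct_at": r["AT"], "pct_gc": r["GC"],
            "at_skew": r["at_skew"], "gc_skew": r["gc_skew"],
        })
    return pd.DataFrame(rows)
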