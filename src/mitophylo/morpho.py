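"""Range-based morphometric comparison of a specimen against species references.

External measurement indices (body mass BM in grams; forearm length FL,
head-and-body length LHB, tibia length TBL, tail length TL, ear length EL,
ear width EW, tragus length TRL, hindfoot length LHF, wing measures and wing
bone lengths, all in mm) are compared index by index against published
reference ranges with inclusive bounds.  References reported from a single
individual (low == high) are compared with a configurable relative
tolerance instead of a degenerate interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "MorphoRecord",
    "ReferenceRange",
    "range_check",
    "load_reference_ranges",
    "load_specimen",
    "bundled_reference_path",
    "bundled_specimen_path",
]

VERDICTS = ("within", "below", "above", "no_reference")


@dataclass(frozen=True)
class MorphoRecord:
    """One specimen's measurements: index name -> positive value."""

    measurements: dict[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.measurements.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive measurements: {bad}")


@dataclass(frozen=True)
class ReferenceRange:
    """Published range for one index of one species (low == high when the
    reference reports a single individual)."""

    species: str
    index: str
    low: float
    high: float
    source: str = ""
    n: Optional[int] = None

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.index}: low {self.low} > high {self.high}")

    @property
    def is_single(self) -> bool:
        return self.low == self.high


def range_check(
    record: MorphoRecord,
    ranges: list[ReferenceRange],
    species: str,
    source: Optional[str] = None,
    single_value_rel_tol: float = 0.05,
) -> pd.DataFrame:
    """Verdict per measurement index against one species' reference ranges.

    Bounds are inclusive.  Single-individual references count as ``within``
    when the specimen is within ``single_value_rel_tol`` (relative) of the
    reported value.  Indices without a reference get ``no_reference``.  The
    returned frame carries a ``fraction_within`` attribute: the share of
    indices *with* a reference that fall within range.
    """
    selected = {
        r.index: r for r in ranges
        if r.species == species and (source is None or r.source == source)
    }
    rows = []
    for index in record.measurements:
        value = record.measurements[index]
        ref = selected.get(index)
        if ref is None:
            verdict, low, high = "no_reference", None, None
        elif ref.is_single:
            low = high = ref.low
            tol = single_value_rel_tol * ref.low
            if abs(value - ref.low) <= tol:
                verdict = "within"
            else:
                verdict = "below" if value < ref.low else "above"
        else:
            low, high = ref.low, ref.high
            if value < low:
                verdict = "below"
            elif value > high:
                verdict = "above"
            else:
                verdict = "within"
        rows.append({
            "index": index, "value": value, "low": low, "high": high,
            "verdict": verdict,
        })
    df = pd.DataFrame(rows)
    with_ref = df[df["verdict"] != "no_reference"]
    df.attrs["fraction_within"] = (
        float((with_ref["verdict"] == "within").mean()) if len(with_ref) else 0.0
    )
    return df


def load_reference_ranges(path: str | Path) -> list[ReferenceRange]:
    """Read reference ranges from CSV: species,source,index,low,high[,n]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(ReferenceRange(
            species=str(row["species"]),
            source=str(row.get("source", "")),
            index=str(row["index"]),
            low=float(row["low"]),
            high=float(row["high"]),
            n=int(row["n"]) if "n" in row and pd.notna(row["n"]) else None,
        ))
    return out


def load_specimen(path: str | Path) -> MorphoRecord:
    """Read specimen measurements from CSV: index,value."""
    df = pd.read_csv(path)
    return MorphoRecord(
        measurements={str(r["index"]): float(r["value"]) for _, r in df.iterrows()}
    )


def bundled_reference_path() -> Path:
    """Packaged reference table (steppe whiskered bat vs David's myotis)."""
    return Path(str(files("mitophylo.data") / "morphometric_reference.csv"))


def bundled_specimen_path() -> Path:
    """Packaged measurements of the Inner Mongolian voucher specimen."""
    return Path(str(files("mitophylo.data") / "specimen_measurements.csv"))
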