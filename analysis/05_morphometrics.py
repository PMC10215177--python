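#!/usr/bin/env python
"""Morphometric attribution of the voucher specimen by reference ranges.

Checks the Inner Mongolian voucher's external measurements against the
bundled reference ranges for the steppe whiskered bat (two published series)
and for David's myotis, writing one verdict table per reference set under
``results/05_morpho/`` and printing the attribution summary.
"""

from pathlib import Path

from mitophylo.morpho import (
    bundled_reference_path, bundled_specimen_path, load_reference_ranges,
    load_specimen, range_check,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "05_morpho"
REFERENCE_SETS = (
    ("M. aurascens", "kim2011"),
    ("M. aurascens", "oh2013"),
    ("M. davidii", "you2021"),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    specimen = load_specimen(bundled_specimen_path())
    refs = load_reference_ranges(bundled_reference_path())

    for species, source in REFERENCE_SETS:
        df = range_check(specimen, refs, species, source=source)
        tag = f"{species.replace('. ', '_')}_{source}"
        df.to_csv(OUT / f"verdicts_{tag}.csv", index=False)
        scored = df[df["verdict"] != "no_reference"]
        below = sorted(df[df["verdict"] == "below"]["index"])
        above = sorted(df[df["verdict"] == "above"]["index"])
        print(f"{species} ({source}): "
              f"{df.attrs['fraction_within']:.0%} of {len(scored)} scored "
              f"indices within range"
              + (f"; below: {', '.join(below)}" if below else "")
              + (f"; above: {', '.join(above)}" if above else ""))
    print(f"verdict tables under {OUT}/")


if __name__ == "__main__":
    main()
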