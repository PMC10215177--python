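#!/usr/bin/env python
"""Characterize the steppe whiskered bat mitogenome from its annotation table.

Loads the bundled genome-organization table (sequence-free mode, with the
published per-gene base compositions), then writes the per-feature
composition/skew table and the feature-class length roll-ups under
``results/01_characterize/``.  Prints the headline numbers: total length,
protein-coding fraction, tRNA total, and the whole-genome AT/GC skews.
"""

from pathlib import Path

import mitophylo as mp
from mitophylo.composition import class_totals, genome_composition_table

OUT = Path(__file__).resolve().parent.parent / "results" / "01_characterize"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = mp.read_feature_table(mp.bundled_annotation_path())

    comp = genome_composition_table(genome)
    comp.to_csv(OUT / "composition.tsv", sep="\t", index=False)
    totals = class_totals(genome)
    totals.to_csv(OUT / "class_totals.tsv", sep="\t")

    total_row = comp.iloc[-1]
    pcg = totals.loc["PCG"]
    print(f"genome: {genome.identifier}, {genome.length:,} bp, "
          f"{len(genome.features)} features")
    print(f"protein-coding genes: {int(pcg['n_features'])} spanning "
          f"{int(pcg['total_bp']):,} bp "
          f"({pcg['percent_of_genome']:.1f}% of the genome)")
    print(f"tRNA total: {int(totals.loc['tRNA', 'total_bp']):,} bp; "
          f"rRNA total: {int(totals.loc['rRNA', 'total_bp']):,} bp; "
          f"control region: {int(totals.loc['control_region', 'total_bp']):,} bp")
    print(f"whole-genome AT skew {total_row['at_skew']:+.3f}, "
          f"GC skew {total_row['gc_skew']:+.3f} "
          "(A over T; strong C over G)")
    pcgs = comp[comp["class"] == "PCG"]
    pos_at = sorted(pcgs[pcgs["at_skew"] > 0]["name"])
    pos_gc = sorted(pcgs[pcgs["gc_skew"] > 0]["name"])
    print(f"PCGs with positive AT skew: {', '.join(pos_at)}")
    print(f"PCGs with positive GC skew: {', '.join(pos_gc)} "
          "(the lone light-strand PCG)")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
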