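#!/usr/bin/env python
"""Fetch the deposited mitogenome records needed for the real-data checks.

Downloads GenBank flat files for the steppe whiskered bat (OK053029) and
David's myotis (NC_025568.1) mitogenomes from NCBI E-utilities into
``data/downloads/``, where the real-data acceptance test looks for them.
Run this on a machine with network access:

    python scripts/fetch_accessions.py
"""

from pathlib import Path
from urllib.request import urlopen

ACCESSIONS = ("OK053029", "NC_025568.1")
EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gb&retmode=text"
)


def main() -> None:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "downloads"
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        print(f"fetching {acc} ...")
        with urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            text = resp.read().decode()
        if "ORIGIN" not in text:
            raise RuntimeError(f"unexpected response for {acc}")
        dest.write_text(text)
        print(f"wrote {dest} ({len(text)} bytes)")


if __name__ == "__main__":
    main()
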