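"""Download the two deposited GenBank records used by the accession-based
acceptance checks into ./data (network required).

Usage: python scripts/fetch_accessions.py [--out data]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")
ACCESSIONS = ("KP747440", "NC_001875")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="data", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=120) as r:
            dest.write_bytes(r.read())
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
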