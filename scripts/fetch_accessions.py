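#!/usr/bin/env python
"""Download the study's GenBank records for real-data runs (needs network).

The library and test-suite never require these files; they enable runs such
as:

    python scripts/fetch_accessions.py --out data/accessions
    psyllomito run data/accessions/KU501214.gb ... --out report

Mitogenomes: KU501214 (Bactericera cockerelli), NC_024577 (Paratrioza
sinica), NC_027087 (Cacopsylla coccinea), NC_006157 (Pachypsylla venusta),
outgroups NC_024926 and NC_006160; AY601890 (3,077 bp partial B. cockerelli)
and the cox1 haplotype records.
"""
import argparse
import time
import urllib.request
from pathlib import Path

MITOGENOMES = ["KU501214", "NC_024577", "NC_027087", "NC_006157",
               "NC_024926", "NC_006160", "AY601890"]
COX1_HAPLOTYPES = ["JQ708093", "JQ708094", "JQ708095", "AY971885", "AY971888",
                   "FJ175374", "EF372597", "KC305359", "KR534765", "KR534766",
                   "KR534767", "KR534768", "KR534769", "KR534770"]

EUTILS = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gb&retmode=text")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("data/accessions"))
    ap.add_argument("--haplotypes", action="store_true",
                    help="also fetch the cox1 haplotype records")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    accs = MITOGENOMES + (COX1_HAPLOTYPES if args.haplotypes else [])
    for acc in accs:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with urllib.request.urlopen(EUTILS.format(acc=acc), timeout=60) as r:
            dest.write_bytes(r.read())
        print(f"{acc}: {dest.stat().st_size} bytes")
        time.sleep(0.4)          # NCBI rate courtesy


if __name__ == "__main__":
    main()
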