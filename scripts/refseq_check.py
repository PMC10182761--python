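#!/usr/bin/env python
"""Optional network helper: re-detect the tetrads of the reference RefSeq
plastomes and compare with their published coordinates.

Downloads each record in ``irdraw.reference`` from NCBI E-utilities (needs
network access; not part of the offline test suite), runs IR detection on
the deposited sequence, and prints detected vs published coordinates.

Usage::

    python scripts/refseq_check.py [--outdir scratch/refseq] [--email you@x]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

from irdraw.genbank_io import format_tetrad, parse_genbank
from irdraw.ir_core import detect_tetrad
from irdraw.reference import REFERENCE_PLASTOMES

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str, outdir: Path, email: str) -> Path:
    path = outdir / f"{accession}.gb"
    if path.exists():
        return path
    query = urllib.parse.urlencode(
        {
            "db": "nuccore",
            "id": accession,
            "rettype": "gbwithparts",
            "retmode": "text",
            "email": email,
        }
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=120) as resp:
        path.write_bytes(resp.read())
    time.sleep(0.4)  # NCBI rate limit
    return path


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/refseq"))
    ap.add_argument("--email", default="anonymous@example.org")
    args = ap.parse_args(argv)
    args.outdir.mkdir(parents=True, exist_ok=True)

    mismatches = 0
    for acc, (organism, group, coords, _) in REFERENCE_PLASTOMES.items():
        try:
            gb = fetch(acc, args.outdir, args.email)
            genome = parse_genbank(gb)
            detected = format_tetrad(detect_tetrad(genome).tetrad)
        except Exception as exc:  # network or detection failure
            print(f"{acc}\t{organism}\tERROR: {exc}")
            mismatches += 1
            continue
        status = "MATCH" if detected == coords.replace("–", "-") else "DIFFER"
        if status == "DIFFER":
            mismatches += 1
        print(f"{acc}\t{organism}\t{status}")
        print(f"  published: {coords}")
        print(f"  detected:  {detected}")
    return 1 if mismatches else 0


if __name__ == "__main__":
    sys.exit(main())
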