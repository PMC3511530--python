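#!/usr/bin/env python
"""Fetch the public Streptomyces genome annotations used by the optional
genome spot-checks into scratch/genomes/ (requires NCBI network access).

Accessions: AL645882 (S. coelicolor M145), AP009493 (S. griseus),
BA000030 (S. avermitilis). The genome-wide aggregate check additionally
needs scratch/genomes/divergent_pairs.tsv (columns: accession, tfr_locus,
neighbor_locus), transcribed from the published analysis of regulators
with divergent neighbors; it is not downloadable in machine-readable form
and must be prepared by hand.
"""
import sys
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = ["AL645882", "AP009493", "BA000030"]
EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT = Path(__file__).resolve().parent.parent / "scratch" / "genomes"


def fetch(accession: str) -> None:
    out = OUT / f"{accession}.gb"
    if out.exists():
        print(f"{out} already present")
        return
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "gbwithparts", "retmode": "text"}
    )
    url = f"{EFETCH}?{params}"
    print(f"fetching {accession} ...")
    with urllib.request.urlopen(url, timeout=300) as resp:
        data = resp.read()
    if not data.startswith(b"LOCUS"):
        raise RuntimeError(f"unexpected response for {accession}")
    out.write_bytes(data)
    print(f"wrote {out} ({len(data) / 1e6:.1f} MB)")


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    for accession in ACCESSIONS:
        fetch(accession)
    return 0


if __name__ == "__main__":
    sys.exit(main())
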