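"""One-time download of the public brittle-star opsin gene records.

Fetches the 14 deposited nucleotide records KM276762-KM276775 from NCBI
nucleotide via EUtils and writes them to data/deposited/af_opsin_cds.fasta,
where the deposited-sequence reproduction test expects them.  Requires
network access; the records are public but are not redistributed inside this
repository.

Usage:  python scripts/fetch_deposited.py
"""

import pathlib
import sys
import urllib.request

ACCESSIONS = [f"KM2767{n}" for n in range(62, 76)]
URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={ids}&rettype=fasta&retmode=text"
)


def main() -> int:
    out = pathlib.Path(__file__).resolve().parents[1] / "data" / "deposited"
    out.mkdir(parents=True, exist_ok=True)
    url = URL.format(ids=",".join(ACCESSIONS))
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            fasta = resp.read().decode()
    except OSError as exc:
        print(f"download failed ({exc}); network access is required", file=sys.stderr)
        return 1
    n_records = fasta.count(">")
    if n_records != len(ACCESSIONS):
        print(f"expected {len(ACCESSIONS)} records, got {n_records}", file=sys.stderr)
        return 1
    (out / "af_opsin_cds.fasta").write_text(fasta)
    print(f"wrote {n_records} records to {out / 'af_opsin_cds.fasta'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
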