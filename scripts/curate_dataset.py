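#!/usr/bin/env python
"""UNTESTED helper: assemble a non-redundant RNA structure set.

Outline of the published curation recipe this mirrors:

1. download a representative-set release list from the RNA 3D Hub
   non-redundant lists (resolution cutoff 4.0 Å) and keep one
   representative per equivalence class;
2. drop entries whose representative contains no RNA chain;
3. all-against-all blastn on the chain sequences and drop one member of
   every pair above 80% identity;
4. fetch the surviving mmCIF files from the PDB.

Requires network access and the blast+ suite on PATH.  This script is a
documented convenience only: nothing in the package or its test suite
depends on it, and the word-size/seeding parameters of the identity
filter are left at blastn defaults.
"""

from __future__ import annotations

import argparse
import subprocess
import sys
import urllib.request
from pathlib import Path

NRLIST = "http://rna.bgsu.edu/rna3dhub/nrlist/download/{release}/4.0A/csv"
CIF_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--release", default="current")
    ap.add_argument("--identity", type=float, default=80.0)
    ap.add_argument("--out", type=Path, default=Path("dataset"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    listing = args.out / "nrlist.csv"
    urllib.request.urlretrieve(NRLIST.format(release=args.release), listing)
    pdb_ids = sorted({line.split(",")[1].split("|")[0].strip('"')
                      for line in listing.read_text().splitlines() if "," in line})
    print(f"{len(pdb_ids)} representatives", file=sys.stderr)

    for pdb_id in pdb_ids:
        target = args.out / f"{pdb_id}.cif"
        if not target.exists():
            urllib.request.urlretrieve(CIF_URL.format(pdb_id=pdb_id), target)

    # sequence-identity pruning: extract chains to FASTA, all-vs-all blastn,
    # greedily drop the shorter member of any hit above the threshold
    fasta = args.out / "chains.fasta"
    _write_chain_fasta(args.out, fasta)
    hits = subprocess.run(
        ["blastn", "-query", str(fasta), "-subject", str(fasta),
         "-outfmt", "6 qseqid sseqid pident"],
        check=True, capture_output=True, text=True).stdout
    drop: set[str] = set()
    for line in hits.splitlines():
        q, s, pident = line.split("\t")
        if q != s and float(pident) > args.identity:
            drop.add(max(q, s))
    keep = [p for p in pdb_ids if p not in {d.split("_")[0] for d in drop}]
    (args.out / "kept_ids.txt").write_text("\n".join(keep) + "\n")
    print(f"kept {len(keep)} structures", file=sys.stderr)


def _write_chain_fasta(directory: Path, fasta: Path) -> None:
    from rnadesc.structure_model import read_structure

    with fasta.open("w") as fh:
        for cif in sorted(directory.glob("*.cif")):
            try:
                st = read_structure(cif)
            except Exception:
                continue
            for chain in st.chains:
                seq = "".join(r.base for r in chain.residues)
                fh.write(f">{st.id}_{chain.id}\n{seq}\n")


if __name__ == "__main__":
    main()
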