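#!/usr/bin/env python
"""Benchmark the site predictor on a real structure you supply.

This is an optional, accession-based check for large structures that
cannot be generated synthetically (for example PDB entry 1YK3, an
acetyltransferase whose large predicted site spans dozens of residues
around His130/Asp168).  Download the PDB or mmCIF file yourself, then:

    python scripts/benchmark_accession.py --structure 1yk3.pdb \
        --chain A --expected expected_residues.txt

``--expected`` is an optional file with one author residue number per
line; the script reports the overlap between the predicted sites and
that list.  Because surface triangulation and numerical details differ
between surface-point generators, residue-for-residue identity with any
previously published site list is not expected; the overlap fraction is
the interesting number.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from leapfs import dpa
from leapfs import structure_io as sio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--structure", required=True, type=Path,
                    help="PDB or mmCIF file of the accession to analyse")
    ap.add_argument("--chain", default=None, help="Author chain id (default: all)")
    ap.add_argument("--expected", type=Path, default=None,
                    help="File of expected author residue numbers, one per line")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data = sio.read_structure(args.structure)
    chains = ([args.chain] if args.chain else
              sorted({r.chain_id for r in data.residues if r.is_polymer_aa}))
    ddef = sio.DomainDef(args.structure.stem, data.structure_id,
                         tuple((c, None, None) for c in chains))
    domain = sio.extract_domain(data, ddef)
    print(f"{len(domain.residues)} residues in {'+'.join(chains)}")

    field = dpa.predict_sites(domain, seed=args.seed)
    predicted = set()
    for site in field.sites:
        nums = sorted(k[1] for k in site.residues)
        predicted.update(nums)
        print(f"site {site.site_label}: mean D_x {site.mean_dx:.3f}, "
              f"{len(nums)} residues: {nums}")

    if args.expected:
        expected = {int(line) for line in args.expected.read_text().split()
                    if line.strip()}
        hit = expected & predicted
        print(f"expected residues: {len(expected)}; recovered: {len(hit)} "
              f"({100.0 * len(hit) / len(expected):.0f}%)")


if __name__ == "__main__":
    main()
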