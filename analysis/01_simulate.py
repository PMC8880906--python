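#!/usr/bin/env python
"""Simulate the study inputs: a planted-theme scenario and βTL structures.

Writes, under results/data/:
  families/<id>.afa   aligned FASTA per family (donor, recipient, decoys)
  domains.fasta       all searchable target sequences
  domains.tsv         target classification table (ECOD-style groups)
  donor_ss.tsv        secondary-structure string for the donor master
  structures/*.pdb    βTL (wet + dry) and decoy structures, with waters
  truth.json          ground truth for both tracks

Run:  python analysis/01_simulate.py --seed 7
"""

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from trefoil_themes import formats_io as fio  # noqa: E402
from trefoil_themes import synthetic_data as sd  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()

    fam_dir = os.path.join(args.out, "families")
    struct_dir = os.path.join(args.out, "structures")
    os.makedirs(fam_dir, exist_ok=True)
    os.makedirs(struct_dir, exist_ok=True)

    scenario = sd.generate_theme_scenario(seed=args.seed)
    for msa, group in scenario.families + scenario.decoy_families:
        fam = msa.master_id.split("|")[0]
        fio.write_alignment(os.path.join(fam_dir, f"{fam}.afa"), msa)
    fio.write_fasta(
        os.path.join(args.out, "domains.fasta"),
        [(d, seq) for d, seq, _ in scenario.database()],
    )
    with open(os.path.join(args.out, "domains.tsv"), "w") as fh:
        fh.write("domain_id\tpdb\tchain\trange\tgroup\n")
        for d, seq, group in scenario.database():
            fh.write(f"{d}\t-\tA\t1-{len(seq)}\t{group}\n")
    with open(os.path.join(args.out, "donor_ss.tsv"), "w") as fh:
        fh.write(f"{scenario.families[0][0].master_id}\t{scenario.donor_ss}\n")

    wet = sd.generate_btl_structure(0.0, dry=False, seed=args.seed)
    dry = sd.generate_btl_structure(0.0, dry=True, seed=args.seed)
    helix = sd.generate_decoy_structure(36, "helix", seed=args.seed)
    coil = sd.generate_decoy_structure(60, "random_coil", seed=args.seed)
    structures = {"btl_wet": wet, "btl_dry": dry, "decoy_helix": helix, "decoy_coil": coil}
    for name, s in structures.items():
        fio.write_pdb(os.path.join(struct_dir, f"{name}.pdb"), s.structure)

    truth = json.loads(scenario.truth_sidecar())
    truth["structures"] = {
        name: {
            "has_motif": s.has_motif,
            "is_dry": s.is_dry,
            "ss": s.ss,
            "motif_segments": s.motif_segments,
            "water_partners": s.water_partners,
            "donor_positions": s.donor_positions,
            "clamp_residues": s.clamp_residues,
        }
        for name, s in structures.items()
    }
    with open(os.path.join(args.out, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    print(f"wrote scenario ({len(scenario.database())} target domains, "
          f"{len(scenario.truth)} truth windows) and {len(structures)} structures "
          f"to {args.out}")


if __name__ == "__main__":
    main()
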