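#!/usr/bin/env python
"""Aggregate both tracks into the headline counting objects.

Reads results/theme and results/motif, prints the bridging-theme network
(edges between query families and target lineages), the per-lineage
unique-theme counts, and the motif annotation summary.

Run:  python analysis/04_summarize.py
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--theme", default="results/theme")
    parser.add_argument("--motif", default="results/motif")
    args = parser.parse_args()

    edges = pd.read_csv(os.path.join(args.theme, "network_edges.tsv"),
                        sep="\t", comment="#")
    counts = pd.read_csv(os.path.join(args.theme, "theme_counts.tsv"),
                         sep="\t", comment="#")
    hits = pd.read_csv(os.path.join(args.theme, "theme_hits.tsv"),
                       sep="\t", comment="#")
    motif = pd.read_csv(os.path.join(args.motif, "motif_hits.tsv"),
                        sep="\t", comment="#")

    print("== bridging-theme network ==")
    print(edges.to_string(index=False))
    print("\n== unique themes per target lineage ==")
    print(counts.to_string(index=False))
    print(f"\ntotal hits: {len(hits)}; distinct profiles with a hit: "
          f"{hits.profile_id.nunique()}")
    print("\n== βTL motif annotation ==")
    print(motif.to_string(index=False))


if __name__ == "__main__":
    main()
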