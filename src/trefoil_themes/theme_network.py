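"""Aggregate theme hits into network and counting summaries.

The headline objects: a bipartite network of (query F-group, target
X-group) edges supported by profiles and hits; per-X-group unique-theme
counts (a theme = one profile with at least one hit into that lineage);
deduplicated F-group pair associations; per-hit strand associations; and
metamorphism statistics over segment RMSDs.
"""

from __future__ import annotations

import dataclasses
import logging

import networkx as nx
import pandas as pd

from .formats_io import parse_group
from .secstruct_fragments import strand_segments

__all__ = [
    "ThemeNetwork",
    "build_network",
    "count_unique_themes",
    "fgroup_pair_associations",
    "strand_associations",
    "metamorphism_stats",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ThemeNetwork:
    """Bipartite network: query F-groups vs target X-groups."""

    graph: nx.Graph

    @property
    def trefoil_nodes(self) -> list:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("side") == "fgroup"
        )

    @property
    def lineage_nodes(self) -> list:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("side") == "xgroup"
        )

    @property
    def edges(self) -> list:
        out = []
        for u, v, d in self.graph.edges(data=True):
            f, x = (u, v) if self.graph.nodes[u]["side"] == "fgroup" else (v, u)
            out.append((f, x, sorted(d["profiles"]), d["hits"]))
        return sorted(out, key=lambda e: (e[0], e[1]))

    def to_frames(self):
        nodes = pd.DataFrame(
            [(n, d["side"]) for n, d in self.graph.nodes(data=True)],
            columns=["node", "side"],
        ).sort_values(["side", "node"], ignore_index=True)
        edges = pd.DataFrame(
            [
                (f, x, len(profiles), ";".join(profiles), len(hits))
                for f, x, profiles, hits in self.edges
            ],
            columns=["query_fgroup", "target_xgroup", "n_profiles", "profiles", "n_hits"],
        )
        return nodes, edges


def build_network(hits, classification: dict) -> ThemeNetwork:
    """One edge per (query F-group, target X-group) with supporting hits.

    ``classification`` maps domain id -> dotted group label (used for the
    query side; targets carry their group on the hit).  Hits whose query or
    target cannot be classified are skipped and logged.
    """
    g = nx.Graph()
    for hit in hits:
        q_group = classification.get(hit.master_domain)
        if not q_group or not hit.target_group:
            logger.warning("skipping unclassified hit %s -> %s",
                           hit.master_domain, hit.target_domain)
            continue
        f_label = f"F:{q_group}"
        x_label = f"X:{parse_group(hit.target_group)[0]}"
        g.add_node(f_label, side="fgroup")
        g.add_node(x_label, side="xgroup")
        if not g.has_edge(f_label, x_label):
            g.add_edge(f_label, x_label, profiles=set(), hits=[])
        g[f_label][x_label]["profiles"].add(hit.profile_id)
        g[f_label][x_label]["hits"].append(hit)
    return ThemeNetwork(graph=g)


def count_unique_themes(hits, per: str = "xgroup") -> pd.DataFrame:
    """Distinct profiles with >= 1 hit, per target X-group (or T/F-group).

    This is the redundancy-corrected "unique theme" count: many hits by one
    profile into the same lineage count once.
    """
    level = {"xgroup": 1, "tgroup": 2, "fgroup": 3}[per]
    buckets: dict = {}
    for hit in hits:
        fields = parse_group(hit.target_group)[:level]
        if any(f is None for f in fields):
            key = ".".join(str(f) for f in fields if f is not None) + ".?"
        else:
            key = ".".join(str(f) for f in fields)
        buckets.setdefault(key, set()).add(hit.profile_id)
    rows = [(k, len(v)) for k, v in buckets.items()]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=[per, "n_unique_themes"])


def fgroup_pair_associations(hits, classification: dict | None = None) -> pd.DataFrame:
    """Unique (query F-group, target F-group) pairs, grouped by target
    X-group.

    ``classification`` maps the query master domain to its dotted group
    label; without it the master domain id stands in for its family.
    Targets lacking an F-group land in a "T-group-only" bucket (logged).
    """
    classification = classification or {}
    pairs: dict = {}
    for hit in hits:
        x, t, f = parse_group(hit.target_group)
        if f is None:
            logger.warning("target %s lacks an F-group; bucketed by T-group",
                           hit.target_domain)
            target_label = f"{x}.{t}.?" if t is not None else f"{x}.?"
        else:
            target_label = f"{x}.{t}.{f}"
        query_f = classification.get(hit.master_domain, hit.master_domain)
        pairs.setdefault(x, set()).add((query_f, target_label))
    rows = [
        (x, len(ps), sorted(ps)) for x, ps in sorted(pairs.items())
    ]
    return pd.DataFrame(rows, columns=["target_xgroup", "n_pairs", "pairs"])


def strand_associations(hit, ss_query: str, ss_target: str,
                        min_overlap: int = 3, min_strand_len: int = 2) -> list:
    """Strand index pairs implied by a hit alignment.

    A pair (i, j) is emitted when at least ``min_overlap`` aligned residue
    pairs fall inside query strand i and target strand j simultaneously;
    strand numbering follows ``strand_segments`` over each full domain.
    """
    if not ss_query or not ss_target:
        logger.warning("missing secondary structure; no strand associations")
        return []
    q_strands = strand_segments(ss_query, min_len=min_strand_len)
    t_strands = strand_segments(ss_target, min_len=min_strand_len)

    def strand_of(pos, segments):
        for seg in segments:
            if seg.start <= pos <= seg.end:
                return seg.index
        return None

    counts: dict = {}
    for q_pos, t_pos in hit.alignment:
        qi = strand_of(q_pos, q_strands)
        ti = strand_of(t_pos, t_strands)
        if qi is not None and ti is not None:
            counts[(qi, ti)] = counts.get((qi, ti), 0) + 1
    return sorted(k for k, v in counts.items() if v >= min_overlap)


def metamorphism_stats(hits_with_rmsd, threshold: float = 2.5):
    """Median segment RMSD and the fraction strictly below ``threshold``.

    Hits without a defined RMSD are excluded from the denominator and
    counted separately.  Returns (median, fraction, n_defined, n_missing);
    median and fraction are NaN when nothing is defined.
    """
    import math

    values = []
    missing = 0
    for hit in hits_with_rmsd:
        r = getattr(hit, "segment_rmsd", None) if not isinstance(hit, (int, float)) else hit
        if r is None or (isinstance(r, float) and math.isnan(r)):
            missing += 1
        else:
            values.append(float(r))
    if not values:
        logger.debug("metamorphism_stats: no defined RMSD values")
        return float("nan"), float("nan"), 0, missing
    values.sort()
    n = len(values)
    median = values[n // 2] if n % 2 else 0.5 * (values[n // 2 - 1] + values[n // 2])
    fraction = sum(1 for v in values if v < threshold) / n
    return median, fraction, n, missing
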