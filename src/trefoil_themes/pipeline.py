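"""End-to-end orchestration of the two search tracks.

``run_theme_pipeline`` runs the sequence track: filter each family MSA,
assign strands on the master, cut 4-strand windows, build and calibrate one
profile per window, search the domain database, confirm hits by
shuffle/EVD p-value, attach segment RMSDs where coordinates exist, and
aggregate the network/counting outputs.

``run_motif_pipeline`` runs the structure track: thread the search motif
over every target structure by TM-score and annotate accepted hits with
conserved-water, clamp and dry-motif calls.

All defaults equal the study conditions: E-value cutoff 1e-3, X-group 6
excluded, 90%/30% MSA coverage/identity filters, 1000 shuffles, TM > 0.5.
Every output is reproducible from the config and seed; a manifest records
content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import formats_io, profile_hmm, secstruct_fragments, structure_motif, theme_network
from .evd_significance import shuffle_pvalue

__all__ = ["RunConfig", "run_theme_pipeline", "run_motif_pipeline"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Knobs for a pipeline run; defaults are the study conditions."""

    window_k: int = 4
    min_strand_len: int = 2
    coverage_min: float = 0.90
    identity_min: float = 0.30
    occupancy_min: float = 0.5
    pseudocount_alpha: float = 0.5
    evalue_max: float = 1e-3
    exclude_xgroup: int | None = 6
    n_shuffles: int = 1000
    n_calibration: int = 200
    calibration_len: int | None = None
    shuffle_pvalue_max: float | None = None  # no p filter by default
    tm_min: float = 0.5
    short_hbond: float = 3.0
    max_hbond: float = 3.5
    clamp_cutoff: float = 5.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not 0 < self.coverage_min <= 1 or not 0 <= self.identity_min <= 1:
            raise ValueError("coverage/identity thresholds must be in (0, 1]")
        if self.evalue_max < 0 or self.n_shuffles < 30:
            raise ValueError("bad threshold configuration")
        logger.info(
            "run config: E<%g, exclude X-group %s, cov>=%.2f, id>=%.2f, "
            "%d shuffles, TM>%.2f",
            self.evalue_max, self.exclude_xgroup, self.coverage_min,
            self.identity_min, self.n_shuffles, self.tm_min,
        )


@dataclasses.dataclass
class ThemeRunResult:
    hits: list
    windows: list
    profiles: list
    hit_table: pd.DataFrame
    network: theme_network.ThemeNetwork
    theme_counts: pd.DataFrame
    metamorphism: tuple


def _window_sequence(msa, residue_range) -> str:
    master = msa.master.replace("-", "")
    lo, hi = residue_range
    return master[lo - 1 : hi]


def run_theme_pipeline(
    msas: list,
    domains: list,
    config: RunConfig | None = None,
    master_ss: dict | None = None,
    classification: dict | None = None,
    coords: dict | None = None,
) -> ThemeRunResult:
    """Sequence track, end to end.

    ``msas``: list of (MSA, group label) query families.  ``domains``:
    (domain_id, sequence, group) search targets.  ``master_ss`` maps master
    id -> secondary-structure string (in master ungapped coordinates);
    ``coords`` optionally maps domain/master ids to CA coordinate arrays
    for segment RMSDs.
    """
    config = config or RunConfig()
    classification = dict(classification or {})
    master_ss = master_ss or {}
    coords = coords or {}
    rng = np.random.default_rng(config.seed)

    all_hits = []
    windows_out = []
    profiles = []
    lengths = sorted(len(d[1]) for d in domains)
    median_len = lengths[len(lengths) // 2] if lengths else None
    calibration_len = config.calibration_len or median_len
    for msa, group in msas:
        classification.setdefault(msa.master_id, group)
        ss = master_ss.get(msa.master_id)
        if ss is None:
            logger.warning("no secondary structure for %s; skipped", msa.master_id)
            continue
        filtered = secstruct_fragments.filter_msa(
            msa, coverage_min=config.coverage_min, identity_min=config.identity_min
        )
        segments = secstruct_fragments.strand_segments(ss, min_len=config.min_strand_len)
        windows = secstruct_fragments.make_windows(segments, k=config.window_k)
        for span, residue_range in windows:
            restricted = secstruct_fragments.restrict_msa(filtered, residue_range)
            window = secstruct_fragments.FragmentWindow(
                master_id=msa.master_id,
                strand_span=span,
                residue_range=residue_range,
                restricted_msa=restricted,
            )
            windows_out.append(window)
            hmm = profile_hmm.build_hmm(
                restricted,
                pseudocount_alpha=config.pseudocount_alpha,
                occupancy_min=config.occupancy_min,
                master_id=msa.master_id,
                strand_span=span,
            )
            profile_hmm.calibrate_evalue(
                hmm,
                n_random=config.n_calibration,
                random_len=calibration_len,
                seed=int(rng.integers(2**31)),
            )
            profiles.append(hmm)
            hits = profile_hmm.search(
                hmm,
                domains,
                evalue_max=config.evalue_max,
                exclude_xgroup=config.exclude_xgroup,
            )
            query_seq = _window_sequence(msa, residue_range)
            target_seq = {d[0]: d[1] for d in domains}
            for hit in hits:
                p, _, _ = shuffle_pvalue(
                    query_seq,
                    target_seq[hit.target_domain],
                    n_shuffles=config.n_shuffles,
                    seed=int(rng.integers(2**31)),
                )
                hit.shuffle_pvalue = p
                if msa.master_id in coords and hit.target_domain in coords:
                    offset = residue_range[0] - 1
                    aligned = [(q + offset, t) for q, t in hit.alignment]
                    hit.segment_rmsd = structure_motif.theme_rmsd(
                        aligned, coords[msa.master_id], coords[hit.target_domain]
                    )
            if config.shuffle_pvalue_max is not None:
                hits = [h for h in hits if h.shuffle_pvalue < config.shuffle_pvalue_max]
            all_hits.extend(hits)

    table = pd.DataFrame(
        [
            {
                "profile_id": h.profile_id,
                "master_domain": h.master_domain,
                "window_strands": h.profile_id.rsplit("|", 1)[-1],
                "target_domain": h.target_domain,
                "target_group": h.target_group,
                "bit_score": h.bit_score,
                "evalue": h.evalue,
                "shuffle_pvalue": h.shuffle_pvalue,
                "aln_master_range": _pair_range(h.alignment, 0),
                "aln_target_range": _pair_range(h.alignment, 1),
                "segment_rmsd": h.segment_rmsd,
            }
            for h in all_hits
        ],
        columns=formats_io.HIT_TABLE_COLUMNS,
    )
    network = theme_network.build_network(all_hits, classification)
    counts = theme_network.count_unique_themes(all_hits)
    meta = theme_network.metamorphism_stats(all_hits)
    result = ThemeRunResult(
        hits=all_hits,
        windows=windows_out,
        profiles=profiles,
        hit_table=table,
        network=network,
        theme_counts=counts,
        metamorphism=meta,
    )
    if config.output_dir:
        _write_theme_outputs(result, config)
    return result


def _pair_range(alignment, side) -> str:
    if not alignment:
        return ""
    vals = [p[side] for p in alignment]
    return f"{min(vals)}-{max(vals)}"


def _write_theme_outputs(result: ThemeRunResult, config: RunConfig) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    header = f"seed={config.seed}"
    formats_io.write_hit_table(
        os.path.join(out, "theme_hits.tsv"),
        result.hit_table.to_dict("records"),
        header_comment=header,
    )
    nodes, edges = result.network.to_frames()
    _write_tsv(os.path.join(out, "network_nodes.tsv"), nodes, header)
    _write_tsv(os.path.join(out, "network_edges.tsv"), edges, header)
    _write_tsv(os.path.join(out, "theme_counts.tsv"), result.theme_counts, header)
    median, fraction, n_def, n_miss = result.metamorphism
    meta = pd.DataFrame(
        [[median, fraction, n_def, n_miss]],
        columns=["median_rmsd", "fraction_below_2.5", "n_defined", "n_missing"],
    )
    _write_tsv(os.path.join(out, "metamorphism.tsv"), meta, header)
    _write_manifest(out)


def _write_tsv(path, frame: pd.DataFrame, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _write_manifest(out_dir: str) -> None:
    entries = {}
    for name in sorted(os.listdir(out_dir)):
        if name == "MANIFEST.json":
            continue
        path = os.path.join(out_dir, name)
        with open(path, "rb") as fh:
            entries[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)


def run_motif_pipeline(
    motif: structure_motif.StructuralMotif,
    targets: list,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Structure track: thread the motif over each target and annotate.

    ``targets``: list of (target_id, Structure, ss or None).  Unreadable
    entries are skipped with a log record.  Returns a table sorted by TM
    descending with water/clamp/dry annotation on hits with TM >= tm_min.
    """
    config = config or RunConfig()
    rows = []
    for entry in targets:
        try:
            target_id, structure, ss = entry
            ca = structure.ca_coords()
            hit = structure_motif.motif_search(motif, ca, target_id=target_id)
        except Exception as exc:  # noqa: BLE001 - a bad structure must not kill the run
            logger.warning("skipping target %r: %s", entry[0] if entry else "?", exc)
            continue
        row = {
            "target": target_id,
            "tm_score": hit.tm_score,
            "rmsd": hit.rmsd,
            "n_mapped": len(hit.mapping),
            "n_waters": 0,
            "n_short_hbonds": 0,
            "water_contexts": "",
            "clamp": False,
            "dry": False,
        }
        if hit.tm_score >= config.tm_min and hit.mapping:
            numbers = [
                structure.residues[t].number
                for _, t in hit.mapping
                if t < len(structure.residues)
            ]
            reports = structure_motif.find_water_motif(
                structure,
                numbers,
                ss=ss,
                short_cutoff=config.short_hbond,
                max_cutoff=config.max_hbond,
            )
            row["n_waters"] = len(reports)
            if reports:
                best = max(reports, key=lambda r: r.n_short_hbonds)
                row["n_short_hbonds"] = best.n_short_hbonds
                row["water_contexts"] = ",".join(sorted(best.partner_context))
                row["clamp"] = best.clamp
            else:
                row["dry"] = structure_motif.detect_dry_motif(
                    structure, hit, motif.donor_positions, ss=ss
                )
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("tm_score", ascending=False, ignore_index=True)
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        _write_tsv(
            os.path.join(config.output_dir, "motif_hits.tsv"),
            table,
            f"seed={config.seed}",
        )
        _write_manifest(config.output_dir)
    return table
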