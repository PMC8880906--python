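"""β-strand assignment, MSA filtering and sliding 4-strand windows.

Secondary structure is assigned with the Kabsch–Sander electrostatic
hydrogen-bond model: the amide hydrogen is placed 1.01 Å from N opposite the
preceding carbonyl, the bond energy is

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and a bond exists when E < -0.5.  A residue is labelled E when it takes part
in at least one inter-strand bridge (the two antiparallel and two parallel
bridge patterns), H when it sits in a run of at least four i→i+4 bonds, and
C otherwise.  Users may supply secondary-structure strings directly and
bypass assignment entirely.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .formats_io import MSA, Structure

__all__ = [
    "StrandSegment",
    "FragmentWindow",
    "assign_ss",
    "strand_segments",
    "filter_msa",
    "make_windows",
    "restrict_msa",
    "hbond_energy",
    "backbone_hbonds",
]

logger = logging.getLogger(__name__)

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q = 0.084 * 332.0


@dataclasses.dataclass
class StrandSegment:
    """One β-strand: 1-based ordinal and inclusive residue range."""

    index: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("strand start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class FragmentWindow:
    """A 4-consecutive-strand window with its column-restricted MSA."""

    master_id: str
    strand_span: tuple
    residue_range: tuple
    restricted_msa: MSA

    @property
    def profile_id(self) -> str:
        i, j = self.strand_span
        return f"{self.master_id}|w{i}-{j}"


def hbond_energy(n_d, h_d, c_a, o_a) -> float:
    """Kabsch–Sander electrostatic energy of one N-H···O=C contact."""

    def inv(a, b):
        r = float(np.linalg.norm(a - b))
        return 1.0 / max(r, 0.5)

    return _Q * (inv(n_d, o_a) + inv(c_a, h_d) - inv(o_a, h_d) - inv(c_a, n_d))


def backbone_hbonds(structure: Structure) -> set:
    """(donor residue index, acceptor residue index) pairs, 0-based.

    Residues with incomplete backbones neither donate nor accept.
    """
    res = structure.residues
    n = len(res)
    ok = [r.complete_backbone for r in res]
    bonds = set()
    coords = {
        name: np.array(
            [r.atoms.get(name, np.full(3, np.nan)) for r in res]
        )
        for name in ("N", "CA", "C", "O")
    }
    for i in range(1, n):
        if not (ok[i] and ok[i - 1]):
            continue
        if res[i].name == "PRO":
            continue  # proline has no amide hydrogen
        v = coords["O"][i - 1] - coords["C"][i - 1]
        h = coords["N"][i] - 1.01 * v / np.linalg.norm(v)
        # cheap distance prefilter before the energy evaluation
        d_no = np.linalg.norm(coords["O"] - coords["N"][i], axis=1)
        for j in np.flatnonzero(d_no < 5.0):
            if abs(i - j) < 2 or not ok[j]:
                continue
            e = hbond_energy(coords["N"][i], h, coords["C"][j], coords["O"][j])
            if e < HBOND_ENERGY_CUTOFF:
                bonds.add((i, int(j)))
    return bonds


def assign_ss(structure: Structure) -> str:
    """One letter per residue over {H, E, C}; incomplete backbones get C."""
    res = structure.residues
    n = len(res)
    bonds = backbone_hbonds(structure)

    def hb(i, j):
        return 0 <= i < n and 0 <= j < n and (i, j) in bonds

    labels = ["C"] * n

    # helix: runs of >= 4 consecutive i+4 -> i bonds
    turn_start = [i for i in range(n) if hb(i + 4, i)]
    run = []
    for i in sorted(turn_start):
        if run and i == run[-1] + 1:
            run.append(i)
        else:
            run = [i]
        if len(run) >= 4:
            for s in run:
                for k in range(s, s + 5):
                    if 0 <= k < n:
                        labels[k] = "H"

    # strand: DSSP bridge patterns, |i-j| >= 3
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3:
                continue
            antiparallel = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            if antiparallel or parallel:
                if labels[i] != "H":
                    labels[i] = "E"
                if labels[j] != "H":
                    labels[j] = "E"
    for i, r in enumerate(res):
        if not r.complete_backbone:
            labels[i] = "C"
    return "".join(labels)


def strand_segments(ss: str, min_len: int = 2) -> list:
    """Maximal runs of E with length >= min_len, numbered 1..n."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    segments = []
    start = None
    for i, c in enumerate(ss + "C"):
        if c == "E" and start is None:
            start = i
        elif c != "E" and start is not None:
            if i - start >= min_len:
                segments.append(
                    StrandSegment(index=len(segments) + 1, start=start + 1, end=i)
                )
            start = None
    return segments


def filter_msa(msa: MSA, coverage_min: float = 0.90, identity_min: float = 0.30) -> MSA:
    """Keep rows covering >= ``coverage_min`` of the master's columns with
    identity >= ``identity_min`` to the master over mutually aligned columns.

    Both thresholds are inclusive; the master row is always kept.  Dropped
    rows are logged with the failing criterion.
    """
    master = msa.master
    master_cols = [i for i, c in enumerate(master) if c != "-"]
    m_len = len(master_cols)
    kept = []
    for rid, seq in msa.rows:
        if rid == msa.master_id:
            kept.append((rid, seq))
            continue
        non_gap = [i for i in master_cols if seq[i] != "-"]
        coverage = len(non_gap) / m_len if m_len else 0.0
        if coverage < coverage_min:
            logger.debug("filter_msa: dropped %s (coverage %.3f)", rid, coverage)
            continue
        matches = sum(1 for i in non_gap if seq[i] == master[i])
        identity = matches / len(non_gap) if non_gap else 0.0
        if identity < identity_min:
            logger.debug("filter_msa: dropped %s (identity %.3f)", rid, identity)
            continue
        kept.append((rid, seq))
    return MSA(master_id=msa.master_id, rows=kept)


def make_windows(segments: list, k: int = 4) -> list:
    """Sliding windows of ``k`` consecutive strands.

    Returns [(strand_span, residue_range)]: span (i, i+k-1) in strand
    ordinals, residue_range from the first strand's start to the last
    strand's end (intervening loops included, flanking loops excluded).
    """
    windows = []
    for i in range(len(segments) - k + 1):
        span = (segments[i].index, segments[i + k - 1].index)
        windows.append((span, (segments[i].start, segments[i + k - 1].end)))
    return windows


def restrict_msa(msa: MSA, residue_range: tuple) -> MSA:
    """Columns where the master's ungapped 1-based position lies in range.

    Rows left entirely gapped are dropped (the master is always kept).
    """
    lo, hi = residue_range
    master = msa.master
    ungapped = 0
    cols = []
    for i, c in enumerate(master):
        if c != "-":
            ungapped += 1
            if lo <= ungapped <= hi:
                cols.append(i)
    if lo < 1 or hi > ungapped:
        raise ValueError(f"residue range {residue_range} outside master (1..{ungapped})")
    rows = []
    for rid, seq in msa.rows:
        sub = "".join(seq[i] for i in cols)
        if rid != msa.master_id and not sub.replace("-", ""):
            logger.debug("restrict_msa: dropped all-gap row %s", rid)
            continue
        rows.append((rid, sub))
    return MSA(master_id=msa.master_id, rows=rows)
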