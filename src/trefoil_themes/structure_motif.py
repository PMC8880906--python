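"""Structural motif search and conserved-water geometry detection.

The search motif is a (possibly discontinuous) set of CA coordinates — for
the β-trefoil-like (βTL) motif, strands β1/β2 and the water-binding loop.
Targets are scanned by gapless threading of the motif segments at every
order-preserving offset combination, then the best candidates are refined
by the usual TM-score iteration: superpose on the close subset, re-derive a
monotone residue mapping by dynamic programming on the distance score
matrix 1/(1 + (d_ij/d0)^2), repeat until the mapping is stable.

TM-scores are normalized to the motif length L_norm with

    d0 = 1.24 * (L_norm - 15)^(1/3) - 1.8   (floored at 0.5 A)

so a score > 0.5 indicates the same-fold level of similarity regardless of
the size of the host domain.

Water context: a conserved water is operationally a water oxygen with at
least three short (<= 3.0 A) hydrogen bonds to backbone N/O atoms of motif
residues, annotated by secondary-structure context (strand/loop), the
hydrophobic clamp of the two strand partners, and the proline "dry" variant
in which the water is absent because its donor site cannot donate.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .formats_io import Structure

__all__ = [
    "MotifHit",
    "WaterMotifReport",
    "StructuralMotif",
    "kabsch",
    "tm_d0",
    "tm_score",
    "motif_search",
    "theme_rmsd",
    "find_water_motif",
    "hydrophobic_clamp",
    "detect_dry_motif",
    "extract_motif",
]

logger = logging.getLogger(__name__)

HYDROPHOBIC = set("AVLIMFWYC")


def kabsch(P, Q):
    """Least-squares rigid superposition of P onto Q.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1; reflections are corrected).  Apply as ``P @ R.T + t``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale for normalization length ``l_norm``."""
    if l_norm < 16:
        logger.warning("TM-score d0 floored: L_norm=%d < 16", l_norm)
        return 0.5
    return max(1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8, 0.5)


@dataclasses.dataclass
class MotifHit:
    """Structural alignment of the motif onto one target."""

    target_domain: str
    mapping: list  # (motif index, target index) 0-based, strictly increasing
    tm_score: float
    rmsd: float
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None

    def __post_init__(self):
        if self.tm_score > 1.0 + 1e-9:
            raise ValueError("TM-score cannot exceed 1")
        for (a1, b1), (a2, b2) in zip(self.mapping, self.mapping[1:]):
            if not (a2 > a1 and b2 > b1):
                raise ValueError("mapping must be order-preserving")


@dataclasses.dataclass
class WaterMotifReport:
    """One conserved-water candidate and its hydrogen-bond context."""

    water_id: str
    partners: list  # (residue number, atom name, distance A)
    partner_context: list  # 'strand' | 'loop' per short partner
    n_short_hbonds: int
    clamp: bool
    dry: bool = False


@dataclasses.dataclass
class StructuralMotif:
    """A discontinuous CA motif plus its water-partner annotation.

    ``segments`` are (start, end) 1-based ranges on the source chain;
    ``donor_positions`` index into the concatenated motif (0-based) at
    residues whose amide N-H donates to the conserved water.
    """

    ca: np.ndarray
    segment_lengths: list
    source_id: str = ""
    donor_positions: list = dataclasses.field(default_factory=list)
    residue_numbers: list = dataclasses.field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.ca)


def extract_motif(structure: Structure, segments, source_id: str = "",
                  donor_residues=()) -> StructuralMotif:
    """CA coordinates of the author-numbered ``segments`` of a chain.

    ``donor_residues`` (author numbers) are translated into 0-based motif
    positions for the dry-motif rule.
    """
    ca = []
    numbers = []
    seg_lengths = []
    for lo, hi in segments:
        n0 = len(ca)
        for r in structure.residues:
            if lo <= r.number <= hi and "CA" in r.atoms:
                ca.append(r.atoms["CA"])
                numbers.append(r.number)
        if len(ca) == n0:
            raise ValueError(f"segment {lo}-{hi} has no CA atoms in chain")
        seg_lengths.append(len(ca) - n0)
    donors = [i for i, n in enumerate(numbers) if n in set(donor_residues)]
    return StructuralMotif(
        ca=np.array(ca),
        segment_lengths=seg_lengths,
        source_id=source_id,
        donor_positions=donors,
        residue_numbers=numbers,
    )


def _tm_from_distances(d: np.ndarray, d0: float, l_norm: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_score(mapping, motif_ca, target_ca, l_norm: int) -> float:
    """Motif-length-normalized TM-score of a fixed residue mapping,
    maximized over rigid superpositions by iterative subset refinement."""
    if not len(mapping):
        raise ValueError("empty mapping")
    motif_ca = np.asarray(motif_ca, dtype=float)
    target_ca = np.asarray(target_ca, dtype=float)
    mi = np.array([m for m, _ in mapping])
    ti = np.array([t for _, t in mapping])
    P, Q = motif_ca[mi], target_ca[ti]
    d0 = tm_d0(l_norm)
    best = 0.0
    n = len(P)
    seeds = [np.arange(n)]
    if n >= 6:
        seeds.append(np.arange(n // 2))
        seeds.append(np.arange(n - n // 2, n))
    for subset in seeds:
        for _ in range(20):
            if len(subset) < 3:
                break
            R, t, _ = kabsch(P[subset], Q[subset])
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            best = max(best, _tm_from_distances(d, d0, l_norm))
            cutoff = max(d0, 1.5)
            new = np.flatnonzero(d < cutoff)
            if len(new) < 3 or np.array_equal(new, subset):
                break
            subset = new
    return best


def _monotone_mapping(score: np.ndarray):
    """Maximum-sum monotone (order-preserving, ungapped-cost) alignment of a
    score matrix; returns index pairs with positive contribution."""
    n, m = score.shape
    D = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = D[i - 1, j - 1] + score[i - 1, j - 1]
            up = D[i - 1, j]
            left = D[i, j - 1]
            best = diag
            p = 0
            if up > best:
                best, p = up, 1
            if left > best:
                best, p = left, 2
            D[i, j] = best
            ptr[i, j] = p
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _refine(mapping, motif_ca, target_ca, l_norm):
    """TM-align-style alternation between superposition and monotone
    re-mapping; returns the best (tm, mapping, R, t) encountered."""
    d0 = tm_d0(l_norm)
    best = (0.0, mapping, None, None)
    current = list(mapping)
    seen = set()
    for _ in range(20):
        key = tuple(current)
        if key in seen or len(current) < 3:
            break
        seen.add(key)
        mi = np.array([m for m, _ in current])
        ti = np.array([t for _, t in current])
        subset = np.arange(len(current))
        R = t = None
        for _ in range(10):
            if len(subset) < 3:
                break
            R, t, _ = kabsch(motif_ca[mi][subset], target_ca[ti][subset])
            d = np.linalg.norm(motif_ca[mi] @ R.T + t - target_ca[ti], axis=1)
            tm_here = _tm_from_distances(d, d0, l_norm)
            if tm_here > best[0]:
                best = (tm_here, current, R, t)
            new = np.flatnonzero(d < max(d0, 1.5))
            if len(new) < 3 or np.array_equal(new, subset):
                break
            subset = new
        if R is None:
            break
        # re-derive the mapping from the current superposition
        moved = motif_ca @ R.T + t
        dmat = np.linalg.norm(moved[:, None, :] - target_ca[None, :, :], axis=2)
        smat = 1.0 / (1.0 + (dmat / d0) ** 2) - 0.05  # small floor: skip junk pairs
        current = _monotone_mapping(smat)
    return best


def _threadings(segment_lengths, target_len, max_candidates=2000):
    """Gapless placements of the motif segments on the target (segment order
    preserved, inter-segment target gaps >= 0)."""
    if len(segment_lengths) == 1:
        l1 = segment_lengths[0]
        for o in range(target_len - l1 + 1):
            yield (o,)
        return
    l1, l2 = segment_lengths[0], sum(segment_lengths[1:])
    count = 0
    for o1 in range(target_len - l1 - l2 + 1):
        for o2 in range(o1 + l1, target_len - l2 + 1):
            yield (o1, o2)
            count += 1
            if count >= max_candidates:
                return


def motif_search(motif: StructuralMotif, target_ca, target_id: str = "",
                 l_norm: int | None = None) -> MotifHit:
    """Best motif placement on a target chain by TM-score.

    Pass 1 scores every gapless segment threading with a single
    superposition; pass 2 refines the best few with the iterative
    subset/re-mapping loop.  Returns an empty hit (tm 0) when the target is
    shorter than half the motif.
    """
    target_ca = np.asarray(target_ca, dtype=float)
    L = len(target_ca)
    l_norm = l_norm or motif.length
    if L < motif.length / 2 or L < 3:
        return MotifHit(target_domain=target_id, mapping=[], tm_score=0.0, rmsd=float("nan"))
    d0 = tm_d0(l_norm)

    seg_lengths = list(motif.segment_lengths)
    if sum(seg_lengths) > L:
        # allow partial threading of the first segments that fit
        seg_lengths = seg_lengths[:1]

    scored = []
    for offsets in _threadings(seg_lengths, L):
        mapping = []
        pos = 0
        for seg_len, off in zip(seg_lengths, offsets):
            for k in range(seg_len):
                mapping.append((pos, off + k))
                pos += 1
        mi = np.array([m for m, _ in mapping])
        ti = np.array([t for _, t in mapping])
        try:
            R, t, _ = kabsch(motif.ca[mi], target_ca[ti])
        except ValueError:
            continue
        d = np.linalg.norm(motif.ca[mi] @ R.T + t - target_ca[ti], axis=1)
        scored.append((_tm_from_distances(d, d0, l_norm), mapping))
    if not scored:
        return MotifHit(target_domain=target_id, mapping=[], tm_score=0.0, rmsd=float("nan"))
    scored.sort(key=lambda x: -x[0])

    best_tm, best_map, best_R, best_t = 0.0, [], None, None
    for tm0, mapping in scored[:5]:
        tm, mp, R, t = _refine(mapping, motif.ca, target_ca, l_norm)
        if tm > best_tm:
            best_tm, best_map, best_R, best_t = tm, mp, R, t
    if best_R is None:
        tm0, best_map = scored[0]
        mi = np.array([m for m, _ in best_map])
        ti = np.array([t for _, t in best_map])
        best_R, best_t, _ = kabsch(motif.ca[mi], target_ca[ti])
        best_tm = tm0
    mi = np.array([m for m, _ in best_map])
    ti = np.array([t for _, t in best_map])
    _, _, rmsd = kabsch(motif.ca[mi], target_ca[ti])
    return MotifHit(
        target_domain=target_id,
        mapping=best_map,
        tm_score=min(best_tm, 1.0),
        rmsd=rmsd,
        rotation=best_R,
        translation=best_t,
    )


def theme_rmsd(alignment, coords_a, coords_b) -> float:
    """Superposition RMSD over aligned CA pairs.

    ``alignment`` holds 1-based (pos_a, pos_b) pairs; pairs with a missing
    CA on either side are dropped (logged); fewer than 3 usable pairs gives
    NaN (undefined, flagged).
    """
    P, Q = [], []
    dropped = 0
    for a, b in alignment:
        ca_a = coords_a.get(a) if isinstance(coords_a, dict) else (
            coords_a[a - 1] if a - 1 < len(coords_a) else None
        )
        ca_b = coords_b.get(b) if isinstance(coords_b, dict) else (
            coords_b[b - 1] if b - 1 < len(coords_b) else None
        )
        if ca_a is None or ca_b is None:
            dropped += 1
            continue
        P.append(ca_a)
        Q.append(ca_b)
    if dropped:
        logger.debug("theme_rmsd: dropped %d pairs lacking CA", dropped)
    if len(P) < 3:
        logger.warning("theme_rmsd undefined: only %d usable pairs", len(P))
        return float("nan")
    _, _, rmsd = kabsch(np.array(P), np.array(Q))
    return rmsd


def find_water_motif(
    structure: Structure,
    motif_residues,
    ss: str | None = None,
    short_cutoff: float = 3.0,
    max_cutoff: float = 3.5,
    min_short: int = 3,
    sidechain_acceptors: bool = False,
) -> list:
    """Conserved-water candidates among the structure's waters.

    For each water, backbone N/O atoms of ``motif_residues`` (1-based
    residue numbers) within ``max_cutoff`` are listed with distances; the
    water is reported when at least ``min_short`` distinct residues lie at
    <= ``short_cutoff``.  Contexts come from ``ss`` (E -> strand, else
    loop).  With ``sidechain_acceptors`` serine/threonine/tyrosine hydroxyl
    oxygens also count as partners (the β-grasp variant).
    """
    motif_set = set(motif_residues)
    reports = []
    index_of = {r.number: i for i, r in enumerate(structure.residues)}
    for water in structure.waters:
        partners = []
        for r in structure.residues:
            if r.number not in motif_set:
                continue
            names = ["N", "O"]
            if sidechain_acceptors and r.name in ("SER", "THR", "TYR"):
                names += [n for n in ("OG", "OG1", "OH") if n in r.atoms]
            for name in names:
                if name not in r.atoms:
                    continue
                dist = float(np.linalg.norm(r.atoms[name] - water.coord))
                if dist <= max_cutoff:
                    partners.append((r.number, name, dist))
        short = [p for p in partners if p[2] <= short_cutoff]
        if len({p[0] for p in short}) < min_short:
            continue
        context = []
        for rn, _, _ in short:
            if ss is not None and rn in index_of and index_of[rn] < len(ss):
                context.append("strand" if ss[index_of[rn]] == "E" else "loop")
            else:
                context.append("loop")
        strand_partners = sorted({rn for (rn, _, _), c in zip(short, context) if c == "strand"})
        clamp = False
        if len(strand_partners) >= 2:
            clamp = hydrophobic_clamp(structure, strand_partners[:2])
        reports.append(
            WaterMotifReport(
                water_id=water.water_id,
                partners=sorted(partners, key=lambda p: p[2]),
                partner_context=context,
                n_short_hbonds=len(short),
                clamp=clamp,
            )
        )
    return reports


def hydrophobic_clamp(structure: Structure, strand_partner_residues,
                      contact_cutoff: float = 5.0, cb_cutoff: float = 6.5) -> bool:
    """Do the two water-binding strand residues clamp with their sidechains?

    True when both are hydrophobic and their sidechain heavy atoms touch
    (<= ``contact_cutoff``); with CB-only models the CB–CB distance at
    <= ``cb_cutoff`` is the proxy.
    """
    try:
        r1 = structure.residue_by_number(strand_partner_residues[0])
        r2 = structure.residue_by_number(strand_partner_residues[1])
    except KeyError:
        return False
    from .formats_io import AA1

    aa1 = AA1.get(r1.name, "X")
    aa2 = AA1.get(r2.name, "X")
    if aa1 not in HYDROPHOBIC or aa2 not in HYDROPHOBIC:
        return False
    backbone = {"N", "CA", "C", "O"}
    sc1 = {k: v for k, v in r1.atoms.items() if k not in backbone}
    sc2 = {k: v for k, v in r2.atoms.items() if k not in backbone}
    if not sc1 or not sc2:
        return False
    cb_only = set(sc1) == {"CB"} and set(sc2) == {"CB"}
    cutoff = cb_cutoff if cb_only else contact_cutoff
    dmin = min(
        float(np.linalg.norm(v1 - v2)) for v1 in sc1.values() for v2 in sc2.values()
    )
    return dmin <= cutoff


def detect_dry_motif(structure: Structure, motif_hit: MotifHit,
                     donor_positions, ss: str | None = None) -> bool:
    """Is this a proline-enabled "dry" βTL motif?

    True iff no qualifying water exists among the mapped residues AND at
    least one mapped backbone H-bond donor position carries a proline.  A
    waterless motif without a proline at a donor site is incomplete, not
    dry.
    """
    numbers = [structure.residues[t].number for _, t in motif_hit.mapping
               if t < len(structure.residues)]
    if find_water_motif(structure, numbers, ss=ss):
        return False
    target_of = dict(motif_hit.mapping)
    for pos in donor_positions:
        t = target_of.get(pos)
        if t is not None and t < len(structure.residues):
            if structure.residues[t].name == "PRO":
                return True
    return False
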