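"""Synthetic inputs with known ground truth for both pipeline tracks.

Sequence track: families of homologous sequences around a master, with a
"planted theme" — a shared segment copied, at controlled divergence, from a
donor master into an otherwise unrelated recipient family — plus decoy
families of random sequences.

Structure track: idealized four-strand antiparallel sheets built from
standard bond lengths and angles, with a planted water satisfying the
three-backbone-H-bond geometry of the conserved β-trefoil water (one β1
site, one β2 site, one loop site), optional Gaussian coordinate noise, a
hydrophobic clamp (Leu/Ile across the water-binding strands) and a "dry"
proline variant with no water.  Decoys are ideal α-helices and self-avoiding
random coils.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import functools
import json

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .formats_io import MSA, Residue, Structure, Water

__all__ = [
    "AMINO_ACIDS",
    "ScenarioParams",
    "ThemeScenario",
    "SyntheticStructure",
    "generate_family",
    "plant_theme",
    "generate_theme_scenario",
    "generate_btl_structure",
    "generate_decoy_structure",
    "build_backbone",
    "place_atom",
    "ideal_helix_backbone",
    "equal_chord_arc",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# ---------------------------------------------------------------------------
# sequence track
# ---------------------------------------------------------------------------


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng, sequence: str, rate: float) -> str:
    """Substitute each position independently at ``rate`` (uniform over the
    19 alternatives)."""
    out = list(sequence)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_family(
    master_sequence: str,
    n_members: int,
    substitution_rate: float,
    seed: int,
    family_id: str = "fam",
) -> MSA:
    """A gapless family MSA: the master plus members mutated i.i.d. from it."""
    if not master_sequence:
        raise ValueError("empty master sequence")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must be in [0, 1]")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [(f"{family_id}|master", master_sequence)]
    for i in range(n_members - 1):
        rows.append((f"{family_id}|m{i + 1}", _mutate(rng, master_sequence, substitution_rate)))
    return MSA(master_id=rows[0][0], rows=rows)


def plant_theme(
    theme: str,
    host_sequence: str,
    position: int,
    divergence_rate: float,
    seed: int,
) -> str:
    """Substitute ``theme`` (mutated at ``divergence_rate``) into the host
    in place at 1-based ``position``; host length is preserved."""
    if len(theme) > len(host_sequence):
        raise ValueError("theme longer than host")
    if not 1 <= position <= len(host_sequence) - len(theme) + 1:
        raise ValueError(f"position {position} out of range")
    rng = np.random.default_rng(seed)
    mutated = _mutate(rng, theme, divergence_rate)
    i = position - 1
    return host_sequence[:i] + mutated + host_sequence[i + len(theme):]


@dataclasses.dataclass
class ScenarioParams:
    """Study conditions for a planted-theme scenario.

    Defaults describe one donor (β-trefoil-like, X-group 6) family whose
    master carries six β-strands, a 30-residue theme covering four of them,
    one recipient family (X-group 11) that received the theme at 30%
    divergence, and two decoy families of unrelated random sequences.
    """

    master_length: int = 100
    theme_length: int = 30
    theme_divergence: float = 0.3
    theme_position_donor: int = 31  # 1-based start within donor master
    theme_position_recipient: int = 41
    family_size: int = 20
    family_substitution_rate: float = 0.2
    n_decoy_families: int = 2
    decoy_family_size: int = 10
    donor_group: str = "6.1.1"
    recipient_group: str = "11.1.1"
    decoy_groups: tuple = ("99.1.1", "98.1.1", "97.1.1", "96.1.1")

    def __post_init__(self):
        if self.theme_length < 15:
            raise ValueError("planted theme must be >= 15 residues")
        if self.n_decoy_families > len(self.decoy_groups):
            raise ValueError("not enough decoy group labels")


def _donor_ss(params: ScenarioParams) -> str:
    """Secondary-structure string for the donor master: four strands evenly
    spread over the planted theme plus one flanking strand on each side, so
    at least one 4-strand window covers the theme."""
    L = params.master_length
    start = params.theme_position_donor - 1  # 0-based
    tl = params.theme_length
    ss = ["C"] * L
    # four strands inside the theme: split the theme into 4 strands with
    # 1-residue gaps between them
    gap = 1
    strand_len = (tl - 3 * gap) // 4
    pos = start
    strands = []
    for k in range(4):
        end = pos + strand_len
        if k == 3:
            end = start + tl  # last strand absorbs the remainder
        strands.append((pos, min(end, start + tl)))
        pos = end + gap
    # flanking strands outside the theme (if room)
    if start >= 8:
        strands.insert(0, (start - 7, start - 3))
    if start + tl + 8 <= L:
        strands.append((start + tl + 3, start + tl + 7))
    for lo, hi in strands:
        for i in range(lo, hi):
            ss[i] = "E"
    return "".join(ss)


@dataclasses.dataclass
class ThemeScenario:
    """Families plus ground truth for the planted shared segment."""

    families: list  # (MSA, group) pairs, donor first, then recipient
    decoy_families: list  # (MSA, group) pairs
    theme: str
    donor_family_id: str
    recipient_family_id: str
    theme_position_donor: int
    theme_position_recipient: int
    theme_divergence: float
    donor_ss: str
    truth: list  # (window_span, recipient_family_id) expected hit pairs
    params: ScenarioParams

    def database(self) -> list:
        """All searchable (domain_id, sequence, group) targets: recipient and
        decoy family members (the donor family is the query side)."""
        db = []
        for msa, group in self.families[1:] + self.decoy_families:
            for rid, seq in msa.rows:
                db.append((rid, seq.replace("-", ""), group))
        return db

    def truth_sidecar(self) -> str:
        """JSON ground-truth record (documented keys)."""
        return json.dumps(
            {
                "theme": self.theme,
                "donor_family": self.donor_family_id,
                "recipient_family": self.recipient_family_id,
                "theme_position_donor": self.theme_position_donor,
                "theme_position_recipient": self.theme_position_recipient,
                "theme_divergence": self.theme_divergence,
                "truth_pairs": [
                    {"window_span": list(span), "target_family": fam}
                    for span, fam in self.truth
                ],
            },
            indent=2,
        )


def generate_theme_scenario(params: ScenarioParams | None = None, seed: int = 0) -> ThemeScenario:
    """Build a full planted-theme scenario with its ground truth.

    The donor master is annotated with strands such that at least one
    4-strand sliding window covers the theme; ``truth`` lists every window
    whose residue range overlaps the planted segment by at least half the
    theme length, paired with the recipient family.
    """
    from .secstruct_fragments import make_windows, strand_segments

    params = params or ScenarioParams()
    rng = np.random.default_rng(seed)
    donor_master = _random_sequence(rng, params.master_length)
    theme = donor_master[
        params.theme_position_donor - 1 : params.theme_position_donor - 1 + params.theme_length
    ]
    donor = generate_family(
        donor_master,
        params.family_size,
        params.family_substitution_rate,
        seed=int(rng.integers(2**31)),
        family_id="donor",
    )

    recipient_host = _random_sequence(rng, params.master_length)
    recipient_master = plant_theme(
        theme,
        recipient_host,
        params.theme_position_recipient,
        params.theme_divergence,
        seed=int(rng.integers(2**31)),
    )
    recipient = generate_family(
        recipient_master,
        params.family_size,
        params.family_substitution_rate,
        seed=int(rng.integers(2**31)),
        family_id="recipient",
    )

    decoys = []
    for d in range(params.n_decoy_families):
        master = _random_sequence(rng, params.master_length)
        decoys.append(
            (
                generate_family(
                    master,
                    params.decoy_family_size,
                    params.family_substitution_rate,
                    seed=int(rng.integers(2**31)),
                    family_id=f"decoy{d + 1}",
                ),
                params.decoy_groups[d],
            )
        )

    ss = _donor_ss(params)
    segments = strand_segments(ss, min_len=2)
    windows = make_windows(segments, k=4)
    t_lo = params.theme_position_donor
    t_hi = t_lo + params.theme_length - 1
    truth = []
    for span, (lo, hi) in windows:
        overlap = max(0, min(hi, t_hi) - max(lo, t_lo) + 1)
        if overlap >= params.theme_length / 2:
            truth.append((span, "recipient"))
    if not truth:
        raise ValueError("scenario configuration: no 4-strand window covers the theme")

    return ThemeScenario(
        families=[(donor, params.donor_group), (recipient, params.recipient_group)],
        decoy_families=decoys,
        theme=theme,
        donor_family_id="donor",
        recipient_family_id="recipient",
        theme_position_donor=params.theme_position_donor,
        theme_position_recipient=params.theme_position_recipient,
        theme_divergence=params.theme_divergence,
        donor_ss=ss,
        truth=truth,
        params=params,
    )


# ---------------------------------------------------------------------------
# structure track: ideal backbone geometry
# ---------------------------------------------------------------------------

_DEG = np.pi / 180.0

# ideal backbone internal coordinates (Å, degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.53
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8

STRAND_PHI, STRAND_PSI = -139.0, 135.0
HELIX_PHI, HELIX_PSI = -57.0, -47.0

HBOND_NO = 2.9  # target N···O donor-acceptor distance in the sheet


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d after a-b-c."""
    ang, tor = angle * _DEG, torsion * _DEG
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-bond * np.cos(ang), bond * np.cos(tor) * np.sin(ang), bond * np.sin(tor) * np.sin(ang)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phis, psis) -> dict:
    """Backbone N/CA/C/O coordinate arrays from per-residue torsions."""
    n = len(phis)
    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    O = np.zeros((n, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [B_N_CA, 0.0, 0.0]
    C[0] = place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0], B_CA_C, A_N_CA_C, phis[0] + 60.0)
    for i in range(n):
        if i > 0:
            N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psis[i - 1])
            CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, 180.0)
            C[i] = place_atom(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phis[i])
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psis[i] + 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def ideal_helix_backbone(n_res: int) -> dict:
    return build_backbone([HELIX_PHI] * n_res, [HELIX_PSI] * n_res)


def ideal_strand_backbone(n_res: int) -> dict:
    return build_backbone([STRAND_PHI] * n_res, [STRAND_PSI] * n_res)


def _transform(coords: np.ndarray, params: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    return coords @ rot.T + params[3:]


@functools.lru_cache(maxsize=16)
def _strand_pair_transform(n_res: int, parity: int) -> tuple:
    """Rigid transform placing an antiparallel partner next to the template
    strand so that alternating residue pairs form mutual 2.9 Å N···O bonds.

    ``parity`` selects which register pairs (template residue i with partner
    residue n-1-i, i odd or even) carry the bonds; the two registers place
    the partner on opposite faces, which is what lets an up-down sheet grow
    by alternating them.  The template carries one virtual residue at each
    end (indices 0 and n+1 of an n+2 chain) whose carbonyls are later
    grafted onto the flanking turn residues so that amide hydrogens at
    strand entry points keep ideal geometry.  Returned as (rotation matrix,
    translation, pairs in template-local 0-based inner indices);
    deterministic.
    """
    ext = ideal_strand_backbone(n_res + 2)
    inner = slice(1, n_res + 1)
    center = ext["CA"][inner].mean(axis=0)
    A = {k: v - center for k, v in ext.items()}
    # amide hydrogens (defined for ext indices >= 1)
    H = np.zeros_like(A["N"])
    for i in range(1, n_res + 2):
        v = A["O"][i - 1] - A["C"][i - 1]
        H[i] = A["N"][i] - 1.01 * v / np.linalg.norm(v)
    A["H"] = H
    A["CB"] = np.array(
        [_cb_position(A["N"][i], A["CA"][i], A["C"][i]) for i in range(n_res + 2)]
    )
    # inner residue i (0-based within the strand) = ext index i+1
    pairs = [(i, n_res - 1 - i) for i in range(parity, n_res, 2)]

    def objective(params):
        Bn = _transform(A["N"], params)
        Bo = _transform(A["O"], params)
        Bh = _transform(A["H"], params)
        Bcb = _transform(A["CB"], params)
        cost = 0.0
        for i, j in pairs:
            # mutual N-H···O=C bonds: the donor hydrogen must point at the
            # acceptor oxygen, not merely sit near it
            cost += (np.linalg.norm(A["O"][i + 1] - Bn[j + 1]) - HBOND_NO) ** 2
            cost += (np.linalg.norm(A["N"][i + 1] - Bo[j + 1]) - HBOND_NO) ** 2
            cost += (np.linalg.norm(A["O"][i + 1] - Bh[j + 1]) - 1.90) ** 2
            cost += (np.linalg.norm(A["H"][i + 1] - Bo[j + 1]) - 1.90) ** 2
            # bonded pairs pleat in register: their sidechains face the same
            # sheet face (this is what makes the hydrophobic clamp possible)
            cost += max(np.linalg.norm(A["CB"][i + 1] - Bcb[j + 1]) - 5.5, 0.0) ** 2
        allA = np.concatenate([A[k][inner] for k in ("N", "CA", "C", "O")])
        allB = np.concatenate(
            [_transform(A[k], params)[inner] for k in ("N", "CA", "C", "O")]
        )
        d = np.linalg.norm(allA[:, None, :] - allB[None, :, :], axis=2)
        cost += float(np.sum(np.clip(2.7 - d, 0.0, None) ** 2)) * 10.0
        return cost

    res = None
    for y0 in (4.8, -4.8):
        x0 = np.array([0.0, 0.0, np.pi, 0.0, y0, 0.0])
        cand = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-12},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    if res.fun > 3.0:
        raise RuntimeError("strand pairing optimization failed to converge")
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    # full transform in the original (uncentered) frame:
    #   y = R (x - c) + t + c
    trans = res.x[3:] + center - rot @ center
    return rot, trans, tuple(pairs)


def equal_chord_arc(p: np.ndarray, q: np.ndarray, n_points: int, step: float = 3.8,
                    bulge_dir: np.ndarray | None = None) -> np.ndarray:
    """``n_points`` intermediate positions on a circular arc from p to q such
    that all n_points+1 consecutive chords have length ``step``."""
    g = float(np.linalg.norm(q - p))
    m = n_points + 1
    if g > m * step:
        raise ValueError("gap too wide for the requested number of points")
    u = q - p
    u = u / np.linalg.norm(u)
    if bulge_dir is None:
        bulge_dir = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(bulge_dir, u)) > 0.9:
            bulge_dir = np.array([1.0, 0.0, 0.0])
    w = bulge_dir - np.dot(bulge_dir, u) * u
    if np.linalg.norm(w) < 1e-9:
        raise ValueError("bulge direction parallel to the chord")
    w = w / np.linalg.norm(w)

    # total arc angle theta: g = 2R sin(theta/2), step = 2R sin(theta/2m)
    def chord_ratio(theta):
        return np.sin(theta / 2.0) / np.sin(theta / (2.0 * m))

    lo, hi = 1e-9, 2.0 * np.pi - 1e-6
    target = g / step
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if chord_ratio(mid) > target:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    R = g / (2.0 * np.sin(theta / 2.0))
    center = 0.5 * (p + q) - w * np.sqrt(max(R**2 - (g / 2.0) ** 2, 0.0))
    # rotate p about the axis normal to the (u, w) plane through center,
    # in whichever sense actually lands on q after m steps
    axis = np.cross(u, w)
    axis = axis / np.linalg.norm(axis)
    sign = min(
        (1.0, -1.0),
        key=lambda s: np.linalg.norm(
            center + Rotation.from_rotvec(axis * s * theta).as_matrix() @ (p - center) - q
        ),
    )
    out = []
    for k in range(1, m):
        rot = Rotation.from_rotvec(axis * sign * theta * k / m).as_matrix()
        out.append(center + rot @ (p - center))
    return np.array(out)


def _cb_position(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Tetrahedral CB placement from the backbone frame."""
    v1 = N - CA
    v1 /= np.linalg.norm(v1)
    v2 = C - CA
    v2 /= np.linalg.norm(v2)
    bisector = -(v1 + v2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    direction = bisector * np.cos(0.963) + perp * np.sin(0.963)  # ~55.2 deg tilt
    return CA + B_CA_CB * direction / np.linalg.norm(direction)


def _loop_atoms(ca_path: np.ndarray, prev_ca: np.ndarray, next_ca: np.ndarray,
                out_dir: np.ndarray) -> list:
    """Approximate N/C/O placement for loop residues given the CA trace."""
    pts = np.vstack([prev_ca, ca_path, next_ca])
    atoms = []
    for i in range(1, len(pts) - 1):
        ca = pts[i]
        n = ca + 0.384 * (pts[i - 1] - ca)
        c = ca + 0.40 * (pts[i + 1] - ca)
        o = c + 1.23 * out_dir / np.linalg.norm(out_dir)
        atoms.append({"N": n, "CA": ca, "C": c, "O": o})
    return atoms


def _trilaterate(p1, p2, p3, r: float) -> list:
    """The (up to two) points at distance ``r`` from all three anchors."""
    ex = p2 - p1
    d = np.linalg.norm(ex)
    ex = ex / d
    i = np.dot(ex, p3 - p1)
    ey = p3 - p1 - i * ex
    j = np.linalg.norm(ey)
    ey = ey / j
    ez = np.cross(ex, ey)
    x = d / 2.0  # equal radii
    y = (i**2 + j**2 - 2.0 * i * x) / (2.0 * j)
    h2 = r**2 - x**2 - y**2
    if h2 < 0:
        return []
    h = np.sqrt(h2)
    base = p1 + x * ex + y * ey
    return [base + h * ez, base - h * ez] if h > 1e-9 else [base]


WATER_HBOND_MAX = 2.95  # planted water–backbone donor/acceptor distance, Å


def _carve_water_site(residues, strand_ranges, strands, turn1_len):
    """Open the β1/β2 hairpin and place the conserved water above the last
    ladder rung.

    The two middle residues of the first turn are swung rigidly about the
    axis through the flanking turn CAs (all CA–CA distances are preserved),
    the swung loop carbonyl is aimed at a site above the terminal
    O(β1)···N(β2) ladder bond, and the water is placed at that site.  A
    small deterministic grid over swing angle and site position maximises
    the distance to every non-partner backbone N/O, so that the planted
    water makes exactly three short hydrogen bonds: a β1 carbonyl, a β2
    amide and the loop carbonyl — the strand/strand/loop pattern of the
    conserved β-trefoil water.

    Returns (modified residue atoms, partner list, donor positions, water).
    """
    strand_len = strand_ranges[0][1] - strand_ranges[0][0] + 1
    _, _, pairs = _strand_pair_transform(strand_len, 1)
    # rung closest to the first turn: the pair with the largest β1 index
    i_loc, j_loc = max(pairs)
    i1 = strand_ranges[0][0] + i_loc  # β1 carbonyl acceptor residue
    i2 = strand_ranges[1][0] + j_loc  # β2 amide donor residue
    turn_first = strand_ranges[0][1] + 1
    # swing only the interior turn residues; the first and last turn
    # residues anchor the rotation axis and the last one carries the
    # grafted strand-entry carbonyl, which must stay put
    swing = (turn_first + 1, turn_first + turn1_len - 2)
    il = swing[1]  # loop carbonyl residue (last swung)
    ax1 = strands[0]["CA"][strand_len] - strands[0]["CA"][1]
    ax1 = ax1 / np.linalg.norm(ax1)

    O1 = residues[i1 - 1]["O"]
    N2 = residues[i2 - 1]["N"]
    mid = 0.5 * (O1 + N2)
    rung = N2 - O1
    half = float(np.linalg.norm(rung)) / 2.0
    rung = rung / np.linalg.norm(rung)
    normal = np.cross(ax1, rung)
    normal = normal / np.linalg.norm(normal)

    pivot_a = residues[swing[0] - 2]["CA"]  # first turn residue
    pivot_b = residues[swing[1]]["CA"]  # last turn residue
    axis = pivot_b - pivot_a
    axis = axis / np.linalg.norm(axis)

    best = None
    for alpha in (20.0, 30.0, 40.0, 50.0):
        for sgn in (1.0, -1.0):
            rot = Rotation.from_rotvec(axis * np.deg2rad(sgn * alpha)).as_matrix()
            swung = [dict((k, v.copy()) for k, v in r.items()) for r in residues]
            for idx in range(swing[0] - 1, swing[1]):
                for k in swung[idx]:
                    swung[idx][k] = pivot_a + rot @ (swung[idx][k] - pivot_a)
            for h in np.arange(-2.6, 2.61, 0.2):
                for e in np.arange(-1.0, 2.01, 0.2):
                    if h * h + e * e > WATER_HBOND_MAX**2 - half**2:
                        continue
                    w = mid + h * normal + e * ax1
                    if max(np.linalg.norm(w - O1), np.linalg.norm(w - N2)) > WATER_HBOND_MAX:
                        continue
                    c_loop = swung[il - 1]["C"]
                    dc = np.linalg.norm(w - c_loop)
                    if dc < 3.0 or dc - B_C_O > WATER_HBOND_MAX:
                        continue
                    o_loop = c_loop + B_C_O * (w - c_loop) / dc
                    used = {(i1, "O"), (i2, "N"), (il, "O")}
                    clearance = min(
                        np.linalg.norm(
                            (o_loop if (i + 1, nm) == (il, "O") else swung[i][nm]) - w
                        )
                        for i in range(len(swung))
                        for nm in ("N", "O")
                        if (i + 1, nm) not in used
                    )
                    heavy = min(
                        np.linalg.norm(swung[i][nm] - w)
                        for i in range(len(swung))
                        for nm in ("CA", "C")
                    )
                    score = min(clearance - 3.05, heavy - 2.6)
                    if best is None or score > best[0]:
                        best = (score, alpha, sgn, w, swung, o_loop)
    if best is None or best[0] <= 0.0:
        raise RuntimeError("no admissible water site on the ideal sheet")
    _, _, _, water, swung, o_loop = best
    swung[il - 1]["O"] = o_loop
    partners = [(i1, "O"), (i2, "N"), (il, "O")]
    return swung, partners, [i2], water


@dataclasses.dataclass
class SyntheticStructure:
    """An idealized chain with ground-truth annotation.

    ``water_partners`` are (1-based residue index, backbone atom name)
    triples designated to hydrogen-bond the planted water; ``donor_positions``
    are the residues whose amide N-H donates to the water (prolines there in
    the dry variant).  ``motif_segments`` are the 1-based residue ranges that
    define the searchable structural motif.
    """

    structure: Structure
    sequence: str
    ss: str
    has_motif: bool
    is_dry: bool
    clamp_residues: tuple | None
    water_partners: list
    donor_positions: list
    motif_segments: list

    @property
    def ca(self) -> np.ndarray:
        return self.structure.ca_coords()


_STRAND_AA = "VTIYVTI"  # β-prone filler pattern
_LOOP_AA = "GN"


def _sheet_scaffold(n_strands: int, strand_len: int, turn_lens=(2, 2, 2)):
    """Up-down antiparallel sheet: per-strand atom dicts plus turn CA arcs.

    Strand k+1 is the template carried through k alternating pair
    transforms (odd/even bond registers), so every neighbouring pair of
    strands carries the designed mutual N···O bonds.  Truth secondary
    structure is derived from that designed bond topology: a strand residue
    is E when it lies within the bonded span of its strand; turns are C.

    Returns (residue atom dicts in chain order, truth ss string, strand
    ranges [(start, end) 1-based], per-strand atom arrays).
    """
    template = ideal_strand_backbone(strand_len + 2)  # with virtual end residues
    transforms = [
        _strand_pair_transform(strand_len, 1),
        _strand_pair_transform(strand_len, 0),
    ]
    # G_{k+1} = G_k o T_k (T applied in the template frame)
    G = (np.eye(3), np.zeros(3))
    strands = [template]
    placements = [G]
    bonded = [set() for _ in range(n_strands)]
    for k in range(n_strands - 1):
        rot_t, trans_t, pairs = transforms[k % 2]
        R, t = placements[k]
        G = (R @ rot_t, R @ trans_t + t)
        placements.append(G)
        strands.append(
            {name: coords @ G[0].T + G[1] for name, coords in template.items()}
        )
        for i, j in pairs:
            bonded[k].add(i)
            bonded[k + 1].add(j)

    sheet_center = np.mean([s["CA"][1:-1].mean(axis=0) for s in strands], axis=0)
    residues = []
    ss = []
    strand_ranges = []
    for k, s in enumerate(strands):
        start = len(residues) + 1
        lo, hi = min(bonded[k]), max(bonded[k])
        for i in range(strand_len):  # inner template indices are i + 1
            residues.append(
                {name: s[name][i + 1].copy() for name in ("N", "CA", "C", "O")}
            )
            ss.append("E" if lo <= i <= hi else "C")
        strand_ranges.append((start, len(residues)))
        if k < n_strands - 1:
            nxt = strands[k + 1]
            p = s["CA"][strand_len]  # last real residue of strand k
            q = nxt["CA"][1]  # first real residue of strand k+1
            end_dir = p - sheet_center
            arc = equal_chord_arc(p, q, turn_lens[k], step=3.8, bulge_dir=end_dir)
            out_dir = end_dir / (np.linalg.norm(end_dir) + 1e-9)
            loop = _loop_atoms(arc, p, q, out_dir)
            # graft the next strand's virtual-residue carbonyl onto the last
            # turn residue so the strand-entry amide hydrogen stays ideal
            loop[-1]["C"] = nxt["C"][0].copy()
            loop[-1]["O"] = nxt["O"][0].copy()
            for atom in loop:
                residues.append(atom)
                ss.append("C")
    return residues, "".join(ss), strand_ranges, strands


def _finalize(residues, sequence, waters, noise_sigma, rng, chain="A") -> Structure:
    res_objs = []
    from .formats_io import _AA3

    for i, (atoms, aa) in enumerate(zip(residues, sequence), start=1):
        atom_dict = {}
        for name, xyz in atoms.items():
            noisy = xyz + (rng.normal(0.0, noise_sigma, 3) if noise_sigma > 0 else 0.0)
            atom_dict[name] = np.asarray(noisy, dtype=float)
        if aa != "G":
            cb = _cb_position(atoms["N"], atoms["CA"], atoms["C"])
            atom_dict["CB"] = cb + (rng.normal(0.0, noise_sigma, 3) if noise_sigma > 0 else 0.0)
        res_objs.append(Residue(number=i, name=_AA3.get(aa, "UNK"), atoms=atom_dict))
    water_objs = [
        Water(f"HOH_A_{9000 + i}", np.asarray(w, dtype=float)) for i, w in enumerate(waters, 1)
    ]
    return Structure(chain, res_objs, water_objs)


def generate_btl_structure(
    noise_sigma: float = 0.0, dry: bool = False, seed: int = 0
) -> SyntheticStructure:
    """Four-strand idealized motif with the conserved-water geometry planted.

    The water sits at the β1/β2 hairpin end, 2.85 Å from a β1 backbone
    carbonyl O, the β2 first-strand amide N and a turn carbonyl O — the
    strand/strand/loop pattern of the conserved β-trefoil water.  ``dry``
    omits the water and mutates the designated amide donor to proline.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    strand_len, n_strands = 7, 4
    # the first turn is longer: its wider arc opens the hairpin end so the
    # planted water has exactly three backbone sites within H-bond range
    residues, ss, strand_ranges, strands = _sheet_scaffold(n_strands, strand_len, (4, 2, 2))
    residues, partners, donor_positions, water = _carve_water_site(
        residues, strand_ranges, strands, turn1_len=4
    )
    r_b1, r_b2 = partners[0][0], partners[1][0]

    # sequence: β-prone strands, G/N turns, Leu/Ile clamp on the water strands
    seq = []
    for i, s in enumerate(ss):
        seq.append(_STRAND_AA[i % len(_STRAND_AA)] if s == "E" else _LOOP_AA[i % 2])
    clamp = (r_b1, r_b2)
    seq[r_b1 - 1] = "L"
    seq[r_b2 - 1] = "I"
    if dry:
        for pos in donor_positions:
            seq[pos - 1] = "P"
    sequence = "".join(seq)

    waters = [] if dry else [water]
    structure = _finalize(residues, sequence, waters, noise_sigma, rng)
    motif_segments = [(strand_ranges[0][0], strand_ranges[1][1]),
                      (strand_ranges[2][1] + 1, strand_ranges[3][1])]
    return SyntheticStructure(
        structure=structure,
        sequence=sequence,
        ss=ss,
        has_motif=True,
        is_dry=dry,
        clamp_residues=None if dry else clamp,
        water_partners=partners,
        donor_positions=donor_positions,
        motif_segments=motif_segments,
    )


def generate_decoy_structure(n_res: int, kind: str, seed: int = 0) -> SyntheticStructure:
    """A structure with no planted water geometry: ideal helix or random coil."""
    if n_res < 20:
        raise ValueError("n_res must be >= 20")
    rng = np.random.default_rng(seed)
    if kind == "helix":
        bb = ideal_helix_backbone(n_res)
        residues = [
            {name: bb[name][i].copy() for name in ("N", "CA", "C", "O")} for i in range(n_res)
        ]
        ss_truth = "C" + "H" * (n_res - 2) + "C"
    elif kind == "random_coil":
        # self-avoiding CA random walk with 3.8 Å steps
        cas = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        while len(cas) < n_res:
            for _ in range(100):
                step = direction + rng.normal(0.0, 0.8, 3)
                step = 3.8 * step / np.linalg.norm(step)
                cand = cas[-1] + step
                if all(np.linalg.norm(cand - c) > 3.5 for c in cas[:-1]):
                    cas.append(cand)
                    direction = step / 3.8
                    break
            else:  # restart direction if trapped
                direction = rng.normal(0.0, 1.0, 3)
                direction /= np.linalg.norm(direction)
        cas = np.array(cas)
        pts = np.vstack([cas[0] + np.array([-3.8, 0, 0]), cas, cas[-1] + np.array([3.8, 0, 0])])
        residues = []
        for i in range(1, n_res + 1):
            ca = pts[i]
            n = ca + 0.384 * (pts[i - 1] - ca)
            c = ca + 0.40 * (pts[i + 1] - ca)
            up = np.cross(pts[i + 1] - ca, pts[i - 1] - ca)
            if np.linalg.norm(up) < 1e-6:
                up = np.array([0.0, 0.0, 1.0])
            o = c + 1.23 * up / np.linalg.norm(up)
            residues.append({"N": n, "CA": ca, "C": c, "O": o})
        ss_truth = "C" * n_res
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    sequence = "".join(
        rng.choice(list(AMINO_ACIDS.replace("G", "").replace("P", "")), size=n_res)
    )
    structure = _finalize(residues, sequence, [], 0.0, rng)
    return SyntheticStructure(
        structure=structure,
        sequence=sequence,
        ss=ss_truth,
        has_motif=False,
        is_dry=False,
        clamp_residues=None,
        water_partners=[],
        donor_positions=[],
        motif_segments=[],
    )
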