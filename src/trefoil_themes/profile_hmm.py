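"""Profile hidden Markov models for fragment (theme) searching.

A profile is built from a column-restricted MSA with Henikoff
position-based sequence weights and background-proportional pseudocounts,
then searched against unaligned domain sequences with a local forward
algorithm.  Scores are log-odds in bits against a background residue
distribution:

    score = log2 [ sum over local paths P(subsequence | profile)
                   / P(subsequence | background) ]

with uniform entry over (match state, start position) pairs — weight
1/(M*L) — and a uniform-exit-point distribution: match state k exits with
probability 1/(M - k + 1) and continues with the complementary weight, so
the local path ensemble is a proper sub-probability and background
sequences score at most 0 bits in expectation.  Statistical significance is
calibrated empirically: scores of random background sequences are fitted to
a Gumbel distribution and E-values are reported as
``db_size * P(S >= s | null)``.

The per-sequence E-value here stands in for the conditional (per-domain)
E-value of a full multi-domain decomposition; at fragment scale the two
coincide for single-hit targets.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .evd_significance import GumbelFit, fit_gumbel
from .formats_io import MSA

__all__ = [
    "AA_ORDER",
    "ROBINSON_BACKGROUND",
    "ProfileHMM",
    "ThemeHit",
    "build_hmm",
    "forward_score",
    "viterbi_align",
    "calibrate_evalue",
    "search",
]

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Robinson & Robinson amino-acid frequencies (the HMMER default background)
ROBINSON_BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_LN2 = np.log(2.0)


def background_vector(kind: str = "robinson") -> np.ndarray:
    if kind == "uniform":
        return np.full(20, 0.05)
    bg = np.array([ROBINSON_BACKGROUND[a] for a in AA_ORDER])
    return bg / bg.sum()


@dataclasses.dataclass
class GumbelCalibration:
    """Simulation-fitted null for forward bit scores.

    The Gumbel (method-of-moments) fit describes the bulk of the null; its
    moment-fitted rate decays faster than the true right tail of forward
    scores, whose asymptotic slope is ln 2 per bit (for a normalised
    log-odds score S, Markov's inequality gives P(S >= s) <= 2^-s).  The
    reported p-value therefore never drops below an exponential tail of
    slope ln 2 anchored at the calibration sample's upper ``tail_h``
    quantile (a peaks-over-threshold anchor) — a conservative guard that
    controls false positives far beyond the simulated sample size.
    """

    fit: GumbelFit
    random_len: int
    n_random: int
    tail_anchor: float = 0.0  # (1 - tail_h) quantile of calibration scores
    tail_h: float = 0.02

    def pvalue(self, score: float) -> float:
        z = self.fit.lam * (score - self.fit.mu)
        p_gumbel = float(-np.expm1(-np.exp(-z)))
        p_tail = self.tail_h * min(1.0, 2.0 ** -(score - self.tail_anchor))
        return min(1.0, max(p_gumbel, p_tail))


@dataclasses.dataclass
class ProfileHMM:
    """Match/insert/delete profile with emissions, transitions, background.

    ``match_emissions``: (M, 20); ``insert_emissions``: (M+1, 20);
    transitions are per-node probability arrays over the seven profile
    moves.  Probabilities are strictly positive after smoothing and each
    distribution sums to 1.
    """

    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    t_mm: np.ndarray  # M_k -> M_{k+1}, length M-1 (index k-1)
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    background: np.ndarray
    master_id: str = ""
    strand_span: tuple | None = None
    calibration: GumbelCalibration | None = None

    def __post_init__(self):
        for name in ("match_emissions", "insert_emissions"):
            rows = getattr(self, name)
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if not (rows > 0).all():
                raise ValueError(f"{name} must be strictly positive")
        out_m = self.t_mm + self.t_mi + self.t_md
        if len(out_m) and not np.allclose(out_m, 1.0, atol=1e-9):
            raise ValueError("match-state outgoing transitions must sum to 1")

    @property
    def M(self) -> int:
        return len(self.match_emissions)

    @property
    def profile_id(self) -> str:
        if self.strand_span:
            return f"{self.master_id}|w{self.strand_span[0]}-{self.strand_span[1]}"
        return self.master_id


@dataclasses.dataclass
class ThemeHit:
    """One significant profile-vs-domain alignment."""

    profile_id: str
    master_domain: str
    target_domain: str
    target_group: str
    bit_score: float
    evalue: float
    alignment: list  # (master window position, target position), 1-based
    shuffle_pvalue: float | None = None
    segment_rmsd: float | None = None

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        pairs = self.alignment
        for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]):
            if not (a2 > a1 and b2 > b1):
                raise ValueError("alignment must be strictly increasing")


def _encode(sequence: str) -> np.ndarray:
    """Residues to indices; unknowns (incl. X) map to -1 = background."""
    idx = np.array([_AA_INDEX.get(a, -1) for a in sequence.upper()], dtype=int)
    n_unknown = int((idx < 0).sum())
    if n_unknown:
        logger.debug("%d unknown residues scored as background", n_unknown)
    return idx


def henikoff_weights(rows: list) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to 1."""
    n = len(rows)
    if n == 1:
        return np.ones(1)
    w = np.zeros(n)
    length = len(rows[0])
    for c in range(length):
        col = [row[c] for row in rows]
        counts: dict = {}
        for a in col:
            if a != "-":
                counts[a] = counts.get(a, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for i, a in enumerate(col):
            if a != "-":
                w[i] += 1.0 / (r * counts[a])
    if w.sum() == 0:
        return np.full(n, 1.0 / n)
    return w / w.sum()


def build_hmm(
    msa: MSA,
    pseudocount_alpha: float = 0.5,
    occupancy_min: float = 0.5,
    background: str = "robinson",
    master_id: str = "",
    strand_span: tuple | None = None,
) -> ProfileHMM:
    """Estimate a profile from an MSA.

    Match columns are those with non-gap fraction >= ``occupancy_min``.
    Emissions are (weighted counts + alpha * background) / (total + alpha);
    transitions come from the observed per-row state paths with a Laplace
    ``alpha`` pseudocount on every transition type.
    """
    bg = background_vector(background)
    rows = [seq for _, seq in msa.rows]
    n_cols = len(rows[0])
    weights = henikoff_weights(rows)

    occupancy = np.array(
        [sum(1 for row in rows if row[c] != "-") / len(rows) for c in range(n_cols)]
    )
    match_cols = [c for c in range(n_cols) if occupancy[c] >= occupancy_min]
    if not match_cols:
        raise ValueError("MSA has no match columns at this occupancy threshold")
    M = len(match_cols)
    a = pseudocount_alpha

    m_em = np.tile(bg * a, (M, 1))
    m_tot = np.full(M, a)
    i_em = np.tile(bg * a, (M + 1, 1))
    i_tot = np.full(M + 1, a)

    # transition counts per node (0..M); Laplace alpha on each type
    t_counts = {k: np.full(M + 1, a) for k in ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    match_set = set(match_cols)
    for row, w in zip(rows, weights):
        # emissions
        node = 0
        state_path = []  # (state, node)
        for c in range(n_cols):
            if c in match_set:
                node += 1
                if row[c] != "-":
                    ai = _AA_INDEX.get(row[c])
                    if ai is not None:
                        m_em[node - 1, ai] += w
                    m_tot[node - 1] += w
                    state_path.append(("M", node))
                else:
                    state_path.append(("D", node))
            else:
                if row[c] != "-":
                    ai = _AA_INDEX.get(row[c])
                    if ai is not None:
                        i_em[node, ai] += w
                    i_tot[node] += w
                    state_path.append(("I", node))
        # transitions
        for (s1, n1), (s2, n2) in zip(state_path, state_path[1:]):
            key = (s1 + s2).lower()
            if key in t_counts:
                t_counts[key][n1] += w
            # combinations outside the seven profile moves (D->I, I->D) are
            # ignored

    match_emissions = m_em / m_tot[:, None]
    insert_emissions = i_em / i_tot[:, None]

    def norm(*keys):
        tot = sum(t_counts[k] for k in keys)
        return [t_counts[k] / tot for k in keys]

    t_mm_full, t_mi_full, t_md_full = norm("mm", "mi", "md")
    t_im_full, t_ii_full = norm("im", "ii")
    t_dm_full, t_dd_full = norm("dm", "dd")

    return ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        t_mm=t_mm_full[1:M],
        t_mi=t_mi_full[1:M],
        t_md=t_md_full[1:M],
        t_im=t_im_full[1:M],
        t_ii=t_ii_full[1:M],
        t_dm=t_dm_full[1:M],
        t_dd=t_dd_full[1:M],
        background=bg,
        master_id=master_id or msa.master_id,
        strand_span=strand_span,
    )


def _log_odds_tables(hmm: ProfileHMM):
    """Natural-log odds emission tables padded with a background column for
    unknown residues."""
    lm = np.log(hmm.match_emissions / hmm.background)
    li = np.log(hmm.insert_emissions[1:hmm.M] / hmm.background) if hmm.M > 1 else np.zeros((0, 20))
    lm = np.hstack([lm, np.zeros((lm.shape[0], 1))])  # column -1: unknown
    if len(li):
        li = np.hstack([li, np.zeros((li.shape[0], 1))])
    return lm, li


def _local_params(hmm: ProfileHMM, L: int):
    """Entry weight and per-state exit/continuation log weights."""
    M = hmm.M
    entry = -np.log(M * L)
    # uniform exit point: match state k exits with probability 1/(M - k + 1)
    tau = 1.0 / (M - np.arange(1, M + 1) + 1.0)
    with np.errstate(divide="ignore"):
        l_exit = np.log(tau)
        l_cont = np.log1p(-tau)  # -inf at k = M: the last match must exit
    return entry, l_exit, l_cont


def forward_score(hmm: ProfileHMM, sequence: str) -> float:
    """Local forward log-odds score in bits (log-sum over all local paths)."""
    if not sequence:
        raise ValueError("empty sequence")
    x = _encode(sequence)
    L, M = len(x), hmm.M
    lm, li = _log_odds_tables(hmm)
    entry, l_exit, l_cont = _local_params(hmm, L)
    with np.errstate(divide="ignore"):
        l_mm = np.log(hmm.t_mm) + l_cont[:-1]
        l_mi = np.log(hmm.t_mi) + l_cont[:-1]
        l_md = np.log(hmm.t_md) + l_cont[:-1]
        l_im = np.log(hmm.t_im)
        l_ii = np.log(hmm.t_ii)
        l_dm = np.log(hmm.t_dm)
        l_dd = np.log(hmm.t_dd)

    NEG = -np.inf
    vm_prev = np.full(M, NEG)
    vi_prev = np.full(max(M - 1, 0), NEG)
    vd_prev = np.full(M, NEG)
    total = NEG
    for i in range(L):
        em = lm[:, x[i]]
        # match: entry, M->M, I->M, D->M (from position i-1)
        if i == 0:
            vm = em + entry
        else:
            stay = np.full(M, NEG)
            stay[1:] = np.logaddexp(
                np.logaddexp(vm_prev[:-1] + l_mm, vd_prev[:-1] + l_dm),
                (vi_prev + l_im) if M > 1 else NEG,
            )
            vm = em + np.logaddexp(entry, stay)
        # delete: M->D, D->D chains within the same i
        vd = np.full(M, NEG)
        if M > 1:
            # vd[k] = logsum over j < k of vm[j] + md[j] + sum dd in between
            cum_dd = np.concatenate([[0.0], np.cumsum(l_dd)])  # length M-1+1
            seed = vm[:-1] + l_md - cum_dd[1:]
            run = np.logaddexp.accumulate(seed)
            vd[1:] = run + cum_dd[1:]
        # insert
        if M > 1:
            ins_em = li[:, x[i]]
            if i == 0:
                vi = np.full(M - 1, NEG)
            else:
                vi = ins_em + np.logaddexp(vm_prev[:-1] + l_mi, vi_prev + l_ii)
        else:
            vi = vi_prev
        total = np.logaddexp(total, np.logaddexp.reduce(vm + l_exit))
        vm_prev, vi_prev, vd_prev = vm, vi, vd
    return float(total / _LN2)


def viterbi_align(hmm: ProfileHMM, sequence: str):
    """Best local path: returns (alignment, bit score).

    The alignment is a list of (match state, residue position) pairs,
    1-based, strictly increasing in both coordinates.  Ties prefer match
    over insert over delete.
    """
    if not sequence:
        raise ValueError("empty sequence")
    x = _encode(sequence)
    L, M = len(x), hmm.M
    lm, li = _log_odds_tables(hmm)
    entry, l_exit, l_cont = _local_params(hmm, L)
    with np.errstate(divide="ignore"):
        l_mm = np.log(hmm.t_mm) + l_cont[:-1]
        l_mi = np.log(hmm.t_mi) + l_cont[:-1]
        l_md = np.log(hmm.t_md) + l_cont[:-1]
        l_im = np.log(hmm.t_im)
        l_ii = np.log(hmm.t_ii)
        l_dm = np.log(hmm.t_dm)
        l_dd = np.log(hmm.t_dd)

    NEG = -np.inf
    VM = np.full((L, M), NEG)
    VI = np.full((L, max(M - 1, 0)), NEG)
    VD = np.full((L, M), NEG)
    PM = np.zeros((L, M), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    PI = np.zeros((L, max(M - 1, 0)), dtype=np.int8)  # 1 M, 2 I
    PD = np.zeros((L, M), dtype=np.int8)  # 1 M, 3 D

    for i in range(L):
        for k in range(M):
            cands = [(entry, 0)]
            if i > 0 and k > 0:
                cands.append((VM[i - 1, k - 1] + l_mm[k - 1], 1))
                if M > 1:
                    cands.append((VI[i - 1, k - 1] + l_im[k - 1], 2))
                cands.append((VD[i - 1, k - 1] + l_dm[k - 1], 3))
            best, ptr = max(cands, key=lambda t: (t[0], -t[1]))
            VM[i, k] = lm[k, x[i]] + best
            PM[i, k] = ptr
        for k in range(1, M):
            cands = [(VM[i, k - 1] + l_md[k - 1], 1), (VD[i, k - 1] + l_dd[k - 1], 3)]
            best, ptr = max(cands, key=lambda t: (t[0], -t[1]))
            VD[i, k] = best
            PD[i, k] = ptr
        if M > 1 and i > 0:
            for k in range(M - 1):
                cands = [(VM[i - 1, k] + l_mi[k], 1), (VI[i - 1, k] + l_ii[k], 2)]
                best, ptr = max(cands, key=lambda t: (t[0], -t[1]))
                VI[i, k] = li[k, x[i]] + best
                PI[i, k] = ptr

    # best exit over (i, k): prefer earlier k then earlier i on exact ties
    exit_scores = VM + l_exit[None, :]
    flat = np.argmax(exit_scores)
    i, k = divmod(int(flat), M)
    score = exit_scores[i, k]
    pairs = []
    state = "M"
    while True:
        if state == "M":
            pairs.append((k + 1, i + 1))
            ptr = PM[i, k]
            if ptr == 0:
                break
            if ptr == 1:
                i, k, state = i - 1, k - 1, "M"
            elif ptr == 2:
                i, k, state = i - 1, k - 1, "I"
            else:
                i, k, state = i - 1, k - 1, "D"
        elif state == "D":
            ptr = PD[i, k]
            if ptr == 1:
                state = "M"
                k = k - 1
            else:
                state = "D"
                k = k - 1
        else:  # insert I_k+1 (stored at index k)
            ptr = PI[i, k]
            if ptr == 1:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "I"
    pairs.reverse()
    return pairs, float(score / _LN2)


def sample_background_sequence(rng, length: int, bg: np.ndarray) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=length, p=bg))


def calibrate_evalue(
    hmm: ProfileHMM,
    n_random: int = 200,
    random_len: int | None = None,
    seed: int = 0,
    db_size: int | None = None,
) -> GumbelCalibration:
    """Fit a Gumbel null from scores of random background sequences.

    ``random_len`` defaults to 3x the profile length (a proxy for the median
    database domain length when the database is not at hand); pass the
    median database length for a faithful null.  The calibration is stored
    on the profile.
    """
    if n_random < 50:
        raise ValueError("n_random must be >= 50 for a stable fit")
    if random_len is None:
        random_len = 3 * hmm.M
    rng = np.random.default_rng(seed)
    scores = np.array(
        [
            forward_score(hmm, sample_background_sequence(rng, random_len, hmm.background))
            for _ in range(n_random)
        ]
    )
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate calibration: zero score variance")
    fit = fit_gumbel(scores)
    calib = GumbelCalibration(
        fit=fit,
        random_len=random_len,
        n_random=n_random,
        tail_anchor=float(np.quantile(scores, 0.98)),
    )
    hmm.calibration = calib
    del db_size  # accepted for interface compatibility; E-values use the
    # actual database size at search time
    return calib


def evalue(hmm: ProfileHMM, score: float, db_size: int) -> float:
    if hmm.calibration is None:
        raise RuntimeError("profile is not calibrated")
    return db_size * hmm.calibration.pvalue(score)


def search(
    hmm: ProfileHMM,
    domains: list,
    evalue_max: float = 1e-3,
    exclude_xgroup: int | None = 6,
) -> list:
    """Score every domain; keep hits with E-value < ``evalue_max`` whose
    X-group differs from ``exclude_xgroup``.

    ``domains`` is a list of (domain_id, sequence, group) triples.  Hits are
    sorted by E-value ascending and carry the Viterbi alignment.
    """
    if hmm.calibration is None:
        raise RuntimeError("profile must be calibrated before searching")
    from .formats_io import parse_group

    db_size = len(domains)
    hits = []
    for domain_id, sequence, group in domains:
        if exclude_xgroup is not None and group:
            if parse_group(group)[0] == exclude_xgroup:
                continue
        if not sequence:
            continue
        s = forward_score(hmm, sequence)
        e = evalue(hmm, s, db_size)
        if e < evalue_max:
            alignment, _ = viterbi_align(hmm, sequence)
            hits.append(
                ThemeHit(
                    profile_id=hmm.profile_id,
                    master_domain=hmm.master_id,
                    target_domain=domain_id,
                    target_group=group,
                    bit_score=s,
                    evalue=e,
                    alignment=alignment,
                )
            )
    hits.sort(key=lambda h: h.evalue)
    return hits
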