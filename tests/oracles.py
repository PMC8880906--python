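"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
numerical optimisation, sharing no code with the implementations they
check.
"""

import itertools

import numpy as np


def enumerate_local_paths(hmm, sequence, mode: str):
    """Score of the local profile alignment ensemble by path enumeration.

    Semantics mirror the documented scoring model: entry weight 1/(M*L)
    into any (match state, start position), exit from match state k with
    probability 1/(M - k + 1) and continuation with the complementary
    weight, emissions scored as odds against the background, insert
    emissions as stored.  ``mode`` is "sum" (forward) or "max" (Viterbi);
    returns bits (and the best path's match pairs for "max").
    """
    from trefoil_themes.profile_hmm import AA_ORDER

    idx = [AA_ORDER.index(a) for a in sequence]
    M = hmm.M
    L = len(idx)
    bg = hmm.background

    def tau(k):
        return 1.0 / (M - k + 1)

    def m_odds(k, i):
        return hmm.match_emissions[k - 1, idx[i]] / bg[idx[i]]

    def i_odds(k, i):
        return hmm.insert_emissions[k, idx[i]] / bg[idx[i]]

    results = []  # (weight, match pairs)

    def walk(node, pos, weight, pairs):
        # just emitted residue pos at match state `node`
        results.append((weight * tau(node), list(pairs)))  # exit now
        if pos + 1 >= L:
            return
        cont = 1.0 - tau(node)
        if node < M and cont > 0:
            # M -> M
            walk(
                node + 1,
                pos + 1,
                weight * cont * hmm.t_mm[node - 1] * m_odds(node + 1, pos + 1),
                pairs + [(node + 1, pos + 2)],
            )
            # M -> I_node (chains) -> M_{node+1}
            w_ins = weight * cont * hmm.t_mi[node - 1]
            p = pos + 1
            while p < L:
                w_ins2 = w_ins * i_odds(node, p)
                if p + 1 < L:
                    walk(
                        node + 1,
                        p + 1,
                        w_ins2 * hmm.t_im[node - 1] * m_odds(node + 1, p + 1),
                        pairs + [(node + 1, p + 2)],
                    )
                w_ins = w_ins2 * hmm.t_ii[node - 1]
                p += 1
            # M -> D ... D -> M
            w_del = weight * cont * hmm.t_md[node - 1]
            nd = node + 1
            while nd < M:
                walk(
                    nd + 1,
                    pos + 1,
                    w_del * hmm.t_dm[nd - 1] * m_odds(nd + 1, pos + 1),
                    pairs + [(nd + 1, pos + 2)],
                )
                w_del = w_del * hmm.t_dd[nd - 1]
                nd += 1

    for start in range(L):
        for k0 in range(1, M + 1):
            walk(k0, start, (1.0 / (M * L)) * m_odds(k0, start), [(k0, start + 1)])

    if mode == "sum":
        return np.log2(sum(w for w, _ in results))
    w, pairs = max(results, key=lambda t: t[0])
    return np.log2(w), pairs


def brute_force_local_alignment(a, b, matrix, gap_open=11.0, gap_extend=1.0):
    """Optimal local alignment score by enumerating every monotone pairing.

    A gap of length g costs gap_open + (g - 1) * gap_extend; gaps in the
    two sequences between consecutive aligned columns are charged
    separately.  The empty alignment scores 0.
    """

    def gap_cost(g):
        return gap_open + (g - 1) * gap_extend if g > 0 else 0.0

    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ai in itertools.combinations(range(n), k):
            for bi in itertools.combinations(range(m), k):
                s = 0.0
                for t in range(k):
                    s += matrix[a[ai[t]], b[bi[t]]]
                    if t:
                        s -= gap_cost(ai[t] - ai[t - 1] - 1)
                        s -= gap_cost(bi[t] - bi[t - 1] - 1)
                best = max(best, s)
    return best


def grid_rmsd(P, Q, coarse_step=20.0):
    """Minimum superposition RMSD over proper rotations by a coarse Euler
    grid followed by Nelder-Mead refinement of the rotation vector."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = Pc @ R.T - Qc
        return float(np.sqrt((d**2).sum() / len(P)))

    candidates = []
    grid = np.deg2rad(np.arange(0.0, 360.0, coarse_step))
    half = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, coarse_step))
    for ez1 in grid:
        for ey in half:
            for ez2 in grid:
                rv = Rotation.from_euler("zyz", [ez1, ey, ez2]).as_rotvec()
                candidates.append((rmsd_of(rv), tuple(rv)))
    candidates.sort(key=lambda t: t[0])
    best = np.inf
    for _, rv in candidates[:10]:
        res = minimize(rmsd_of, np.array(rv), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10000})
        best = min(best, float(res.fun))
    return best


def random_profile_hmm(rng, M, background="uniform"):
    """A randomly parameterized valid ProfileHMM (for oracle comparisons)."""
    from trefoil_themes.profile_hmm import ProfileHMM, background_vector

    bg = background_vector(background)
    match = rng.dirichlet(np.ones(20), size=M)
    insert = rng.dirichlet(np.ones(20), size=M + 1)
    tm = rng.dirichlet(np.ones(3), size=max(M - 1, 0))
    ti = rng.dirichlet(np.ones(2), size=max(M - 1, 0))
    td = rng.dirichlet(np.ones(2), size=max(M - 1, 0))
    return ProfileHMM(
        match_emissions=match,
        insert_emissions=insert,
        t_mm=tm[:, 0] if M > 1 else np.zeros(0),
        t_mi=tm[:, 1] if M > 1 else np.zeros(0),
        t_md=tm[:, 2] if M > 1 else np.zeros(0),
        t_im=ti[:, 0] if M > 1 else np.zeros(0),
        t_ii=ti[:, 1] if M > 1 else np.zeros(0),
        t_dm=td[:, 0] if M > 1 else np.zeros(0),
        t_dd=td[:, 1] if M > 1 else np.zeros(0),
        background=bg,
        master_id="random",
    )
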