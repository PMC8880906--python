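"""Shuffle-and-realign significance for a putative shared segment.

The confirmation statistic for a theme hit: realign the two sequences after
composition-preserving shuffles, fit the null score distribution with an
extreme value (Gumbel) distribution, and report

    p = P(S >= s_obs | null) = 1 - exp(-exp(-lambda * (s_obs - mu)))

Realignment is local Smith–Waterman with affine gaps (BLOSUM62, open 11,
extend 1 by default), via Biopython's pairwise aligner.  The Gumbel fit is
by the method of moments:

    lambda = pi / (sigma * sqrt(6)),   mu = mean - gamma / lambda

with gamma the Euler–Mascheroni constant.
"""

from __future__ import annotations

import dataclasses
import functools

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = ["GumbelFit", "sw_align", "fit_gumbel", "shuffle_pvalue"]

EULER_GAMMA = 0.5772156649015329


@dataclasses.dataclass
class GumbelFit:
    """Location (mu) and rate (lam) of a fitted Gumbel distribution."""

    mu: float
    lam: float
    n_samples: int

    def __post_init__(self):
        if not (np.isfinite(self.mu) and np.isfinite(self.lam) and self.lam > 0):
            raise ValueError("degenerate Gumbel fit")

    def pvalue(self, score: float) -> float:
        """Upper-tail probability P(S >= score)."""
        z = self.lam * (score - self.mu)
        return float(-np.expm1(-np.exp(-z)))


@functools.lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length g costs gap_open + (g - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    return "".join(a if a in alphabet else "X" for a in seq.upper())


def sw_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    return_alignment: bool = True,
):
    """Optimal local alignment score (and aligned pairs) under affine gaps.

    Residues outside the matrix alphabet are scored as X.  The score is
    never negative: when no positive-scoring pair exists the empty local
    alignment (score 0) is optimal.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    a2, b2 = _sanitize(a, alphabet), _sanitize(b, alphabet)
    score = float(aligner.score(a2, b2))
    if score <= 0:
        return (0.0, []) if return_alignment else 0.0
    if not return_alignment:
        return score
    aln = aligner.align(a2, b2)[0]
    pairs = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            pairs.append((a_start + off + 1, b_start + off + 1))  # 1-based
    return score, pairs


def fit_gumbel(scores) -> GumbelFit:
    """Method-of-moments Gumbel fit to a sample of maxima."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 30:
        raise ValueError("need at least 30 scores to fit")
    sigma = scores.std(ddof=1)
    if sigma < 1e-12:
        raise ValueError("zero variance: cannot fit a Gumbel")
    lam = np.pi / (sigma * np.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lam
    return GumbelFit(mu=float(mu), lam=float(lam), n_samples=len(scores))


def shuffle_sequence(rng, sequence: str) -> str:
    """Fisher–Yates shuffle (via the generator's permutation) preserving the
    exact residue multiset."""
    order = rng.permutation(len(sequence))
    return "".join(sequence[i] for i in order)


def shuffle_pvalue(
    query: str,
    subject: str,
    n_shuffles: int = 1000,
    seed: int = 0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    shuffle: str = "subject",
):
    """Significance of the observed query/subject alignment score against a
    shuffled-sequence Gumbel null.

    Returns (p_value, GumbelFit, observed_score).  ``shuffle`` picks which
    side is shuffled: "subject" (default; the query and hence the null
    composition pairing is held fixed) or "both".
    """
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    if shuffle not in ("subject", "both"):
        raise ValueError("shuffle must be 'subject' or 'both'")
    rng = np.random.default_rng(seed)
    kwargs = dict(matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
                  return_alignment=False)
    observed = sw_align(query, subject, **kwargs)
    null_scores = np.empty(n_shuffles)
    for t in range(n_shuffles):
        q = shuffle_sequence(rng, query) if shuffle == "both" else query
        s = shuffle_sequence(rng, subject)
        null_scores[t] = sw_align(q, s, **kwargs)
    fit = fit_gumbel(null_scores)
    return fit.pvalue(observed), fit, observed
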