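# Methods

## Scope and model

The package detects two kinds of cross-lineage similarity at sub-domain
scale: shared sequence segments ("bridging themes") between domain
families classified in different X-groups, and a structural motif ("βTL",
β-trefoil-like) defined by a conserved buried water hydrogen-bonded to
three backbone sites. Both tracks run end to end on synthetic data with
planted ground truth; the same functions accept real family alignments,
domain tables and PDB structures.

## Sequence track

**Windows.** The master's secondary structure (user-supplied string or
assigned from coordinates, below) is segmented into maximal β-strand runs
of at least 2 residues; a sliding window covers each set of 4 consecutive
strands (strands 1–4, 2–5, …), spanning from the first strand's first
residue to the fourth strand's last residue. Loops *between* the window's
strands are included; loops flanking the terminal strands are not — the
window is the repetitive structural element, not its context. MSA columns
are selected where the master's ungapped position falls inside the window
(1-based, inclusive). Rows failing a coverage ≥ 0.90 or master-identity
≥ 0.30 filter (both inclusive thresholds; identity over mutually non-gap
columns) are dropped first.

**Profiles.** Match columns are those with unweighted non-gap fraction
≥ 0.5. Emissions use Henikoff position-based sequence weights (normalized
to total weight 1) and a single background-proportional pseudocount:
`(weighted counts + α·bg) / (total + α)` with α = 0.5 — simpler than
Dirichlet mixtures and adequate at fragment scale. Transitions are counted
from each row's observed match/insert/delete path with a Laplace α on
every transition type. The background is the Robinson–Robinson amino-acid
frequency vector (uniform 1/20 optional). Unknown residues (incl. X) emit
the background and hence score zero.

**Scoring.** The local forward score is a log-odds in bits over a
*normalized* local path ensemble: entry weight 1/(M·L) over (match state,
start position), exit from match state k with probability 1/(M − k + 1)
(a uniform exit-point distribution), continuation scaled by the
complement. Normalisation matters: it makes `P(S ≥ s) ≤ 2⁻ˢ` a theorem
(Markov's inequality on `2^S`), so background sequences score ≤ 0 bits in
expectation and the E-value tail guard below is principled rather than
heuristic. Viterbi uses the same parameterization with max in place of
sum; traceback ties prefer match over insert over delete. A
single-match-state profile emitting one residue with probability 1 scores
exactly log₂ 20 bits against the uniform background on that residue —
the analytic anchor case for both algorithms and their exhaustive-path
test oracle.

**E-values.** Each profile is calibrated by scoring `n_random = 200`
i.i.d. background sequences whose length defaults to the median database
sequence length. The null is summarized two ways: a method-of-moments
Gumbel fit (λ = π/(σ√6), μ = mean − γ/λ) describing the bulk, and an
exponential tail of slope ln 2 per bit anchored at the sample's 98th
percentile (a peaks-over-threshold anchor). The reported p-value is the
maximum of the two; `E = db_size · p`. The tail guard exists because the
moment fit's rate (≈ 2/bit on typical windows) decays faster than the true
forward-score tail, which underestimated p by 1–2 orders of magnitude at
the `E < 10⁻³` working point and produced decoy false positives; the ln 2
slope is the asymptotic (and worst-case, by the Markov bound) tail of a
normalized log-odds score — the same reasoning behind forward-score
calibration in mainstream HMM search tools. Measured on 50 simulated
scenarios this choice yields recall ≈ 0.92–0.97 of planted windows with
≈ 0.02 decoy hits per scenario.

The per-sequence E-value stands in for a conditional (per-domain) E-value;
at fragment scale with single-hit targets the two coincide.

**Shuffle confirmation.** For each hit, the master's window sequence is
locally realigned (Smith–Waterman, BLOSUM62, gap open 11 / extend 1, via
Biopython's pairwise aligner) against the target after
composition-preserving shuffles of the subject (1000 by default; the
query is held fixed, halving variance sources; `shuffle="both"` is
available). Null scores are fitted by the moment Gumbel and the observed
score converted to `p = 1 − exp(−exp(−λ(s − μ)))`. Under the composition
null this p is approximately uniform (measured fraction below 0.05 ≈ 0.06
over 500 replicates at 200 shuffles).

## Structure track

**Secondary structure.** Kabsch–Sander electrostatic hydrogen bonds
(`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond if
E < −0.5; amide H placed 1.01 Å from N anti to the preceding carbonyl).
A residue is E when it takes part in an antiparallel or parallel bridge
pattern (|i−j| ≥ 3), H when inside a run of ≥ 4 consecutive i+4→i bonds,
C otherwise; prolines never donate, incomplete backbones are C. This is a
deliberate simplification of torsion-aware assigners, adequate for
idealized and well-resolved inputs; users can bypass it with their own
strings.

**TM search.** The motif is an ordered set of CA segments (discontinuous
allowed; inter-segment target gaps unconstrained ≥ 0). Pass 1 scores every
gapless threading of the segments with one Kabsch superposition
(reflection-corrected SVD). Pass 2 refines the top 5 candidates by
alternating (a) superposition on the close-pair subset (distance <
max(d0, 1.5 Å)), and (b) re-derivation of the mapping by monotone dynamic
programming on the score matrix `1/(1 + (d_ij/d0)²)` (a −0.05 floor skips
junk pairs), until the mapping is stable or 20 rounds. TM-scores are
normalized to the motif length: `d0 = 1.24·(L_norm − 15)^⅓ − 1.8`, floored
at 0.5 Å for L_norm < 16; TM > 0.5 is the acceptance default. This is a
reduced form of the standard structure-alignment heuristics (no secondary
structure seeding, no sequence-order-independent mode); on hard cases its
optimum can sit slightly below a full implementation's, which is why the
worked-example check carries a ±0.02 band.

**Water, clamp, dry.** A conserved-water candidate is a water oxygen with
at least three distinct-residue backbone N/O partners at ≤ 3.0 Å among the
motif residues (all partners up to 3.5 Å are listed with distances; an
option adds Ser/Thr/Tyr hydroxyl oxygens for the lineage whose loop
contacts the water through a serine sidechain). Distance-only criteria are
used deliberately: water hydrogens are absent from crystal structures.
Context comes from the secondary structure (E → strand, else loop). The
*hydrophobic clamp* is true when both strand partners are hydrophobic
(AVLIMFWYC) and their sidechain heavy atoms touch at ≤ 5.0 Å (CB-only
models: ≤ 6.5 Å). A *dry* motif requires both the absence of any
qualifying water on the mapped residues and a proline at a mapped donor
position; a waterless motif without the proline is reported as incomplete,
not dry.

## Synthetic data: what it emulates, what it does not

**Families and themes.** Members are derived from a master by i.i.d.
substitutions uniform over the 19 alternatives — no rate matrix, no
indels by default — because identity is the only property the downstream
search depends on. The default scenario (one donor family of 20 at 20%
substitution, master length 100; one recipient family carrying a
30-residue theme at 30% divergence; two decoy families of 10 random
sequences) mirrors the regime where a fragment search must separate a
real shared segment from composition noise. Scenario truth lists every
4-strand window overlapping the planted segment by at least half the
theme length; windows that cover only part of the theme are genuinely
harder and dominate the residual misses.

**Structures.** Strands are built by natural-extension-reference-frame
propagation of ideal bond lengths/angles (N–CA 1.458, CA–C 1.525, C–N
1.329 Å; φ/ψ = −139°/135° for strands, −57°/−47° for helices). An
antiparallel partner placement is optimized once per strand length so
that alternating register pairs form mutual 2.90 Å N···O bonds with
correctly aimed amide hydrogens and in-register sidechains; alternating
two bond registers grows an up-down four-strand sheet. Turns are
equal-chord circular arcs (CA–CA 3.8 Å throughout), and each turn's last
residue inherits the next strand's virtual-residue carbonyl so that
strand-entry amide hydrogens keep ideal geometry. The conserved water is
planted by swinging the first turn's interior rigidly about its flanking
CA–CA axis (which preserves all CA–CA distances), aiming one loop
carbonyl, and placing the water above the terminal β1···β2 ladder rung;
a deterministic grid maximizes clearance so that exactly three backbone
N/O sites fall within hydrogen-bond range. The dry variant omits the
water and substitutes proline at the amide-donor position; the clamp
plants Leu/Ile at the two water-binding strand residues (CB–CB ≈ 5.5 Å).
Gaussian coordinate noise of width `noise_sigma` (per coordinate) is
added last.

These structures are flat, fully regular single sheets: passing tests
shows the detectors implement their geometric definitions correctly, not
that they are robust to crystallographic disorder, alternate
conformations, or the curved, twisted sheets of real β-trefoils. Likewise
the sequence generator contains no alignment error, so MSA-filter behavior
on noisy real alignments is untested here.

## Numerical choices and degenerate inputs

* All randomness flows through seeded NumPy generators; every pipeline
  output is byte-reproducible from config + seed, and a manifest of
  content hashes is written alongside.
* Forward/Viterbi run in natural-log space with exact log-sum-exp; delete
  chains use a prefix-scan so the per-position cost is O(M).
* Gumbel fits require ≥ 30 scores and nonzero variance; degenerate nulls
  raise instead of returning nonsense.
* `theme_rmsd` drops aligned pairs lacking CA coordinates and returns NaN
  (flagged) below 3 usable pairs; metamorphism statistics exclude such
  hits from the denominator and count them separately, with a strict `<`
  at the 2.5 Å threshold.
* Empty inputs produce empty outputs with exit code 0; an unreadable
  structure is skipped with a log record rather than killing a run.
* Profile deduplication: overlapping windows are distinct themes (the
  operational definition used for the unique-theme counts); hits by one
  profile into one lineage count once.

## Problem sizes

Defaults used by the test suite and the acceptance script: 50 scenarios
for recall/false-positive measurement, 200-sequence E-value calibrations,
200-shuffle confirmation p-values inside those loops (1000 remains the
pipeline default for real runs), 500 replicates for the null-uniformity
check, 20 seeds for noise/decoy TM distributions. These sizes give stable
estimates (binomial s.e. ≈ 0.02 on the recall) at desk-scale runtime.

## Known limitations

* The E-value is per-sequence, not a true multi-domain conditional
  E-value; repeats within one target are not decomposed into envelopes.
* The secondary-structure rule has no π/3₁₀ discrimination and trims
  strand termini relative to torsion-aware assigners.
* The TM search is gapless-threading plus refinement; it can undershoot a
  full structure aligner on hard, highly discontinuous cases.
* Database-scale quantities (counts of lineages, themes per lineage,
  RMSD distributions over hundreds of real structure pairs) depend on
  external classified databases and are out of scope; the counting
  operations that would produce them are verified on planted scenarios
  and toy tables instead.
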