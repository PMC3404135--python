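# Methods

## Problem and notation

Input: n strings over a fixed alphabet Σ (DNA presets |Σ| = 4, protein
|Σ| = 20), parameters (ℓ, d, q) with 0 ≤ d < ℓ and 1 ≤ q ≤ n. An ℓ-mer m
is an **(ℓ, d)-motif with quorum q** iff at least q sequences contain a
length-ℓ window w with Hamming distance h(m, w) ≤ d. q = n is the classic
planted-motif search; all engines here are exact: they output the full
motif set, deduplicated and lexicographically sorted. Coordinates are
0-based half-open everywhere; machine outputs say so in their headers.

Sequences are uppercased on load and stored as int8 code arrays.
Characters outside the alphabet (e.g. `N`) code as −1; any window
containing one is ineligible both as a candidate l-mer and as a match
witness. A strict mode rejects such sequences outright (the CLI defaults
to strict because the simulator's i.i.d. model assumes clean strings).

## Neighborhood machinery

B_d(x), the Hamming ball, has size Σ_{i≤d} C(ℓ,i)(|Σ|−1)^i, independent
of the center. It is enumerated by the mutation tree T_d(x): node =
(t, p) with p the last mutated position (1-based; 0 at root); children
mutate one position p' > p to each character ≠ x[p']; node depth equals
h(x, t). Children are visited in increasing position, then alphabet
order, making every traversal deterministic.

**Minimum descendant distance.** A descendant of (t, p) at depth k may
mutate only positions > p, at most d − k of them. Its minimal distance
to any ℓ-mer y is therefore `a + max(0, b − (d − k))` where a/b are the
prefix (≤ p) / suffix (> p) mismatch counts of t vs y. This form is exact
(each suffix mutation can fix at most one mismatch, and fixing is always
permitted because y differs from x = t at those positions), and is the
package's single pruning primitive: a window y is *ignorable* at a node
iff the value exceeds d, which is equivalent to the prefix/suffix
ball-disjointness view (the prefix budgets spent make the two suffix
balls disjoint). A dedicated unit test checks it against brute-force
minima over every node of small random trees.

**Three-ball intersection.** qPMS7 needs "is B_{r1}(c1) ∩ B_{r2}(c2) ∩
B_{r3}(c3) non-empty?" decided exactly. We use an O(ℓ·d²) dynamic
program over positions with state (mismatches to c1, mismatches to c2)
minimizing mismatches to c3. Only characters actually present in a
column are branched on: any other character incurs (1,1,1), pointwise
dominated by copying whichever center already disagrees with the other
two, so dropping it never changes feasibility — this also makes the DP
correct for every alphabet size ≥ 2 (for binary alphabets the "fourth
character" simply never exists). We chose the DP over the constant-time
case analysis known for this subproblem: identical answers, and it can
be verified directly against exhaustive search over Σ^L (done for all
radius triples on hundreds of random center triples, DNA L ≤ 6 and
protein L ≤ 4, plus a binary-alphabet suite).

## Search engines

**Brute force (oracle).** Either full Σ^ℓ enumeration or the union of
the d-balls of the first n−q+1 sequences' windows (every motif lies in
such a ball), whichever is smaller under a configurable candidate cap
(default 2²²; exceeding it is a refusal, not an attempt). Quorum is then
tested per candidate from the definition.

**Single-pivot branch and bound.** Any motif lies in B_d(x) for some
window x of one of the first n−q+1 sequences (if the quorum sequences
were all later ones, the earliest of them still appears among the first
n−q+1). For each pivot, T_d(x) is walked depth-first; at each node t the
per-sequence minimum window distances are known; t is emitted when
≥ q−1 non-pivot sequences are within d (support over all n is
recomputed at report time), and the subtree is pruned when fewer than
q−1 non-pivot sequences are within 2d − depth — any deeper motif t'
would force h(t, s_j) ≤ h(t, t') + d ≤ 2d − depth for q−1 sequences.
The surviving-lists variant stores, per sequence, the windows whose
minimum descendant distance is still ≤ d; lists only shrink along a
root-to-leaf path (restored on backtrack) and both the emission and the
pruning counts are computed from surviving windows only. This is sound:
a dropped window cannot be within d of the node itself (the node is its
own descendant) nor of any descendant, and witnesses of any deeper
motif provably survive. Outputs are bit-identical; only the
distance-update counter drops (asserted as dominance on every suite
instance — the direction of the known ~5× practical speedup, which we
do not assert as a ratio since it is hardware- and instance-bound).

**Two-pivot engine (qPMS7).** Any motif lies in B_d(x) ∩ B_d(y) for
windows x, y of two distinct sequences r1 < r2 ≤ n−q+2. Pairs with
h(x, y) > 2d are skipped (disjoint balls). The walk over T_d(x) visits
only nodes whose minimum descendant distance to y is ≤ d — the exact
cone that can still reach B_d(y); this is the graph-restricted traversal
in tree form. A window w of sequence j survives at node (t, p, k) iff
the three suffix balls — centers x, w, y restricted to positions > p,
radii d−k, d−a_w, d−a_y with a the respective prefix mismatches against
t — intersect (negative radius ⇒ drop). Emission requires h(t, y) ≤ d
(h(t, x) = depth ≤ d holds by construction) and ≥ q−2 non-pivot
sequences holding a surviving window within d; backtracking happens when
fewer than q−2 surviving lists are non-empty. Per-node quorum counts use
surviving windows only (sound, as above; left open in the original
formulation, fixed here as a design choice).

**Preprocessing filter.** A window u of s_i can be an instance of some
quorum motif only if ≥ q−1 other sequences contain a window within 2d
of u (two instances of one motif are within 2d by the triangle
inequality). Filtered windows are removed from pivot candidacy and from
initial surviving lists. The filter is exact-output-preserving for every
engine (instances of true motifs always pass) and is on by default only
for qPMS7, off for the oracle — the oracle stays definition-pure.

Implementation: the hot loops (tree walks, cross-window distance tables,
candidate scans, evidence distances) are numba-compiled kernels over the
int8 window matrix; node distances are recomputed statelessly from
per-pivot prefix-mismatch cumulative tables plus the ≤ d mutations on
the current path, which keeps backtracking trivially correct. The
two-pivot engine precomputes all pairwise cross-window distance tables
capped at 2d (O(n² m²) bytes — 66 MB at the n=20, m=600 benchmark
shape; ℓ < 255 is required by the uint8 encoding). Work is chunked per
pivot window, so wall-clock budgets (`deadline`) abort cleanly between
chunks. Emission buffers grow on overflow and the tree is re-walked —
deterministic, so retries are idempotent.

## Simulator

`generate_planted_instance(n=20, m=600, l, d, q, alphabet, seed, mode)`:
i.i.d. uniform background (optionally per-character frequencies), one
uniform random ℓ-mer as motif, q distinct sequences chosen uniformly,
and in each a mutated copy overwriting a uniform random window. Default
mode `exact-d` mutates exactly d distinct positions (each to a uniformly
chosen *different* character); plants then sit on the ball boundary —
the hardest placement consistent with the "at most d" contract — while
`up-to-d` draws the mutation count uniformly from 0..d. One plant per
chosen sequence, overwrite not insertion, so overlapping-plant
pathologies cannot arise. All randomness flows through
`numpy.random.default_rng(seed)` (PCG64); equal seeds give byte-equal
FASTA/truth files. The defaults n=20, m=600 are the canonical
"challenging instance" benchmark shape; `challenging_presets` returns
the published (ℓ, d) ladders (DNA PMS (13,4)…(23,9); DNA qPMS
(13,3)…(21,7); protein PMS (11,5)…(19,9); protein qPMS (11,4)…(19,8)).

What the simulator does *not* emulate: positional bias, composition
bias within the motif (no PWM plants), correlated backgrounds, repeats,
or double-strandedness. Passing recovery tests on simulated data shows
the engines are exact and complete under the i.i.d. planted model, not
that real binding sites at a given (ℓ, d) are detectable in real
promoters.

## Binding-site discovery

Phase I sweeps ℓ = l_min..l_max; per ℓ, d rises from 0 and stops at the
first non-empty result (motifs found at small d for this ℓ subsume the
signal) or when the per-run time budget is exhausted (logged; the sweep
moves to the next ℓ). Phase II scores candidates by **sequence
specificity**: Σ_i ln E_i, where E_i = (m_i − ℓ + 1)·P(≤ d mismatches)
is the expected number of windows of sequence i matching the motif under
an i.i.d. background — P computed by an exact Poisson-binomial tail DP
with per-position match probability equal to the background frequency of
the motif character. The log-sum is monotone-equivalent to the product
of the E_i and numerically safe; lower = rarer by chance = ranked
better; ties break lexicographically. The top k_top motifs are kept and
every window within d_site (default: the d the motif was found at) is
reported as a site.

Defaults (artifact decisions, user-overridable): l_min=10, l_max=20,
d_max(ℓ) = ⌈ℓ/4⌉, k_top=5, 600 s per-(ℓ,d) budget; background defaults
to frequencies estimated from the input (pseudocount 1), with a uniform
option — real promoter sets are compositionally biased, and the i.i.d.
scoring model does not fix the frequency vector.

## Numerical and degenerate-input choices

* Determinism everywhere: fixed child order in tree walks, pivot windows
  in offset order, results sorted lexicographically, seeds mandatory in
  the simulator.
* `min_hamming_to_sequence` returns (∞, []) when no window is eligible
  (only possible with out-of-alphabet characters).
* Quorum q > n, ℓ longer than the shortest sequence, d ≥ ℓ, q < 2 for
  the two-pivot engine: parameter errors, raised before any work.
* Background frequencies must be positive and sum to 1 (tolerance 1e-6);
  a zero expected count is treated as a degenerate-background error.
* Zero time budgets terminate cleanly with empty results in Phase I and
  a `TimeBudgetError` in direct solver calls.

## Problem sizes used in the shipped checks

Oracle-equivalence suites run on randomized instances with n ∈ 4..8,
m ∈ 20..60, DNA ℓ ∈ 5..9 with d ∈ {1,2} and protein ℓ ∈ 4..6 with d=1 —
the range where full brute-force enumeration stays cheap enough to serve
as an oracle on a single CPU. The planted-recovery checks run at the
full canonical shape n=20, m=600 with (11,3, q=20) and (9,2, q=10);
(9,2) at half quorum is *saturated* (roughly two thirds of all 4⁹
9-mers reach the quorum by chance, an output of ~2·10⁵ motifs), which
makes it a stress test of exact completeness rather than a realistic
discovery setting. Larger published ladder instances — (13,4) and up —
are reachable by the same code but are multi-hour runs in this
implementation and are not part of the shipped checks.

## Known limitations

Single-strand search only (no reverse complement), no IUPAC-degenerate
or gapped motifs, no PWM refinement, no parallelism. The two-pivot
engine's pairwise distance tables are quadratic in sequence length;
inputs far longer than a few kilobases per sequence will want the
single-pivot engine or more memory. More than two pivots is a natural
extension and deliberately out of scope.
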