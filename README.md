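# qmotif — exact quorum planted (ℓ, d)-motif search

Transcription factors recognize short, degenerate sequence patterns.
The *planted motif search* (PMS) abstraction models this combinatorially:
an **(ℓ, d)-motif** of n sequences is an ℓ-mer `m` such that enough
sequences contain a window `w` with Hamming distance `h(m, w) ≤ d`. The
**quorum** variant (qPMS) asks for at least `q ≤ n` such sequences —
realistic promoter collections rarely contain a site in every sequence.
The problem is NP-hard; this package implements *exact* solvers (they
report every motif, never a heuristic subset) for users who study
regulatory regions, benchmark motif finders, or need a ground-truth
oracle:

* `brute_force_search` — the definition applied directly (full ℓ-mer
  enumeration or the union of the d-balls of one sequence's windows);
  the correctness oracle.
* `qpmsprune_search` — single-pivot branch and bound: for each window
  `x` of the first n−q+1 sequences, the Hamming ball B_d(x) is explored
  as a mutation tree, depth-first; a subtree rooted at depth k dies when
  fewer than q−1 non-pivot sequences lie within 2d − k of its root (the
  triangle inequality). With `use_surviving_lists=True` the engine also
  drops, per sequence, every window that can no longer be within d of any
  descendant (the "qPMSPruneI" speedup — same output, much less work).
* `qpms7_search` — the two-pivot engine: pivot windows `x`, `y` from two
  different sequences with `h(x, y) ≤ 2d`; traversal of B_d(x) restricted
  to the cone that can still reach B_d(y); window survival decided by an
  exact three-Hamming-ball intersection test (a small dynamic program on
  the unmutated suffix); plus a preprocessing filter that discards windows
  with too few 2d-neighbors across sequences.

A planted-instance simulator (`generate_planted_instance`; i.i.d. random
background, a random ℓ-mer planted with ≤ d mutations into q of n
sequences; canonical benchmark shape n=20, m=600) and a two-phase
transcription-factor binding-site discovery driver (`phase1_select` /
`phase2_sites`, candidates ranked by *sequence specificity* — the
log-product over sequences of expected chance match counts under an
i.i.d. background) complete the toolkit. See `docs/methods.md` for the
model details and design choices.

## Worked example

```python
import qmotif as qm

# plant an (11,3) motif into all 20 of 20 random 600-mers
inst = qm.generate_planted_instance(n=20, m=600, l=11, d=3, q=20, seed=101)
print(inst.motif)

res = qm.qpms7_search(inst.seqs, qm.SearchParams(l=11, d=3, q=20))
print(len(res), "motifs;", "planted found:", inst.motif in res.motifs)
print(res.stats)
rep = res.report(inst.motif)
print(rep.support, [e[0] for e in rep.evidence][:5])
```

prints (seed 101):

```
TCCTACGAAGT
5 motifs; planted found: True
SearchStats(nodes_visited=1165637, nodes_pruned=4047744, distance_updates=172304423, motifs_found=5)
20 [3, 3, 3, 3, 3]
```

The search returned five motifs: the planted ℓ-mer plus four spurious
(11,3)-motifs that arise by chance at this instance shape — (11,3) sits
at the "challenging" edge where random sequences begin to contain quorum
motifs. The report shows the planted motif matched in all 20 sequences
(support 20), each at exactly the 3 mismatches the simulator planted.

The same runs from a shell:

```
qmotif simulate -o inst --n 20 --m 600 -l 11 -d 3 --seed 101
qmotif search inst.fasta -l 11 -d 3 --algorithm qpms7 -o motifs.tsv -v
qmotif tfbs promoters.fasta --l-min 10 --l-max 16 -o candidates.tsv --sites-out sites.tsv
```

Outputs are TSV with a self-describing `#` header (version, full
configuration); coordinates are 0-based, half-open.

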