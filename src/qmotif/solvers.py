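"""The motif-search engines.

Four exact engines solve the quorum planted motif problem — find every
l-mer m such that at least q of the n input sequences contain a window
within Hamming distance d of m:

``brute_force_search``
    The definition applied directly, either over the whole l-mer space or
    over the union of the d-balls of the first n-q+1 sequences' windows.
    Deliberately simple; serves as the oracle for everything else.

``qpmsprune_search``
    Single-pivot branch and bound: for each window x of the first n-q+1
    sequences, traverse the mutation tree T_d(x) depth-first, keep per-
    sequence minimum window distances, emit nodes with quorum support among
    the non-pivot sequences, and prune subtrees by the triangle inequality
    (a subtree rooted at depth k is dead once fewer than q-1 non-pivot
    sequences are within 2d - k). With ``use_surviving_lists`` the engine
    additionally drops, per sequence, every window whose minimal descendant
    distance exceeds d — the qPMSPruneI speedup; outputs are unchanged,
    only work shrinks.

``qpms7_search``
    Two pivots x, y drawn from different sequences with h(x, y) <= 2d. The
    traversal of T_d(x) is restricted to nodes whose descendants can still
    reach B_d(y), and window survival is decided by an exact three-ball
    intersection test on the unmutated suffix. Backtracks when fewer than
    q-2 non-pivot sequences keep a non-empty surviving list.

All engines return the same deduplicated, lexicographically sorted motif
set; they differ only in how much of the space they touch (``SearchStats``).
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .core import Alphabet, SearchParams, SequenceSet, _min_dist_eligible
from .errors import CapacityError, ParameterError, TimeBudgetError

__all__ = [
    "SearchStats",
    "MotifReport",
    "MotifSearchResult",
    "brute_force_search",
    "qpmsprune_search",
    "qpms7_search",
    "preprocess_filter",
    "assemble_report",
    "write_motifs_tsv",
]

#: refuse full enumeration / ball unions above this many candidate l-mers
DEFAULT_CANDIDATE_CAP = 1 << 22


@dataclass
class SearchStats:
    """Work counters for one search run."""

    nodes_visited: int = 0
    nodes_pruned: int = 0
    distance_updates: int = 0
    motifs_found: int = 0

    def _add_raw(self, raw: np.ndarray) -> None:
        self.nodes_visited += int(raw[0])
        self.nodes_pruned += int(raw[1])
        self.distance_updates += int(raw[2])


@dataclass
class MotifReport:
    """A found (l, d)-motif with per-sequence best-match evidence.

    ``evidence[j]`` is ``(best distance, tuple of best offsets)`` for
    sequence j (0-based half-open window coordinates); ``support`` counts
    sequences with best distance <= d and is always >= q.
    """

    motif: str
    l: int
    d: int
    q: int
    support: int
    evidence: list[tuple[int, tuple[int, ...]]]

    def __post_init__(self):
        assert self.support >= self.q, (
            f"motif {self.motif!r} has support {self.support} < q={self.q}"
        )


class _WindowTable:
    """All length-l windows of a sequence set, integer-coded, plus
    eligibility flags (windows containing out-of-alphabet characters are
    ineligible). Local window index == 0-based offset."""

    def __init__(self, seqs: SequenceSet, l: int):
        self.seqs = seqs
        self.l = l
        n = seqs.n
        counts = [len(s) - l + 1 for s in seqs.seqs]
        self.wcount = np.array(counts, dtype=np.int32)
        self.wstart = np.zeros(n, dtype=np.int32)
        self.wstart[1:] = np.cumsum(self.wcount)[:-1].astype(np.int32)
        W = int(self.wcount.sum())
        self.win = np.empty((W, l), dtype=np.int8)
        self.elig = np.empty(W, dtype=np.uint8)
        for j, codes in enumerate(seqs.encoded):
            view = np.lib.stride_tricks.sliding_window_view(codes, l)
            s = self.wstart[j]
            self.win[s : s + counts[j]] = view
            self.elig[s : s + counts[j]] = (view >= 0).all(axis=1)

    @property
    def wm(self) -> int:
        return int(self.wcount.max())

    def pair_ids(self) -> tuple[np.ndarray, int]:
        n = self.seqs.n
        pid = np.full((n, n), -1, dtype=np.int32)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                pid[i, j] = k
                k += 1
        return pid, k


class MotifSearchResult:
    """Deduplicated, sorted motif set plus search statistics.

    Full :class:`MotifReport` objects (support recomputed over all n
    sequences, per-sequence best distances and offsets) are assembled
    lazily via :meth:`report` / :meth:`reports` — the motif set of a dense
    instance can be very large.
    """

    def __init__(
        self,
        motifs: list[str],
        stats: SearchStats,
        params: SearchParams,
        seqs: SequenceSet,
        algorithm: str,
    ):
        self.motifs = motifs
        self.stats = stats
        self.params = params
        self.seqs = seqs
        self.algorithm = algorithm
        stats.motifs_found = len(motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif: str) -> bool:
        return motif in set(self.motifs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.motifs)

    def motif_set(self) -> set[str]:
        return set(self.motifs)

    def report(self, motif: str) -> MotifReport:
        return assemble_report(motif, self.seqs, self.params)

    def reports(self) -> Iterator[MotifReport]:
        for m in self.motifs:
            yield self.report(m)

    def __repr__(self) -> str:
        p = self.params
        return (
            f"<MotifSearchResult {self.algorithm} (l={p.l}, d={p.d}, q={p.q}): "
            f"{len(self.motifs)} motifs>"
        )


def assemble_report(motif: str, seqs: SequenceSet, params: SearchParams) -> MotifReport:
    """Build the evidence report for a motif that passed quorum.

    Evidence is recomputed from the definition over all n sequences (a motif
    found through particular pivots may match excluded sequences as well).
    """
    evidence = []
    support = 0
    for j, (_, s) in enumerate(seqs):
        dist, offs = _min_dist_eligible(motif, s, seqs.encoded[j])
        if dist <= params.d:
            support += 1
        evidence.append((dist, tuple(offs)))
    return MotifReport(
        motif=motif, l=params.l, d=params.d, q=params.q,
        support=support, evidence=evidence,
    )


def _check_deadline(deadline: float | None) -> None:
    if deadline is not None and time.monotonic() > deadline:
        raise TimeBudgetError("search exceeded its time budget")


def _decode_sorted(codes: np.ndarray, alphabet: Alphabet, l: int) -> list[str]:
    codes = np.unique(codes)
    # packed codes order by last character first; resort lexicographically
    return sorted(alphabet.decode_int(int(c), l) for c in codes)


def _elig_with_filter(
    table: _WindowTable, params: SearchParams, use_filter: bool
) -> np.ndarray:
    if not use_filter:
        return table.elig
    keep = _filter_keep_mask(table, params)
    return (table.elig.astype(bool) & keep.astype(bool)).astype(np.uint8)


def _filter_keep_mask(table: _WindowTable, params: SearchParams) -> np.ndarray:
    if table.l >= 255:
        raise CapacityError("preprocessing filter supports l < 255")
    pid, npairs = table.pair_ids()
    D = _kernels.build_pair_dists(
        table.win, table.wstart, table.wcount, table.elig,
        pid, npairs, table.wm, 2 * params.d,
    )
    return _kernels.filter_keep(
        table.wstart, table.wcount, table.elig, pid, D, 2 * params.d, params.q
    )


def preprocess_filter(seqs: SequenceSet, params: SearchParams) -> list[np.ndarray]:
    """Per-sequence offsets of windows that could still be motif instances.

    Window u of s_i is kept iff at least q-1 of the other sequences contain
    a window within 2d of it (any instance of a quorum motif passes, by the
    triangle inequality). Removed windows are excluded from pivot candidacy
    and from surviving lists when the filter is enabled in a solver.
    """
    params.validate_for(seqs)
    table = _WindowTable(seqs, params.l)
    keep = _filter_keep_mask(table, params)
    out = []
    for j in range(seqs.n):
        s = table.wstart[j]
        c = table.wcount[j]
        out.append(np.nonzero(keep[s : s + c])[0].astype(np.int64))
    return out


def brute_force_search(
    seqs: SequenceSet,
    params: SearchParams,
    use_filter: bool = False,
    mode: str = "auto",
    candidate_cap: int = DEFAULT_CANDIDATE_CAP,
    deadline: float | None = None,
) -> MotifSearchResult:
    """Oracle: the motif definition applied to an explicit candidate set.

    mode "full" enumerates all sigma^l l-mers; mode "balls" enumerates the
    union of the d-balls of the first n-q+1 sequences' windows (every motif
    lies in one of those balls); "auto" picks whichever is smaller. Refuses
    with :class:`CapacityError` when the candidate set would exceed
    ``candidate_cap`` — this engine exists for correctness, not scale.
    """
    params.validate_for(seqs)
    alphabet = seqs.alphabet
    sigma = alphabet.size
    l, d, q = params.l, params.d, params.q
    table = _WindowTable(seqs, l)
    elig = _elig_with_filter(table, params, use_filter)

    full_size = sigma**l
    from .neighborhood import ball_size

    npivots = int(
        sum(
            elig[table.wstart[i] : table.wstart[i] + table.wcount[i]].sum()
            for i in range(seqs.n - q + 1)
        )
    )
    balls_size = npivots * ball_size(l, d, sigma)
    if mode == "auto":
        mode = "full" if full_size <= balls_size else "balls"
    if mode == "full":
        if full_size > candidate_cap:
            raise CapacityError(
                f"full enumeration of {sigma}^{l} = {full_size} l-mers exceeds "
                f"the cap ({candidate_cap}); use mode='balls' or raise the cap"
            )
        cands = np.arange(full_size, dtype=np.int64)
    elif mode == "balls":
        if balls_size > candidate_cap:
            raise CapacityError(
                f"union of {npivots} d-balls (~{balls_size} l-mers) exceeds "
                f"the cap ({candidate_cap})"
            )
        from .neighborhood import ball_codes

        chunks = []
        for i in range(seqs.n - q + 1):
            s = table.wstart[i]
            for u in range(table.wcount[i]):
                if not elig[s + u]:
                    continue
                _check_deadline(deadline)
                codes, _ = ball_codes(table.win[s + u], d, alphabet)
                chunks.append(codes)
        cands = np.unique(np.concatenate(chunks)) if chunks else np.empty(0, np.int64)
    else:
        raise ParameterError(f"unknown brute-force mode {mode!r}")

    keep = _kernels.quorum_mask(
        cands, table.win, table.wstart, table.wcount, elig, d, q, sigma, l
    )
    motifs = _decode_sorted(cands[keep.astype(bool)], alphabet, l)
    stats = SearchStats(nodes_visited=len(cands))
    return MotifSearchResult(motifs, stats, params, seqs, "brute")


def _run_with_retry(kernel_call, buf_size: int = 1 << 12):
    """Run an emitting kernel, growing the output buffer on overflow."""
    while True:
        out = np.empty(buf_size, dtype=np.int64)
        raw = np.zeros(3, dtype=np.int64)
        cnt = kernel_call(out, raw)
        if cnt >= 0:
            return out[:cnt], raw
        buf_size *= 8


def qpmsprune_search(
    seqs: SequenceSet,
    params: SearchParams,
    use_surviving_lists: bool = False,
    use_filter: bool = False,
    deadline: float | None = None,
) -> MotifSearchResult:
    """Single-pivot branch-and-bound qPMS search (qPMSPrune / qPMSPruneI).

    With ``use_surviving_lists`` the per-sequence lists of windows that can
    still witness a descendant motif are maintained and shrunk along each
    root-to-leaf path (qPMSPruneI); the output set is identical, only
    ``SearchStats.distance_updates`` drops.
    """
    params.validate_for(seqs)
    alphabet = seqs.alphabet
    l, d, q = params.l, params.d, params.q
    table = _WindowTable(seqs, l)
    elig = _elig_with_filter(table, params, use_filter)
    stats = SearchStats()
    chunks = []
    for i in range(seqs.n - q + 1):
        s = table.wstart[i]
        for u in range(table.wcount[i]):
            if not elig[s + u]:
                continue
            _check_deadline(deadline)
            x = table.win[s + u].copy()
            codes, raw = _run_with_retry(
                lambda out, st: _kernels.qpmsprune_tree(
                    table.win, table.wstart, table.wcount, elig,
                    d, q, alphabet.size, i, x, use_surviving_lists, out, st,
                )
            )
            stats._add_raw(raw)
            if codes.size:
                chunks.append(codes)
    all_codes = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    motifs = _decode_sorted(all_codes, alphabet, l)
    name = "qpmsprune-i" if use_surviving_lists else "qpmsprune"
    return MotifSearchResult(motifs, stats, params, seqs, name)


def qpms7_search(
    seqs: SequenceSet,
    params: SearchParams,
    use_filter: bool = True,
    deadline: float | None = None,
) -> MotifSearchResult:
    """Two-pivot qPMS search (qPMS7).

    Pivot pairs run over sequences r1 < r2 <= n-q+2 (1-based) and window
    pairs (x, y) with h(x, y) <= 2d; the preprocessing filter is on by
    default (it removes windows that provably cannot be motif instances and
    never changes the output).
    """
    params.validate_for(seqs)
    if params.q < 2:
        raise ParameterError("qPMS7 needs a quorum q >= 2 (two pivot sequences)")
    alphabet = seqs.alphabet
    l, d, q = params.l, params.d, params.q
    if l >= 255:
        raise CapacityError("qPMS7's distance tables support l < 255")
    table = _WindowTable(seqs, l)
    elig = _elig_with_filter(table, params, use_filter)
    pid, npairs = table.pair_ids()
    D = _kernels.build_pair_dists(
        table.win, table.wstart, table.wcount, elig, pid, npairs, table.wm, 2 * d
    )
    stats = SearchStats()
    chunks = []
    n = seqs.n
    for r1 in range(n - q + 1):
        for r2 in range(r1 + 1, n - q + 2):
            s1 = table.wstart[r1]
            for a_local in range(table.wcount[r1]):
                if not elig[s1 + a_local]:
                    continue
                _check_deadline(deadline)
                codes, raw = _run_with_retry(
                    lambda out, st: _kernels.qpms7_pair(
                        table.win, table.wstart, table.wcount, elig,
                        d, q, alphabet.size, r1, r2, a_local, D, pid, out, st,
                    )
                )
                stats._add_raw(raw)
                if codes.size:
                    chunks.append(codes)
    all_codes = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    motifs = _decode_sorted(all_codes, alphabet, l)
    return MotifSearchResult(motifs, stats, params, seqs, "qpms7")


def write_motifs_tsv(
    result: MotifSearchResult,
    path,
    header_lines: Sequence[str] = (),
    max_offsets: int = 16,
) -> None:
    """Write motifs as TSV: motif, l, d, q, support, then one
    ``dist:off1|off2...`` column per sequence (0-based, half-open windows)."""
    seqs = result.seqs
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 0-based, half-open [start, start+l)\n")
        cols = ["motif", "l", "d", "q", "support"] + list(seqs.ids)
        fh.write("\t".join(cols) + "\n")
        for rep in result.reports():
            cells = [rep.motif, str(rep.l), str(rep.d), str(rep.q), str(rep.support)]
            for dist, offs in rep.evidence:
                shown = "|".join(str(o) for o in offs[:max_offsets])
                cells.append(f"{dist}:{shown}")
            fh.write("\t".join(cells) + "\n")
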