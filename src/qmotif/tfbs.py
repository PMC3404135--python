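"""Two-phase transcription-factor binding-site discovery.

Phase I sweeps an (l, d) grid: for each motif length l it raises the
mismatch budget d from 0 until the search backend returns motifs (then
stops for that l) or the per-run time budget is exhausted (then moves to
the next l). Phase II ranks the candidates by *sequence specificity* — the
log-product over sequences of the expected number of windows matching the
motif with up to d mismatches under an i.i.d. background model (smaller =
rarer by chance = better) — keeps the top k, and reports every window
within the distance threshold as a binding site.
"""

from __future__ import annotations

import math
import sys
import time
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import Alphabet, SearchParams, SequenceSet
from .errors import ParameterError, TimeBudgetError
from .solvers import (
    MotifSearchResult,
    brute_force_search,
    qpms7_search,
    qpmsprune_search,
)

__all__ = [
    "ScoredMotif",
    "BindingSite",
    "uniform_background",
    "estimate_background",
    "expected_match_count",
    "sequence_specificity",
    "phase1_select",
    "phase2_sites",
    "write_candidates_tsv",
    "write_sites_tsv",
]


@dataclass(frozen=True)
class ScoredMotif:
    """A candidate motif with the (l, d) it was found at and its
    sequence-specificity score (lower = more specific)."""

    motif: str
    l: int
    d: int
    score: float


@dataclass(frozen=True)
class BindingSite:
    """A window within ``distance`` of ``motif`` (0-based, half-open)."""

    seq_id: str
    offset: int
    length: int
    window: str
    distance: int
    motif: str


def uniform_background(alphabet: Alphabet) -> np.ndarray:
    return np.full(alphabet.size, 1.0 / alphabet.size)


def estimate_background(seqs: SequenceSet, pseudocount: float = 1.0) -> np.ndarray:
    """Per-character frequencies of the input (in-alphabet characters only),
    with a pseudocount to keep every frequency positive."""
    counts = np.full(seqs.alphabet.size, pseudocount, dtype=float)
    for codes in seqs.encoded:
        valid = codes[codes >= 0]
        counts += np.bincount(valid, minlength=seqs.alphabet.size)
    return counts / counts.sum()


def _background_probs(
    motif: str, background, alphabet: Alphabet
) -> np.ndarray:
    """Per-position probability that a random background character matches
    the motif character."""
    if isinstance(background, Mapping):
        try:
            p = np.array([background[c] for c in motif], dtype=float)
        except KeyError as exc:
            raise ParameterError(f"background lacks a frequency for {exc}") from None
        total = float(sum(background.values()))
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (alphabet.size,):
            raise ParameterError(
                f"background must have one frequency per alphabet symbol "
                f"({alphabet.size}), got shape {bg.shape}"
            )
        codes = alphabet.encode(motif)
        if (codes < 0).any():
            raise ParameterError(f"motif {motif!r} is not over alphabet {alphabet.name}")
        p = bg[codes]
        total = float(bg.sum())
    if abs(total - 1.0) > 1e-6:
        raise ParameterError(f"background frequencies must sum to 1, got {total}")
    if (p <= 0).any():
        raise ParameterError("background frequencies must all be positive")
    return p


def expected_match_count(
    motif: str,
    seq_length: int,
    background,
    d: int,
    alphabet: Alphabet | None = None,
) -> float:
    """Expected number of windows of an i.i.d. random string of
    ``seq_length`` matching ``motif`` with at most d mismatches.

    Equals (seq_length - l + 1) * P(X <= d) where X is the Poisson-binomial
    mismatch count with per-position match probability = background
    frequency of the motif character (computed by an exact DP tail).
    """
    l = len(motif)
    if seq_length < l:
        raise ParameterError(f"seq_length {seq_length} shorter than motif ({l})")
    if not (0 <= d <= l):
        raise ParameterError(f"need 0 <= d <= l, got d={d}")
    if alphabet is None:
        from .core import DNA, PROTEIN

        alphabet = DNA if set(motif) <= set(DNA.symbols) else PROTEIN
    p = _background_probs(motif, background, alphabet)
    # dp[k] = P(exactly k mismatches so far), overflow bucket at d+1
    dp = np.zeros(d + 2)
    dp[0] = 1.0
    for pj in p:
        nxt = np.zeros_like(dp)
        nxt[: d + 1] += dp[: d + 1] * pj
        nxt[1 : d + 2] += dp[: d + 1] * (1.0 - pj)
        nxt[d + 1] += dp[d + 1]
        dp = nxt
    tail = float(dp[: d + 1].sum())
    return (seq_length - l + 1) * tail


def sequence_specificity(
    motif: str,
    seqs: SequenceSet,
    d: int,
    background=None,
) -> float:
    """Sum over sequences of ln(expected match count) — the log of the
    product of the per-sequence expected counts. Lower scores mean the
    motif is rarer by chance, hence more likely to be a real signal."""
    if background is None:
        background = estimate_background(seqs)
    score = 0.0
    for s in seqs.seqs:
        e = expected_match_count(motif, len(s), background, d, seqs.alphabet)
        if e <= 0.0:
            raise ParameterError("degenerate background: expected count is zero")
        score += math.log(e)
    return score


_BACKENDS: dict[str, Callable] = {
    "qpms7": lambda seqs, params, deadline: qpms7_search(seqs, params, deadline=deadline),
    "qpmsprune": lambda seqs, params, deadline: qpmsprune_search(
        seqs, params, deadline=deadline
    ),
    "qpmsprune-i": lambda seqs, params, deadline: qpmsprune_search(
        seqs, params, use_surviving_lists=True, deadline=deadline
    ),
    "brute": lambda seqs, params, deadline: brute_force_search(
        seqs, params, deadline=deadline
    ),
}


def default_d_max(l: int) -> int:
    """Default mismatch-budget cap for the Phase I grid: ceil(l / 4)."""
    return -(-l // 4)


def phase1_select(
    seqs: SequenceSet,
    l_min: int = 10,
    l_max: int = 20,
    d_max_fn: Callable[[int], int] = default_d_max,
    q: int | None = None,
    backend: str | Callable = "qpms7",
    time_budget: float = 600.0,
    background=None,
    log=None,
) -> list[ScoredMotif]:
    """Phase I: collect candidate motifs over the (l, d) grid.

    For each l in [l_min, l_max] the backend runs at d = 0, 1, ... up to
    ``d_max_fn(l)``; the first non-empty result for an l ends its inner
    loop. A run exceeding ``time_budget`` seconds is terminated and the
    sweep moves to the next l (logged, non-fatal). Candidates are tagged
    with the (l, d) they were found at and scored by sequence specificity.
    """
    if q is None:
        q = seqs.n
    if not (1 <= l_min <= l_max):
        raise ParameterError(f"need 1 <= l_min <= l_max, got {l_min}..{l_max}")
    if l_max > seqs.min_length:
        raise ParameterError(
            f"l_max={l_max} exceeds shortest sequence length {seqs.min_length}"
        )
    run = _BACKENDS[backend] if isinstance(backend, str) else backend
    if background is None:
        background = estimate_background(seqs)
    if log is None:
        log = lambda msg: print(msg, file=sys.stderr)

    out: list[ScoredMotif] = []
    for l in range(l_min, l_max + 1):
        d_cap = min(d_max_fn(l), l - 1)
        for d in range(0, d_cap + 1):
            params = SearchParams(l=l, d=d, q=q)
            deadline = time.monotonic() + time_budget
            try:
                if time_budget <= 0:
                    raise TimeBudgetError("zero time budget")
                result: MotifSearchResult = run(seqs, params, deadline)
            except TimeBudgetError:
                log(f"phase1: (l={l}, d={d}) exceeded the {time_budget}s budget; "
                    f"moving to next l")
                break
            log(f"phase1: (l={l}, d={d}) -> {len(result)} motifs")
            if len(result):
                for m in result:
                    out.append(
                        ScoredMotif(
                            motif=m, l=l, d=d,
                            score=sequence_specificity(m, seqs, d, background),
                        )
                    )
                break
    return out


def phase2_sites(
    seqs: SequenceSet,
    candidates: Sequence[ScoredMotif],
    k_top: int = 5,
    d_site: int | None = None,
) -> list[BindingSite]:
    """Phase II: rank candidates, keep the top ``k_top``, report sites.

    Candidates are sorted by (score ascending, motif lexicographic); for
    each retained motif every eligible window of every sequence within
    ``d_site`` (default: the d the motif was found at) is emitted as a
    binding site. Fully deterministic.
    """
    if k_top < 1:
        raise ParameterError(f"k_top must be >= 1, got {k_top}")
    ranked = sorted(candidates, key=lambda c: (c.score, c.motif))[:k_top]
    sites: list[BindingSite] = []
    for cand in ranked:
        dthr = cand.d if d_site is None else d_site
        motif = cand.motif
        l = cand.l
        for j, (sid, s) in enumerate(seqs):
            codes = seqs.encoded[j]
            for off in range(len(s) - l + 1):
                window = s[off : off + l]
                if (codes[off : off + l] < 0).any():
                    continue
                dist = sum(a != b for a, b in zip(motif, window))
                if dist <= dthr:
                    sites.append(
                        BindingSite(
                            seq_id=sid, offset=off, length=l,
                            window=window, distance=dist, motif=motif,
                        )
                    )
    return sites


def write_candidates_tsv(
    candidates: Sequence[ScoredMotif], path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("motif\tl\td\tscore\n")
        for c in sorted(candidates, key=lambda c: (c.score, c.motif)):
            fh.write(f"{c.motif}\t{c.l}\t{c.d}\t{c.score:.6g}\n")


def write_sites_tsv(
    sites: Sequence[BindingSite], path, header_lines: Sequence[str] = ()
) -> None:
    """BED-like TSV: sequence id, start, end (0-based half-open), motif,
    distance, window."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# coordinates: 0-based, half-open [start, end)\n")
        fh.write("seq_id\tstart\tend\tmotif\tdistance\twindow\n")
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.offset}\t{s.offset + s.length}\t"
                f"{s.motif}\t{s.distance}\t{s.window}\n"
            )
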