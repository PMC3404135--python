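"""d-neighborhood (Hamming-ball) machinery.

The d-neighborhood B_d(x) of an l-mer x is the set of l-mers within Hamming
distance d of x. It is enumerated without repetition by the mutation tree
T_d(x): each node is a pair (t, p) where p is the last mutated position
(1-based; p = 0 at the root), children of (t, p) mutate exactly one position
p' > p — where t still agrees with x — to each character different from
x[p'], as long as the node's depth (= its Hamming distance to x) is below d.

This module also provides the ball-intersection feasibility tests that power
the solvers' pruning: two balls intersect iff their center distance is at
most the sum of their radii; three-ball intersection is decided exactly by a
small dynamic program (:func:`three_ball_nonempty`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from . import _kernels
from .core import DNA, Alphabet, hamming
from .errors import ParameterError

__all__ = [
    "SearchNode",
    "BallSpec",
    "ball_size",
    "ball_codes",
    "enumerate_ball",
    "dfs_mutation_tree",
    "min_descendant_distance",
    "two_ball_nonempty",
    "three_ball_nonempty",
]


@dataclass(frozen=True)
class SearchNode:
    """A node (t, p) of the mutation tree T_d(x).

    ``p`` is the last mutated position, 1-based (0 at the root); ``depth``
    equals hamming(x, t) and also the number of positions <= p where t
    differs from the pivot x.
    """

    t: str
    p: int
    depth: int


@dataclass(frozen=True)
class BallSpec:
    """A Hamming ball: all strings within ``radius`` of ``center``."""

    center: str
    radius: int

    def __post_init__(self):
        if not (0 <= self.radius <= len(self.center)):
            raise ParameterError(
                f"ball radius must be in [0, {len(self.center)}], got {self.radius}"
            )


def ball_size(l: int, d: int, sigma: int) -> int:
    """|B_d(x)| = sum_{i=0..d} C(l, i) (sigma-1)^i — independent of the center."""
    if not (0 <= d <= l):
        raise ParameterError(f"need 0 <= d <= l, got d={d}, l={l}")
    if sigma < 2:
        raise ParameterError(f"alphabet size must be >= 2, got {sigma}")
    return sum(math.comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


def ball_codes(
    x: str | np.ndarray, d: int, alphabet: Alphabet = DNA
) -> tuple[np.ndarray, np.ndarray]:
    """All members of B_d(x) as packed int64 codes plus their distances to x.

    Fast path used by the solvers and mass tests; order is the depth-first
    traversal order of the mutation tree. Decode with
    ``alphabet.decode_int(code, l)``.
    """
    codes_x = x if isinstance(x, np.ndarray) else alphabet.encode(x)
    if (codes_x < 0).any():
        raise ParameterError("center contains characters outside the alphabet")
    l = len(codes_x)
    if not (0 <= d <= l):
        raise ParameterError(f"need 0 <= d <= l, got d={d}, l={l}")
    size = ball_size(l, d, alphabet.size)
    out_codes = np.empty(size, dtype=np.int64)
    out_depths = np.empty(size, dtype=np.int8)
    cnt = _kernels.ball_collect(
        codes_x.astype(np.int8), d, alphabet.size, out_codes, out_depths
    )
    assert cnt == size
    return out_codes, out_depths


def enumerate_ball(x: str, d: int, alphabet: Alphabet = DNA) -> Iterator[str]:
    """Yield each l-mer within Hamming distance d of x exactly once."""
    codes, _ = ball_codes(x, d, alphabet)
    l = len(x)
    for code in codes:
        yield alphabet.decode_int(int(code), l)


def dfs_mutation_tree(
    x: str,
    d: int,
    alphabet: Alphabet = DNA,
    enter: Callable[[SearchNode], None] | None = None,
    leave: Callable[[SearchNode], None] | None = None,
) -> dict:
    """Depth-first traversal of T_d(x) with enter/leave callbacks.

    Children are visited in increasing mutated position, then alphabet
    order; enter/leave calls nest properly. Returns traversal statistics
    (``nodes``, ``max_depth``).
    """
    if not (0 <= d <= len(x)):
        raise ParameterError(f"need 0 <= d <= l, got d={d}, l={len(x)}")
    if x not in alphabet:
        raise ParameterError("pivot contains characters outside the alphabet")
    stats = {"nodes": 0, "max_depth": 0}

    def visit(t: list[str], p: int, depth: int) -> None:
        node = SearchNode("".join(t), p, depth)
        stats["nodes"] += 1
        stats["max_depth"] = max(stats["max_depth"], depth)
        if enter is not None:
            enter(node)
        if depth < d:
            for pos in range(p, len(x)):  # 0-based pos == 1-based p' - 1
                ref = t[pos]
                for c in alphabet.symbols:
                    if c == ref:
                        continue
                    t[pos] = c
                    visit(t, pos + 1, depth + 1)
                t[pos] = ref
        if leave is not None:
            leave(node)

    visit(list(x), 0, 0)
    return stats


def min_descendant_distance(node: SearchNode, y: str, d: int) -> int:
    """Exact minimum of hamming(t', y) over all descendants t' of ``node``
    (itself included) in the mutation tree of radius d.

    Descendants may mutate only positions past p, at most d - depth of them,
    so the minimum is a + max(0, b - (d - depth)) with a the prefix (<= p)
    and b the suffix mismatch count between node.t and y.
    """
    t = node.t
    if len(y) != len(t):
        raise ParameterError(f"length mismatch: {len(y)} != {len(t)}")
    a = sum(tc != yc for tc, yc in zip(t[: node.p], y[: node.p]))
    b = sum(tc != yc for tc, yc in zip(t[node.p :], y[node.p :]))
    return a + max(0, b - (d - node.depth))


def two_ball_nonempty(b1: BallSpec, b2: BallSpec) -> bool:
    """Two Hamming balls intersect iff h(c1, c2) <= r1 + r2."""
    if len(b1.center) != len(b2.center):
        raise ParameterError("ball centers must have equal length")
    return hamming(b1.center, b2.center) <= b1.radius + b2.radius


def three_ball_nonempty(b1: BallSpec, b2: BallSpec, b3: BallSpec) -> bool:
    """Exact emptiness test for the intersection of three Hamming balls.

    True iff some string z of the common length satisfies h(z, ci) <= ri for
    all three balls; decided by a dynamic program over positions with state
    (mismatches to c1, mismatches to c2) minimizing mismatches to c3. The
    answer is exact for any alphabet with at least 2 characters.
    """
    L = len(b1.center)
    if not (len(b2.center) == len(b3.center) == L):
        raise ParameterError("ball centers must have equal length")
    # characters are compared only for equality; map bytes directly
    c1 = np.frombuffer(b1.center.encode(), dtype=np.int8)
    c2 = np.frombuffer(b2.center.encode(), dtype=np.int8)
    c3 = np.frombuffer(b3.center.encode(), dtype=np.int8)
    r1 = min(b1.radius, L)
    r2 = min(b2.radius, L)
    r3 = min(b3.radius, L)
    cur = np.empty((r1 + 1, r2 + 1), dtype=np.int16)
    nxt = np.empty((r1 + 1, r2 + 1), dtype=np.int16)
    return bool(
        _kernels.three_ball_suffix_dp(c1, c2, c3, 0, r1, r2, r3, cur, nxt)
    )
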