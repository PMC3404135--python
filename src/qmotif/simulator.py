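"""Planted (l, d, q) benchmark instance generation.

The standard planted-motif benchmark: n i.i.d. uniform random background
strings of length m, one uniform random l-mer chosen as the motif, and a
mutated copy of it (the plant) written over a random window of q of the n
sequences. Defaults n=20, m=600 are the canonical benchmark shape. In the
default "exact-d" mode each plant differs from the motif in exactly d
positions (the hardest placement, at the edge of the ball); "up-to-d" draws
the mutation count uniformly from 0..d.

Randomness comes from ``numpy.random.default_rng`` (PCG64); identical seeds
give byte-identical instances across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DNA, Alphabet, SequenceSet
from .errors import ParameterError

__all__ = [
    "PlantedInstance",
    "generate_planted_instance",
    "challenging_presets",
    "write_truth",
    "read_truth",
]

#: (l, d) ladders of the published challenging-instance benchmarks
_PRESETS: dict[str, list[tuple[int, int]]] = {
    "dna-pms": [(13, 4), (15, 5), (17, 6), (19, 7), (21, 8), (23, 9)],
    "dna-qpms": [(13, 3), (15, 4), (17, 5), (19, 6), (21, 7)],
    "protein-pms": [(11, 5), (13, 6), (15, 7), (17, 8), (19, 9)],
    "protein-qpms": [(11, 4), (13, 5), (15, 6), (17, 7), (19, 8)],
}


@dataclass
class PlantedInstance:
    """Simulator output: sequences plus ground truth.

    ``plants`` holds one ``(sequence index, offset, mutated copy)`` triple
    per planted sequence (0-based, half-open windows).
    """

    seqs: SequenceSet
    motif: str
    plants: list[tuple[int, int, str]]
    seed: int
    params: dict

    @property
    def plant_coords(self) -> list[tuple[int, int]]:
        return [(i, off) for i, off, _ in self.plants]


def generate_planted_instance(
    n: int = 20,
    m: int = 600,
    l: int = 13,
    d: int = 4,
    q: int | None = None,
    alphabet: Alphabet = DNA,
    seed: int | None = None,
    mode: str = "exact-d",
    background: Sequence[float] | None = None,
) -> PlantedInstance:
    """Generate one planted (l, d, q) instance.

    Each background string is i.i.d. random over the alphabet (uniform by
    default, or per-character frequencies via ``background``); the motif is
    a uniform random l-mer; q distinct sequences are chosen and a mutated
    copy of the motif overwrites a uniform random window of each. Fully
    reproducible from ``seed``.
    """
    if q is None:
        q = n
    if not (1 <= q <= n):
        raise ParameterError(f"need 1 <= q <= n, got q={q}, n={n}")
    if not (0 <= d < l):
        raise ParameterError(f"need 0 <= d < l, got d={d}, l={l}")
    if m < l:
        raise ParameterError(f"sequence length m={m} shorter than motif length l={l}")
    if mode not in ("exact-d", "up-to-d"):
        raise ParameterError(f"unknown mutation mode {mode!r}")
    if seed is None:
        raise ParameterError("a seed is required (reproducibility contract)")
    sigma = alphabet.size
    if background is not None:
        background = np.asarray(background, dtype=float)
        if background.shape != (sigma,) or background.min() <= 0:
            raise ParameterError("background must be positive, one weight per symbol")
        background = background / background.sum()
    rng = np.random.default_rng(seed)

    if background is None:
        mat = rng.integers(0, sigma, size=(n, m))
    else:
        mat = rng.choice(sigma, size=(n, m), p=background)
    motif_codes = rng.integers(0, sigma, size=l)
    motif = alphabet.decode(motif_codes)

    chosen = np.sort(rng.choice(n, size=q, replace=False))
    plants: list[tuple[int, int, str]] = []
    for i in chosen:
        k = d if mode == "exact-d" else int(rng.integers(0, d + 1))
        plant = motif_codes.copy()
        if k > 0:
            positions = rng.choice(l, size=k, replace=False)
            # shift by 1..sigma-1 guarantees a different character
            shifts = rng.integers(1, sigma, size=k)
            plant[positions] = (plant[positions] + shifts) % sigma
        off = int(rng.integers(0, m - l + 1))
        mat[i, off : off + l] = plant
        plants.append((int(i), off, alphabet.decode(plant)))

    seqs = SequenceSet(
        ((f"seq{i + 1}", alphabet.decode(mat[i])) for i in range(n)),
        alphabet=alphabet,
    )
    params = {
        "n": n, "m": m, "l": l, "d": d, "q": q,
        "alphabet": alphabet.name, "mode": mode,
    }
    return PlantedInstance(seqs=seqs, motif=motif, plants=plants,
                           seed=int(seed), params=params)


def challenging_presets(kind: str) -> list[tuple[int, int]]:
    """The published (l, d) ladders of challenging benchmark instances.

    ``kind`` is one of dna-pms, dna-qpms, protein-pms, protein-qpms (pms =
    quorum equals n; qpms = the generalized quorum setting).
    """
    try:
        return list(_PRESETS[kind.lower()])
    except KeyError:
        raise ParameterError(
            f"unknown preset kind {kind!r} (choose from {sorted(_PRESETS)})"
        ) from None


def write_truth(instance: PlantedInstance, path) -> None:
    """Machine-readable ground-truth sidecar (JSON; 0-based half-open)."""
    payload = {
        "motif": instance.motif,
        "seed": instance.seed,
        "params": instance.params,
        "coordinates": "0-based, half-open [offset, offset+l)",
        "plants": [
            {"sequence_index": i, "offset": off, "planted_copy": copy}
            for i, off, copy in instance.plants
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
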