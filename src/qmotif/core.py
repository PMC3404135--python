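"""Alphabets, sequence sets and Hamming-distance primitives.

Conventions used throughout the package:

* coordinates are 0-based, half-open ``[start, start + l)``;
* sequences are uppercased on load and stored both as strings and as
  ``int8`` code arrays over the declared alphabet (characters outside the
  alphabet, e.g. ``N``, are coded as -1 and make every window containing
  them ineligible, both as an l-mer and as a match witness);
* the Hamming distance between an l-mer and a longer string is the minimum
  over all its length-l windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "Alphabet",
    "DNA",
    "PROTEIN",
    "SequenceSet",
    "SearchParams",
    "hamming",
    "min_hamming_to_sequence",
    "quorum_count",
]


class Alphabet:
    """An ordered alphabet of distinct single characters."""

    __slots__ = ("symbols", "_index", "name")

    def __init__(self, symbols: str, name: str = "custom"):
        symbols = str(symbols)
        if len(symbols) < 2:
            raise ParameterError("an alphabet needs at least 2 symbols")
        if len(set(symbols)) != len(symbols):
            raise ParameterError("alphabet symbols must be distinct")
        if any(len(s.encode()) != 1 for s in symbols):
            raise ParameterError("alphabet symbols must be single ASCII characters")
        self.symbols = symbols
        self.name = name
        self._index = {c: i for i, c in enumerate(symbols)}

    @property
    def size(self) -> int:
        return len(self.symbols)

    def encode(self, s: str) -> np.ndarray:
        """Encode a string to an ``int8`` code array; unknown chars become -1."""
        idx = self._index
        return np.array([idx.get(c, -1) for c in s], dtype=np.int8)

    def decode(self, codes: Iterable[int]) -> str:
        return "".join(self.symbols[int(c)] for c in codes)

    def decode_int(self, code: int, l: int) -> str:
        """Decode a base-``size`` packed integer (least-significant = position 0)."""
        out = []
        sigma = self.size
        for _ in range(l):
            out.append(self.symbols[code % sigma])
            code //= sigma
        return "".join(out)

    def encode_int(self, s: str) -> int:
        """Pack a string into a base-``size`` integer (position 0 least significant)."""
        code = 0
        for c in reversed(s):
            try:
                code = code * self.size + self._index[c]
            except KeyError:
                raise InputError(f"character {c!r} not in alphabet {self.name}") from None
        return code

    def __contains__(self, s: str) -> bool:
        return all(c in self._index for c in s)

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and other.symbols == self.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def __repr__(self) -> str:
        return f"Alphabet({self.symbols!r}, name={self.name!r})"


#: The 4-letter DNA alphabet.
DNA = Alphabet("ACGT", name="dna")
#: The 20-letter protein alphabet (standard amino acids, alphabetical).
PROTEIN = Alphabet("ACDEFGHIKLMNPQRSTVWY", name="protein")

_PRESETS = {"dna": DNA, "protein": PROTEIN}


def get_alphabet(name: str) -> Alphabet:
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise ParameterError(f"unknown alphabet preset {name!r} (dna, protein)") from None


class SequenceSet:
    """A set of named sequences over one alphabet.

    Parameters
    ----------
    records:
        Iterable of ``(id, sequence)`` pairs. Sequences are uppercased.
    alphabet:
        The declared alphabet; defaults to DNA.
    strict:
        If true, any character outside the alphabet raises :class:`InputError`.
        Otherwise such characters are kept but coded as -1, and windows
        containing them are ineligible.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, str]],
        alphabet: Alphabet = DNA,
        strict: bool = False,
    ):
        self.alphabet = alphabet
        self.ids: list[str] = []
        self.seqs: list[str] = []
        for rid, seq in records:
            seq = str(seq).upper()
            if not seq:
                raise InputError(f"sequence {rid!r} is empty")
            if strict and seq not in alphabet:
                bad = sorted({c for c in seq if c not in alphabet._index})
                raise InputError(
                    f"sequence {rid!r} contains characters {bad} outside alphabet "
                    f"{alphabet.name!r}"
                )
            self.ids.append(str(rid))
            self.seqs.append(seq)
        if not self.seqs:
            raise InputError("no sequences given")
        self.encoded: list[np.ndarray] = [alphabet.encode(s) for s in self.seqs]

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def min_length(self) -> int:
        return min(len(s) for s in self.seqs)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    def __repr__(self) -> str:
        return f"<SequenceSet n={self.n} alphabet={self.alphabet.name}>"

    @classmethod
    def from_strings(
        cls, seqs: Sequence[str], alphabet: Alphabet = DNA, strict: bool = False
    ) -> "SequenceSet":
        return cls(
            ((f"seq{i + 1}", s) for i, s in enumerate(seqs)),
            alphabet=alphabet,
            strict=strict,
        )

    @classmethod
    def from_fasta(
        cls, path, alphabet: Alphabet = DNA, strict: bool = False
    ) -> "SequenceSet":
        """Read a multi-record FASTA file (id = text after '>' up to whitespace)."""
        from Bio import SeqIO

        try:
            records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        except OSError as exc:
            raise InputError(f"cannot read FASTA file {path}: {exc}") from exc
        if not records:
            raise InputError(f"no FASTA records found in {path}")
        return cls(records, alphabet=alphabet, strict=strict)

    @classmethod
    def from_plain(
        cls, path, alphabet: Alphabet = DNA, strict: bool = False
    ) -> "SequenceSet":
        """Read plain text, one sequence per line (blank lines skipped)."""
        try:
            with open(path) as fh:
                lines = [ln.strip() for ln in fh]
        except OSError as exc:
            raise InputError(f"cannot read {path}: {exc}") from exc
        seqs = [ln for ln in lines if ln]
        if not seqs:
            raise InputError(f"no sequences found in {path}")
        return cls.from_strings(seqs, alphabet=alphabet, strict=strict)

    @classmethod
    def from_file(
        cls, path, alphabet: Alphabet = DNA, strict: bool = False
    ) -> "SequenceSet":
        """Auto-detect FASTA ('>' first char) vs plain one-sequence-per-line."""
        try:
            with open(path) as fh:
                first = fh.read(1)
        except OSError as exc:
            raise InputError(f"cannot read {path}: {exc}") from exc
        if first == ">":
            return cls.from_fasta(path, alphabet=alphabet, strict=strict)
        return cls.from_plain(path, alphabet=alphabet, strict=strict)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for rid, seq in self:
                fh.write(f">{rid}\n")
                for k in range(0, len(seq), width):
                    fh.write(seq[k : k + width] + "\n")


@dataclass(frozen=True)
class SearchParams:
    """The (l, d, q) problem instance: motif length, mismatch budget, quorum."""

    l: int
    d: int
    q: int

    def __post_init__(self):
        if self.l < 1:
            raise ParameterError(f"motif length l must be >= 1, got {self.l}")
        if not (0 <= self.d < self.l):
            raise ParameterError(f"need 0 <= d < l, got d={self.d}, l={self.l}")
        if self.q < 1:
            raise ParameterError(f"quorum q must be >= 1, got {self.q}")

    def validate_for(self, seqs: SequenceSet) -> None:
        if self.q > seqs.n:
            raise ParameterError(f"quorum q={self.q} exceeds number of sequences n={seqs.n}")
        if self.l > seqs.min_length:
            raise ParameterError(
                f"motif length l={self.l} exceeds shortest sequence "
                f"length {seqs.min_length}"
            )


def _as_codes(u, alphabet: Alphabet | None) -> np.ndarray:
    if isinstance(u, np.ndarray):
        return u.astype(np.int8, copy=False)
    if alphabet is None:
        alphabet = DNA if set(u) <= set(DNA.symbols) else PROTEIN
    return alphabet.encode(u)


def hamming(u: str, v: str) -> int:
    """Number of mismatching positions between two equal-length strings.

    A metric: identity of indiscernibles, symmetry and the triangle
    inequality all hold.
    """
    if len(u) != len(v):
        raise ParameterError(f"length mismatch: |u|={len(u)} != |v|={len(v)}")
    return sum(a != b for a, b in zip(u, v))


def min_hamming_to_sequence(u: str, s: str) -> tuple[int | float, list[int]]:
    """Minimum Hamming distance from l-mer ``u`` to any window of ``s``.

    Returns ``(dist, offsets)`` where *offsets* (0-based, ascending) are all
    window starts attaining *dist*. Windows are the contiguous substrings of
    length ``len(u)``. If no window is eligible (only possible when windows
    contain out-of-alphabet characters, filtered by the caller), returns
    ``(math.inf, [])``.
    """
    l = len(u)
    if len(s) < l:
        raise ParameterError(f"sequence shorter than l-mer: {len(s)} < {l}")
    best: int | float = math.inf
    offsets: list[int] = []
    for off in range(len(s) - l + 1):
        dist = sum(a != b for a, b in zip(u, s[off : off + l]))
        if dist < best:
            best = dist
            offsets = [off]
        elif dist == best:
            offsets.append(off)
    return best, offsets


def quorum_count(
    t: str,
    seqs: SequenceSet,
    d: int,
    exclude: frozenset[int] | set[int] = frozenset(),
) -> int:
    """Number of non-excluded sequences with a window within distance ``d`` of ``t``.

    ``t`` is an l-mer over the same alphabet as ``seqs``; ``exclude`` holds
    0-based record indices. Non-decreasing in ``d`` and non-increasing as
    ``exclude`` grows.
    """
    if t.upper() not in seqs.alphabet:
        raise InputError(f"l-mer {t!r} is not over alphabet {seqs.alphabet.name!r}")
    count = 0
    for j, (_, s) in enumerate(seqs):
        if j in exclude:
            continue
        dist, _ = _min_dist_eligible(t.upper(), s, seqs.encoded[j])
        if dist <= d:
            count += 1
    return count


def _min_dist_eligible(u: str, s: str, codes: np.ndarray) -> tuple[int | float, list[int]]:
    """Like :func:`min_hamming_to_sequence` but skipping windows that contain
    out-of-alphabet characters (code -1)."""
    if (codes >= 0).all():
        return min_hamming_to_sequence(u, s)
    l = len(u)
    if len(s) < l:
        raise ParameterError(f"sequence shorter than l-mer: {len(s)} < {l}")
    bad = codes < 0
    best: int | float = math.inf
    offsets: list[int] = []
    for off in range(len(s) - l + 1):
        if bad[off : off + l].any():
            continue
        dist = sum(a != b for a, b in zip(u, s[off : off + l]))
        if dist < best:
            best = dist
            offsets = [off]
        elif dist == best:
            offsets.append(off)
    return best, offsets
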