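"""Reference-anchored genotype representation for substitution-only mutant libraries.

A genotype is a set of point substitutions relative to a fixed reference
sequence (the wild-type ribozyme). Positions are 1-based so that labels match
the conventional secondary-structure numbering (G1, U20, G25, C57). The
alphabet is RNA {A, C, G, U}; T is accepted on input (sequencing reads are
DNA) and normalized to U.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

ALPHABET = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def normalize_bases(seq: str) -> str:
    """Uppercase and convert DNA thymine to RNA uracil."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReferenceSequence:
    """Wild-type sequence against which all mutations are defined."""

    bases: str

    def __post_init__(self) -> None:
        norm = normalize_bases(self.bases)
        if len(norm) < 1:
            raise ValueError("reference sequence must be nonempty")
        bad = set(norm) - set(ALPHABET)
        if bad:
            raise ValueError(f"reference contains non-ACGU(T) symbols: {sorted(bad)}")
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.bases):
            raise IndexError(f"position {position} outside 1..{len(self.bases)}")
        return self.bases[position - 1]


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: ref_base at 1-based position replaced by alt_base."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_base", normalize_bases(self.ref_base))
        object.__setattr__(self, "alt_base", normalize_bases(self.alt_base))
        if self.ref_base not in ALPHABET or self.alt_base not in ALPHABET:
            raise ValueError(f"bases must be in {ALPHABET}")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    def __str__(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"


@dataclass(frozen=True)
class Genotype:
    """An immutable set of mutations, canonically sorted by position.

    ``order`` (the mutational distance from wild-type) is the number of
    mutations. Order 0 is the wild-type itself.
    """

    mutations: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations, key=lambda m: (m.position, m.alt_base)))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValueError("mutations must be at pairwise distinct positions")
        object.__setattr__(self, "mutations", muts)

    @property
    def order(self) -> int:
        return len(self.mutations)

    @property
    def is_wildtype(self) -> bool:
        return not self.mutations

    def sequence(self, ref: ReferenceSequence) -> str:
        """Reconstruct the full sequence of this genotype on ``ref``."""
        bases = list(ref.bases)
        for m in self.mutations:
            if ref.base_at(m.position) != m.ref_base:
                raise ValueError(
                    f"mutation {m} inconsistent with reference base "
                    f"{ref.base_at(m.position)} at position {m.position}"
                )
            bases[m.position - 1] = m.alt_base
        return "".join(bases)

    def __str__(self) -> str:
        if not self.mutations:
            return "WT"
        return ";".join(str(m) for m in self.mutations)

    @classmethod
    def wildtype(cls) -> "Genotype":
        return cls(())

    @classmethod
    def from_string(cls, label: str, ref: ReferenceSequence | None = None) -> "Genotype":
        """Parse the semicolon-joined token syntax, e.g. ``"G1A;U20C"`` or ``"WT"``.

        If ``ref`` is given, each token's reference base is validated against it.
        """
        label = label.strip()
        if label.upper() == "WT" or label == "":
            return cls(())
        muts = []
        for token in label.split(";"):
            token = token.strip()
            if len(token) < 3:
                raise ValueError(f"malformed mutation token {token!r}")
            ref_base, pos_str, alt_base = token[0], token[1:-1], token[-1]
            try:
                position = int(pos_str)
            except ValueError as exc:
                raise ValueError(f"malformed mutation token {token!r}") from exc
            m = Mutation(position=position, ref_base=ref_base, alt_base=alt_base)
            if ref is not None and ref.base_at(position) != m.ref_base:
                raise ValueError(
                    f"token {token!r}: reference base is {ref.base_at(position)}"
                )
            muts.append(m)
        return cls(tuple(muts))

    @classmethod
    def from_sequence(cls, seq: str, ref: ReferenceSequence) -> "Genotype":
        """Diff a full-length sequence against the reference."""
        seq = normalize_bases(seq)
        if len(seq) != len(ref):
            raise ValueError(f"sequence length {len(seq)} != reference length {len(ref)}")
        muts = [
            Mutation(position=i + 1, ref_base=r, alt_base=s)
            for i, (r, s) in enumerate(zip(ref.bases, seq))
            if r != s
        ]
        return cls(tuple(muts))


@dataclass(frozen=True)
class VariablePositionScheme:
    """Positions allowed to vary and the alternative bases allowed at each.

    Models a doped-synthesis design where only selected positions carry
    non-reference bases (e.g. the 13 naturally variable positions of the
    phylogenetic library).
    """

    entries: tuple[tuple[int, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        entries = tuple(
            (pos, tuple(sorted(normalize_bases(b) for b in alts)))
            for pos, alts in self.entries
        )
        positions = [pos for pos, _ in entries]
        if len(set(positions)) != len(positions):
            raise ValueError("scheme positions must be distinct")
        for pos, alts in entries:
            if not alts:
                raise ValueError(f"empty alternative set at position {pos}")
        object.__setattr__(self, "entries", tuple(sorted(entries)))

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for pos, _ in self.entries)

    def validate_against(self, ref: ReferenceSequence) -> None:
        for pos, alts in self.entries:
            for b in alts:
                if b == ref.base_at(pos):
                    raise ValueError(
                        f"alternative {b} at position {pos} equals the reference base"
                    )


# ---------------------------------------------------------------------------
# Enumeration


def enumerate_single_mutants(ref: ReferenceSequence) -> list[Genotype]:
    """All 3L single mutants, ordered by position then alt base (A<C<G<U)."""
    out = []
    for pos in range(1, len(ref) + 1):
        r = ref.base_at(pos)
        for alt in ALPHABET:
            if alt != r:
                out.append(Genotype((Mutation(pos, r, alt),)))
    return out


def enumerate_double_mutants(ref: ReferenceSequence) -> list[Genotype]:
    """All 9*C(L,2) double mutants over distinct position pairs."""
    if len(ref) < 2:
        raise ValueError("need at least two positions to form double mutants")
    out = []
    for i in range(1, len(ref) + 1):
        ri = ref.base_at(i)
        alts_i = [a for a in ALPHABET if a != ri]
        for j in range(i + 1, len(ref) + 1):
            rj = ref.base_at(j)
            alts_j = [a for a in ALPHABET if a != rj]
            for ai in alts_i:
                for aj in alts_j:
                    out.append(
                        Genotype((Mutation(i, ri, ai), Mutation(j, rj, aj)))
                    )
    return out


def enumerate_combinatorial_variants(
    ref: ReferenceSequence,
    scheme: VariablePositionScheme,
    include_wildtype: bool = True,
) -> list[Genotype]:
    """Cartesian product of {reference} ∪ alternatives over the scheme positions.

    Count = Π(1 + |alternatives_i|), including the all-reference combination
    (the wild-type) unless ``include_wildtype`` is False.
    """
    scheme.validate_against(ref)
    per_position: list[list[Mutation | None]] = []
    for pos, alts in scheme.entries:
        r = ref.base_at(pos)
        choices: list[Mutation | None] = [None]
        choices.extend(Mutation(pos, r, a) for a in alts)
        per_position.append(choices)
    out = []
    for combo in itertools.product(*per_position):
        muts = tuple(m for m in combo if m is not None)
        if not muts and not include_wildtype:
            continue
        out.append(Genotype(muts))
    return out


# ---------------------------------------------------------------------------
# Distance and encoding


def hamming_distance(a: Genotype, b: Genotype) -> int:
    """Number of positions at which the two genotypes' sequences differ.

    Both genotypes must live on the same reference; since mutations are
    reference-anchored the distance is computable from the mutation sets alone.
    """
    amap = {m.position: m for m in a.mutations}
    bmap = {m.position: m for m in b.mutations}
    d = 0
    for pos, m in amap.items():
        other = bmap.get(pos)
        if other is None:
            d += 1
        else:
            if other.ref_base != m.ref_base:
                raise ValueError(
                    f"genotypes disagree on the reference base at position {pos}"
                )
            if other.alt_base != m.alt_base:
                d += 1
    d += sum(1 for pos in bmap if pos not in amap)
    return d


def one_hot_encode(g: Genotype, ref: ReferenceSequence) -> np.ndarray:
    """L x 4 one-hot matrix of the genotype's sequence; columns A,C,G,U."""
    seq = g.sequence(ref)
    mat = np.zeros((len(ref), 4), dtype=np.float64)
    for i, base in enumerate(seq):
        mat[i, _BASE_INDEX[base]] = 1.0
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`: recover the sequence string."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[1] != 4:
        raise ValueError("expected an L x 4 matrix")
    if not np.all(mat.sum(axis=1) == 1):
        raise ValueError("each row must sum to exactly 1")
    return "".join(ALPHABET[j] for j in mat.argmax(axis=1))


def flatten_one_hot(mat: np.ndarray) -> np.ndarray:
    """Position-major flat vector of length 4L."""
    return np.asarray(mat).reshape(-1)


def encoding_feature_labels(L: int) -> list[tuple[int, str]]:
    """(position, base) label for each column of the flattened one-hot vector."""
    return [(pos, base) for pos in range(1, L + 1) for base in ALPHABET]


def sequence_to_indices(seq: str) -> np.ndarray:
    """Integer symbol indices (A=0, C=1, G=2, U=3) for the recurrent-model path."""
    return np.array([_BASE_INDEX[b] for b in normalize_bases(seq)], dtype=np.int64)
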