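"""Codon-level machinery: sense-codon enumeration, translation, hit classes.

The substitution models in this package operate on the state space of *sense*
codons (61 states for the universal code; stop codons are excluded from the
chain). Codon pairs are classified by the number of nucleotide positions at
which they differ ("hits": 1H, 2H, 3H) and by whether the exchange is
synonymous. These classifications index the entries of the instantaneous
rate matrix and the event log of the simulator.

The module is table-driven off :mod:`Bio.Data.CodonTable`, so alternate NCBI
translation tables can be added without touching consumers; only the
universal code is exercised by the rest of the package. Ambiguous
nucleotides are *not* resolved here — they become partial states at the
likelihood layer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: Unordered nucleotide pairs indexing the GTR exchangeability parameters.
NUCLEOTIDE_PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

# IUPAC ambiguity codes -> compatible nucleotides (gap characters handled too)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}


class StopCodonError(ValueError):
    """Raised when a stop codon enters a context restricted to sense codons."""


@dataclass(frozen=True)
class HitClass:
    """Classification of an ordered codon pair."""

    n_diff: int
    positions: tuple[int, ...]
    synonymous: bool


@dataclass
class GeneticCode:
    """A translation table restricted to its sense codons.

    Attributes
    ----------
    code_id : str
        Identifier ("universal" maps to NCBI table 1).
    sense_codons : list of str
        The non-stop codons in fixed lexicographic ACGT order; every rate
        matrix, alignment encoding and simulator state index in the package
        refers to this ordering.
    """

    code_id: str = "universal"
    codon_to_aa: dict[str, str] = field(default_factory=dict, repr=False)
    stop_codons: tuple[str, ...] = ()
    sense_codons: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.codon_to_aa:
            ncbi_id = 1 if self.code_id == "universal" else int(self.code_id)
            table = CodonTable.unambiguous_dna_by_id[ncbi_id]
            all_codons = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
            stops = tuple(sorted(table.stop_codons))
            self.stop_codons = stops
            self.codon_to_aa = {
                c: ("*" if c in stops else table.forward_table[c]) for c in all_codons
            }
            self.sense_codons = [c for c in all_codons if c not in stops]
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self._build_pair_tables()

    # -- pair tables ------------------------------------------------------
    def _build_pair_tables(self) -> None:
        n = self.n_sense
        codes = np.array(
            [[NUCLEOTIDES.index(b) for b in codon] for codon in self.sense_codons],
            dtype=np.int8,
        )
        self.codon_nucleotides = codes  # (n, 3) nucleotide indices
        diff = codes[:, None, :] != codes[None, :, :]  # (n, n, 3)
        self.n_diff_matrix = diff.sum(axis=2).astype(np.int8)
        aa = np.array([self.codon_to_aa[c] for c in self.sense_codons])
        self.nonsyn_matrix = aa[:, None] != aa[None, :]

        # exchangeability index per position: which theta pair applies to a
        # change at position p between codons i and j (-1 where unchanged)
        pair_idx = {p: k for k, p in enumerate(NUCLEOTIDE_PAIRS)}
        theta_pos = np.full((n, n, 3), -1, dtype=np.int8)
        for p in range(3):
            a = codes[:, None, p]
            b = codes[None, :, p]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            changed = a != b
            key = np.array(
                [[pair_idx["".join(sorted(NUCLEOTIDES[l] + NUCLEOTIDES[h]))]
                  if l != h else -1 for h in range(4)] for l in range(4)],
                dtype=np.int8,
            )
            theta_pos[:, :, p] = np.where(changed, key[lo, hi], -1)
        self.theta_position_index = theta_pos

    # -- basic queries ----------------------------------------------------
    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def hit_class(self, codon_i: str, codon_j: str) -> HitClass:
        """Classify the ordered pair (codon_i, codon_j).

        Returns the Hamming distance over the three positions, the changed
        positions, and whether the translations agree. Both codons must be
        sense codons of the active code.
        """
        for c in (codon_i, codon_j):
            if c in self.stop_codons:
                raise StopCodonError(f"stop codon {c!r} has no hit class")
            if c not in self.codon_index:
                raise ValueError(f"{c!r} is not an unambiguous sense codon")
        positions = tuple(p for p in range(3) if codon_i[p] != codon_j[p])
        return HitClass(
            n_diff=len(positions),
            positions=positions,
            synonymous=self.codon_to_aa[codon_i] == self.codon_to_aa[codon_j],
        )

    def compatible_sense_indices(self, codon: str) -> np.ndarray:
        """Indicator vector over sense codons compatible with an ambiguous codon."""
        codon = codon.upper()
        try:
            options = [IUPAC[b] for b in codon]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unrecognized nucleotide in codon {codon!r}") from exc
        mask = np.zeros(self.n_sense, dtype=bool)
        for combo in itertools.product(*options):
            idx = self.codon_index.get("".join(combo))
            if idx is not None:
                mask[idx] = True
        return mask


@lru_cache(maxsize=4)
def get_code(code_id: str = "universal") -> GeneticCode:
    """Shared, cached :class:`GeneticCode` instance."""
    return GeneticCode(code_id=code_id)
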