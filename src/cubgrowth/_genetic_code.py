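"""Genetic-code tables and fast nucleotide/codon encodings.

Codons are indexed 0..63 as ``16*A + 4*B + 4*C`` with the base order
A=0, C=1, G=2, T=3.  Synonymous families are the amino-acid families of a
selectable NCBI translation table (default 11, the bacterial/archaeal code);
stop codons and single-codon families (Met, Trp under table 11) carry no
synonymous-choice information and are excluded from family bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"

#: codon string for each index 0..63
CODON_STRINGS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: maps ASCII byte -> base index 0..3, or 255 for anything else (N, gaps, ...)
NT_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    NT_LOOKUP[ord(_b)] = _i
    NT_LOOKUP[ord(_b.lower())] = _i


def codon_index(codon: str) -> int:
    """Index of a 3-letter codon string, or -1 if it contains ambiguous bases."""
    i = 0
    for ch in codon.upper():
        v = NT_LOOKUP[ord(ch)]
        if v > 3:
            return -1
        i = i * 4 + int(v)
    return i


def encode_nucleotides(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 base indices (255 = ambiguous)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return NT_LOOKUP[raw]


def codon_indices(nt: np.ndarray) -> np.ndarray:
    """In-frame codon indices for an encoded sequence; -1 where ambiguous.

    Trailing bases beyond the last full codon are ignored.
    """
    n = (nt.size // 3) * 3
    tri = nt[:n].reshape(-1, 3).astype(np.int64)
    valid = (tri < 4).all(axis=1)
    idx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    idx[~valid] = -1
    return idx


@dataclass(frozen=True)
class GeneticCode:
    """Synonymous-family structure of one translation table."""

    table_id: int
    families: dict[str, tuple[str, ...]]  # amino acid -> codon strings, degeneracy >= 2
    family_of: np.ndarray  # (64,) family ordinal per codon, -1 if none
    family_codon_idx: tuple[np.ndarray, ...]  # per family, sorted codon indices
    degeneracy: np.ndarray  # (n_families,) family sizes r_a
    stop_codon_idx: frozenset[int]
    codon_gc: np.ndarray  # (64,) G+C fraction of each codon

    @property
    def n_families(self) -> int:
        return len(self.family_codon_idx)

    @property
    def family_names(self) -> tuple[str, ...]:
        return tuple(self.families)

    def degenerate_codon_mask(self) -> np.ndarray:
        return self.family_of >= 0


@lru_cache(maxsize=None)
def genetic_code(table_id: int = 11) -> GeneticCode:
    """Build the family structure for an NCBI translation table (cached)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families = {
        aa: tuple(sorted(codons))
        for aa, codons in sorted(by_aa.items())
        if len(codons) >= 2
    }
    family_of = np.full(64, -1, dtype=np.int64)
    fam_idx: list[np.ndarray] = []
    for ordinal, codons in enumerate(families.values()):
        idx = np.array(sorted(codon_index(c) for c in codons), dtype=np.int64)
        fam_idx.append(idx)
        family_of[idx] = ordinal
    degeneracy = np.array([len(i) for i in fam_idx], dtype=np.int64)
    stops = frozenset(codon_index(c) for c in table.stop_codons)
    codon_gc = np.array(
        [sum(ch in "GC" for ch in c) / 3.0 for c in CODON_STRINGS], dtype=float
    )
    return GeneticCode(
        table_id=table_id,
        families=families,
        family_of=family_of,
        family_codon_idx=tuple(fam_idx),
        degeneracy=degeneracy,
        stop_codon_idx=stops,
        codon_gc=codon_gc,
    )
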