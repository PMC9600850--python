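"""Codon counting, GC content, MILC codon usage bias, shuffled-null
backgrounds, the consistency statistic Ψ, and gene filters.

MILC (Measure Independent of Length and Composition) compares a gene's
within-family synonymous codon frequencies ``f`` to a background expectation
``g``::

    M_a  = 2 * sum_c o_{a,c} * ln(f_{a,c} / g_{a,c})
    MILC = (sum_a M_a) / L  -  C,   C = (sum_a (r_a - 1)) / L  -  0.5

where ``o_{a,c}`` are observed codon counts, ``r_a`` the degeneracy of
amino-acid family ``a``, and ``L`` the number of counted codons in degenerate
families.  The sums run over families represented in the gene; terms with
``o_{a,c} = 0`` contribute zero.  Highly expressed (HE) genes — operationally
the ribosomal proteins — with strong bias relative to the rest of a genome or
metagenome are the signature of fast maximal growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._genetic_code import (
    CODON_STRINGS,
    GeneticCode,
    codon_indices,
    encode_nucleotides,
    genetic_code,
)

__all__ = [
    "CubgrowthWarning",
    "GeneRecord",
    "CodonCountTable",
    "BackgroundFrequencies",
    "clean_sequence",
    "count_codons",
    "gene_counts",
    "gc_content",
    "background_from_counts",
    "pooled_counts",
    "milc",
    "milc_values",
    "self_shuffle_background",
    "weighted_median",
    "cub_he",
    "icub_mean",
    "sample_background_genes",
    "psi",
    "filter_genes",
    "drop_high_ambiguity_genes",
]


class CubgrowthWarning(UserWarning):
    """Warnings raised by the analysis pipeline (also embedded in outputs)."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class GeneRecord:
    """One coding sequence with its HE designation and abundance weight."""

    id: str
    sequence: str
    is_highly_expressed: bool = False
    weight: float = 1.0
    description: str = ""
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"gene {self.id!r}: weight must be >= 0")
        self.sequence = self.sequence.upper()

    @property
    def length_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass
class CodonCountTable:
    """Observed codon counts (length-64 vector indexed like CODON_STRINGS)."""

    counts: np.ndarray
    skipped: int = 0

    @property
    def total_codons(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {
            CODON_STRINGS[i]: int(c) for i, c in enumerate(self.counts) if c > 0
        }


@dataclass
class BackgroundFrequencies:
    """Expected synonymous-codon frequencies per amino-acid family.

    ``freqs`` is a length-64 vector normalized within each represented family
    (zeros elsewhere).  ``counts`` retains the underlying codon counts when the
    background was built from counts; they are needed for the pseudocount rule
    that keeps MILC finite when a background frequency is zero at a codon the
    gene uses.
    """

    freqs: np.ndarray
    source: str
    counts: np.ndarray | None = None
    code: GeneticCode = field(default_factory=genetic_code)

    def family_freqs(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for aa, idx in zip(self.code.family_names, self.code.family_codon_idx):
            sub = self.freqs[idx]
            if sub.sum() > 0:
                out[aa] = {
                    CODON_STRINGS[i]: float(f) for i, f in zip(idx, sub)
                }
        return out


# --------------------------------------------------------------------------
# sequence handling


def clean_sequence(sequence: str, code: GeneticCode | None = None,
                   gene_id: str = "?") -> str:
    """Apply the trimming policy: upper-case, drop trailing bases beyond the
    last full codon (with a warning), drop a terminal stop codon if present."""
    code = code or genetic_code()
    seq = sequence.upper()
    extra = len(seq) % 3
    if extra:
        warnings.warn(
            f"gene {gene_id!r}: length {len(seq)} not divisible by 3; "
            f"dropping {extra} trailing base(s)",
            CubgrowthWarning,
            stacklevel=2,
        )
        seq = seq[: len(seq) - extra]
    if len(seq) >= 3:
        from ._genetic_code import codon_index

        if codon_index(seq[-3:]) in code.stop_codon_idx:
            seq = seq[:-3]
    return seq


def count_codons(sequence: str) -> CodonCountTable:
    """Count in-frame codons; codons containing non-ACGT symbols are skipped
    and the skip count reported."""
    if len(sequence) < 3:
        raise ValueError(
            f"sequence of length {len(sequence)} is too short to contain a codon"
        )
    idx = codon_indices(encode_nucleotides(sequence))
    valid = idx >= 0
    counts = np.bincount(idx[valid], minlength=64).astype(np.int64)
    return CodonCountTable(counts=counts, skipped=int((~valid).sum()))


def gene_counts(gene: GeneRecord) -> CodonCountTable:
    """Codon counts of a gene, cached on the record (sequences are treated as
    immutable once constructed)."""
    cached = getattr(gene, "_counts", None)
    if cached is None:
        cached = count_codons(gene.sequence)
        gene._counts = cached
    return cached


def gc_content(genes: list[GeneRecord], weighted: bool = False) -> float:
    """Fraction of G+C among unambiguous nucleotides across genes.

    When ``weighted``, each gene's nucleotides contribute proportional to its
    abundance weight.
    """
    if not genes:
        raise ValueError("gc_content requires at least one gene")
    num = 0.0
    den = 0.0
    for g in genes:
        nt = encode_nucleotides(g.sequence)
        valid = nt < 4
        w = g.weight if weighted else 1.0
        num += w * float(((nt == 1) | (nt == 2)).sum())
        den += w * float(valid.sum())
    if den == 0:
        raise ValueError("no unambiguous nucleotides in input genes")
    return num / den


# --------------------------------------------------------------------------
# backgrounds


def background_from_counts(
    counts: CodonCountTable | np.ndarray,
    source: str = "sample-wide",
    code: GeneticCode | None = None,
) -> BackgroundFrequencies:
    """Within-family frequencies o_{a,c} / sum_c o_{a,c}; empty families omitted."""
    code = code or genetic_code()
    raw = counts.counts if isinstance(counts, CodonCountTable) else counts
    raw = np.asarray(raw, dtype=np.int64)
    freqs = np.zeros(64, dtype=float)
    for idx in code.family_codon_idx:
        tot = raw[idx].sum()
        if tot > 0:
            freqs[idx] = raw[idx] / tot
    return BackgroundFrequencies(freqs=freqs, source=source, counts=raw, code=code)


def pooled_counts(genes: list[GeneRecord]) -> CodonCountTable:
    """Pooled codon counts of a gene set (the sample-wide background counts)."""
    total = np.zeros(64, dtype=np.int64)
    skipped = 0
    for g in genes:
        t = gene_counts(g)
        total += t.counts
        skipped += t.skipped
    return CodonCountTable(counts=total, skipped=skipped)


def self_shuffle_background(
    gene: GeneRecord,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
) -> BackgroundFrequencies:
    """Per-gene null background from nucleotide permutations of the gene.

    Codon counts are pooled over ``n_shuffles`` uniform permutations of the
    gene's nucleotide sequence (controlling for nucleotide composition) and
    converted to within-family frequencies.  Deterministic given the seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    nt = encode_nucleotides(gene.sequence)
    n = (nt.size // 3) * 3
    if n < 3:
        raise ValueError(f"gene {gene.id!r} too short to shuffle")
    tiled = np.tile(nt, (n_shuffles, 1))
    rng.permuted(tiled, axis=1, out=tiled)
    tri = tiled[:, :n].reshape(-1, 3).astype(np.int64)
    idx = tri[:, 0] * 16 + tri[:, 1] * 4 + tri[:, 2]
    if nt.max() > 3:  # ambiguous bases: drop codons containing them
        idx = idx[(tri < 4).all(axis=1)]
    counts = np.bincount(idx, minlength=64).astype(np.int64)
    return background_from_counts(counts, source="self-shuffle")


# --------------------------------------------------------------------------
# MILC


def milc(
    gene_counts: CodonCountTable,
    background: BackgroundFrequencies,
    code: GeneticCode | None = None,
) -> float:
    """MILC codon usage bias of one gene against a background expectation."""
    code = code or background.code or genetic_code()
    o = gene_counts.counts
    fam_of = code.family_of
    used = (fam_of >= 0) & (o > 0)
    if not used.any():
        raise ValueError("no informative codons (only single-codon families)")
    g_used = background.freqs[used]
    if np.all(g_used > 0):
        # vectorized fast path (no pseudocounts needed)
        fams = fam_of[used]
        fam_sums = np.bincount(fams, weights=o[used], minlength=code.n_families)
        present = fam_sums > 0
        length = int(fam_sums.sum())
        corr = int((code.degeneracy[present] - 1).sum())
        f = o[used] / fam_sums[fams]
        m_sum = 2.0 * float(np.sum(o[used] * np.log(f / g_used)))
        return m_sum / length - (corr / length - 0.5)
    return _milc_slow(o, background, code)


def _milc_slow(
    o: np.ndarray, background: BackgroundFrequencies, code: GeneticCode
) -> float:
    """Family-by-family evaluation, handling zero background frequencies via
    the pseudocount rule."""
    m_sum = 0.0
    length = 0
    corr = 0
    for fam, idx in enumerate(code.family_codon_idx):
        fam_o = o[idx]
        n_a = int(fam_o.sum())
        if n_a == 0:
            continue
        g = background.freqs[idx].astype(float)
        if np.any((g == 0) & (fam_o > 0)):
            # small backgrounds can miss a codon the gene uses; one pseudocount
            # per family codon keeps the log finite
            if background.counts is None:
                raise ValueError(
                    "background lacks codon counts; cannot apply the "
                    "pseudocount rule for a zero background frequency"
                )
            warnings.warn(
                "zero background frequency at an observed codon; applying a "
                "+1 pseudocount to the family",
                CubgrowthWarning,
                stacklevel=2,
            )
            raw = background.counts[idx].astype(float) + 1.0
            g = raw / raw.sum()
        f = fam_o / n_a
        nz = fam_o > 0
        m_sum += 2.0 * float(np.sum(fam_o[nz] * np.log(f[nz] / g[nz])))
        length += n_a
        corr += int(code.degeneracy[fam]) - 1
    if length == 0:
        raise ValueError("no informative codons (only single-codon families)")
    c = corr / length - 0.5
    return m_sum / length - c


def milc_values(
    genes: list[GeneRecord],
    background: BackgroundFrequencies,
    code: GeneticCode | None = None,
) -> np.ndarray:
    return np.array([milc(gene_counts(g), background, code) for g in genes])


# --------------------------------------------------------------------------
# aggregation


def weighted_median(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted median: smallest value whose cumulative normalized weight
    reaches 0.5; when it lands exactly on 0.5 the straddling pair is averaged
    (reducing to the plain median at equal weights)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty values")
    if weights is None:
        weights = np.ones_like(values)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cum = np.cumsum(weights[order]) / weights.sum()
    i = int(np.searchsorted(cum, 0.5 - 1e-12))
    if np.isclose(cum[i], 0.5, rtol=0.0, atol=1e-9) and i + 1 < v.size:
        return float(0.5 * (v[i] + v[i + 1]))
    return float(v[i])


def cub_he(
    genes: list[GeneRecord],
    background: BackgroundFrequencies,
    aggregate: str = "median",
    code: GeneticCode | None = None,
) -> float:
    """(Weighted) median MILC of the HE genes against the sample-wide
    background — the CUB̄_HE predictor."""
    he = [g for g in genes if g.is_highly_expressed]
    if not he:
        raise ValueError("no highly expressed genes available for CUB_HE")
    if len(he) < 10:
        warnings.warn(
            f"only {len(he)} highly expressed genes (<10); the CUB_HE estimate "
            "may be unstable",
            CubgrowthWarning,
            stacklevel=2,
        )
    vals = milc_values(he, background, code)
    if aggregate == "median":
        w = np.ones(len(he))
    elif aggregate == "weighted-median":
        w = np.array([g.weight for g in he], dtype=float)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return weighted_median(vals, w)


def icub_mean(
    genes: list[GeneRecord],
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    weighted: bool = False,
    code: GeneticCode | None = None,
) -> float:
    """(Weighted) mean MILC of genes against their own shuffled-null
    backgrounds — the iCUB̄ quantity of the bias-corrected model."""
    if not genes:
        raise ValueError("icub_mean requires at least one gene")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    vals = np.empty(len(genes))
    for i, g in enumerate(genes):
        bg = self_shuffle_background(g, n_shuffles=n_shuffles, seed=rng)
        vals[i] = milc(gene_counts(g), bg, code)
    w = (
        np.array([g.weight for g in genes], dtype=float)
        if weighted
        else np.ones(len(genes))
    )
    return float(np.average(vals, weights=w))


def sample_background_genes(
    genes: list[GeneRecord],
    k: int = 100,
    seed: int | np.random.Generator = 0,
    weights: np.ndarray | None = None,
) -> list[GeneRecord]:
    """Sample up to ``k`` background (non-HE) genes without replacement.

    ``weights`` gives inclusion probabilities proportional to abundance; None
    means uniform.  All genes are returned when fewer than ``k`` are available.
    """
    if not genes:
        raise ValueError("empty background gene set")
    if any(g.is_highly_expressed for g in genes):
        raise ValueError("background sample input must exclude HE genes")
    if len(genes) <= k:
        return list(genes)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if weights is None:
        p = np.full(len(genes), 1.0 / len(genes))
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            p = np.full(len(genes), 1.0 / len(genes))
        else:
            p = weights / weights.sum()
    idx = rng.choice(len(genes), size=k, replace=False, p=p)
    return [genes[i] for i in idx]


def psi(
    genes_he: list[GeneRecord], code: GeneticCode | None = None
) -> float:
    """Consistency statistic Ψ: mean MILC of the HE genes against the pooled
    HE-gene background.  Larger Ψ means the HE genes (ribosomal proteins) have
    more dissimilar codon usages — i.e. the sample mixes organisms with
    different codon preferences."""
    if len(genes_he) < 2:
        raise ValueError("psi requires at least 2 highly expressed genes")
    bg = background_from_counts(pooled_counts(genes_he), source="he-pool", code=code)
    return float(np.mean(milc_values(genes_he, bg, code)))


# --------------------------------------------------------------------------
# filters


def filter_genes(genes: list[GeneRecord], min_codons: int = 80) -> list[GeneRecord]:
    """Retain genes at least ``min_codons`` codons long (80 by default, 40 in
    fragment mode)."""
    kept = [g for g in genes if g.length_codons >= min_codons]
    if not kept:
        raise ValueError(
            f"no genes remain after the {min_codons}-codon length filter"
        )
    return kept


def drop_high_ambiguity_genes(
    genes: list[GeneRecord], max_skipped_fraction: float = 0.10
) -> list[GeneRecord]:
    """Drop genes whose skipped (ambiguous) codon fraction exceeds the cap."""
    kept: list[GeneRecord] = []
    for g in genes:
        t = gene_counts(g)
        total = t.total_codons + t.skipped
        if total and t.skipped / total > max_skipped_fraction:
            warnings.warn(
                f"gene {g.id!r}: {t.skipped}/{total} codons ambiguous; dropped",
                CubgrowthWarning,
                stacklevel=2,
            )
        else:
            kept.append(g)
    if not kept:
        raise ValueError("all genes dropped by the ambiguity filter")
    return kept
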