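"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain Python dict/loop arithmetic and a
hand-transcribed synonymous family table (bacterial translation table),
deliberately sharing no code with the package implementation.
"""

import math

# synonymous families of NCBI translation table 11 (degeneracy >= 2);
# Met (ATG) and Trp (TGG) and the stop codons are excluded
FAMILIES = {
    "Ala": ["GCT", "GCC", "GCA", "GCG"],
    "Arg": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "Asn": ["AAT", "AAC"],
    "Asp": ["GAT", "GAC"],
    "Cys": ["TGT", "TGC"],
    "Gln": ["CAA", "CAG"],
    "Glu": ["GAA", "GAG"],
    "Gly": ["GGT", "GGC", "GGA", "GGG"],
    "His": ["CAT", "CAC"],
    "Ile": ["ATT", "ATC", "ATA"],
    "Leu": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "Lys": ["AAA", "AAG"],
    "Phe": ["TTT", "TTC"],
    "Pro": ["CCT", "CCC", "CCA", "CCG"],
    "Ser": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "Thr": ["ACT", "ACC", "ACA", "ACG"],
    "Tyr": ["TAT", "TAC"],
    "Val": ["GTT", "GTC", "GTA", "GTG"],
}

ALL_FAMILY_CODONS = [c for fam in FAMILIES.values() for c in fam]


def count_codons_brute(sequence):
    """Count unambiguous in-frame codons of a nucleotide string."""
    counts = {}
    skipped = 0
    for i in range(0, len(sequence) - len(sequence) % 3, 3):
        codon = sequence[i : i + 3].upper()
        if set(codon) <= set("ACGT"):
            counts[codon] = counts.get(codon, 0) + 1
        else:
            skipped += 1
    return counts, skipped


def milc_brute(sequence, background):
    """MILC of a gene against a {codon: frequency} background, from scratch.

    M_a = 2 sum_c o_c ln(f_c / g_c); MILC = sum_a M_a / L - C with
    C = sum_a (r_a - 1) / L - 0.5, over families represented in the gene.
    """
    counts, _ = count_codons_brute(sequence)
    m_total = 0.0
    length = 0
    corr = 0
    for codons in FAMILIES.values():
        obs = {c: counts.get(c, 0) for c in codons}
        n = sum(obs.values())
        if n == 0:
            continue
        for c in codons:
            if obs[c] > 0:
                m_total += 2.0 * obs[c] * math.log((obs[c] / n) / background[c])
        length += n
        corr += len(codons) - 1
    if length == 0:
        raise ValueError("no degenerate-family codons")
    c_term = corr / length - 0.5
    return m_total / length - c_term


def gc_brute(sequences_weights):
    """Weighted GC content over (sequence, weight) pairs."""
    num = den = 0.0
    for seq, w in sequences_weights:
        for ch in seq.upper():
            if ch in "ACGT":
                den += w
                if ch in "GC":
                    num += w
    return num / den


def weighted_median_brute(values, weights):
    """Cumulative-weight median; averages the straddling pair at exactly 0.5."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for i, (v, w) in enumerate(pairs):
        cum += w / total
        if cum > 0.5 + 1e-12:
            return v
        if abs(cum - 0.5) <= 1e-12:
            return 0.5 * (v + pairs[i + 1][0])
    return pairs[-1][0]
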