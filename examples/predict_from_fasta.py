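"""Predict a community's maximal growth rate from a CDS FASTA.

Builds a small synthetic metagenome (10 genomes, lognormal abundances),
writes it to FASTA + coverage TSV, then runs the prediction pipeline the way
a user would on real called genes: read the FASTA, flag ribosomal proteins
by header, attach coverage weights, and predict with the Ψ-switching model.
"""

import tempfile
from pathlib import Path

import cubgrowth as cg

tmp = Path(tempfile.mkdtemp())
pool = cg.synthesize_pool(n_genomes=15, n_clusters=1, gc_range=(0.45, 0.55), seed=7)
spec, genes = cg.simulate_community(pool, n=10, seed=8)

fasta = tmp / "community.fasta"
cg.write_cds_fasta(genes, fasta)
coverage = tmp / "coverage.tsv"
coverage.write_text(
    "gene_id\tcoverage\n"
    + "".join(f"{g.id}\t{g.weight:.6g}\n" for g in genes)
)

loaded = cg.read_cds_fasta(fasta)
cg.designate_he_genes(loaded)  # "ribosomal protein" header match
cg.apply_coverage(loaded, cg.read_coverage_tsv(coverage))

models = cg.load_default_models()
pred = cg.predict_community(
    loaded, models, cg.SampleOptions(mode="mmv2", weighted=True, seed=0)
)

print(f"predicted community doubling time: {pred.doubling_time:.2f} h")
print(f"model branch used: {pred.mode_used}  (psi = {pred.psi:.3f})")
print(f"CUB_HE = {pred.features.cub_he:.3f}, GC = {pred.features.gc:.3f}")
# The doubling time is the abundance-weighted average minimal doubling time
# of the community; psi < 0.6 means members share codon preferences, so the
# whole-sample-background branch (mmv1) was used.
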