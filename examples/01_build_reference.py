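"""Build an extended mature-tRNA reference from a toy gene.

The mapping database for tsRNA discovery extends each mature tRNA with the
post-transcriptional CCA and 50 genomic nucleotides of 3' trailer, so that
fragments of the primary transcript (tRF-1) are mappable alongside
fragments of the mature molecule.
"""

from tsrnakit import build_mature_reference, make_trna_gene

gene = make_trna_gene(seed=1, isotype="Thr", anticodon="TGT", with_intron=True)
ref = build_mature_reference(gene)

print(f"gene {gene.gene_id}: {len(gene.exons)} exons, intron {gene.intron}")
print(f"mature body      : {len(ref.mature_seq)} nt")
print(f"mature + CCA     : {len(ref.mature_cca_seq)} nt")
print(f"extended         : {len(ref.extended_seq)} nt "
      f"(= mature + 3 + 50; trailer starts at {ref.trailer_start})")
print(f"anticodon (33-36): {ref.mature_seq[33:36]}")
# The extended length always exceeds the mature body by exactly 53 nt:
# 3 nt of appended CCA plus the 50-nt genomic trailer.
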