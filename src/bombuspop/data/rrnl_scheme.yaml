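# In-silico haplotyping scheme for the short mitochondrial rrnL amplicon.
# The primer pair and product length are as used for degraded (pinned)
# material; the diagnostic rules below are illustrative placeholders --
# real surveys should substitute their validated SNP positions and/or
# restriction recognition sites here.
marker_name: rrnL
primer_fwd: TCAACATCGAGGTCGCAATCA
primer_rev: TGGCTGCGGTATAATTGACTGT
expected_amplicon_length: 388
diagnostic_rules:
  - kind: snp
    position: 120
    bases:
      A: H1_iberian
      G: H2_central_european
  - kind: restriction
    site: GAATTC
    present: H2_central_european
    absent: H1_iberian
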