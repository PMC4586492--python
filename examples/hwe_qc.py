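"""Additive genotype coding and Hardy-Weinberg QC on a small sample.

Allele-pair strings are converted to minor-allele counts (0/1/2), and each
SNP's genotype distribution is tested against Hardy-Weinberg proportions
with the exact (conditional-on-allele-counts) test.
"""

import snpmediate as sm

labels = ["AA"] * 49 + ["AC"] * 42 + ["CC"] * 9
codes = sm.encode_genotypes(labels, minor_allele="C")
print(f"coded {len(codes)} genotypes; first five: {codes[:5].tolist()}")

qc = sm.snp_qc(codes, label="rs_example")
print(f"counts AA/AC/CC = {qc['n_major_hom']}/{qc['n_het']}/{qc['n_minor_hom']}")
print(f"minor allele frequency = {qc['maf']:.3f}")
print(f"HWE exact p = {qc['hwe_p']:.4f}  (flagged: {qc['hwe_flag']})")
# A non-significant p (> 0.05) means the genotype frequencies are consistent
# with random mating; a flag would warn of genotyping artefacts or structure.
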