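"""Allele harmonization on a tiny hand-built pair of tables.

Shows the four situations harmonization must handle: aligned alleles,
swapped alleles (sign flip), a strand flip, and a palindromic SNP whose
near-0.5 allele frequency makes its orientation unresolvable.
"""

from mrkit import GwasSummaryTable, VariantAssociation, harmonize


def v(snp, ea, oa, beta, eaf):
    return VariantAssociation(snp_id=snp, effect_allele=ea, other_allele=oa,
                              beta=beta, se=0.02, pval=1e-10, n=50_000,
                              eaf=eaf)


exposure = GwasSummaryTable("exposure", (
    v("rs1", "A", "G", 0.10, 0.30),
    v("rs2", "C", "T", 0.12, 0.25),
    v("rs3", "A", "G", 0.09, 0.40),
    v("rs4", "A", "T", 0.11, 0.50),   # palindromic, eaf exactly 0.5
))
outcome = GwasSummaryTable("outcome", (
    v("rs1", "A", "G", 0.010, 0.30),  # aligned: kept as is
    v("rs2", "T", "C", 0.012, 0.75),  # swapped: beta negated, eaf -> 1-eaf
    v("rs3", "T", "C", 0.008, 0.40),  # opposite strand: kept as is
    v("rs4", "A", "T", 0.011, 0.50),  # ambiguous palindrome: dropped
))

instruments, log = harmonize(exposure, outcome)
print(log.to_frame().to_string(index=False))
print()
for inst in instruments:
    print(f"{inst.snp_id}: beta_out = {inst.beta_out:+.3f} on effect "
          f"allele {inst.effect_allele} (eaf_out = {inst.eaf_out:.2f})")
print("\nrs2's outcome effect changed sign because its effect allele was "
      "the exposure's other allele; rs4 was dropped because an A/T SNP at "
      "eaf 0.5 cannot be oriented.")
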