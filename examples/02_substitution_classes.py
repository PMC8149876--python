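"""Classify wrong-species peptides as isobaric vs non-isobaric.

Wrong-species collagen peptides usually differ from the true species' peptide
by one amino acid. Isobaric variants (I/L swaps, hydroxyproline-compensated
pairs, local inversions) are mass-identical alternative interpretations of
the same spectrum; non-isobaric variants are mass-changing substitutions
graded by how many nucleotide changes would be needed to encode them.
"""

from osteoproba import substitution

cases = [
    ("GPLGK", "GPIGK"),        # isoleucine <-> leucine
    ("GP[OH]AGK", "GPSGK"),    # hydroxyproline + Ala <-> Pro + Ser
    ("APGSK", "ASGPK"),        # near-adjacent inversion
    ("GPAGK", "GPSGK"),        # Ala -> Ser, one nucleotide
    ("GWAGK", "GFSGK"),        # two substitutions, three nucleotides
]

print(f"{'peptide':12}{'reference':12}{'class':14}{'AA':>3}{'nt':>4}  mechanisms")
for pep, ref in cases:
    c = substitution.classify(pep, ref)
    nt = "-" if c.min_nt_changes is None else c.min_nt_changes
    print(f"{pep:12}{ref:12}{c.klass:14}{c.n_aa_changes:3}{nt!s:>4}  "
          f"{','.join(sorted(c.mechanisms)) or '-'}")

# Isobaric calls carry an identifiable mechanism and zero mass difference;
# non-isobaric calls report the minimal codon-level edit distance, the
# biological plausibility scale for a true polymorphism.
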