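# Default metabolite-class vocabulary for a Quant-500-style targeted panel:
# 14 small-molecule classes and 9 lipid classes (after the vendor-side merge
# of lyso-/phosphatidylcholines into glycerophospholipids and of hexosyl-,
# dihexosyl- and trihexosylceramides into glycosylceramides).
#
# Counts sum to 630. The triacylglycerol (242) and glycerophospholipid (90)
# counts are the panel's published composition; the remaining counts are
# representative defaults and can be overridden by a user-supplied file of
# the same shape.
small_molecule_classes:
  Alkaloids: 1
  Amine Oxides: 1
  Amino Acids: 20
  Amino Acid Related: 30
  Bile Acids: 14
  Biogenic Amines: 9
  Carbohydrates: 1
  Carboxylic Acids: 7
  Cresols: 1
  Fatty Acids: 12
  Hormones: 4
  Indole Derivatives: 4
  Nucleobases Related: 2
  Vitamins & Cofactors: 1
lipid_classes:
  Acylcarnitines: 40
  Ceramides: 28
  Cholesteryl Esters: 22
  Diacylglycerols: 44
  Dihydroceramides: 8
  Glycerophospholipids: 90
  Glycosylceramides: 34
  Sphingomyelins: 15
  Triacylglycerols: 242
class_merge:
  Lysophosphatidylcholines: Glycerophospholipids
  Phosphatidylcholines: Glycerophospholipids
  Hexosylceramides: Glycosylceramides
  Dihexosylceramides: Glycosylceramides
  Trihexosylceramides: Glycosylceramides
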