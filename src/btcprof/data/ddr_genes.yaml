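# DNA-damage-repair gene -> pathway map: TP53 plus eight functional families,
# 47 genes in total.  The main-text-named genes (TP53, ATM, ATR, BRCA1/2,
# PRKDC, POLE, POLD1, DDR2, MUTYH, MSH/MLH family) are fixed; the remaining
# members are NON-CANONICAL placeholders chosen from standard DDR gene lists
# and should be reconciled against a curated source before use on real data.
# Edit freely: classification code only requires that every gene map to
# exactly one pathway and that the total is 47.
TP53: TP53
# checkpoint factors (CPF)
ATM: checkpoint_factors
ATR: checkpoint_factors
CHEK1: checkpoint_factors
CHEK2: checkpoint_factors
MDC1: checkpoint_factors
RAD50: checkpoint_factors
MRE11: checkpoint_factors
NBN: checkpoint_factors
# Fanconi anemia (FA)
FANCA: fanconi_anemia
FANCC: fanconi_anemia
FANCD2: fanconi_anemia
FANCE: fanconi_anemia
FANCF: fanconi_anemia
FANCG: fanconi_anemia
FANCI: fanconi_anemia
FANCL: fanconi_anemia
PALB2: fanconi_anemia
# mismatch repair (MMR)
MLH1: mismatch_repair
MSH2: mismatch_repair
MSH6: mismatch_repair
PMS2: mismatch_repair
# homologous recombination (HR)
BRCA1: homologous_recombination
BRCA2: homologous_recombination
RAD51: homologous_recombination
RAD51B: homologous_recombination
RAD51C: homologous_recombination
RAD51D: homologous_recombination
BARD1: homologous_recombination
BRIP1: homologous_recombination
# nucleotide excision repair (NER)
ERCC1: nucleotide_excision_repair
ERCC2: nucleotide_excision_repair
ERCC3: nucleotide_excision_repair
ERCC4: nucleotide_excision_repair
ERCC5: nucleotide_excision_repair
XPA: nucleotide_excision_repair
XPC: nucleotide_excision_repair
# base excision repair (BER)
MUTYH: base_excision_repair
OGG1: base_excision_repair
PARP1: base_excision_repair
# non-homologous end joining (NHEJ)
PRKDC: non_homologous_end_joining
XRCC4: non_homologous_end_joining
XRCC5: non_homologous_end_joining
LIG4: non_homologous_end_joining
# other DDR factors
POLE: other_ddr
POLD1: other_ddr
DDR2: other_ddr
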