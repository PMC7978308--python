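# Potentially-actionable-target (PAT) knowledge base: one entry per
# (target, alteration_class).  A target is a PAT when its best evidence is
# OncoKB level <= 3A or ESCAT tier <= II-B.  The default base lists 19 PAT
# genes plus the MSI-H biomarker; genes not named in a curated source are
# NON-CANONICAL placeholders drawn from pan-cancer actionability practice and
# should be reconciled against OncoKB / ESCAT before use on real data.
#
# oncokb_level: L1 | L2 | L3A | L3B | L4 | none
# escat_tier:   IA | IB | IC | IIA | IIB | IIIA | IIIB | IV | V | none
# printed_label: free-text label as quoted in older nomenclature, if any.
# allowed_loci: optional 1-based genomic position window {chrom, min_pos, max_pos}.
tier_order: [IA, L1, IB, IC, L2, IIA, IIB, L3A, L3B, IIIA, IIIB, L4, IV, V]
entries:
  - target: MSI-H
    alteration_class: msi_high
    oncokb_level: L1
    escat_tier: IC
    drug_hint: pembrolizumab
  - target: ERBB2
    alteration_class: amplification
    oncokb_level: L2
    printed_label: level-2B
    escat_tier: IIB
    drug_hint: trastuzumab+pertuzumab
  - target: MET
    alteration_class: amplification
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: cabozantinib
  - target: MET
    alteration_class: activating_mutation
    oncokb_level: L3A
    escat_tier: none
    drug_hint: cabozantinib
  - target: CDK4
    alteration_class: amplification
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: palbociclib
  - target: EGFR
    alteration_class: activating_mutation
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: afatinib (requires EGFR IHC 2+/3+)
    # exons 18-21 window (GRCh37 EGFR); the alternative exon 17-20 window is
    # chr7:55240676-55260002 — swap in via config if preferred.
    allowed_loci: {chrom: "7", min_pos: 55241614, max_pos: 55279321}
  - target: FGFR2
    alteration_class: fusion
    oncokb_level: L1
    escat_tier: IB
    drug_hint: pemigatinib
  - target: FGFR3
    alteration_class: fusion
    oncokb_level: L2
    escat_tier: IIB
    drug_hint: erdafitinib
  - target: NTRK1
    alteration_class: fusion
    oncokb_level: L1
    escat_tier: IC
    drug_hint: larotrectinib
  - target: NTRK2
    alteration_class: fusion
    oncokb_level: L1
    escat_tier: IC
    drug_hint: larotrectinib
  - target: NTRK3
    alteration_class: fusion
    oncokb_level: L1
    escat_tier: IC
    drug_hint: larotrectinib
  - target: IDH1
    alteration_class: activating_mutation
    oncokb_level: L1
    escat_tier: IB
    drug_hint: ivosidenib
  - target: BRCA1
    alteration_class: truncating_mutation
    oncokb_level: L3A
    escat_tier: IIA
    drug_hint: olaparib
  - target: BRCA2
    alteration_class: truncating_mutation
    oncokb_level: L3A
    escat_tier: IIA
    drug_hint: olaparib
  - target: BRAF
    alteration_class: activating_mutation
    oncokb_level: L2
    escat_tier: IIB
    drug_hint: dabrafenib+trametinib
  - target: PIK3CA
    alteration_class: activating_mutation
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: alpelisib
  - target: ALK
    alteration_class: fusion
    oncokb_level: L2
    escat_tier: IIB
    drug_hint: alectinib
  - target: RET
    alteration_class: fusion
    oncokb_level: L2
    escat_tier: IIB
    drug_hint: selpercatinib
  - target: ROS1
    alteration_class: fusion
    oncokb_level: L2
    escat_tier: IIB
    drug_hint: crizotinib
  - target: ATM
    alteration_class: truncating_mutation
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: olaparib
  - target: PALB2
    alteration_class: truncating_mutation
    oncokb_level: L3A
    escat_tier: IIB
    drug_hint: olaparib
  # off-PAT evidence (emitted with is_pat=false, surfaced only on request)
  - target: KRAS
    alteration_class: activating_mutation
    oncokb_level: L3B
    escat_tier: IIIA
    drug_hint: adagrasib (off-label)
  - target: CDKN2A
    alteration_class: deletion
    oncokb_level: none
    escat_tier: IIIA
    drug_hint: abemaciclib (off-label)
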