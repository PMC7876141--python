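# Cancer pathway gene lists with per-gene roles used by the alteration
# tabulation.  Roles decide which SSV/mutation rules apply: oncogenes
# require hotspot SNVs and upstream/1Mb breakpoints with overexpression;
# tumor suppressors accept inactivating mutations and gene-body
# breakpoints with underexpression.  Edit or supply your own file to
# override.  The NRF2 pathway ships disabled by default.
pathways:
  - name: RTK
    genes:
      BRAF: oncogene
      EGFR: oncogene
      ERBB2: oncogene
      ERBB3: oncogene
      ERBB4: oncogene
      FGFR1: oncogene
      FGFR2: oncogene
      FGFR3: oncogene
      FGFR4: oncogene
      HRAS: oncogene
      KIT: oncogene
      KRAS: oncogene
      MET: oncogene
      NF1: tumor_suppressor
      NRAS: oncogene
  - name: HIPPO
    genes:
      NF2: tumor_suppressor
      SAV1: tumor_suppressor
      WWC1: tumor_suppressor
  - name: chromatin_modification
    genes:
      CREBBP: tumor_suppressor
      EHMT1: tumor_suppressor
      EHMT2: tumor_suppressor
      EP300: tumor_suppressor
      EZH1: oncogene
      EZH2: oncogene
      KAT2A: tumor_suppressor
      KAT2B: tumor_suppressor
      KDM1A: oncogene
      KDM1B: oncogene
      KDM4A: oncogene
      KDM4B: oncogene
      KDM5A: oncogene
      KDM5B: oncogene
      KDM5C: tumor_suppressor
      KDM6A: tumor_suppressor
      KDM6B: tumor_suppressor
      KMT2A: tumor_suppressor
      KMT2B: tumor_suppressor
      KMT2C: tumor_suppressor
      KMT2D: tumor_suppressor
      KMT2E: tumor_suppressor
      NSD1: tumor_suppressor
      SETD2: tumor_suppressor
      SMYD4: tumor_suppressor
      SRCAP: tumor_suppressor
  - name: SWI_SNF
    genes:
      ACTB: tumor_suppressor
      ACTL6A: tumor_suppressor
      ACTL6B: tumor_suppressor
      ARID1A: tumor_suppressor
      ARID1B: tumor_suppressor
      ARID2: tumor_suppressor
      BCL11A: tumor_suppressor
      BCL11B: tumor_suppressor
      BCL6: oncogene
      BCL6B: tumor_suppressor
      BRD7: tumor_suppressor
      BRD9: tumor_suppressor
      DPF1: tumor_suppressor
      DPF2: tumor_suppressor
      DPF3: tumor_suppressor
      PBRM1: tumor_suppressor
      PHF10: tumor_suppressor
      SMARCA2: tumor_suppressor
      SMARCA4: tumor_suppressor
      SMARCB1: tumor_suppressor
      SMARCC1: tumor_suppressor
      SMARCC2: tumor_suppressor
      SMARCD1: tumor_suppressor
      SMARCD2: tumor_suppressor
      SMARCD3: tumor_suppressor
      SMARCE1: tumor_suppressor
  - name: PI3K_AKT_mTOR
    genes:
      AKT1: oncogene
      AKT2: oncogene
      AKT3: oncogene
      MTOR: oncogene
      PIK3CA: oncogene
      PIK3R1: tumor_suppressor
      PTEN: tumor_suppressor
      RHEB: oncogene
      STK11: tumor_suppressor
      TSC1: tumor_suppressor
      TSC2: tumor_suppressor
      IDH1: oncogene
      IDH2: oncogene
      VHL: tumor_suppressor
  - name: MYC_family
    genes:
      MYC: oncogene
      MYCN: oncogene
      MYB: oncogene
  - name: TERT
    genes:
      TERT: oncogene
  - name: Wnt_beta_catenin
    genes:
      APC: tumor_suppressor
      AXIN1: tumor_suppressor
      CTNNB1: oncogene
      FGF19: oncogene
      NCOR1: tumor_suppressor
  - name: p53_Rb
    genes:
      ATM: tumor_suppressor
      CCND1: oncogene
      CCNE1: oncogene
      CDK4: oncogene
      CDKN1A: tumor_suppressor
      CDKN2A: tumor_suppressor
      E2F2: oncogene
      E2F3: oncogene
      FBXW7: tumor_suppressor
      MDM2: oncogene
      RB1: tumor_suppressor
      TP53: tumor_suppressor
  - name: NRF2
    enabled: false
    genes:
      NFE2L2: oncogene
      KEAP1: tumor_suppressor
      CUL3: tumor_suppressor
      SIRT1: tumor_suppressor
      FH: tumor_suppressor
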