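# Genes carrying known-pathogenic / expected-pathogenic (KP/EP) actionable
# variants per the ACMG incidental-findings recommendations, listed per panel.
# The actionable gene list used by the registry is the union of these lists.
actionable:
  CMP: [MYBPC3, MYH7, TNNT2, TNNI3, TPM1, MYL3, ACTC1, PRKAG2, GLA, MYL2,
        LMNA, RYR2, PKP2, DSP, DSC2, TMEM43, DSG2, SCN5A]
  HCM: [MYBPC3, MYH7, TNNT2, TNNI3, TPM1, MYL3, ACTC1, PRKAG2, GLA, MYL2]
  DCM_LVNC: [MYBPC3, MYH7, TNNT2, TNNI3, TPM1, ACTC1, LMNA, SCN5A]
  ARVC: [LMNA, PKP2, DSP, DSC2, TMEM43, DSG2]
  MFS_LDS: [FBN1, TGFBR1, TGFBR2]
  TAAD: [COL3A1, FBN1, TGFBR1, TGFBR2, SMAD3, ACTA2, MYLK, MYH11]
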