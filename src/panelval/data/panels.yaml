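# Cardiovascular NGS sub-panel gene content.
# Each panel lists its HGNC gene symbols; reflex_of marks panels offered as a
# physician-requested reflex after a negative first result on a sub-panel.
panels:
  - name: CMP
    description: Comprehensive cardiomyopathy (also offered as reflex CMP)
    reflex_available: true
    genes: [ABCC9, ACTC1, ACTN2, ANKRD1, BAG3, CASQ2, CAV3, CRYAB, CSRP3,
            CTNNA3, DES, DMD, DSC2, DSG2, DSP, DTNA, EMD, EYA4, FHL1, FHL2,
            FKTN, GATAD1, GLA, JPH2, JUP, KLF10, LAMA4, LAMP2, LDB3, LMNA,
            MYBPC3, MYH6, MYH7, MYL2, MYL3, MYLK2, MYOZ2, NEBL, NEXN, PDLIM3,
            PKP2, PLN, PRKAG2, PSEN1, PSEN2, RAF1, RBM20, RYR2, SCN5A, SGCD,
            TAZ, TCAP, TMEM43, TMPO, TNNC1, TNNI3, TNNT2, TPM1, TTN, TTR, VCL]
  - name: HCM
    description: Hypertrophic cardiomyopathy
    genes: [ACTC1, ACTN2, CSRP3, GLA, LAMP2, MYBPC3, MYH7, MYL2, MYL3, MYOZ2,
            NEXN, PLN, PRKAG2, TNNC1, TNNI3, TNNT2, TPM1, TTR]
  - name: DCM_LVNC
    description: Dilated cardiomyopathy / left ventricular non-compaction
    genes: [ABCC9, ACTC1, ACTN2, ANKRD1, BAG3, CRYAB, CSRP3, DES, DMD, DTNA,
            EMD, EYA4, GATAD1, LAMP2, LDB3, LMNA, MYBPC3, MYH7, NEXN, PLN,
            RAF1, RBM20, SCN5A, SGCD, TAZ, TCAP, TNNC1, TNNI3, TNNT2, TPM1,
            TTN, TTR, VCL]
  - name: ARVC
    description: Arrhythmogenic right ventricular cardiomyopathy
    genes: [CTNNA3, DSC2, DSG2, DSP, JUP, LMNA, PKP2, TMEM43]
  - name: MFS_LDS
    description: Marfan syndrome / Loeys-Dietz syndrome
    genes: [FBN1, TGFBR1, TGFBR2]
  - name: TAAD
    description: Thoracic aortic aneurysms and dissections (also reflex TAAD)
    reflex_available: true
    genes: [ACTA2, CBS, COL3A1, COL5A1, COL5A2, ELN, FBN1, FBN2, MED12, MYH11,
            MYLK, PLOD1, SLC2A10, SMAD3, SMAD4, TGFB2, TGFBR1, TGFBR2]
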