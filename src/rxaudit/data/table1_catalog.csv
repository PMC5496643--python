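raw_code,stem,generic_name,atc_class
ALGY-T-,ALGY,Alginic acid tablet,A02A
ALHY-T-,ALHY,Aluminium hydroxide 500 mg,A02A
ALHY-N2,ALHY,Aluminium hydroxide 6.10%,A02A
ANTT-T-,ANTT,Aluminium hydroxide tablet,A02A
ANTC-N2,ANTC,Aluminium hydroxide 1000 ml,A02A
ANTC-N1,ANTC,Aluminium hydroxide 240 ml,A02A
GAVD-T-,GAVD,Sodium alginate Dual Action,A02A
GAVI-N-,GAVI,Sodium alginate Liquid,A02A
GAST-T-,GAST,Bismuth subsalicylate 524 mg,A02A
MUCT-T-,MUCT,Rebamipide 100 mg,A02A
ULCF-N-,ULCF,Sucralfate 240 ml,A02A
ULCF-N1,ULCF,Sucralfate 60 ml,A02A
ULSN-T-,ULSN,Sucralfate 500 mg,A02A
ULSN1T-,ULSN,Sucralfate 1000 mg,A02A
CYTT-T-,CYTT,Misoprostol 200 mcg,A02B
XAND-T-,XAND,Ranitidine 150 mg,A02B
COTL2T-,COTL,Pantoprazole 20 mg,A02B
COTL-T-,COTL,Pantoprazole 40 mg,A02B
DEXI1C-,DEXI,Dexlansoprazole 60 mg,A02B
DEXI-C-,DEXI,Dexlansoprazole 30 mg,A02B
LOSC-C-,LOSC,Omeprazole MUPS 20 mg,A02B
NEXM1T-,NEXM,Esomeprazole 20 mg,A02B
NEXM2T-,NEXM,Esomeprazole 40 mg,A02B
OMPZ-C-,OMPZ,Omeprazole 20 mg,A02B
PARI-T-,PARI,Rabeprazole 10 mg,A02B
PARI1T-,PARI,Rabeprazole 20 mg,A02B
PRVF1T-,PRVF,Lansoprazole 15 mg,A02B
PRVF2T-,PRVF,Lansoprazole 30 mg,A02B
ASPT-T-,ASPT,Acetylsalicylic acid 300 mg,M01A_conventional
ASA.1T-,ASA.,Acetylsalicylic acid 81 mg,M01A_conventional
CAPN-T-,CAPN,Acetylsalicylic acid 100 mg,M01A_conventional
CLIR-T-,CLIR,Sulindac 200 mg,M01A_conventional
DICF-T-,DICF,Diclofenac 25 mg,M01A_conventional
FAFX-T-,FAFX,Nabumetone 500 mg,M01A_conventional
FLAM-C-,FLAM,Piroxicam 10 mg,M01A_conventional
IBUP-S-,IBUP,Ibuprofen (100 mg/5 ml),M01A_conventional
IBUP1T-,IBUP,Ibuprofen 200 mg,M01A_conventional
IBUP2T-,IBUP,Ibuprofen 400 mg,M01A_conventional
INDM-C-,INDM,Indomethacin 25 mg,M01A_conventional
MEFN1C-,MEFN,Mefenamic acid 250 mg,M01A_conventional
MEFN2T-,MEFN,Mefenamic acid 500 mg,M01A_conventional
MELO-T-,MELO,Meloxicam 7.5 mg,M01A_conventional
MELO1T-,MELO,Meloxicam 15 mg,M01A_conventional
NAPS-T-,NAPS,Naproxen LE 250 mg,M01A_conventional
NAPX-T-,NAPX,Naproxen 250 mg,M01A_conventional
REMT-T-,REMT,Diclofenac 100 mg,M01A_conventional
VOLS1T-,VOLS,Diclofenac SR 75 mg,M01A_conventional
VOLS-T-,VOLS,Diclofenac SR 100 mg,M01A_conventional
MOBC-T-,MOBC,Meloxicam (inferred brand),M01A_conventional
ARCX4T-,ARCX,Etoricoxib 30 mg,M01A_cox2
ARCX1T-,ARCX,Etoricoxib 60 mg,M01A_cox2
ARCX2T-,ARCX,Etoricoxib 90 mg,M01A_cox2
CELB-C-,CELB,Celecoxib 200 mg,M01A_cox2
CELB1C-,CELB,Celecoxib 400 mg,M01A_cox2
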