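{
  "name": "trp_degradation_subnetwork",
  "metabolites": {
    "Trp": "L-tryptophan",
    "Kyn": "kynurenine",
    "KA": "kynurenic acid",
    "Anth": "anthranilic acid",
    "3OHKyn": "3-hydroxy-kynurenine",
    "Xanth": "xanthurenic acid",
    "3OHAnth": "3-hydroxy-anthranilic acid",
    "ACMS": "2-amino-3-carboxymuconate semialdehyde",
    "QA": "quinolinic acid",
    "PA": "picolinic acid",
    "NAMN": "nicotinic acid mononucleotide",
    "NAD": "NAD+",
    "NAM": "nicotinamide",
    "5OHTrp": "5-hydroxy-tryptophan",
    "Sero": "serotonin"
  },
  "reactions": [
    {
      "id": "TRP2KYN",
      "name": "tryptophan dioxygenation to kynurenine (lumped)",
      "substrates": ["Trp"],
      "products": ["Kyn"],
      "gpr": "IDO1 or IDO2 or TDO2"
    },
    {
      "id": "KYN2KA",
      "name": "kynurenine transamination to kynurenic acid",
      "substrates": ["Kyn"],
      "products": ["KA"],
      "gpr": "KYAT1 or KYAT3 or AADAT"
    },
    {
      "id": "KYN2ANTH",
      "name": "kynurenine hydrolysis to anthranilic acid",
      "substrates": ["Kyn"],
      "products": ["Anth"],
      "gpr": "KYNU"
    },
    {
      "id": "KYN2OHKYN",
      "name": "kynurenine 3-monooxygenation",
      "substrates": ["Kyn"],
      "products": ["3OHKyn"],
      "gpr": "KMO"
    },
    {
      "id": "OHKYN2XANTH",
      "name": "3-hydroxy-kynurenine transamination to xanthurenic acid",
      "substrates": ["3OHKyn"],
      "products": ["Xanth"],
      "gpr": "KYAT1 or AADAT"
    },
    {
      "id": "OHKYN2OHANTH",
      "name": "3-hydroxy-kynurenine hydrolysis to 3-hydroxy-anthranilic acid",
      "substrates": ["3OHKyn"],
      "products": ["3OHAnth"],
      "gpr": "KYNU"
    },
    {
      "id": "OHANTH2ACMS",
      "name": "3-hydroxy-anthranilate ring opening",
      "substrates": ["3OHAnth"],
      "products": ["ACMS"],
      "gpr": "HAAO"
    },
    {
      "id": "ACMS2QA",
      "name": "spontaneous cyclization of ACMS to quinolinic acid",
      "substrates": ["ACMS"],
      "products": ["QA"],
      "gpr": null
    },
    {
      "id": "ACMS2PA",
      "name": "ACMS decarboxylation toward picolinic acid (lumped)",
      "substrates": ["ACMS"],
      "products": ["PA"],
      "gpr": "ACMSD"
    },
    {
      "id": "R24a",
      "name": "quinolinate phosphoribosyltransfer to NAMN",
      "substrates": ["QA"],
      "products": ["NAMN"],
      "gpr": "QPRT"
    },
    {
      "id": "NAMN2NAD",
      "name": "NAMN to NAD+ (lumped via NAAD)",
      "substrates": ["NAMN"],
      "products": ["NAD"],
      "gpr": "(NMNAT1 or NMNAT2 or NMNAT3) and NADSYN1"
    },
    {
      "id": "NAM2NAD",
      "name": "salvage entry: nicotinamide to NAD+ (lumped via NMN)",
      "substrates": ["NAM"],
      "products": ["NAD"],
      "gpr": "NAMPT and (NMNAT1 or NMNAT2 or NMNAT3)"
    },
    {
      "id": "TRP2OHTRP",
      "name": "tryptophan 5-hydroxylation",
      "substrates": ["Trp"],
      "products": ["5OHTrp"],
      "gpr": "TPH1 or TPH2"
    },
    {
      "id": "OHTRP2SERO",
      "name": "5-hydroxy-tryptophan decarboxylation to serotonin",
      "substrates": ["5OHTrp"],
      "products": ["Sero"],
      "gpr": "DDC"
    }
  ]
}
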