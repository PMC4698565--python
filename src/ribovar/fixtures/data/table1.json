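{
  "W136": {
    "species": "Polyommatus (Agrodiaetus) peilei",
    "alias": null,
    "positions": ["128", "130", "131", "171", "172", "173", "235", "316", "326",
                  "329", "330", "331", "332", "333", "334", "335", "336", "337",
                  "338", "339", "340", "341", "342", "343", "344", "345", "346",
                  "356", "400", "414", "465"],
    "rows": {
      "#01": "TG-CGCAATTTTTTTT--CGTTTTT-CGGGC",
      "#02": "TG-CGCAATTTTTTTT--CGTTTTT-CGGGT",
      "#03": "TAACACGGCTTTTTTTTTTGTTTTT-CAGAC",
      "#04": "TG-CGCAATTTTTTTT--TGTTTTT-CGGGC",
      "#05": "TAACACGGCTTTTTTTTTTGTTTTTT-AGGC",
      "#06": "TG-CGCAATTTTTT----TGTTTTT-CGGGC",
      "#07": "TG-CGCAACTTTTTTTTTTGTTTTTT-AGGC",
      "#08": "AA----AAT------------------AAGC",
      "#09": "TAACACGGCTTTTTTTTTTGTTTTTT-AGGC",
      "#10": "TG-CGCAATTTTTTTT--TGTTTTT-CGGGC"
    }
  },
  "W202": {
    "species": "Polyommatus (Agrodiaetus) peilei",
    "alias": null,
    "positions": ["14", "41", "128", "131", "169", "170", "171", "176",
                  "184", "185", "186", "187", "188", "189", "190", "191", "192",
                  "193", "194", "195", "196", "197", "198", "199", "200",
                  "235", "236", "326", "336", "337", "338", "345", "346", "356"],
    "rows": {
      "#01": "TCT-ACCT-----------------A-TTT-T-A",
      "#02": "TTTAACCTTCGCGTCGGCGACGTGCGGCTTTT-A",
      "#03": "TTG----TTCGCGTCGGCGACGTGCGGTTTC-CG",
      "#04": "TTT-ACCC-----------------A-TT-C-CG",
      "#05": "CCTAACCTTCGCGTCGGCGACGTGCGGCTT-T-A",
      "#06": "TTTAACCTTCGCGTCGGCGACGTGCGGCTTTT-A",
      "#07": "TTTAACCTTCGCGTCGGCGACGTGCGGCTTTT-A",
      "#08": "TCT-ACCT-----------------A-T--C-CG",
      "#09": "TTTAACCTTCGCGTCGGCGACGTGCGGTTTTT-A",
      "#10": "TCT-ACCTTCGCGTCGGCGACGTGCA-TTTC-CG"
    }
  },
  "V145": {
    "species": "Polyommatus (Agrodiaetus) karindus",
    "alias": null,
    "positions": ["20", "150", "154", "155", "166", "239", "340", "341", "342"],
    "rows": {
      "#01": "AC--TTTT-",
      "#02": "AC--TTT--",
      "#03": "ATCGTT---",
      "#04": "ATCGTT---",
      "#05": "ATCGTTT--",
      "#06": "AC--TC---",
      "#07": "ATCGCTTTT",
      "#08": "AC--TTT--",
      "#09": "AC--TT---",
      "#10": "GC--TT---"
    }
  },
  "Z704": {
    "species": "Polyommatus (Agrodiaetus) karindus",
    "alias": "Z04",
    "positions": ["27", "84", "128", "136", "169", "170", "171", "331", "335",
                  "336", "337", "337b", "338", "339", "340", "346", "351",
                  "352", "353", "354"],
    "rows": {
      "#01": "CGTTCCACTTTTTTTC-AAA",
      "#02": "CGTTCCATTTTTTTTC-AAA",
      "#03": "CGTTCCATTTTTTTTC-AAA",
      "#04": "CGTTCCATTTTTTTTC-AAA",
      "#05": "TGT-CCATTTTTTT-CAAAA",
      "#06": "TGT-CCATTTTTTT-CAAAA",
      "#07": "TAT-CCATTTTTTT-CAAAA",
      "#08": "CGTTCCATTTTTTT-C-AAA",
      "#09": "CGTTCCATTTTTTT-C-AAA",
      "#10": "TGG----C------------"
    }
  },
  "W127": {
    "species": "Polyommatus (Agrodiaetus) morgani",
    "alias": "V127",
    "positions": ["7", "38", "43", "79", "127", "128", "148", "171", "172", "173",
                  "229", "301",
                  "318", "319", "320", "321", "322", "323", "324", "325", "326",
                  "327", "328", "329", "330", "331", "332", "333", "334",
                  "347", "348", "349", "350", "352", "353", "354", "355",
                  "357", "358", "391", "400", "472"],
    "rows": {
      "#01": "AAC-CGT---TCACACGTTTTTTTT----AACG---AAAAGG",
      "#02": "AAC-CGT---CCACACGTTTTTTTTTTTTAACG---AATAGG",
      "#03": "AAC-ATCCGCTG---------------------GCAAGAGGT",
      "#04": "AGCGATTCGCTG---------------------GCAAGAGGG",
      "#05": "GGCGCGT---TCACACGTTCTTTTTTTT-AACG---AAAAGG",
      "#06": "AAC-CGT---TCACACGTTTTTTTTTT--AACG---AAAAAG",
      "#07": "AAC-CGTCGCTG---------------------GCAAGAGGG",
      "#08": "AACGATTCGCTC---------------------GCA-AAAGT",
      "#09": "AATGATTCGCTG---------------------GCAAGAGGG",
      "#10": "AAC-CGT---TG---------------------GCAAGAGGG"
    }
  }
}
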