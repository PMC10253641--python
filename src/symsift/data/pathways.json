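{
  "schema": "symsift-pathways-v1",
  "enzymes": {
    "ipt": {"name": "adenylate dimethylallyltransferase (IPT)", "symbol": "ipt", "ec": ["2.5.1.27", "2.5.1.112"]},
    "miaa": {"name": "tRNA dimethylallyltransferase", "symbol": "miaa", "ec": ["2.5.1.75"]},
    "miab": {"name": "tRNA-2-methylthio-N6-dimethylallyladenosine synthase", "symbol": "miab", "ec": ["2.8.4.3"]},
    "nt5": {"name": "5'-nucleotidase", "symbol": "nt5", "ec": ["3.1.3.5"]},
    "ade_nucleosidase": {"name": "adenosine nucleosidase / purine-nucleoside phosphorylase", "symbol": "ade_nucleosidase", "ec": ["3.2.2.7", "2.4.2.1"]},
    "apt": {"name": "adenine phosphoribosyltransferase", "symbol": "apt", "ec": ["2.4.2.7"]},
    "dxs": {"name": "1-deoxy-D-xylulose-5-phosphate synthase", "symbol": "dxs", "ec": ["2.2.1.7"]},
    "dxr": {"name": "1-deoxy-D-xylulose-5-phosphate reductoisomerase (ispC)", "symbol": "dxr", "ec": ["1.1.1.267"]},
    "ispd": {"name": "2-C-methyl-D-erythritol 4-phosphate cytidylyltransferase", "symbol": "ispd", "ec": ["2.7.7.60"]},
    "ispe": {"name": "4-diphosphocytidyl-2-C-methyl-D-erythritol kinase", "symbol": "ispe", "ec": ["2.7.1.148"]},
    "ispf": {"name": "2-C-methyl-D-erythritol 2,4-cyclodiphosphate synthase", "symbol": "ispf", "ec": ["4.6.1.12"]},
    "ispg": {"name": "HMBDP synthase (gcpE)", "symbol": "ispg", "ec": ["1.17.7.1", "1.17.7.3"]},
    "isph": {"name": "HMBDP reductase", "symbol": "isph", "ec": ["1.17.7.4"]},
    "lysc": {"name": "aspartate kinase", "symbol": "lysc", "ec": ["2.7.2.4"]},
    "asd": {"name": "aspartate-semialdehyde dehydrogenase", "symbol": "asd", "ec": ["1.2.1.11"]},
    "hom": {"name": "homoserine dehydrogenase", "symbol": "hom", "ec": ["1.1.1.3"]},
    "lass": {"name": "LASS (homoserine acylation step; identity recorded by gene symbol only)", "symbol": "lass", "ec": []},
    "meta": {"name": "homoserine O-succinyl/acetyl-transferase", "symbol": "meta", "ec": ["2.3.1.46", "2.3.1.31"]},
    "metb": {"name": "cystathionine gamma-synthase", "symbol": "metb", "ec": ["2.5.1.48"]},
    "metc": {"name": "cystathionine beta-lyase", "symbol": "metc", "ec": ["4.4.1.8"]},
    "mete": {"name": "methionine synthase (metE/metH)", "symbol": "mete", "ec": ["2.1.1.14", "2.1.1.13"]},
    "metk": {"name": "S-adenosylmethionine synthetase", "symbol": "metk", "ec": ["2.5.1.6"]},
    "iaam": {"name": "tryptophan 2-monooxygenase", "symbol": "iaam", "ec": ["1.13.12.3"]},
    "trp_aminotransferase": {"name": "tryptophan aminotransferase", "symbol": "trp_aminotransferase", "ec": ["2.6.1.27", "2.6.1.99"]},
    "trp_decarboxylase": {"name": "aromatic-L-amino-acid/tryptophan decarboxylase", "symbol": "trp_decarboxylase", "ec": ["4.1.1.28"]},
    "iaah": {"name": "indole-3-acetamide hydrolase", "symbol": "iaah", "ec": ["3.5.1.4"]},
    "ipdc": {"name": "indole-3-pyruvate decarboxylase", "symbol": "ipdc", "ec": ["4.1.1.74"]},
    "amine_oxidase": {"name": "tryptamine/amine oxidase", "symbol": "amine_oxidase", "ec": ["1.4.3.22"]},
    "ald": {"name": "indole-3-acetaldehyde dehydrogenase/oxidase", "symbol": "ald", "ec": ["1.2.1.3", "1.2.3.7"]},
    "nitrilase": {"name": "indole-3-acetonitrile nitrilase", "symbol": "nitrilase", "ec": ["3.5.5.1"]}
  },
  "pathways": [
    {
      "id": "MEP_00900",
      "name": "MEP pathway to DMAPP / HMBDP (map 00900)",
      "products": ["DMAPP", "HMBDP"],
      "entry_substrates": [
        {"substrate": "pyruvate + D-glyceraldehyde 3-phosphate", "enters_at_step": 0},
        {"substrate": "1-deoxy-d-xylulose-5-phosphate", "enters_at_step": 1}
      ],
      "steps": [
        {"name": "DXP synthesis", "alternatives": ["dxs"]},
        {"name": "MEP synthesis", "alternatives": ["dxr"]},
        {"name": "CDP-ME synthesis", "alternatives": ["ispd"]},
        {"name": "CDP-MEP synthesis", "alternatives": ["ispe"]},
        {"name": "MEcPP synthesis", "alternatives": ["ispf"]},
        {"name": "HMBDP synthesis", "alternatives": ["ispg"]},
        {"name": "DMAPP synthesis", "alternatives": ["isph"]}
      ]
    },
    {
      "id": "SAM_00270",
      "name": "S-adenosyl-L-methionine from aspartate or homoserine (map 00270)",
      "products": ["S-adenosyl-L-methionine"],
      "entry_substrates": [
        {"substrate": "L-aspartate", "enters_at_step": 0},
        {"substrate": "L-homoserine", "enters_at_step": 3},
        {"substrate": "L-methionine", "enters_at_step": 7}
      ],
      "steps": [
        {"name": "aspartate kinase", "alternatives": ["lysc"]},
        {"name": "aspartate-semialdehyde", "alternatives": ["asd"]},
        {"name": "homoserine synthesis", "alternatives": ["hom"]},
        {"name": "homoserine acylation", "alternatives": ["lass", "meta"]},
        {"name": "cystathionine synthesis", "alternatives": ["metb"]},
        {"name": "homocysteine synthesis", "alternatives": ["metc"]},
        {"name": "methionine synthesis", "alternatives": ["mete"]},
        {"name": "SAM synthesis", "alternatives": ["metk"]}
      ]
    },
    {
      "id": "ZEATIN_00908",
      "name": "tRNA-bound cytokinin production (map 00908)",
      "products": ["tRNA-bound cytokinins", "methylthiolated cytokinins"],
      "entry_substrates": [
        {"substrate": "DMAPP + adenine(37) in tRNA", "enters_at_step": 0},
        {"substrate": "prenylated tRNA", "enters_at_step": 1}
      ],
      "steps": [
        {"name": "adenine prenylation", "alternatives": ["ipt", "miaa"]},
        {"name": "prenyl-group methylthiolation", "alternatives": ["miab"]}
      ]
    },
    {
      "id": "IAA_00380",
      "name": "IAA from tryptophan (map 00380; all routes pooled per step)",
      "products": ["indole-3-acetic acid"],
      "entry_substrates": [
        {"substrate": "L-tryptophan", "enters_at_step": 0}
      ],
      "steps": [
        {"name": "tryptophan activation", "alternatives": ["iaam", "trp_aminotransferase", "trp_decarboxylase"]},
        {"name": "intermediate conversion", "alternatives": ["iaah", "ipdc", "amine_oxidase"]},
        {"name": "IAA formation", "alternatives": ["ald", "nitrilase"]}
      ]
    },
    {
      "id": "ADENINE_SALVAGE_00230",
      "name": "adenine salvage / AMP-adenosine interconversion (map 00230)",
      "products": ["adenosine", "adenine", "AMP"],
      "entry_substrates": [
        {"substrate": "AMP", "enters_at_step": 0},
        {"substrate": "adenosine", "enters_at_step": 1},
        {"substrate": "adenine", "enters_at_step": 2}
      ],
      "steps": [
        {"name": "AMP dephosphorylation", "alternatives": ["nt5"]},
        {"name": "adenosine cleavage", "alternatives": ["ade_nucleosidase"]},
        {"name": "adenine salvage to AMP", "alternatives": ["apt"]}
      ]
    }
  ]
}
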