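{
 "boundary_compartment": null,
 "compartments": [
  {
   "identifier": "c1",
   "name": "compartment c1"
  },
  {
   "identifier": "c2",
   "name": "compartment c2"
  }
 ],
 "extracellular_compartment": null,
 "metabolites": [
  {
   "charge": 0,
   "formula": "",
   "identifier": "A",
   "name": "A",
   "references": {
    "pubchem": [
     "101"
    ]
   }
  },
  {
   "charge": 0,
   "formula": "",
   "identifier": "B",
   "name": "B",
   "references": {
    "pubchem": [
     "102"
    ]
   }
  },
  {
   "charge": 0,
   "formula": "",
   "identifier": "C",
   "name": "C",
   "references": {
    "pubchem": [
     "103"
    ]
   }
  },
  {
   "charge": 0,
   "formula": "",
   "identifier": "D",
   "name": "D",
   "references": {
    "pubchem": [
     "104"
    ]
   }
  }
 ],
 "processes": [
  {
   "identifier": "cycle",
   "name": "toy cycle"
  }
 ],
 "reactions": [
  {
   "behavior": "conversion",
   "genes": [
    "gene_R1"
   ],
   "identifier": "R1c1",
   "name": "A to B (c1)",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "A",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c1",
     "metabolite": "B",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R1"
   ],
   "identifier": "R1c2",
   "name": "A to B (c2)",
   "participants": [
    {
     "compartment": "c2",
     "metabolite": "A",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "B",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R2"
   ],
   "identifier": "R2c1",
   "name": "B to C (c1)",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "B",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c1",
     "metabolite": "C",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R2"
   ],
   "identifier": "R2c2",
   "name": "B to C (c2)",
   "participants": [
    {
     "compartment": "c2",
     "metabolite": "B",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "C",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R3"
   ],
   "identifier": "R3c1",
   "name": "C to D (c1)",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "C",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c1",
     "metabolite": "D",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R3"
   ],
   "identifier": "R3c2",
   "name": "C to D (c2)",
   "participants": [
    {
     "compartment": "c2",
     "metabolite": "C",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "D",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R4"
   ],
   "identifier": "R4c1",
   "name": "D to A (c1)",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "D",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c1",
     "metabolite": "A",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "conversion",
   "genes": [
    "gene_R4"
   ],
   "identifier": "R4c2",
   "name": "D to A (c2)",
   "participants": [
    {
     "compartment": "c2",
     "metabolite": "D",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "A",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "transport",
   "genes": [],
   "identifier": "T1",
   "name": "transport A c1->c2",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "A",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "A",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [],
   "references": {},
   "reversible": false
  },
  {
   "behavior": "transport",
   "genes": [],
   "identifier": "T2",
   "name": "transport C c1->c2",
   "participants": [
    {
     "compartment": "c1",
     "metabolite": "C",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c2",
     "metabolite": "C",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [],
   "references": {},
   "reversible": false
  }
 ]
}
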