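{
 "boundary_compartment": null,
 "compartments": [
  {
   "identifier": "c",
   "name": "cytosol"
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
  },
  {
   "charge": 0,
   "formula": "",
   "identifier": "H",
   "name": "H",
   "references": {
    "pubchem": [
     "199"
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
   "identifier": "R1",
   "name": "A to B",
   "participants": [
    {
     "compartment": "c",
     "metabolite": "A",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "B",
     "role": "product",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "H",
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
   "identifier": "R2",
   "name": "B to C",
   "participants": [
    {
     "compartment": "c",
     "metabolite": "B",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "C",
     "role": "product",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "H",
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
   "identifier": "R3",
   "name": "C to D",
   "participants": [
    {
     "compartment": "c",
     "metabolite": "C",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "D",
     "role": "product",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "H",
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
   "identifier": "R4",
   "name": "D to A",
   "participants": [
    {
     "compartment": "c",
     "metabolite": "D",
     "role": "reactant",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "A",
     "role": "product",
     "stoichiometry": 1.0
    },
    {
     "compartment": "c",
     "metabolite": "H",
     "role": "product",
     "stoichiometry": 1.0
    }
   ],
   "processes": [
    "cycle"
   ],
   "references": {},
   "reversible": false
  }
 ]
}
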