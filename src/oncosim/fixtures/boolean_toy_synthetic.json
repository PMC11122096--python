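{
  "comment": "Synthetic toy DNA-damage/survival-signalling Boolean network. ATM latches radiation damage; p53 is activated by ATM and repressed by Mdm2; Mdm2 needs both p53 and Akt, closing the oscillatory negative feedback; caspase fires on p53 without Akt protection; cyclin runs when p53 is quiet. Interface nodes Erk, Akt, PTEN are written by a fast signalling module in hybrid mode.",
  "nodes": ["ATM", "Erk", "Akt", "PTEN", "p53", "Mdm2", "Casp", "Cyclin"],
  "edges": [
    ["ATM", "ATM", 1],
    ["Erk", "Erk", 1],
    ["Akt", "Akt", 1],
    ["PTEN", "PTEN", 1],
    ["PTEN", "Akt", -1],
    ["ATM", "p53", 2],
    ["Mdm2", "p53", -2],
    ["p53", "Mdm2", 1],
    ["Akt", "Mdm2", 1],
    ["p53", "Casp", 2],
    ["Akt", "Casp", -1],
    ["p53", "Cyclin", -2],
    ["Erk", "Cyclin", 1]
  ],
  "thresholds": {"ATM": 0, "Erk": 0, "Akt": 0, "PTEN": 0, "p53": 1, "Mdm2": 1, "Casp": 1, "Cyclin": -1}
}
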