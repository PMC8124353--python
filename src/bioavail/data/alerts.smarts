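# Structural alert patterns, one per line: <name><TAB><SMARTS>
# phenol: hydroxyl bonded to an aromatic carbon (selects conjugative gut-wall extraction)
phenol	[OX2H][c]
# beta_lactam: 4-membered cyclic amide core (beta-lactam antibiotics; active intestinal uptake)
beta_lactam	[#7]1[#6][#6][#6]1=[OX1]
# quinolone: 4-oxo-1,4-dihydroquinoline/naphthyridine-3-carboxylate scaffold
# (fluoroquinolone antibacterials; active intestinal uptake)
quinolone	[#8]=[#6]1[#6](=,:[#6][#7;R][#6]2=,:[#6]1[#6,#7]=,:[#6][#6]=,:[#6,#7]2)[#6](=[OX1])[#8]
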