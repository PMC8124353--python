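"""Structural alerts and the applicability-domain gate on a few structures.

Phenols select a gut-wall extraction path; quinolones and beta-lactams get an
active-uptake floor; metals and quaternary amines cannot be predicted at all;
molecular weight outside 100-700 Da marks a prediction as uncertain.
"""
from bioavail import check_domain, detect_alerts, parse_compound

structures = {
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "amoxicillin": "CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O",
    "levofloxacin": "C[C@H]1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23",
    "tetramethylammonium": "C[N+](C)(C)C",
    "cisplatin": "N.N.Cl[Pt]Cl",
    "urea": "NC(N)=O",
}

for name, smiles in structures.items():
    c = parse_compound(name, smiles)
    flags = detect_alerts(c)
    status = check_domain(c)
    alerts = [k for k, v in flags.as_dict().items() if v] or ["-"]
    print(f"{name:20s} MW {c.mol_weight:6.1f}  alerts: {','.join(alerts):22s} "
          f"in_domain={str(status.in_domain):5s} reasons: {', '.join(status.reasons) or '-'}")
# "in_domain=False" with reasons like mw_low still yields an (uncertain)
# estimate downstream; metal / quaternary_amine reasons block estimation.
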