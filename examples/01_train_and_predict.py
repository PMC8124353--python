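"""Train the nine ADME endpoint models on synthetic data and predict oral
bioavailability for a few well-known drugs.

The endpoint models here are fitted to generated data (real training data for
such models is proprietary across the industry), so the F values are
demonstration numbers; the point is the mechanics: descriptors -> nine
endpoints -> gut stage -> well-stirred liver -> F_pred = F_int x F_liver.
"""
import numpy as np

from bioavail import parse_compound, predict_F
from bioavail.qsar import ENDPOINTS, build_feature_matrix, train_pls, train_svm
from bioavail.synthetic import generate_endpoint_dataset

GRID = {"gamma": [2.0**e for e in (-6, -2, 2)], "cost": [2.0**e for e in (0, 4, 8)]}

registry = {}
for name, spec in ENDPOINTS.items():
    ds = generate_endpoint_dataset(name, 120, noise_sd=0.05, seed=41, max_height=1)
    X, vocab = build_feature_matrix(ds.descriptors)
    y = ds.y.astype(int) if spec.task == "classification" else ds.y
    if spec.learner == "svm":
        model = train_svm(spec, X, y, grid=GRID, folds=5, seed=7)
    else:
        model = train_pls(spec, X, y, folds=5, seed=7)
    model.feature_index = vocab
    model.training_meta["max_height"] = 1
    registry[name] = model
    print(f"trained {name:8s} ({spec.learner:6s}) CV aggregate = {model.cv_report.aggregate:.3f}")

drugs = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "ciprofloxacin": "OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
    "cisplatin": "N.N.Cl[Pt]Cl",
}
print()
for name, smiles in drugs.items():
    pred = predict_F(parse_compound(name, smiles), registry)
    if not pred.estimated:
        print(f"{name:14s} no estimate (reasons: {', '.join(pred.domain.reasons)})")
        continue
    print(f"{name:14s} F_pred = {pred.F_pred*100:5.1f}%  "
          f"(F_int = {pred.F_int*100:5.1f}%, F_liver = {pred.F_liver*100:5.1f}%)")
# F_int is the fraction surviving absorption + gut-wall extraction, F_liver the
# fraction escaping hepatic first pass; their product is oral bioavailability.
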