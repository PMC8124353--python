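import numpy as np
import pytest

from bioavail import chemstruct, synthetic
from bioavail.qsar import ENDPOINTS, build_feature_matrix, train_svm, train_pls

#: small grid keeping SVM training fast in fixtures
TINY_GRID = {"gamma": [2.0**e for e in (-6, -2, 2)], "cost": [2.0**e for e in (0, 4, 8)]}


@pytest.fixture(scope="session")
def drug_panel():
    return synthetic.load_drug_panel()


@pytest.fixture(scope="session")
def registry():
    """All nine endpoint models trained on small synthetic sets (height-1
    signatures, 5-fold CV) — enough to exercise the full pipeline."""
    models = {}
    for name, spec in ENDPOINTS.items():
        ds = synthetic.generate_endpoint_dataset(name, 120, noise_sd=0.05, seed=41, max_height=1)
        X, vocab = build_feature_matrix(ds.descriptors)
        y = ds.y.astype(int) if spec.task == "classification" else ds.y
        if spec.learner == "svm":
            model = train_svm(spec, X, y, grid=TINY_GRID, folds=5, seed=7)
        else:
            model = train_pls(spec, X, y, folds=5, seed=7)
        model.feature_index = vocab
        model.training_meta["max_height"] = 1
        models[name] = model
    return models


@pytest.fixture()
def paracetamol():
    return chemstruct.parse_compound("paracetamol", "CC(=O)Nc1ccc(O)cc1")
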