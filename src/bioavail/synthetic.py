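"""Deterministic synthetic-data generators.

Two generators make every stage testable without any external data:

* structure -> endpoint training sets whose response is a known sparse linear
  function of signature counts (plus Gaussian noise), squashed into each
  endpoint's natural range — used for parameter-recovery tests;
* benchmark observed-F tables drawn from a three-component (scaled-Beta)
  mixture whose region weights are exactly the observed tail probabilities
  P(F > 0.90) = 0.28 and P(F > 0.65) = 0.50 of the human reference
  distribution, with optional paired predictions calibrated to a target Q2
  and animal series calibrated to a target interspecies R2.

All randomness flows from a single integer seed; regeneration with the same
seed is bit-identical.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemstruct import Compound, DescriptorVector, compute_signatures, parse_compound
from .evaluation import DEFAULT_EPS, PairedSeries, q2, r2
from .qsar import ENDPOINTS, build_feature_matrix

# scaled-Beta shapes for the low (<=0.65), mid (0.65-0.9] and high (>0.9) regions
_BETA_LOW = (2.2, 1.8)
_BETA_MID = (1.5, 1.5)
_BETA_HIGH = (2.0, 1.2)


def load_drug_panel() -> list[Compound]:
    """The bundled panel of well-known, public drug-like structures."""
    text = resources.files("bioavail.data").joinpath("drug_panel.smi").read_text()
    compounds = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split("\t")
        compounds.append(parse_compound(name, smiles))
    return compounds


@dataclass(frozen=True)
class FixtureEntry:
    """A hand-labelled molecule for alert/domain unit tests."""

    name: str
    smiles: str
    phenol: bool = False
    quinolone: bool = False
    beta_lactam: bool = False
    quaternary_amine: bool = False
    metal: bool = False
    mw_low: bool = False
    mw_high: bool = False


def fixture_panel() -> list[FixtureEntry]:
    """>= 20 hand-curated structures with ground-truth alert/domain labels."""
    E = FixtureEntry
    return [
        E("paracetamol", "CC(=O)Nc1ccc(O)cc1", phenol=True),
        E("estradiol", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", phenol=True),
        E("morphine", "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5", phenol=True),
        E("salbutamol", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1", phenol=True),
        E("labetalol", "CC(Cc1ccccc1)NCC(O)c1ccc(O)c(C(N)=O)c1", phenol=True),
        E("amoxicillin", "CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O",
          phenol=True, beta_lactam=True),
        E("cyclohexanol", "OC1CCCCC1"),
        E("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
        E("diazepam", "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1"),
        E("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        E("quinoline", "c1ccc2ncccc2c1"),
        E("ciprofloxacin", "OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O", quinolone=True),
        E("norfloxacin", "CCn1cc(C(=O)O)c(=O)c2cc(N3CCNCC3)c(F)cc21", quinolone=True),
        E("levofloxacin", "C[C@H]1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23", quinolone=True),
        E("nalidixic_acid", "CCn1cc(C(=O)O)c(=O)c2ccc(C)nc21", quinolone=True),
        E("penicillin_g", "CC1(C)S[C@@H]2[C@H](NC(=O)Cc3ccccc3)C(=O)N2[C@H]1C(=O)O",
          beta_lactam=True),
        E("cephalexin", "CC1=C(C(=O)O)N2C(=O)[C@@H](NC(=O)[C@H](N)c3ccccc3)[C@H]2SC1",
          beta_lactam=True),
        E("aztreonam", "CC1C(NC(=O)C(=NOC(C)(C)C(=O)O)c2csc(N)n2)C(=O)N1S(=O)(=O)O",
          beta_lactam=True),
        E("azetidin-2-one", "O=C1CCN1", beta_lactam=True, mw_low=True),
        E("tetramethylammonium", "C[N+](C)(C)C", quaternary_amine=True, mw_low=True),
        E("bethanechol", "C[N+](C)(C)CC(C)OC(N)=O", quaternary_amine=True),
        E("neostigmine", "CN(C)C(=O)Oc1cccc([N+](C)(C)C)c1", quaternary_amine=True),
        E("cisplatin", "N.N.Cl[Pt]Cl", metal=True),
        # disconnected representation: the kept organic fragment is benzene,
        # so the MW rule sees 78 Da while the metal rule sees the iron
        E("ferrocene", "[Fe].c1ccccc1.c1ccccc1", metal=True, mw_low=True),
        E("lithium_carbonate", "[Li+].[Li+].[O-]C([O-])=O", metal=True, mw_low=True),
        E("urea", "NC(N)=O", mw_low=True),
        E("ethanol", "CCO", mw_low=True),
        E("itraconazole",
          "CCC(C)N1N=CN(c2ccc(N3CCN(c4ccc(OCC5COC(Cn6cncn6)(c6ccc(Cl)cc6Cl)O5)cc4)CC3)cc2)C1=O",
          mw_high=True),
        E("levothyroxine", "NC(Cc1cc(I)c(Oc2cc(I)c(O)c(I)c2)c(I)c1)C(=O)O",
          phenol=True, mw_high=True),
        E("ritonavir",
          "CC(C)c1nc(CN(C)C(=O)NC(C(=O)NC(Cc2ccccc2)CC(O)C(Cc2ccccc2)NC(=O)OCc2cncs2)C(C)C)cs1",
          mw_high=True),
    ]


# ---------------------------------------------------------------------------
# endpoint training sets with known mappings
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEndpointSet:
    endpoint: str
    compounds: list
    descriptors: list
    y: np.ndarray  # natural units (fraction, mL/min, ratio, or bool labels)
    y_latent: np.ndarray  # standardized latent before noise/transform
    true_mapping: dict  # {"coef": {signature: beta}, "offset": .., "scale": ..}
    noise_sd: float
    seed: int
    max_height: int


def _latent_transform(endpoint: str, latent: np.ndarray) -> np.ndarray:
    """Map a unit-scale latent onto the endpoint's natural range."""
    spec = ENDPOINTS[endpoint]
    if spec.task == "classification":
        return latent > 0.0
    if spec.transform == "logit":
        return 1.0 / (1.0 + np.exp(-latent))
    if spec.transform == "log10":
        # clearances around 10^2 mL/min; blood/plasma ratio around 1
        offset = 0.3 if endpoint == "cbl_cpl" else 2.0
        width = 0.3 if endpoint == "cbl_cpl" else 1.0
        return np.power(10.0, offset + width * latent)
    return latent


def _prevalent_features(X: np.ndarray, min_prevalence: float, n_min: int) -> np.ndarray:
    """Columns present in at least ``min_prevalence`` of rows (falling back to
    the most prevalent ``n_min`` columns when the cutoff is too strict)."""
    prevalence = (X > 0).mean(axis=0)
    keep = np.flatnonzero(prevalence >= min_prevalence)
    if len(keep) < n_min:
        keep = np.argsort(prevalence)[::-1][:n_min]
    return keep


def generate_endpoint_dataset(
    endpoint: str,
    n: int,
    noise_sd: float = 0.05,
    seed: int = 0,
    max_height: int = 2,
    n_active: int = 6,
    class_margin: float = 0.5,
    min_prevalence: float = 0.1,
) -> SyntheticEndpointSet:
    """Endpoint values as a fixed sparse linear function of signature counts.

    The latent signal is standardized over the drug panel, Gaussian noise with
    standard deviation ``noise_sd`` (in units of the latent's SD, which is 1)
    is added, and the result is squashed into the endpoint's natural range.
    Active features are drawn from signatures present in at least
    ``min_prevalence`` of the panel — the emulated QSAR signal lives on
    recurrent substructures, and the sparsity stays within the latent-component
    budget of the PLS endpoint models so the mapping is recoverable.  For
    classification endpoints, samples within ``class_margin`` of the class
    boundary are rejected so the two classes are separable.
    """
    if endpoint not in ENDPOINTS:
        raise KeyError(f"unknown endpoint {endpoint!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    spec = ENDPOINTS[endpoint]
    panel = load_drug_panel()
    descriptors = [compute_signatures(c, max_height) for c in panel]
    X, vocab = build_feature_matrix(descriptors)
    rng = np.random.default_rng(seed)
    informative = _prevalent_features(X, min_prevalence, n_active)
    active = rng.choice(informative, size=min(n_active, len(informative)), replace=False)
    beta = np.zeros(len(vocab))
    beta[np.sort(active)] = rng.normal(0.0, 1.0, size=len(active))
    raw = X @ beta
    offset, scale = float(raw.mean()), float(raw.std())
    latent_panel = (raw - offset) / scale

    if spec.task == "classification" and class_margin > 0:
        eligible = np.flatnonzero(np.abs(latent_panel) > class_margin)
        if len(eligible) < 2:
            raise ValueError("class margin leaves too few panel compounds")
        idx = rng.choice(eligible, size=n, replace=True)
    else:
        idx = rng.integers(0, len(panel), size=n)
    latent = latent_panel[idx] + rng.normal(0.0, noise_sd, size=n)
    y = _latent_transform(endpoint, latent)
    coef = {vocab[j]: float(beta[j]) for j in np.sort(active)}
    return SyntheticEndpointSet(
        endpoint=endpoint,
        compounds=[panel[i] for i in idx],
        descriptors=[descriptors[i] for i in idx],
        y=y,
        y_latent=latent,
        true_mapping={"coef": coef, "offset": offset, "scale": scale},
        noise_sd=noise_sd,
        seed=seed,
        max_height=max_height,
    )


def generate_training_table(n: int, seed: int = 0, max_height: int = 2) -> pd.DataFrame:
    """One joint table with all nine endpoint columns (natural units)."""
    panel = load_drug_panel()
    descriptors = [compute_signatures(c, max_height) for c in panel]
    X, vocab = build_feature_matrix(descriptors)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(panel), size=n)
    table = {
        "compound_id": [f"{panel[i].compound_id}_{k}" for k, i in enumerate(idx)],
        "smiles": [panel[i].smiles for i in idx],
    }
    informative = _prevalent_features(X, 0.1, 6)
    for endpoint in ENDPOINTS:
        active = rng.choice(informative, size=min(6, len(informative)), replace=False)
        beta = np.zeros(len(vocab))
        beta[np.sort(active)] = rng.normal(0.0, 1.0, size=len(active))
        raw = X @ beta
        latent = (raw - raw.mean()) / raw.std()
        values = _latent_transform(endpoint, latent[idx] + rng.normal(0.0, 0.05, size=n))
        if ENDPOINTS[endpoint].task == "classification":
            values = values.astype(int)
        table[endpoint] = values
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# benchmark observed/predicted F tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBenchmark:
    n: int
    ids: list
    observed_F: np.ndarray
    predicted_F: np.ndarray | None
    animal_F: dict
    seed: int


def _sample_mixture(rng: np.random.Generator, n: int, p_gt_90: float, p_gt_65: float) -> np.ndarray:
    """Three-region scaled-Beta mixture with exact tail weights."""
    u = rng.random(n)
    out = np.empty(n)
    high = u < p_gt_90
    mid = (~high) & (u < p_gt_65)
    low = ~(high | mid)
    out[high] = 0.9 + 0.1 * rng.beta(*_BETA_HIGH, size=int(high.sum()))
    out[mid] = 0.65 + 0.25 * rng.beta(*_BETA_MID, size=int(mid.sum()))
    out[low] = 0.65 * rng.beta(*_BETA_LOW, size=int(low.sum()))
    return out


def _calibrate_noise(base: np.ndarray, z: np.ndarray, score, target: float,
                     eps: float = DEFAULT_EPS) -> np.ndarray:
    """Bisect the noise scale so score(clip(base + s*z)) hits ``target``.

    ``score`` must be monotone non-increasing in s; the normals ``z`` are
    fixed, so the procedure is deterministic."""
    def at(s):
        return np.clip(base + s * z, eps, 1.0 - eps)

    if target >= 1.0:
        return base.copy()
    lo, hi = 0.0, 0.05
    while score(at(hi)) > target:
        hi *= 2.0
        if hi > 64.0:
            return at(hi)  # target unreachable; return the noisiest series
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if score(at(mid)) > target:
            lo = mid
        else:
            hi = mid
    return at(0.5 * (lo + hi))


def generate_benchmark(
    n: int,
    seed: int = 0,
    p_gt_90: float = 0.28,
    p_gt_65: float = 0.50,
    target_q2: float | None = None,
    animal_r2: Mapping[str, float] | None = None,
) -> SyntheticBenchmark:
    """Observed-F table matching the reference distribution's tails.

    ``target_q2`` adds a paired prediction series whose linear-scale Q2 equals
    the target; ``animal_r2`` maps species name -> target R2 for additional
    observed-animal columns.
    """
    if not 0.0 <= p_gt_90 <= p_gt_65 <= 1.0:
        raise ValueError("need 0 <= p_gt_90 <= p_gt_65 <= 1")
    rng = np.random.default_rng(seed)
    observed = _sample_mixture(rng, n, p_gt_90, p_gt_65)
    ids = [f"cpd{i:06d}" for i in range(n)]
    predicted = None
    if target_q2 is not None:
        z = rng.standard_normal(n)

        def q2_of(pred):
            return q2(PairedSeries.from_arrays(observed, pred), "lin")

        predicted = _calibrate_noise(observed, z, q2_of, target_q2)
    animal = {}
    if animal_r2:
        for species, target in animal_r2.items():
            z = rng.standard_normal(n)

            def r2_of(vals):
                return r2(observed, vals)

            animal[species] = _calibrate_noise(observed, z, r2_of, target)
    return SyntheticBenchmark(
        n=n, ids=ids, observed_F=observed, predicted_F=predicted,
        animal_F=animal, seed=seed,
    )


def benchmark_to_frame(bench: SyntheticBenchmark) -> pd.DataFrame:
    """Evaluation CSV layout (percent units, as in user-facing files)."""
    data = {"compound_id": bench.ids, "observed_F_human": bench.observed_F * 100.0}
    if bench.predicted_F is not None:
        data["predicted_F"] = bench.predicted_F * 100.0
    for species, vals in bench.animal_F.items():
        data[f"observed_F_{species}"] = vals * 100.0
    return pd.DataFrame(data)
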