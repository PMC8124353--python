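"""External-validation mathematics for paired observed/predicted F series.

Q2 is the forward-looking predictive accuracy 1 - SS_res / SS_tot (computed on
the linear or logit scale); R2 the retrospective squared Pearson correlation.
Errors are summarised as median/maximum fold errors (max(p,o)/min(p,o), exact
zeros replaced by eps), absolute errors in percentage points, the fraction of
predictions within 2/3/5-fold and 15/20/35 percentage-point bands, and the
least-squares intercept of predicted on observed (a skewness diagnostic).
A 2x2 concordance table supports the 20%-bioavailability go/no-go analysis.
Internally everything is fractions in [0, 1]; reports are in percent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_EPS = 0.001  # fraction (0.1%): floors fold-error ratios and logit clipping

FOLD_BANDS = (2.0, 3.0, 5.0)
ABS_BANDS = (15.0, 20.0, 35.0)  # percentage points


class UndefinedMetricError(ValueError):
    """Zero-variance input makes the metric undefined."""


@dataclass(frozen=True)
class PairedSeries:
    observed: tuple
    predicted: tuple
    ids: tuple = ()

    def __post_init__(self):
        n = len(self.observed)
        if n < 2 or len(self.predicted) != n:
            raise ValueError("need equal-length observed/predicted with n >= 2")
        if self.ids and len(self.ids) != n:
            raise ValueError("ids length mismatch")
        for v in (*self.observed, *self.predicted):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"value {v} outside [0,1]")

    @classmethod
    def from_arrays(cls, observed, predicted, ids=None) -> "PairedSeries":
        return cls(
            observed=tuple(float(v) for v in observed),
            predicted=tuple(float(v) for v in predicted),
            ids=tuple(ids) if ids is not None else (),
        )

    def __len__(self) -> int:
        return len(self.observed)


def _logit(x: np.ndarray, eps: float) -> np.ndarray:
    p = np.clip(x, eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def q2(series: PairedSeries, scale: str = "lin", eps: float = DEFAULT_EPS) -> float:
    """Predictive accuracy 1 - sum(pred-obs)^2 / sum(obs-mean(obs))^2.

    The denominator uses the evaluation set's own observed mean. ``scale``
    chooses linear or logit space (values clipped to [eps, 1-eps] first).
    """
    obs = np.asarray(series.observed, dtype=float)
    pred = np.asarray(series.predicted, dtype=float)
    if scale == "logit":
        obs, pred = _logit(obs, eps), _logit(pred, eps)
    elif scale != "lin":
        raise ValueError(f"unknown scale {scale!r}")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("observed series has zero variance")
    return 1.0 - float(np.sum((pred - obs) ** 2)) / ss_tot


def r2(a: Sequence[float], b: Sequence[float]) -> float:
    """Retrospective squared Pearson correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length series with n >= 2")
    if float(np.std(a)) == 0.0 or float(np.std(b)) == 0.0:
        raise UndefinedMetricError("zero variance in a correlated series")
    return float(stats.pearsonr(a, b).statistic ** 2)


def fold_errors(series: PairedSeries, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Per-pair fold error max(p,o)/min(p,o); exact zeros are replaced by eps
    so the ratio stays finite, while small non-zero values count at face value."""
    obs = np.asarray(series.observed, dtype=float)
    pred = np.asarray(series.predicted, dtype=float)
    obs = np.where(obs > 0.0, obs, eps)
    pred = np.where(pred > 0.0, pred, eps)
    return np.maximum(pred, obs) / np.minimum(pred, obs)


@dataclass(frozen=True)
class EvalReport:
    q2_lin: float
    q2_logit: float
    r2: float
    median_abs_err: float  # percentage points
    max_abs_err: float
    median_fold_err: float
    max_fold_err: float
    pct_within_fold: Mapping[float, float]  # {2,3,5} -> % of pairs
    pct_within_abs: Mapping[float, float]  # {15,20,35} points -> %
    intercept: float  # percentage points, OLS of predicted on observed
    n: int

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "q2_lin", "q2_logit", "r2", "median_abs_err", "max_abs_err",
            "median_fold_err", "max_fold_err", "intercept", "n")}
        d["pct_within_fold"] = {str(k): v for k, v in self.pct_within_fold.items()}
        d["pct_within_abs"] = {str(k): v for k, v in self.pct_within_abs.items()}
        return d


def error_summary(series: PairedSeries, eps: float = DEFAULT_EPS) -> EvalReport:
    """Full error-distribution report for one paired series."""
    obs = np.asarray(series.observed, dtype=float)
    pred = np.asarray(series.predicted, dtype=float)
    abs_err = np.abs(pred - obs) * 100.0
    folds = fold_errors(series, eps)
    slope, intercept = np.polyfit(obs, pred, 1)
    return EvalReport(
        q2_lin=q2(series, "lin", eps),
        q2_logit=q2(series, "logit", eps),
        r2=r2(series.observed, series.predicted),
        median_abs_err=float(np.median(abs_err)),
        max_abs_err=float(np.max(abs_err)),
        median_fold_err=float(np.median(folds)),
        max_fold_err=float(np.max(folds)),
        pct_within_fold={k: float(np.mean(folds < k) * 100.0) for k in FOLD_BANDS},
        pct_within_abs={k: float(np.mean(abs_err <= k) * 100.0) for k in ABS_BANDS},
        intercept=float(intercept) * 100.0,
        n=len(series),
    )


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 go/no-go table at a minimum-acceptable-F threshold."""

    threshold: float
    go_go: int  # pred >= t, obs >= t
    go_stop: int  # pred >= t, obs < t  (incorrect go)
    stop_go: int  # pred < t, obs >= t  (incorrect stop)
    stop_stop: int
    n: int

    @property
    def incorrect_stop_fraction(self) -> float:
        return self.stop_go / self.n

    @property
    def incorrect_go_fraction(self) -> float:
        return self.go_stop / self.n


def decision_concordance(series: PairedSeries, threshold: float = 0.2) -> ConcordanceTable:
    obs = np.asarray(series.observed, dtype=float)
    pred = np.asarray(series.predicted, dtype=float)
    go_p, go_o = pred >= threshold, obs >= threshold
    return ConcordanceTable(
        threshold=threshold,
        go_go=int(np.sum(go_p & go_o)),
        go_stop=int(np.sum(go_p & ~go_o)),
        stop_go=int(np.sum(~go_p & go_o)),
        stop_stop=int(np.sum(~go_p & ~go_o)),
        n=len(series),
    )


@dataclass(frozen=True)
class SpeciesComparison:
    n: int
    r2_interspecies: float  # animal F_obs vs human F_obs on matched compounds
    q2_insilico: float  # in-silico Q2 on the same matched compounds


@dataclass(frozen=True)
class HeadToHeadReport:
    per_species: Mapping[str, SpeciesComparison]
    pooled_n: int
    pooled_r2: float


def head_to_head(
    human: PairedSeries, animal_obs: Mapping[str, Mapping[str, float]]
) -> HeadToHeadReport:
    """Interspecies comparison on id-matched subsets.

    ``human`` must carry ids; ``animal_obs`` maps species -> {compound_id:
    observed animal F}.  Per species, reports the animal-vs-human R2 and the
    in-silico Q2 restricted to the same compounds; pooled statistics
    concatenate all species matches.
    """
    if not human.ids:
        raise ValueError("human series must carry compound ids")
    idx = {cid: i for i, cid in enumerate(human.ids)}
    per_species = {}
    pooled_animal: list = []
    pooled_human: list = []
    for species, table in animal_obs.items():
        matched = [cid for cid in table if cid in idx]
        if not matched:
            raise ValueError(f"no compounds shared with species {species!r}")
        h_obs = [human.observed[idx[c]] for c in matched]
        h_pred = [human.predicted[idx[c]] for c in matched]
        a_obs = [float(table[c]) for c in matched]
        sub = PairedSeries.from_arrays(h_obs, h_pred, matched)
        per_species[species] = SpeciesComparison(
            n=len(matched),
            r2_interspecies=r2(a_obs, h_obs),
            q2_insilico=q2(sub, "lin"),
        )
        pooled_animal.extend(a_obs)
        pooled_human.extend(h_obs)
    return HeadToHeadReport(
        per_species=per_species,
        pooled_n=len(pooled_animal),
        pooled_r2=r2(pooled_animal, pooled_human),
    )
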