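"""Ensemble variance: confidence estimation, filtering, adaptive sampling.

A k-fold ensemble (k = 5 by default) trains one kernel ridge machine per
fold, each on the structures outside that fold.  The across-fold spread of
the k predictions for a target — reported as the population standard
deviation, in the parameter's own unit — quantifies how well the training
set covers that environment.  Environments unlike anything in the training
set disagree across folds, so the spread supports two uses:

* a *pre-prediction variance filter* that flags predictions whose spread
  exceeds a per-parameter cutoff (defaults 1 Hz for ¹J_CH, 0.1 ppm for
  δ¹H, 5 ppm for δ¹³C) before any reference data is consulted; and
* *adaptive sampling*: iteratively growing a training set by adding the
  superset structures the current ensemble is most uncertain about, so
  each added structure provides the maximum benefit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .krr import (
    KernelParams,
    KRRModel,
    assemble_targets,
    fit_krr_model,
    krr_predict,
    median_heuristic_sigma,
    structure_folds,
)
from .representations import RepParams, rep_for_label, represent_dataset
from .structures import Dataset, LabelRecord, PredictionRow

__all__ = [
    "DEFAULT_CUTOFFS",
    "FilterPolicy",
    "EnsembleModel",
    "EnsemblePrediction",
    "fit_ensemble",
    "predict_with_spread",
    "apply_filter",
    "adaptive_sample",
    "AdaptiveResult",
]

#: Per-parameter spread cutoffs balancing accuracy against exclusions.
DEFAULT_CUTOFFS = {"j1_CH": 1.0, "shift_1H": 0.1, "shift_13C": 5.0}


@dataclass(frozen=True)
class FilterPolicy:
    """Per-parameter spread cutoffs (Hz for couplings, ppm for shifts).

    A prediction is kept when spread ≤ cutoff (inclusive boundary).
    """

    cutoffs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self):
        if any(c <= 0 for c in self.cutoffs.values()):
            raise ValueError("all cutoffs must be positive")

    def cutoff_for(self, param: str) -> float:
        try:
            return self.cutoffs[param]
        except KeyError:
            raise KeyError(f"no spread cutoff configured for {param!r}") from None


@dataclass(frozen=True)
class EnsemblePrediction:
    """Mean prediction with across-fold spread for one target."""

    structure_id: str
    param: str
    atoms: tuple[int, ...]
    mean: float
    spread: float  # population SD of the fold predictions, parameter units
    kept: bool | None = None

    @property
    def key(self):
        return (self.structure_id, self.param, self.atoms)

    def as_row(self) -> PredictionRow:
        return PredictionRow(self.structure_id, self.param, self.atoms,
                             self.mean, self.spread, self.kept)


@dataclass
class EnsembleModel:
    """k kernel ridge machines, each trained on the structures outside one fold."""

    param: str
    fold_models: list[KRRModel]
    fold_assignment: dict[str, int]
    k: int
    kp: KernelParams
    lam: float
    rep_params: RepParams

    def __post_init__(self):
        if self.k < 2 or len(self.fold_models) != self.k:
            raise ValueError("need k >= 2 fold models")


def fit_ensemble(
    d: Dataset,
    param: str,
    kp: KernelParams | None = None,
    lam: float | None = None,
    rep_params: RepParams | None = None,
    k: int = 5,
    seed: int = 0,
    cache: dict | None = None,
) -> EnsembleModel:
    """Split labelled structures into k seeded folds and train one model per fold.

    When ``kp`` is omitted, a Laplacian kernel with the median-heuristic
    length scale of the training representations is used.
    """
    rep_params = rep_params or RepParams()
    sids = d.structure_ids_with(param)
    if len(sids) < k:
        raise ValueError(f"{len(sids)} labelled structures is fewer than k={k}")
    folds = structure_folds(sids, k, seed)
    assignment = {sid: fi for fi, fold in enumerate(folds) for sid in fold}
    if cache is None:
        cache = represent_dataset(d, rep_params)
    if kp is None:
        reps_all, _, _ = assemble_targets(d, param, cache)
        kp = KernelParams("laplacian", median_heuristic_sigma(reps_all, "laplacian"))
    models = []
    for fi in range(k):
        train_ids = [s for s in sids if assignment[s] != fi]
        reps, y, _ = assemble_targets(d, param, cache, structure_ids=train_ids)
        models.append(fit_krr_model(param, reps, y, kp, lam, rep_params))
    lam_val = models[0].lam
    return EnsembleModel(param, models, assignment, k, kp, lam_val, rep_params)


def predict_with_spread(
    e: EnsembleModel,
    d: Dataset,
    keys: Sequence[LabelRecord] | None = None,
    cache: dict | None = None,
) -> list[EnsemblePrediction]:
    """Predict every target with all k fold models.

    ``keys`` defaults to the dataset's labels for the ensemble's parameter
    (their values are ignored; only the (structure, atoms) keys matter).
    mean = arithmetic mean of the k fold predictions; spread = their
    population standard deviation, in the parameter's unit.
    """
    if keys is None:
        keys = d.labels_for(e.param)
    keys = [r for r in keys if r.param == e.param]
    if not keys:
        return []
    if cache is None:
        target_d = Dataset(structures=dict(d.structures),
                           labels=list(keys))
        cache = represent_dataset(target_d, e.rep_params)
    reps = [rep_for_label(r, cache) for r in keys]
    per_fold = np.stack([krr_predict(m, reps) for m in e.fold_models])
    means = per_fold.mean(axis=0)
    spreads = per_fold.std(axis=0)  # population SD (ddof=0)
    spreads[np.ptp(per_fold, axis=0) == 0.0] = 0.0  # coincident folds → exactly 0
    return [
        EnsemblePrediction(r.structure_id, r.param, r.atoms, float(mu), float(sd))
        for r, mu, sd in zip(keys, means, spreads)
    ]


def apply_filter(
    preds: Sequence[EnsemblePrediction], policy: FilterPolicy
) -> tuple[list[EnsemblePrediction], list[EnsemblePrediction]]:
    """Partition predictions into (kept, excluded) by spread ≤ cutoff.

    Order is preserved within each partition; the returned predictions
    carry their kept flag.
    """
    kept, excluded = [], []
    for p in preds:
        ok = p.spread <= policy.cutoff_for(p.param)
        tagged = EnsemblePrediction(p.structure_id, p.param, p.atoms,
                                    p.mean, p.spread, kept=ok)
        (kept if ok else excluded).append(tagged)
    return kept, excluded


@dataclass
class AdaptiveResult:
    """Selected structure ids (in acquisition order) and a per-iteration report."""

    selected: list[str]
    report: pd.DataFrame


def _structure_scores(preds_by_param: dict[str, list[EnsemblePrediction]],
                      z_score: bool, use_max: bool) -> dict[str, float]:
    """Aggregate per-environment spreads to one acquisition score per structure.

    Single parameter: the mean (or max) of the structure's environment
    spreads.  Multiple parameters: spreads are z-scored within each
    parameter first so ppm and Hz are commensurable, then averaged.
    """
    per_param_scores: dict[str, dict[str, float]] = {}
    for param, preds in preds_by_param.items():
        spreads = np.array([p.spread for p in preds])
        if z_score and len(preds_by_param) > 1:
            sd = spreads.std() or 1.0
            spreads = (spreads - spreads.mean()) / sd
        by_sid: dict[str, list[float]] = {}
        for p, sp in zip(preds, spreads):
            by_sid.setdefault(p.structure_id, []).append(float(sp))
        agg = max if use_max else (lambda v: float(np.mean(v)))
        per_param_scores[param] = {sid: agg(v) for sid, v in by_sid.items()}
    sids = set().union(*(s.keys() for s in per_param_scores.values()))
    return {
        sid: float(np.mean([s[sid] for s in per_param_scores.values() if sid in s]))
        for sid in sids
    }


def adaptive_sample(
    superset: Dataset,
    params: str | Sequence[str],
    batch: int = 100,
    initial: int = 100,
    n_iter: int = 3,
    kp: KernelParams | None = None,
    lam: float | None = None,
    rep_params: RepParams | None = None,
    k: int = 5,
    seed: int = 0,
    heldout: Dataset | None = None,
    score_max: bool = False,
    cache: dict | None = None,
    held_cache: dict | None = None,
) -> AdaptiveResult:
    """Variance-ranked active learning over a labelled superset.

    Iteration 0 draws ``initial`` structures uniformly at random (seeded).
    Each subsequent iteration trains a k-fold ensemble per parameter on the
    current training set, predicts all remaining superset structures, scores
    each candidate structure by the mean of its environments' spreads (ties
    broken by structure id), and moves the ``batch`` highest-scoring
    structures into the training set.  The report records per-iteration
    held-out MAE when a held-out dataset is supplied.  The k-fold split is
    re-randomized (seeded) each iteration.
    """
    params = [params] if isinstance(params, str) else list(params)
    rep_params = rep_params or RepParams()
    all_ids = [sid for sid in superset.structures
               if any(superset.labels_for(p, [sid]) for p in params)]
    if len(all_ids) < initial + batch * n_iter:
        raise ValueError(
            f"superset has {len(all_ids)} labelled structures; "
            f"need >= {initial + batch * n_iter}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_ids))
    selected = [all_ids[i] for i in order[:initial]]
    remaining = [sid for sid in all_ids if sid not in set(selected)]

    if cache is None:
        cache = represent_dataset(superset, rep_params)
    if held_cache is None and heldout is not None:
        held_cache = represent_dataset(heldout, rep_params)

    rows = []

    def record(iteration: int, new_ids: list[str]):
        row = {"iteration": iteration, "train_size": len(selected),
               "selected_ids": ";".join(new_ids)}
        if heldout is not None:
            train = superset.subset(selected)
            for param in params:
                ens = fit_ensemble(train, param, kp, lam, rep_params, k,
                                   seed=seed + 31 * iteration, cache=cache)
                preds = predict_with_spread(ens, heldout, cache=held_cache)
                ref = {r.key: r.value for r in heldout.labels_for(param)}
                err = np.array([p.mean - ref[p.key] for p in preds])
                row[f"mae_{param}"] = float(np.abs(err).mean())
                row[f"rmse_{param}"] = float(np.sqrt((err**2).mean()))
                row[f"maxe_{param}"] = float(np.abs(err).max())
        rows.append(row)

    record(0, selected)
    for it in range(1, n_iter + 1):
        if not remaining:
            break
        train = superset.subset(selected)
        preds_by_param = {}
        for param in params:
            ens = fit_ensemble(train, param, kp, lam, rep_params, k,
                               seed=seed + 31 * it, cache=cache)
            keys = [r for r in superset.labels
                    if r.param == param and r.structure_id in set(remaining)]
            preds_by_param[param] = predict_with_spread(ens, superset, keys, cache=cache)
        scores = _structure_scores(preds_by_param, z_score=True, use_max=score_max)
        take = min(batch, len(remaining))
        ranked = sorted(remaining, key=lambda sid: (-scores.get(sid, -np.inf), sid))
        new_ids = ranked[:take]
        selected.extend(new_ids)
        chosen = set(new_ids)
        remaining = [sid for sid in remaining if sid not in chosen]
        record(it, new_ids)

    return AdaptiveResult(selected=selected, report=pd.DataFrame(rows))
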