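"""Error metrics, learning curves, and candidate-structure discrimination.

Errors are reported as the (MAE, RMSE, MaxE) triple in the parameter's
unit.  Candidate 3-D structures (diastereomers, conformers) are ranked
against one experimental label set by per-parameter MAE; when several
parameters are combined, the combined score is the geometric mean of the
per-parameter MAEs, so a candidate must fit *all* parameters to rank well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .krr import assemble_targets, fit_krr_model, krr_predict, KernelParams, median_heuristic_sigma
from .representations import RepParams, represent_dataset
from .structures import Dataset, LabelRecord
from .uncertainty import EnsemblePrediction, FilterPolicy

__all__ = [
    "ErrorReport",
    "CandidateScore",
    "error_report",
    "learning_curve",
    "rank_candidates",
]


@dataclass(frozen=True)
class ErrorReport:
    """MAE/RMSE/MaxE for one parameter (maxe ≥ rmse ≥ mae ≥ 0 always)."""

    param: str
    n_total: int
    n_kept: int
    mae: float
    rmse: float
    maxe: float
    units: str = ""

    def __post_init__(self):
        if not (self.maxe >= self.rmse - 1e-12 and self.rmse >= self.mae - 1e-12
                and self.mae >= 0):
            raise ValueError("expected maxe >= rmse >= mae >= 0")
        if self.n_kept > self.n_total:
            raise ValueError("n_kept cannot exceed n_total")


_UNITS = {"shift_1H": "ppm", "shift_13C": "ppm", "j1_CH": "Hz"}


def error_report(pred, ref, param: str, n_total: int | None = None) -> ErrorReport:
    """MAE, RMSE and MaxE between paired prediction and reference values."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("pred and ref must be non-empty paired 1-D sequences")
    err = pred - ref
    return ErrorReport(
        param=param,
        n_total=len(pred) if n_total is None else n_total,
        n_kept=len(pred),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        maxe=float(np.abs(err).max()),
        units=_UNITS.get(param, ""),
    )


def learning_curve(
    d: Dataset,
    sizes: Sequence[int],
    n_repeats: int,
    param: str,
    kp: KernelParams | None = None,
    lam: float | None = None,
    rep_params: RepParams | None = None,
    seed: int = 0,
    heldout: Dataset | None = None,
) -> pd.DataFrame:
    """Held-out MAE as a function of training-set size.

    When no held-out dataset is supplied, a fixed held-out split (the
    structures left over beyond ``max(sizes)``) is carved from ``d`` by the
    seed.  Within a repeat the training subsets are nested — larger sets
    contain smaller ones — so curves are monotone-comparable.  Deterministic
    given ``seed``.
    """
    rep_params = rep_params or RepParams()
    sizes = sorted(int(s) for s in sizes)
    sids = d.structure_ids_with(param)
    rng = np.random.default_rng(seed)

    if heldout is None:
        if sizes[-1] >= len(sids):
            raise ValueError("max size must leave a non-empty held-out set")
        order = rng.permutation(len(sids))
        held_ids = [sids[i] for i in order[: len(sids) - sizes[-1]]]
        pool = [sids[i] for i in order[len(sids) - sizes[-1]:]]
        heldout_d = d.subset(held_ids)
    else:
        if sizes[-1] > len(sids):
            raise ValueError("max size exceeds available structures")
        pool = list(sids)
        heldout_d = heldout

    cache = represent_dataset(d, rep_params)
    held_cache = represent_dataset(heldout_d, rep_params)
    reps_te, y_te, _ = assemble_targets(heldout_d, param, held_cache)

    rows = []
    for rep_i in range(n_repeats):
        order = rng.permutation(len(pool))
        for size in sizes:
            train_ids = [pool[i] for i in order[:size]]
            reps_tr, y_tr, _ = assemble_targets(d, param, cache, structure_ids=train_ids)
            kp_use = kp or KernelParams("laplacian", median_heuristic_sigma(reps_tr, "laplacian"))
            model = fit_krr_model(param, reps_tr, y_tr, kp_use, lam, rep_params)
            mae = float(np.abs(krr_predict(model, reps_te) - y_te).mean())
            rows.append({"size": size, "repeat": rep_i, "mae": mae})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CandidateScore:
    """Per-parameter error reports and the combined score for one candidate."""

    candidate_id: str
    reports: dict[str, ErrorReport]
    combined: float

    @property
    def params(self) -> tuple[str, ...]:
        return tuple(self.reports)


def _combine(maes: Sequence[float], how: str) -> float:
    maes = np.asarray(maes, dtype=float)
    if how == "geometric":
        return float(np.exp(np.log(np.maximum(maes, 1e-300)).mean())) if maes.min() > 0 else (
            0.0 if maes.min() == 0 else float("nan"))
    return float(maes.mean())


def rank_candidates(
    expt: Sequence[LabelRecord],
    candidates: Mapping[str, Sequence[EnsemblePrediction]],
    policy: FilterPolicy | None = None,
    combine: str = "geometric",
) -> list[CandidateScore]:
    """Rank candidate structures against one experimental label set.

    Experimental records and candidate predictions are matched on
    (param, atoms) keys — each candidate is its own geometry, so structure
    ids are ignored.  When a filter policy is active, any key whose spread
    exceeds the cutoff for *any* candidate is excluded for *all*
    candidates, so every candidate is scored on the identical kept-key
    set.  Candidates are sorted ascending by combined score (geometric
    mean of per-parameter MAEs by default); the ordering is invariant to
    the order candidates are supplied in.
    """
    if combine not in ("geometric", "arithmetic"):
        raise ValueError("combine must be 'geometric' or 'arithmetic'")
    expt_by_key = {(r.param, r.atoms): r.value for r in expt}
    cand_preds: dict[str, dict[tuple, EnsemblePrediction]] = {}
    for cid, preds in candidates.items():
        table = {(p.param, p.atoms): p for p in preds}
        missing = set(expt_by_key) - set(table)
        if missing:
            raise ValueError(f"candidate {cid!r} missing prediction(s) for {sorted(missing)[:3]}")
        cand_preds[cid] = table

    keys = sorted(expt_by_key)
    if policy is not None:
        keys = [
            key for key in keys
            if all(cand_preds[cid][key].spread <= policy.cutoff_for(key[0])
                   for cid in cand_preds)
        ]
        if not keys:
            raise ValueError("no keys survive the variance filter for all candidates")

    n_total_by_param: dict[str, int] = {}
    for param, _ in expt_by_key:
        n_total_by_param[param] = n_total_by_param.get(param, 0) + 1

    scores = []
    for cid in sorted(cand_preds):
        reports: dict[str, ErrorReport] = {}
        for param in sorted({k[0] for k in keys}):
            pkeys = [k for k in keys if k[0] == param]
            pred = [cand_preds[cid][k].mean for k in pkeys]
            ref = [expt_by_key[k] for k in pkeys]
            reports[param] = error_report(pred, ref, param,
                                          n_total=n_total_by_param[param])
        combined = _combine([r.mae for r in reports.values()], combine)
        scores.append(CandidateScore(cid, reports, combined))
    scores.sort(key=lambda s: (s.combined, s.candidate_id))
    return scores
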