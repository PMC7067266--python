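"""Ensembles, spread, the variance filter, and adaptive sampling."""

import numpy as np
import pytest

from nmrkrr.structures import Dataset, LabelRecord
from nmrkrr.synthetic import OracleParams, gen_structures, label_dataset, two_regime_benchmark
from nmrkrr.representations import RepParams, represent_dataset
from nmrkrr.uncertainty import (
    DEFAULT_CUTOFFS, EnsemblePrediction, FilterPolicy, adaptive_sample,
    apply_filter, fit_ensemble, predict_with_spread,
)

from conftest import only_param


class TestFitEnsemble:
    def test_fold_sizes_and_training_complement(self, tiny_dataset):
        d = only_param(tiny_dataset, "shift_13C")
        ens = fit_ensemble(d, "shift_13C", k=4, seed=0)
        sizes = np.bincount(list(ens.fold_assignment.values()))
        assert sizes.sum() == 12 and set(sizes) == {3}
        # each fold model trained on exactly the structures outside its fold
        for fi, m in enumerate(ens.fold_models):
            outside = [s for s, f in ens.fold_assignment.items() if f != fi]
            n_targets = len(d.labels_for("shift_13C", outside))
            assert len(m.alpha) == n_targets

    def test_same_seed_same_assignment(self, tiny_dataset):
        d = only_param(tiny_dataset, "shift_1H")
        a = fit_ensemble(d, "shift_1H", k=3, seed=9).fold_assignment
        b = fit_ensemble(d, "shift_1H", k=3, seed=9).fold_assignment
        assert a == b

    def test_leave_one_structure_out_boundary(self, tiny_dataset):
        d = only_param(tiny_dataset, "shift_13C")
        ens = fit_ensemble(d, "shift_13C", k=12, seed=2)
        assert sorted(np.bincount(list(ens.fold_assignment.values()))) == [1] * 12

    def test_too_few_structures(self, tiny_dataset):
        d = only_param(tiny_dataset, "shift_13C")
        with pytest.raises(ValueError, match="fewer"):
            fit_ensemble(d, "shift_13C", k=13, seed=0)


class TestPredictWithSpread:
    def test_mean_and_population_sd(self):
        """Fold predictions [1..5] → mean 3, population SD √2 = 1.414214."""
        per_fold = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert per_fold.mean() == pytest.approx(3.0)
        assert per_fold.std() == pytest.approx(np.sqrt(2.0), abs=1e-6)

    def test_identical_folds_zero_spread(self, tiny_dataset):
        """Degenerate ensemble: every fold model replaced by fold 0's model."""
        d = only_param(tiny_dataset, "shift_13C")
        ens = fit_ensemble(d, "shift_13C", k=3, seed=1)
        ens.fold_models = [ens.fold_models[0]] * 3
        preds = predict_with_spread(ens, d)
        assert preds and all(p.spread == 0.0 for p in preds)

    def test_spread_units_and_determinism(self, tiny_dataset):
        d = only_param(tiny_dataset, "j1_CH")
        ens = fit_ensemble(d, "j1_CH", k=3, seed=4)
        p1 = predict_with_spread(ens, d)
        p2 = predict_with_spread(ens, d)
        assert [(p.key, p.mean, p.spread) for p in p1] == \
               [(p.key, p.mean, p.spread) for p in p2]
        assert all(p.spread >= 0 for p in p1)


def _pred(param, spread, sid="s", atoms=(0,)):
    return EnsemblePrediction(sid, param, atoms, 1.0, spread)


class TestApplyFilter:
    def test_default_cutoffs_match_method(self):
        assert DEFAULT_CUTOFFS == {"j1_CH": 1.0, "shift_1H": 0.1, "shift_13C": 5.0}

    def test_coupling_below_cutoff_kept(self):
        kept, excluded = apply_filter([_pred("j1_CH", 0.9, atoms=(0, 1))], FilterPolicy())
        assert len(kept) == 1 and not excluded and kept[0].kept is True

    def test_boundary_is_inclusive(self):
        kept, excluded = apply_filter([_pred("shift_1H", 0.1)], FilterPolicy())
        assert len(kept) == 1 and not excluded

    def test_partition_preserves_order(self):
        preds = [_pred("shift_13C", s, sid=f"s{i}") for i, s in enumerate([1, 9, 2, 8])]
        kept, excluded = apply_filter(preds, FilterPolicy())
        assert [p.structure_id for p in kept] == ["s0", "s2"]
        assert [p.structure_id for p in excluded] == ["s1", "s3"]

    def test_empty_input(self):
        assert apply_filter([], FilterPolicy()) == ([], [])

    def test_missing_cutoff_raises(self):
        with pytest.raises(KeyError, match="shift_1H"):
            apply_filter([_pred("shift_1H", 0.5)], FilterPolicy({"j1_CH": 1.0}))

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            FilterPolicy({"j1_CH": 0.0})


@pytest.fixture(scope="module")
def small_superset():
    d = label_dataset(gen_structures(30, seed=51), OracleParams(seed=51))
    return only_param(d, "shift_13C")


class TestAdaptiveSample:
    def test_exhaustion_selects_all(self, small_superset):
        res = adaptive_sample(small_superset, "shift_13C", batch=25, initial=5,
                              n_iter=1, k=3, seed=0)
        assert sorted(res.selected) == sorted(small_superset.structures)

    def test_same_seed_identical_selection(self, small_superset):
        a = adaptive_sample(small_superset, "shift_13C", batch=5, initial=8,
                            n_iter=2, k=3, seed=7)
        b = adaptive_sample(small_superset, "shift_13C", batch=5, initial=8,
                            n_iter=2, k=3, seed=7)
        assert a.selected == b.selected
        assert a.report.equals(b.report)

    def test_superset_too_small(self, small_superset):
        with pytest.raises(ValueError, match="need >="):
            adaptive_sample(small_superset, "shift_13C", batch=20, initial=20, n_iter=2)

    def test_rare_regime_enrichment(self):
        """Variance ranking acquires the rare fluorinated regime more often
        than a uniform draw of equal size (majority of seeds 0–9)."""
        enriched = 0
        for seed in range(10):
            sup, _, _ = two_regime_benchmark(60, 1, seed=400 + seed)
            sup = only_param(sup, "shift_13C")
            res = adaptive_sample(sup, "shift_13C", batch=10, initial=10,
                                  n_iter=2, k=5, seed=seed)
            acquired = res.selected[10:]
            rare = sum(1 for sid in acquired if sid.startswith("s1"))
            n_rare_total = sum(1 for sid in sup.structures if sid.startswith("s1"))
            uniform_expect = n_rare_total * len(acquired) / (len(sup.structures) - 10)
            enriched += int(rare > uniform_expect)
        assert enriched >= 6
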