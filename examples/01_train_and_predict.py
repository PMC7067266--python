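"""Train a 5-fold ensemble on a synthetic benchmark and predict held-out shifts.

Builds 120 training and 30 held-out molecules with oracle ¹³C shift labels,
trains a kernel-ridge ensemble, and prints the held-out error statistics.
The MAE (ppm) is the headline accuracy; the spread column is the
across-fold standard deviation that later drives the variance filter.
"""

import numpy as np

from nmrkrr import make_benchmark
from nmrkrr.evaluation import error_report
from nmrkrr.uncertainty import fit_ensemble, predict_with_spread

superset, heldout, _ = make_benchmark(120, 30, seed=11)

param = "shift_13C"
ensemble = fit_ensemble(superset, param, k=5, seed=11)
print(f"trained {ensemble.k}-fold ensemble for {param} "
      f"({ensemble.kp.kind} kernel, sigma={ensemble.kp.sigma:.1f})")

preds = predict_with_spread(ensemble, heldout)
reference = {r.key: r.value for r in heldout.labels_for(param)}
rep = error_report([p.mean for p in preds],
                   [reference[p.key] for p in preds], param)
print(f"held-out n={rep.n_kept}  MAE={rep.mae:.2f} {rep.units}  "
      f"RMSE={rep.rmse:.2f}  MaxE={rep.maxe:.2f}")
print(f"median across-fold spread: {np.median([p.spread for p in preds]):.2f} ppm")
# MAE ~2-3 ppm on a 200 ppm label range: the machine recovers the smooth
# geometry->shift mapping from ~130 labelled carbon environments per fold.
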