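"""One-at-a-time hyperparameter sweep on a toy problem.

Sweeps the hidden size and epoch count around a reduced base configuration
and reports the best grid point (minimum test RMSE, ties broken by MAPE).
The full grids used for serious tuning are in
``fruitrelax.evaluation.DEFAULT_GRIDS`` (neurons 40–60, lr 0.001–0.009,
drop period 70–90, epochs 400–900).
"""

import fruitrelax as fr
from fruitrelax import evaluation, pipeline

cfg = pipeline.RunConfig(
    seed=0,
    n_per_group=5,
    protocol=fr.CompressionProtocol(hold_duration_s=5.0),
    sequence_stride=2,
    lstm=fr.LSTMConfig(hidden_size=8, epochs=40),
)
population, traces = pipeline.generate(cfg)
curves = pipeline.prepare_curves(cfg, population, traces)
split = fr.split_dataset(population, 0.2, pipeline.sub_seed(cfg.seed, "split"))
train_curves = [curves[i] for i in split.train_ids]
test_curves = [curves[i] for i in split.test_ids]
normalizer = fr.fit_normalizer(list(curves.values()))

results = evaluation.sweep(
    train_curves, test_curves, normalizer, cfg.lstm,
    grids={"hidden_size": [4, 8, 16], "epochs": [20, 40]},
)
for r in results:
    print(f"  {r.param}={r.value:<4}  train MAPE {r.train_mape:6.2f}%  "
          f"test MAPE {r.test_mape:6.2f}%  test RMSE {r.test_rmse:.3e} MPa")
best = evaluation.select_best(results)
print(f"\nbest grid point: {best.param} = {best.value} "
      f"(test RMSE {best.test_rmse:.3e} MPa, MAPE {best.test_mape:.2f}%)")
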