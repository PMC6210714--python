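"""Train an LSTM force regressor on one synthetic subject.

Runs the full path -- simulate, condition, select channels, build
randomly-truncated sets, train with the RMSE% loss and six-epoch early
stopping -- at desk scale (Q = 289, 1000 training samples).  Takes about
a minute on one CPU core.
"""

import numpy as np

import emgforce as ef

Q = 289
patterns = [ef.ForcePattern(lv) for lv in (0.35, 0.50, 0.65)]
recs = [r for r in ef.make_cohort(1, patterns, cycles_per_level=8, master_seed=3)]
print("preprocessing 3 recordings ...")
signals = ef.cohort_to_paired(recs, Q=Q, seed=3)

alloc = ef.allocate(signals, "subject_dependent", subject=0, seed=3)
train, dev, _ = ef.build_standard_sets(alloc.train, alloc.dev, alloc.train,
                                       Q, sizes=(1000, 100, 100), seed=3)
test = ef.random_truncation(alloc.test[0], Q, 100, seed=99, role="test")

model = ef.build_lstm(Q, ef.LSTMSpec(hidden_units=48, frame_size=17), seed=3)
print(f"LSTM: {Q // 17} timesteps x 17 features, 48 hidden units, "
      f"{model.n_parameters():,} parameters")

cfg = ef.TrainConfig(batch_size=32, max_epochs=30, patience=6, lr=1e-3, seed=3)
model, hist = ef.train_model(model, train, dev, cfg)
print(f"trained {len(hist.dev_loss)} epochs "
      f"(early stop: {hist.stopped_early}), best epoch {hist.best_epoch + 1} "
      f"with dev RMSE% {min(hist.dev_loss):.2f}")

report = ef.evaluate_model(model, test)
print(f"test RMSE%: {report.mean:.2f} +/- {report.sd:.2f} over {len(test)} samples")
print("(values below ~15% mean the predicted force trace follows the")
print(" measured trapezoids closely, including windows that cut across cycles)")

pred = model.forward(test.x[0])
ba = ef.bland_altman(test.y[0], pred)
print(f"Bland-Altman on one test window: mean diff {ba.mean_diff:+.4f}, "
      f"limits [{ba.lower:+.4f}, {ba.upper:+.4f}], "
      f"{ba.fraction_within_limits:.0%} of points within limits")
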