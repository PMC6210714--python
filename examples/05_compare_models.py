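"""Compare CNN, LSTM and C-LSTM with rank statistics, at toy scale.

Uses hand-built trapezoid pools (skipping the simulation stage) so the
whole comparison runs in a few seconds; the point is the study machinery:
per-family reports, and pairwise Kruskal-Wallis tests on per-sample RMSE%.
"""

import numpy as np

import emgforce as ef

Q = 64  # 8 x 8 for the CNN
rng = np.random.default_rng(1)

signals = []
for subj in range(2):
    for lv in (0.35, 0.5, 0.65):
        cycle = np.concatenate([np.linspace(0, lv, Q // 4, endpoint=False),
                                np.full(Q - Q // 4 - Q // 8, lv),
                                np.linspace(lv, 0, Q // 8, endpoint=False)])
        y = np.tile(cycle, 10)
        x = y + 0.03 * rng.standard_normal(y.size)
        signals.append(ef.PairedSignal(x=x, y=y, Q=Q, subject_id=subj, level=lv))

kw = {
    "cnn": dict(blocks=(ef.ConvBlockSpec(4), ef.ConvBlockSpec(8)),
                dropout_rate=0.25),
    "lstm": dict(spec=ef.LSTMSpec(hidden_units=16, frame_size=8)),
    "clstm": dict(front=ef.ConvBlockSpec(8, kernel=8, stride=4, pool=1),
                  spec=ef.LSTMSpec(hidden_units=16)),
}
cfg = ef.TrainConfig(batch_size=32, max_epochs=15, patience=6, lr=3e-3, seed=1)

res = ef.run_circumstance_study(signals, "multi_subject",
                                families=("cnn", "lstm", "clstm"),
                                sizes=(400, 50, 50), cfg=cfg,
                                model_kwargs=kw, seed=1)

print("multi-subject circumstance, per-subject test RMSE%:")
for family, reports in res.reports.items():
    means = ", ".join(f"S{r.subject}: {r.mean:.2f}" for r in reports)
    print(f"  {family:6s} {means}")

print("\npairwise Kruskal-Wallis on pooled per-sample RMSE%:")
for (a, b), (H, p) in sorted(res.pairwise.items()):
    verdict = "significant" if p < 0.05 else "not significant"
    print(f"  {a} vs {b}: H = {H:.2f}, p = {p:.4f} ({verdict} at 0.05)")
print("\nA small p means the two families' per-sample error distributions")
print("differ; the sequence models typically beat the CNN on this task.")
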