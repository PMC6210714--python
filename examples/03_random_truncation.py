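"""Build training sets by random truncation.

Whole contraction cycles make a tiny, fixed-pattern data set; drawing
Q-point windows at uniformly random 1-based starts in [1, (P-1)Q] turns
P cycles into as many varied-pattern samples as training needs.
"""

import numpy as np

import emgforce as ef

Q = 289
rng = np.random.default_rng(0)

# ten trapezoidal cycles, resampled so each is exactly Q points long
cycle = np.concatenate([np.linspace(0, 0.5, Q // 4, endpoint=False),
                        np.full(Q - Q // 4 - Q // 8, 0.5),
                        np.linspace(0.5, 0, Q // 8, endpoint=False)])
y = np.tile(cycle, 10)
x = y + 0.02 * rng.standard_normal(y.size)
pool = ef.PairedSignal(x=x, y=y, Q=Q, subject_id=0, level=0.5)
print(f"pool: P = {pool.n_cycles} cycles of Q = {Q} points "
      f"({pool.x.size} samples concatenated)")

fixed = ef.fixed_pattern_sets([pool], Q)
print(f"fixed-pattern set : {len(fixed)} samples (one per cycle)")

varied = ef.random_truncation(pool, Q=Q, R=2000, seed=1)
print(f"varied-pattern set: {len(varied)} samples from "
      f"{(pool.n_cycles - 1) * Q} admissible starts")
print(f"start range drawn : [{varied.starts.min()}, {varied.starts.max()}] "
      f"(admissible [1, {(pool.n_cycles - 1) * Q}])")

# windows cut across cycle boundaries, so samples show ramps, plateaus and
# rests at arbitrary phases -- unlike the stereotyped whole-cycle samples
crossings = np.sum((varied.starts - 1) % Q != 0)
print(f"windows not aligned to a cycle start: {crossings}/{len(varied)}")

counts = np.bincount(varied.starts)[1:]
print(f"empirical start frequency: min {counts.min()}, max {counts.max()} "
      f"(uniform draws with replacement)")
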