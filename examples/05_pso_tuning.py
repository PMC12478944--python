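"""Tune the SVDD penalty and kernel width by particle-swarm optimisation.

Runs a small swarm over (C, sigma) on an easy two-dimensional toy class,
with 10-fold cross-validated own-class acceptance as the (negated) fitness.
"""

from pigsound.multisvdd import PSOConfig, pso_tune
from pigsound.synthetic import gen_feature_set

x, y = gen_feature_set(60, separation=10.0, d=2, seed=42)
target_class = x[y == 0]

cfg = PSOConfig(swarm_size=8, max_iter=15, n_folds=10, seed=0)
C, sigma, trace = pso_tune(target_class, cfg)

print(f"best C     : {C:.3f}")
print(f"best sigma : {sigma:.3f}")
print(f"fitness    : {trace[-1]:.3f}  (negative mean CV acceptance; -1 is perfect)")
print(f"best-so-far trace: {[round(v, 3) for v in trace[:6]]} ...")
# The fitness is the negative fraction of held-out own-class points the
# sphere accepts, averaged over ten folds; the swarm minimises it.
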