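"""Train the two-sphere recogniser on synthetic clips and classify new ones.

A small version of the end-to-end benchmark: 60 training clips per class,
10 test clips each of cough-like, scream-like and distractor sounds, clip
labels decided by per-frame fusion and majority voting.
"""

import numpy as np

from pigsound import NoiseSpec, extract_features, gen_clip
from pigsound import synthetic as syn
from pigsound.multisvdd import MultiSVDDModel, evaluate, recognize_features
from pigsound.wsvdd import fit_wsvdd, median_sigma

rng = np.random.default_rng(0)
noise = NoiseSpec(snr_db=15.0)


def clip_features(spec):
    w, _ = gen_clip(spec, noise, rng)
    return extract_features(w).vectors


def sphere(train):
    zn = (train - train.mean(0)) / train.std(0)
    return fit_wsvdd(train, C=0.02, sigma=0.35 * median_sigma(zn))


train_cough = np.vstack([clip_features(syn.COUGH_LIKE) for _ in range(60)])
train_scream = np.vstack([clip_features(syn.SCREAM_LIKE) for _ in range(60)])
model = MultiSVDDModel(model_cough=sphere(train_cough), model_scream=sphere(train_scream))

truth, pred = [], []
for label, specs in [
    ("cough", [syn.COUGH_LIKE]),
    ("scream", [syn.SCREAM_LIKE]),
    ("other", list(syn.OTHER_VARIANTS)),
]:
    for k in range(10):
        vote, trace = recognize_features(model, clip_features(specs[k % len(specs)]))
        truth.append(label)
        pred.append(vote)

report = evaluate(pred, truth)
correct = sum(p == t for p, t in zip(pred, truth))
print(f"clip accuracy: {100 * correct / len(truth):.1f}%  ({correct}/{len(truth)})")
for cls in report.classes:
    print(
        f"  {cls:7s} accuracy {report.accuracy[cls]:5.1f}%  "
        f"precision {report.precision[cls] if report.precision[cls] is not None else float('nan'):5.1f}%  "
        f"recall {report.recall[cls] if report.recall[cls] is not None else float('nan'):5.1f}%"
    )
# A clip is "cough" when its frames fall inside the cough sphere but outside
# the scream sphere (and symmetrically); frames outside both vote "other".
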