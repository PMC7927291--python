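"""Compare the accuracy of two prediction models sharing the same test sample.

Two models predict the same observed scores, so their accuracy correlations
are dependent; the Williams/Steiger t test (df = n - 3) accounts for the
correlation between the two prediction vectors.
"""

import numpy as np

import rvrfusion as rf

rng = np.random.default_rng(3)
n = 547
y = rng.normal(2.5, 0.8, size=n)
model_a = y + rng.normal(0, 1.0, size=n)   # the stronger model
model_b = y + rng.normal(0, 1.6, size=n)   # the weaker model

result = rf.steiger_from_predictions(y, model_a, model_b)
r_a = np.corrcoef(y, model_a)[0, 1]
r_b = np.corrcoef(y, model_b)[0, 1]

print(f"accuracy of model A: r = {r_a:.3f}")
print(f"accuracy of model B: r = {r_b:.3f}")
print(f"T2 = {result.t2:.3f}, df = {result.df}, one-sided p = {result.p_one_sided:.2e}")

print(
    "\nA positive T2 favours model A; the one-sided p is the upper tail of "
    "Student t\nat df = n - 3.  The same conversion applied to a published "
    "statistic, e.g.\nT2 = 5.170 at df = 544, gives "
    f"p = {rf.t_tail_p(5.170, 544):.2e}."
)
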