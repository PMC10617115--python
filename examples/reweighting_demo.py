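"""How the cross-entropy reweighting shifts attention toward hard samples.

Three samples with constant predicted probabilities across two iterations:
one well classified (P(true) = 0.95), one uncertain (0.6), one badly
misclassified (0.1).  Weights start uniform; after the first update the
weight ordering follows the cross-entropy, and further updates with
unchanged predictions leave the weights fixed (all ratios are 1).
"""

import numpy as np

from rbfs import cross_entropy_scores, reset_weights, update_weights

probs = np.array([[0.95, 0.05], [0.60, 0.40], [0.10, 0.90]])
labels = np.array([0, 0, 0])  # true class is 0 for all three

w = reset_weights(3)
print("initial weights:       ", np.round(w.w, 4))

d1 = cross_entropy_scores(probs, labels, iteration=1)
print("cross-entropy d_j:     ", np.round(d1.d, 4))

w = update_weights(w, d1)  # first update: ratio = raw cross-entropy
print("after first update:    ", np.round(w.w, 4))

d2 = cross_entropy_scores(probs, labels, iteration=2)
w = update_weights(w, d2, d1)  # unchanged predictions: ratios all 1
print("after second update:   ", np.round(w.w, 4))
# The misclassified sample (P(true)=0.1) ends up carrying ~85% of the total
# weight; a sample the model already handles well is nearly ignored.
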