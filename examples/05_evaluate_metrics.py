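"""The two evaluation metrics: macro-accuracy MAP and rank-based cmAP.

MAP (as used for single-species recordings) is the mean over classes of
per-class identification accuracy. cmAP (as used for soundscape evaluations)
ranks all segments by each class's score and averages rank-based average
precision over the ground-truth classes. They answer different questions and
can disagree, as below.
"""

import numpy as np

from chirpid import average_precision_ranked, cmap_rankbased, map_paper

true = np.array([0, 0, 0, 1, 1, 2])
pred = np.array([0, 0, 1, 1, 1, 0])
print("true labels     :", true.tolist())
print("predicted labels:", pred.tolist())
print(f"MAP (macro accuracy) = {map_paper(pred, true, 3):.4f}  "
      "(mean of 2/3, 2/2, 0/1)")

scores = np.array([
    [0.7, 0.2, 0.1],
    [0.6, 0.3, 0.1],
    [0.3, 0.5, 0.2],
    [0.2, 0.7, 0.1],
    [0.1, 0.8, 0.1],
    [0.4, 0.3, 0.3],
])
print(f"cmAP (rank-based)    = {cmap_rankbased(scores, true):.4f}")
print(f"AveP of rel=[1,0,1]  = {average_precision_ranked([1, 0, 1]):.4f}  "
      "(= (1/1 + 2/3)/2 = 5/6)")
print("\ncmAP rewards ranking the true members of a class above everything"
      "\nelse, even when the hard argmax decision is wrong.")
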