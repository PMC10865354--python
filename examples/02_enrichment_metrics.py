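"""Score rankings with normalized LogAUC, the enrichment criterion.

Normalized LogAUC integrates the ROC against log10(false positive rate)
above a floor of 0.1%, then rescales so a random classifier scores 0 and a
perfect classifier scores 1.  It rewards placing ligands at the very top
of the ranked list, which is what matters when only the top of a
billion-molecule screen gets tested.
"""

import numpy as np

from screenopt import ScoredClasses, normalized_logauc

rng = np.random.default_rng(0)

perfect = ScoredClasses(scores_pos=np.arange(20.0), scores_neg=np.arange(1000.0) + 50)
random_ = ScoredClasses(scores_pos=rng.normal(size=20), scores_neg=rng.normal(size=1000))
inverted = ScoredClasses(scores_pos=np.arange(20.0) + 2000, scores_neg=np.arange(1000.0))
partial = ScoredClasses(scores_pos=rng.normal(-1.0, 1, 20), scores_neg=rng.normal(0, 1, 1000))

for name, scored in [("perfect", perfect), ("random", random_),
                     ("inverted", inverted), ("partially enriched", partial)]:
    print(f"{name:>20}: normalized LogAUC = {normalized_logauc(scored):+.4f}")
# Expect +1 for perfect, ~0 for random, -0.169 for worst-possible, and a
# positive intermediate value for the partially enriched ranking.
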