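"""Differential expression and three-group trend-shape classification.

Simulates a 3 conditions x 3 replicates NB count matrix with planted
linear-up and inverted-U features, then runs the two-condition Wald test
(SEN+M vs SEN) and the three-group likelihood-ratio trend test, classifying
each significant feature's shape over Young -> SEN -> SEN+M.
"""

import numpy as np

from isomirseq import (CountSimConfig, PlantedEffect, de_test, lrt_trend,
                       simulate_counts)

effects = (
    [PlantedEffect(f"feat_{i:05d}", "linear-up", (3.0, 2.0))
     for i in range(10)]
    + [PlantedEffect(f"feat_{i:05d}", "inverted-U", (4.0, 0.25))
       for i in range(10, 20)]
)
cfg = CountSimConfig(n_features=800, baseline_log_mean=np.log(400.0),
                     dispersion=0.05, effects=effects, rng_seed=4)
matrix, truth = simulate_counts(cfg)

de = de_test(matrix, "SEN", "SEN+M")
print(f"DE (SEN+M vs SEN): {int(de.called.sum())} of {de.p.notna().sum()} "
      f"features called at FDR < 0.05 and |FC| >= 1.5")

trend = lrt_trend(matrix)
called = trend[trend["shape"] != "flat"]
print(f"LRT trend: {len(called)} features significant; shapes: "
      f"{called['shape'].value_counts().to_dict()}")
print()
planted = trend.iloc[:20][["mean_Young", "mean_SEN", "mean_SEN+M",
                           "fdr", "shape"]]
print(planted.round(3).to_string())
print()
print("Rows 0-9 were planted linear-up (means rise at both transitions);")
print("rows 10-19 inverted-U (senescence-like rise reverted by treatment).")
print("The LRT flags them and the shape classifier separates the two groups.")
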