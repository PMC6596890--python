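"""Distance matching vs demographic and clustering baselines.

On a clone-pair cohort the ground truth is known exactly, so each strategy
can be scored by the fraction of true pairs it recovers.  Self-reported
'race' strata (4-way, 2-way, or a collapsed 4-component mixture) and
PCA + k-means cluster pairing are the usual practice stand-ins.
"""

import numpy as np

from admixpair import (
    evaluate_solution,
    generate_base,
    pam_simple,
    pca_kmeans_match,
    race_match,
    random_match,
)

ds = generate_base(n_pairs=100, K=9, seed=8)
q = ds.cohort.admixture_matrix()

strategies = {
    "greedy GD matching": lambda: pam_simple(ds.cohort),
    "race model 3 (4-comp mixture)": lambda: race_match(ds.cohort, 3, seed=0),
    "race model 1 (4-way label)": lambda: race_match(ds.cohort, 1, seed=0),
    "race model 2 (African / not)": lambda: race_match(ds.cohort, 2, seed=0),
    "random within age/gender": lambda: random_match(ds.cohort, seed=0),
    "PCA + k-means (k=4)": lambda: pca_kmeans_match(q, 4, seed=0, cohort=ds.cohort),
}

print(f"{'strategy':32} {'recovered':>9} {'total GD':>9} {'score':>6}")
for name, fn in strategies.items():
    rep = evaluate_solution(fn(), ds.truth)
    print(
        f"{name:32} {rep.pct_recovered:9.2%} {rep.total_gd:9.3f} {rep.total_score:6d}"
    )
print(
    "\nOnly distance-aware strategies recover the clone pairs; label-based\n"
    "strata do little better than random despite matched demographics."
)
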