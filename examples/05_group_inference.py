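"""Permutation-GLM inference: detect a planted group effect on a brain-state
feature while adjusting for nuisance covariates.

The generator shifts the global state's self-transition probability from
0.90 to 0.80 in the 'group' subjects; the Freedman-Lane permutation test on
per-subject realized self-transitions should detect it decisively.
"""

import numpy as np

import dynfc
from dynfc.synthetic import CovariateEffect

scenario = dynfc.small_scenario(
    n_subjects=200, T=2000, self_transition=0.90, seed=4,
    covariate_effect_map=[CovariateEffect("group", "self_prob:0", -0.10)],
)
_, cohort, truth = dynfc.simulate_cohort(scenario, bold=False)

table = cohort.copy()
table["self_trans_state1"] = truth.realized_matrices[:, 0, 0]

result = dynfc.glm_permutation_scan(
    table,
    responses=["self_trans_state1"],
    covariates=["group", "age", "sex", "motion"],
    term="group",
    n_perm=2000,
    seed=0,
    family="demo",
)
row = result.iloc[0]
print(f"beta = {row.beta:.4f} (planted -0.10)")
print(f"t = {row.t_statistic:.2f}, permutation p = {row.p_perm:.4g}, "
      f"FDR pass = {row.fdr_pass}, n = {row.n}")

grp = cohort["group"] == 1
d = dynfc.cohens_d(table.self_trans_state1[~grp], table.self_trans_state1[grp])
print(f"Cohen's d (non-group vs group) = {d:.2f}")
# beta recovers the planted -0.10 shift; p sits at the permutation floor
# because the effect is overwhelming at n = 200.
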