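"""Per-subject brain-state metrics: fractional occupancy, dwell times,
per-state synchrony, and Markov transition probabilities.
"""

import numpy as np

import dynfc

scenario = dynfc.small_scenario(n_subjects=2, seed=3)
timeseries, _, truth = dynfc.simulate_cohort(scenario)

ph = dynfc.hilbert_phases(dynfc.bandpass_filter(timeseries[0]), trim=10)
kop = dynfc.kop_series(ph)
# here we use the planted (true) state sequence; the pipeline normally uses
# the clustered LEiDA labels
labels = truth.sequences[0][10:-10]
seq = dynfc.StateSequence(labels=labels, K=4, tr=scenario.tr, subject_id="sub-0000")
m = dynfc.subject_metrics(seq, kop)

print("fractional occupancy:", np.round(m.fractional_occupancy, 3))
print("dwell times (s):     ", np.round(m.dwell_time_seconds, 1))
print("state mean sync:     ", np.round(m.state_mean_sync, 3))
print("transition matrix:\n", np.round(m.transition_matrix, 3))
print("no-dwelling matrix:\n", np.round(m.transition_matrix_noself, 3))
# Diagonal dominance of the transition matrix reflects dwelling; the
# no-dwelling matrix conditions on actually leaving the current state.
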