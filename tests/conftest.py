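import numpy as np
import pytest

import dynfc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _analyse_cohort(scenario):
    """Full signal path for a simulated cohort: filter -> phases -> KOP ->
    LEiDA vectors, with ground-truth labels aligned to the trimmed volumes."""
    timeseries, cohort, truth = dynfc.simulate_cohort(scenario)
    vectors, kop_values, true_labels, trims = [], [], [], []
    for i, ts in enumerate(timeseries):
        filtered = dynfc.bandpass_filter(ts)
        phases = dynfc.hilbert_phases(filtered, trim=10)
        vectors.append(dynfc.leida_vectors(phases))
        kop_values.append(dynfc.kop_series(phases).values)
        true_labels.append(truth.sequences[i][phases.trim: scenario.T - phases.trim])
    return {
        "scenario": scenario,
        "cohort": cohort,
        "truth": truth,
        "vectors": np.vstack(vectors),
        "kop": np.concatenate(kop_values),
        "true_labels": np.concatenate(true_labels),
        "n_volumes_each": [v.shape[0] for v in vectors],
    }


@pytest.fixture(scope="session")
def analysed_small_cohort():
    """Default small synthetic cohort pushed through the signal pipeline.

    Session-scoped: several tests interrogate different properties of the
    same end-to-end run.
    """
    return _analyse_cohort(dynfc.small_scenario(seed=7))
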