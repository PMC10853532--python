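"""Synthetic multi-subject BOLD-like cohorts with known dynamic structure.

The generator plants everything the analysis pipeline tries to recover:

* a hidden first-order Markov chain over ``K_true`` brain states per subject;
* per-state *phase-locking templates*: the parcels of the active state's
  community are pulled toward a common oscillator in the 0.02-0.10 Hz band
  (Kuramoto-style sine coupling) while the remaining parcels are driven
  toward its anti-phase, so each state is a phase bipartition whose
  coherence matrix has the planted pattern as leading eigenvector — the
  same structure empirical LEiDA states exhibit (a community whose BOLD
  phase opposes the main cluster);
* covariates ("age", "pnd", "sex", "group", "motion") that shift dynamic
  parameters (e.g. a state's self-transition probability) through an
  explicit effect map;
* an outcome generated as a linear function of a named true dynamic
  feature plus Gaussian noise, with the coefficients recorded.

Each parcel emits ``A * cos(theta_j(t)) + observation noise``, mean-centred,
so the band-pass + Hilbert + phase-coherence pipeline can recover the
planted communities.  Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import fractional_occupancy, transition_matrix
from .phase import ParcelTimeseries

__all__ = [
    "StateTemplate",
    "CovariateEffect",
    "SimulationScenario",
    "GroundTruth",
    "default_templates",
    "base_transition_matrix",
    "small_scenario",
    "simulate_state_sequence",
    "simulate_bold",
    "simulate_fd",
    "simulate_cohort",
]

# population parameters used to standardise continuous covariates in the
# effect map (kept fixed so a subject's planted dynamics do not depend on
# who else was sampled)
_COVARIATE_POPULATION = {
    "age": (41.1, 1.8),     # PMA-like, weeks
    "pnd": (1.5, 1.22),     # postnatal weeks
    "motion": (0.054, 0.026),
}
_BINARY_COVARIATES = ("sex", "group")


@dataclass
class StateTemplate:
    """Phase-locking community of one planted state."""

    community_mask: np.ndarray
    coupling_strength: float
    label: str

    def __post_init__(self) -> None:
        self.community_mask = np.asarray(self.community_mask, dtype=bool)
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")


@dataclass
class CovariateEffect:
    """One planted covariate -> dynamic-parameter effect.

    ``parameter`` is ``"self_prob:<state>"`` (additive shift of that state's
    self-transition probability) or ``"coupling:<state>"`` (additive shift
    of that state's coupling strength).  Binary covariates enter raw (0/1);
    continuous covariates are standardised against fixed population
    parameters, so ``effect`` is the shift per population SD.
    """

    covariate: str
    parameter: str
    effect: float


@dataclass
class SimulationScenario:
    """Full description of one synthetic cohort.

    Defaults mirror the neonatal study design: P = 90 parcels, T = 2300
    volumes at TR = 0.392 s, six states with self-transition probability
    0.92 (dwelling dominates, as in real state sequences), oscillations
    centred at 0.05 Hz inside the 0.02-0.10 Hz analysis band.
    """

    n_subjects: int = 390
    P: int = 90
    T: int = 2300
    tr: float = 0.392
    K_true: int = 6
    base_frequency: float = 0.05
    freq_jitter: float = 0.4            # fractional detuning of parcel frequencies
    coupling_strength: float = 1.0      # rad per volume at quadrature
    phase_noise_sd: float = 0.4         # rad per volume, phase diffusion
    noise_sd: float = 0.2               # observation noise relative to amplitude 1
    amplitude: float = 1.0
    # dwelling dominates real state sequences; 0.98 keeps dwells (~20 s) long
    # relative to the band-pass filter's ~12 s temporal resolution so the
    # planted states stay recoverable after filtering
    self_transition: float = 0.98
    transition_matrix_base: np.ndarray | None = None
    templates: list[StateTemplate] | None = None
    covariate_effect_map: list[CovariateEffect] = field(default_factory=list)
    outcome_feature: str = "fo:0"
    outcome_coef: float = 30.0
    outcome_intercept: float = 100.0
    outcome_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.K_true < 2:
            raise ValueError("K_true must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0.02 <= self.base_frequency <= 0.10) or self.base_frequency >= nyquist:
            raise ValueError("base_frequency must lie in the 0.02-0.10 Hz band")
        if self.transition_matrix_base is None:
            self.transition_matrix_base = base_transition_matrix(
                self.K_true, self.self_transition
            )
        self.transition_matrix_base = _validated_stochastic(self.transition_matrix_base)
        if self.transition_matrix_base.shape[0] != self.K_true:
            raise ValueError("transition matrix size must equal K_true")
        if self.templates is None:
            self.templates = default_templates(
                self.P, self.K_true, coupling=self.coupling_strength
            )
        if len(self.templates) != self.K_true:
            raise ValueError("need one template per state")
        for t in self.templates:
            if t.community_mask.size != self.P:
                raise ValueError("template mask length must equal P")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    sequences: np.ndarray               # (n, T) int state labels 0..K-1
    subject_matrices: np.ndarray        # (n, K, K) planted transition matrices
    realized_matrices: np.ndarray       # (n, K, K) empirical from the sequences
    subject_couplings: np.ndarray       # (n, K) planted coupling strengths
    covariates: pd.DataFrame
    templates: list[StateTemplate]
    outcome_feature: str
    outcome_coef: float
    outcome_intercept: float
    outcome_noise_sd: float
    true_features: np.ndarray           # (n,) value of outcome_feature per subject
    seed: int


def base_transition_matrix(K: int, self_prob: float) -> np.ndarray:
    """Row-stochastic matrix with constant diagonal and uniform off-diagonal."""
    if not (0.0 <= self_prob < 1.0) and K > 1:
        if self_prob == 1.0:
            return np.eye(K)
        raise ValueError("self_prob must lie in [0, 1]")
    tm = np.full((K, K), (1.0 - self_prob) / (K - 1))
    np.fill_diagonal(tm, self_prob)
    return tm


def default_templates(P: int, K: int, coupling: float = 1.0) -> list[StateTemplate]:
    """One global (all-parcel) state plus K-1 disjoint regional communities.

    Mirrors the empirical picture of whole-brain synchronisation states
    coexisting with regionally constrained ones: state 0 locks every parcel
    in phase; states 1..K-1 lock contiguous blocks of roughly P/(K-1)
    parcels, with the remaining majority driven to anti-phase.  Keeping the
    communities a minority (< P/2) keeps the eigenvector sign convention
    stable (the majority side is negative).
    """
    templates = [
        StateTemplate(np.ones(P, dtype=bool), coupling, "global")
    ]
    bounds = np.linspace(0, P, K).astype(int)
    for k in range(1, K):
        mask = np.zeros(P, dtype=bool)
        mask[bounds[k - 1]: bounds[k]] = True
        if not mask.any():
            mask[k % P] = True
        templates.append(StateTemplate(mask, coupling, f"regional_{k}"))
    return templates


def study_effect_map() -> list[CovariateEffect]:
    """Planted covariate effects mirroring the neonatal findings: the
    preterm-like group has weaker global-state coupling (lower mean
    synchronisation) and a less stable global state; age increases the
    stability of one regional state."""
    return [
        CovariateEffect("group", "coupling:0", -0.25),
        CovariateEffect("group", "self_prob:0", -0.05),
        CovariateEffect("age", "self_prob:2", 0.03),
    ]


def small_scenario(**overrides) -> SimulationScenario:
    """Fast preset (P = 12, T = 400, K = 4, n = 40) for tests and examples."""
    params = dict(n_subjects=40, P=12, T=400, K_true=4)
    params.update(overrides)
    return SimulationScenario(**params)


def _validated_stochastic(tm: np.ndarray) -> np.ndarray:
    tm = np.asarray(tm, dtype=float)
    if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(tm < 0):
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    return tm


def stationary_distribution(tm: np.ndarray) -> np.ndarray:
    """Left eigenvector of eigenvalue 1, normalised to a probability vector."""
    tm = _validated_stochastic(tm)
    vals, vecs = np.linalg.eig(tm.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.abs(np.real(vecs[:, idx]))
    return v / v.sum()


def simulate_state_sequence(
    tm: np.ndarray,
    T: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One realisation of the Markov chain, initial state from stationarity."""
    tm = _validated_stochastic(tm)
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    seqs = _simulate_sequences(tm[None, :, :], T, rng)
    return seqs[0]


def _simulate_sequences(
    mats: np.ndarray, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised Markov simulation; one chain per leading-axis matrix."""
    n, K, _ = mats.shape
    cum = mats.cumsum(axis=2)
    states = np.empty((n, T), dtype=int)
    for i in range(n):
        pi = stationary_distribution(mats[i])
        states[i, 0] = rng.choice(K, p=pi)
    idx = np.arange(n)
    for t in range(1, T):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[idx, states[:, t - 1]]).sum(axis=1)
    return states


def _simulate_phase_dynamics(
    sequences: np.ndarray,
    masks: np.ndarray,
    couplings: np.ndarray,
    scenario: SimulationScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phase trajectories (n, T, P) under state-switched sine coupling.

    Community members of the active state are pulled toward the common
    oscillator ``psi(t)`` and the remaining parcels toward ``psi + pi`` by
    ``c * sin(target - theta)`` per volume; infinite coupling copies the
    target exactly.  With zero coupling every parcel is an independent
    oscillator at its own detuned frequency with Gaussian phase diffusion.
    """
    n, T = sequences.shape
    P = masks.shape[1]
    sc = scenario
    omega = (
        2.0 * np.pi * sc.tr
        * sc.base_frequency
        * (1.0 + sc.freq_jitter * rng.uniform(-1.0, 1.0, size=(n, P)))
    )
    psi0 = rng.uniform(-np.pi, np.pi, size=n)
    psi_inc = 2.0 * np.pi * sc.base_frequency * sc.tr
    theta = rng.uniform(-np.pi, np.pi, size=(n, P))
    out = np.empty((n, T, P))
    idx = np.arange(n)
    for t in range(T):
        psi = psi0 + psi_inc * t
        k = sequences[:, t]
        mask = masks[k]                      # (n, P)
        c = couplings[idx, k]                # (n,)
        target = np.where(mask, psi[:, None], psi[:, None] + np.pi)
        if t > 0:
            drift = omega.copy()
            if sc.phase_noise_sd > 0:
                drift += sc.phase_noise_sd * rng.standard_normal((n, P))
            finite_c = np.where(np.isfinite(c), c, 0.0)
            pull = finite_c[:, None] * np.sin(target - theta)
            theta = theta + drift + pull
        hard = np.broadcast_to(np.isinf(c)[:, None], (n, P))
        if hard.any():
            theta = np.where(hard, target, theta)
        out[:, t, :] = theta
    return out


def _phases_to_bold(
    phases: np.ndarray, scenario: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    signal = scenario.amplitude * np.cos(phases)
    if scenario.noise_sd > 0:
        signal = signal + scenario.noise_sd * rng.standard_normal(signal.shape)
    return signal - signal.mean(axis=-2, keepdims=True)


def simulate_bold(
    state_sequence: np.ndarray,
    templates: list[StateTemplate],
    scenario: SimulationScenario,
    seed: int | None = None,
) -> ParcelTimeseries:
    """BOLD-like signal for one subject given its state sequence."""
    state_sequence = np.asarray(state_sequence, dtype=int)
    if len(templates) != scenario.K_true:
        raise ValueError("need one template per state")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    masks = np.stack([t.community_mask for t in templates])
    couplings = np.array([[t.coupling_strength for t in templates]])
    phases = _simulate_phase_dynamics(
        state_sequence[None, :], masks, couplings, scenario, rng
    )
    values = _phases_to_bold(phases, scenario, rng)[0]
    return ParcelTimeseries(values=values, tr=scenario.tr)


def simulate_fd(
    T: int,
    spike_prob: float,
    rng: np.random.Generator,
    baseline: float = 0.05,
) -> np.ndarray:
    """Framewise-displacement stub: lognormal baseline plus sparse spikes."""
    fd = baseline * np.exp(0.4 * rng.standard_normal(T))
    spikes = rng.random(T) < spike_prob
    fd[spikes] += rng.exponential(0.5, size=int(spikes.sum()))
    return fd


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": rng.normal(41.1, 1.8, size=n),
            "pnd": rng.gamma(1.5, 1.0, size=n),
            "sex": rng.binomial(1, 0.45, size=n).astype(float),
            "group": rng.binomial(1, 0.17, size=n).astype(float),
            "motion": rng.beta(4.0, 70.0, size=n),
        }
    )


def _covariate_signal(cov: pd.DataFrame, name: str) -> np.ndarray:
    """Raw binary covariate or population-standardised continuous one."""
    x = cov[name].to_numpy(dtype=float)
    if name in _BINARY_COVARIATES:
        return x
    mu, sd = _COVARIATE_POPULATION[name]
    return (x - mu) / sd


def _apply_effects(
    scenario: SimulationScenario, cov: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject transition matrices and coupling vectors after effects."""
    n = len(cov)
    K = scenario.K_true
    mats = np.repeat(scenario.transition_matrix_base[None, :, :], n, axis=0)
    coup = np.repeat(
        np.array([[t.coupling_strength for t in scenario.templates]]), n, axis=0
    )
    self_shift = np.zeros((n, K))
    for eff in scenario.covariate_effect_map:
        kind, _, state_str = eff.parameter.partition(":")
        k = int(state_str)
        x = _covariate_signal(cov, eff.covariate)
        if kind == "self_prob":
            self_shift[:, k] += eff.effect * x
        elif kind == "coupling":
            coup[:, k] = np.maximum(coup[:, k] + eff.effect * x, 0.0)
        else:
            raise ValueError(f"unknown dynamic parameter: {eff.parameter}")
    for k in range(K):
        if not np.any(self_shift[:, k]):
            continue
        p_old = scenario.transition_matrix_base[k, k]
        p_new = np.clip(p_old + self_shift[:, k], 0.01, 0.99)
        off_scale = (1.0 - p_new) / (1.0 - p_old)
        mats[:, k, :] *= off_scale[:, None]
        mats[:, k, k] = p_new
    return mats, coup


def _chain_feature(name: str, seq: np.ndarray, K: int, tm: np.ndarray) -> float:
    kind, _, state_str = name.partition(":")
    k = int(state_str) if state_str else 0
    if kind == "fo":
        return float(fractional_occupancy(seq, K)[k])
    if kind == "self_prob":
        return float(tm[k, k])
    raise ValueError(f"unknown outcome feature: {name}")


def simulate_cohort(
    scenario: SimulationScenario,
    bold: bool = True,
) -> tuple[list[ParcelTimeseries], pd.DataFrame, GroundTruth]:
    """Generate a full cohort: timeseries, covariate table, ground truth.

    With ``bold=False`` the (possibly large) signal matrices are skipped and
    only state sequences, covariates and outcomes are produced — enough for
    validating the metrics and inference layers against ground truth.

    The cohort table carries the covariates, the generated outcome and, for
    subjects with BOLD data, a synthetic FD series in ``GroundTruth`` is
    mirrored by the per-subject ``fd`` entries returned alongside.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    cov = _draw_covariates(sc.n_subjects, rng)
    mats, coup = _apply_effects(sc, cov)
    sequences = _simulate_sequences(mats, sc.T, rng)

    realized = np.stack(
        [transition_matrix(sequences[i], sc.K_true) for i in range(sc.n_subjects)]
    )
    features = np.array(
        [
            _chain_feature(sc.outcome_feature, sequences[i], sc.K_true, realized[i])
            for i in range(sc.n_subjects)
        ]
    )
    outcome = sc.outcome_intercept + sc.outcome_coef * features
    if sc.outcome_noise_sd > 0:
        outcome = outcome + sc.outcome_noise_sd * rng.standard_normal(sc.n_subjects)
    cohort = cov.copy()
    cohort["outcome"] = outcome

    timeseries: list[ParcelTimeseries] = []
    if bold:
        masks = np.stack([t.community_mask for t in sc.templates])
        phases = _simulate_phase_dynamics(sequences, masks, coup, sc, rng)
        values = _phases_to_bold(phases, sc, rng)
        for i in range(sc.n_subjects):
            timeseries.append(
                ParcelTimeseries(
                    values=values[i],
                    tr=sc.tr,
                    subject_id=cov["subject_id"].iloc[i],
                )
            )

    truth = GroundTruth(
        sequences=sequences,
        subject_matrices=mats,
        realized_matrices=realized,
        subject_couplings=coup,
        covariates=cov,
        templates=list(sc.templates),
        outcome_feature=sc.outcome_feature,
        outcome_coef=sc.outcome_coef,
        outcome_intercept=sc.outcome_intercept,
        outcome_noise_sd=sc.outcome_noise_sd,
        true_features=features,
        seed=sc.seed,
    )
    return timeseries, cohort, truth
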