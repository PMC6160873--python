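"""Synthetic data generators for validating the pipeline.

Two study designs are built in:

* an estimator comparison, generating order-1 MVAR processes with sparse
  coefficient matrices (values 0.1-0.2) over 32 sources, at controlled
  sample counts, densities and additive-noise SNRs, for contrasting
  penalized and ordinary least-squares fits by RMSE; and

* a full pipeline validation, generating two experimental conditions whose
  trials switch between three functional states according to built-in
  3-state Markov chains.  Each state is a distinct sparse order-1 MVAR
  network (10% density, strengths 0.1-0.5); every 40-sample state
  occurrence is an independent MVAR realization; source activity is
  projected through the three-shell spherical head model to 32 electrodes
  and white sensor noise is added at a chosen SNR (noise sd = RMS of the
  noiseless scalp data / SNR).

All draws flow from explicitly passed numpy Generators so runs are
reproducible from a single master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import TrialTensor
from .headmodel import HeadModel, forward_project, sample_source_positions
from .markov import MarkovModel, sample_sequences

__all__ = [
    "TM_CONDITION_1",
    "TM_CONDITION_2",
    "StateSpec",
    "SimConfig",
    "Sim2GroundTruth",
    "sample_state_coeffs",
    "sample_state_sequence",
    "generate_source_data",
    "add_sensor_noise",
    "jitter_trials",
    "generate_sim1_instance",
    "generate_sim2_dataset",
    "rmse",
]

logger = logging.getLogger(__name__)

#: transition matrices of the two simulated conditions (3 functional states)
TM_CONDITION_1 = np.array([
    [0.80, 0.10, 0.10],
    [0.05, 0.80, 0.15],
    [0.05, 0.05, 0.90],
])
TM_CONDITION_2 = np.array([
    [0.70, 0.20, 0.10],
    [0.10, 0.80, 0.10],
    [0.20, 0.05, 0.75],
])

STABILITY_RADIUS = 0.95
BLOCK_BURN_IN = 100


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class StateSpec:
    """Sparse order-1 coefficient matrix defining one functional state."""

    coeffs: np.ndarray
    density: float
    strength_range: tuple

    def __post_init__(self) -> None:
        M = self.coeffs.shape[0]
        if self.coeffs.shape != (M, M):
            raise ValueError("state coefficients must be square")
        nz = np.abs(self.coeffs[self.coeffs != 0])
        expect = int(round(self.density * M * M))
        if nz.size != expect:
            raise ValueError(f"expected {expect} nonzero connections, got {nz.size}")
        if np.linalg.norm(np.linalg.eigvals(self.coeffs), np.inf) >= 1.0:
            raise ValueError("state process is unstable")


@dataclass
class SimConfig:
    """Pipeline-validation study conditions."""

    M: int = 16
    snr: float = 10.0
    n_trials: int = 300
    states_per_trial: int = 25
    samples_per_state: int = 40
    fs: float = 1000.0
    density: float = 0.1
    strength_range: tuple = (0.1, 0.5)
    tm1: np.ndarray = field(default_factory=lambda: TM_CONDITION_1.copy())
    tm2: np.ndarray = field(default_factory=lambda: TM_CONDITION_2.copy())

    def __post_init__(self) -> None:
        if self.M < 2 or self.n_trials < 2:
            raise ValueError("M and n_trials must be at least 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")


@dataclass
class Sim2GroundTruth:
    """Everything needed to audit a generated dataset."""

    state_sequences: dict
    state_coeffs: dict
    gain: np.ndarray
    head: HeadModel


def sample_state_coeffs(
    M: int,
    density: float,
    strength_range: tuple,
    rng,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Sparse nonnegative order-1 coefficient matrix with a stability guard.

    Exactly ``round(density * M^2)`` entries (diagonal eligible) get
    strengths uniform in ``strength_range``.  Unstable draws are rejected;
    after ``max_attempts`` the last draw is scaled down to spectral radius
    ``STABILITY_RADIUS`` (logged).
    """
    rng = _as_rng(rng)
    n_nonzero = int(round(density * M * M))
    A = np.zeros((M, M))
    for attempt in range(max_attempts):
        A[:] = 0.0
        idx = rng.choice(M * M, size=n_nonzero, replace=False)
        A.flat[idx] = rng.uniform(*strength_range, size=n_nonzero)
        radius = np.abs(np.linalg.eigvals(A)).max()
        if radius < 1.0:
            return A
    logger.warning(
        "stability rejection failed after %d attempts; scaling to radius %.2f",
        max_attempts, STABILITY_RADIUS,
    )
    return A * (STABILITY_RADIUS / radius)


def sample_state_sequence(chain: np.ndarray | MarkovModel, length: int = 25, seed=None) -> np.ndarray:
    """One state-symbol sequence (1..Q) shared by all trials of a condition.

    The initial state is drawn uniformly (the chains do not specify one).
    """
    rng = _as_rng(seed)
    if not isinstance(chain, MarkovModel):
        chain = np.asarray(chain, dtype=float)
        Q = chain.shape[0]
        chain = MarkovModel(pi=np.full(Q, 1.0 / Q), Tm=chain)
    return sample_sequences(chain, 1, length, rng)[0]


def _mvar_block(A: np.ndarray, n_samples: int, n_series: int, rng) -> np.ndarray:
    """(M, n_samples, n_series) realization of y_t = A y_{t-1} + e, unit innovations."""
    M = A.shape[0]
    y = rng.standard_normal((M, n_series))
    for _ in range(BLOCK_BURN_IN):
        y = A @ y + rng.standard_normal((M, n_series))
    out = np.empty((M, n_samples, n_series))
    for t in range(n_samples):
        y = A @ y + rng.standard_normal((M, n_series))
        out[:, t, :] = y
    return out


def generate_source_data(
    state_seq: np.ndarray,
    state_coeffs: np.ndarray,
    n_trials: int,
    samples_per_state: int = 40,
    rng=None,
) -> np.ndarray:
    """Source-level data (M, len(seq)*samples_per_state, n_trials).

    Each state occurrence is substituted by an independent stationary MVAR
    realization of that state's coefficients (independent across blocks and
    trials, with a discarded burn-in).
    """
    rng = _as_rng(rng)
    state_coeffs = np.asarray(state_coeffs, dtype=float)
    for A in state_coeffs:
        if np.abs(np.linalg.eigvals(A)).max() >= 1.0:
            raise ValueError("unstable state coefficients")
    M = state_coeffs.shape[1]
    n_blocks = len(state_seq)
    out = np.empty((M, n_blocks * samples_per_state, n_trials))
    for b, s in enumerate(state_seq):
        block = _mvar_block(state_coeffs[s - 1], samples_per_state, n_trials, rng)
        out[:, b * samples_per_state : (b + 1) * samples_per_state, :] = block
    return out


def add_sensor_noise(t: TrialTensor, snr: float, seed=None) -> TrialTensor:
    """White Gaussian sensor noise with sd = RMS(noiseless data) / SNR."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return t.copy_with(t.data)
    rng = _as_rng(seed)
    sd = np.sqrt(np.mean(t.data**2)) / snr
    return t.copy_with(t.data + sd * rng.standard_normal(t.data.shape))


def jitter_trials(t: TrialTensor, max_jitter: int = 20, seed=None) -> TrialTensor:
    """Shift each trial by an integer uniform in [1, max_jitter] samples.

    Leading samples are dropped per trial and all trials truncated to the
    common length n - max_jitter, emulating imprecise event timing.
    """
    if max_jitter >= t.n_samples:
        raise ValueError("max_jitter must be smaller than the trial length")
    rng = _as_rng(seed)
    n_keep = t.n_samples - max_jitter
    shifts = rng.integers(1, max_jitter + 1, size=t.n_trials)
    out = np.empty((t.n_channels, n_keep, t.n_trials))
    for j, s in enumerate(shifts):
        out[:, :, j] = t.data[:, s : s + n_keep, j]
    return t.copy_with(out)


def generate_sim1_instance(
    samples_ratio: float,
    density: float,
    snr: float,
    n_sources: int = 32,
    p: int = 1,
    coeff_range: tuple = (0.1, 0.2),
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """One estimator-comparison instance: (A_true, data).

    ``A_true`` is (M, M) with ``round(density * M^2)`` entries in
    ``coeff_range``; ``data`` is (n_samples, M) with
    ``n_samples = round(samples_ratio * M^2)``, additive white Gaussian
    observation noise at the given SNR (sd_signal / sd_noise), none for
    SNR = inf.
    """
    if p != 1:
        raise NotImplementedError("the estimator-comparison design is order 1")
    rng = _as_rng(seed)
    n_params = n_sources * n_sources
    n_samples = int(round(samples_ratio * n_params))
    A = sample_state_coeffs(n_sources, density, coeff_range, rng)
    sig = _mvar_block(A, n_samples, 1, rng)[:, :, 0].T  # (n_samples, M)
    if not np.isinf(snr):
        sd = sig.std() / snr
        sig = sig + sd * rng.standard_normal(sig.shape)
    return A, sig


def rmse(A_true: np.ndarray, A_est: np.ndarray) -> float:
    """Elementwise root-mean-square difference."""
    A_true = np.asarray(A_true, dtype=float)
    A_est = np.asarray(A_est, dtype=float)
    if A_true.shape != A_est.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((A_true - A_est) ** 2)))


def generate_sim2_dataset(
    cfg: SimConfig, seed=None, n_terms: int = 60
) -> tuple[TrialTensor, Sim2GroundTruth]:
    """Scalp-level two-condition dataset with state-switching sources.

    Returns the 32-electrode TrialTensor (conditions "cond1"/"cond2") and
    the ground-truth bundle (state sequences, per-state coefficients, gain
    matrix, head model).
    """
    rng = _as_rng(seed)
    coeffs = {
        label: np.stack([
            sample_state_coeffs(cfg.M, cfg.density, cfg.strength_range, rng)
            for _ in range(tm.shape[0])
        ])
        for label, tm in (("cond1", cfg.tm1), ("cond2", cfg.tm2))
    }
    seqs = {
        "cond1": sample_state_sequence(cfg.tm1, cfg.states_per_trial, rng),
        "cond2": sample_state_sequence(cfg.tm2, cfg.states_per_trial, rng),
    }
    head = HeadModel(source_positions=sample_source_positions(cfg.M, rng))
    from .headmodel import gain_matrix  # local import avoids cycle at module load

    G = gain_matrix(head, n_terms)
    blocks, labels = [], []
    for label in ("cond1", "cond2"):
        src = generate_source_data(
            seqs[label], coeffs[label], cfg.n_trials, cfg.samples_per_state, rng
        )
        blocks.append(np.einsum("em,mnd->end", G, src))
        labels.extend([label] * cfg.n_trials)
    scalp = np.concatenate(blocks, axis=2)
    names, _ = head.electrode_names, head.electrode_positions
    t = TrialTensor(data=scalp, fs=cfg.fs, channel_names=list(names),
                    condition=np.array(labels))
    t = add_sensor_noise(t, cfg.snr, rng)
    return t, Sim2GroundTruth(state_sequences=seqs, state_coeffs=coeffs, gain=G, head=head)
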