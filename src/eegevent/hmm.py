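"""First pass: per-class left-to-right GMM-HMMs over feature frames.

One hidden Markov model is trained per event class on pooled,
channel-independent 1 s epochs of feature vectors.  States carry
diagonal-covariance Gaussian mixture emissions; training is classic
Baum-Welch (EM) with scaled forward-backward recursions, flat-start
initialization from global statistics, and binary mixture splitting up
to the target component count.  Decoding scores every channel epoch
under all six models and converts the per-model log-likelihoods into a
posterior vector by log-sum-exp normalization, yielding an
epoch x channel x class posterior grid — the interface to the second
pass.

All sequences inside one training batch are equal length (10 frames per
1 s epoch at the default front end), which lets the E-step run
vectorized across segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .edf_io import CLASS_ORDER, N_CLASSES, ClassLabel
from .features import FeatureSequence

logger = logging.getLogger(__name__)

LOG_ZERO = -1e30


class UnderflowError(FloatingPointError):
    """Observation impossible under the model everywhere.

    Usually means collapsed variances; raise the variance floor.
    """


@dataclass
class HmmModel:
    """Left-to-right GMM-HMM for one event class.

    ``trans[i, j]`` is nonzero only for ``j in (i, i+1)``; the chain
    starts in state 0 and the final state self-loops.  Emissions are
    per-state mixtures of diagonal Gaussians.
    """

    trans: np.ndarray            # (S, S)
    weights: np.ndarray          # (S, L)
    means: np.ndarray            # (S, L, D)
    variances: np.ndarray        # (S, L, D)
    label: ClassLabel | None = None

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def dim(self) -> int:
        return self.means.shape[2]

    def validate(self, atol: float = 1e-9) -> None:
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        lower = np.tril(self.trans, k=-1)
        upper = np.triu(self.trans, k=2)
        if np.any(lower != 0) or np.any(upper != 0):
            raise ValueError("transitions must be left-to-right (j in {i, i+1})")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=atol):
            raise ValueError("mixture weights must sum to 1 per state")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")


@dataclass
class Trellis:
    """Scaled forward/backward quantities for one observation sequence.

    ``alpha[t]`` sums to 1 for every t; ``scales[t]`` are the per-frame
    normalizers whose log-sum (plus the emission offsets folded into
    them) gives ``loglik = log P(O | M)``.  With this convention
    ``sum_i alpha[t, i] * beta[t, i] == 1`` for all t.
    """

    alpha: np.ndarray     # (T, S)
    beta: np.ndarray      # (T, S)
    scales: np.ndarray    # (T,)
    loglik: float


@dataclass(frozen=True)
class HmmTrainConfig:
    """Training schedule for the per-class models.

    ``n_components`` is reached by binary splitting (1 -> 2 -> 4 -> ...)
    with ``iters_per_stage`` Baum-Welch iterations after each split and
    ``final_iters`` at the full mixture size.  ``var_floor_frac``
    floors every variance at that fraction of the global per-dimension
    variance.
    """

    n_states: int = 3
    n_components: int = 8
    iters_per_stage: int = 5
    final_iters: int = 10
    tol: float = 1e-4
    var_floor_frac: float = 1e-3
    seed: int = 12345


@dataclass
class EpochPosteriorGrid:
    """Posterior scores, shape ``(n_epochs, n_channels, n_classes)``."""

    scores: np.ndarray
    epoch_duration: float = 1.0

    @property
    def n_epochs(self) -> int:
        return self.scores.shape[0]

    @property
    def n_channels(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------

def _log_gauss_comp(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """Per-component log densities, shape ``obs_shape[:-1] + (S, L)``.

    Uses the quadratic expansion of the diagonal Mahalanobis distance so
    no ``(..., S, L, D)`` temporary is materialized.
    """
    obs = np.asarray(obs, dtype=np.float64)
    mu = model.means                                  # (S, L, D)
    var = model.variances
    inv = 1.0 / var
    # constants per component
    log_norm = -0.5 * (np.log(2.0 * np.pi * var).sum(axis=2))        # (S, L)
    quad_const = -0.5 * np.einsum("sld,sld,sld->sl", mu, mu, inv)
    flat_inv = inv.reshape(-1, model.dim)             # (S*L, D)
    flat_mu_inv = (mu * inv).reshape(-1, model.dim)
    x2 = obs ** 2
    term_sq = -0.5 * (x2 @ flat_inv.T)                # (..., S*L)
    term_cross = obs @ flat_mu_inv.T
    out = term_sq + term_cross
    out = out.reshape(obs.shape[:-1] + (model.n_states, model.n_components))
    return out + log_norm + quad_const


def gaussian_mixture_density(
    o_t: np.ndarray, model: HmmModel, state: int | None = None
) -> np.ndarray | float:
    """Mixture density ``b_i(o_t)`` (linear scale) for one observation.

    Returns the density for ``state``, or the vector over all states if
    ``state`` is None.  Computed in log space internally.
    """
    log_b = state_log_likelihoods(np.atleast_2d(o_t), model)[0]
    dens = np.exp(log_b)
    return float(dens[state]) if state is not None else dens


def state_log_likelihoods(obs: np.ndarray, model: HmmModel) -> np.ndarray:
    """``log b_i(o_t)`` for all frames/states, shape ``(..., S)``."""
    comp = _log_gauss_comp(obs, model)
    logw = np.where(model.weights > 0, np.log(np.maximum(model.weights, 1e-300)),
                    LOG_ZERO)
    return logsumexp(comp + logw, axis=-1)


# ---------------------------------------------------------------------------
# Scaled forward-backward (batched over equal-length sequences)
# ---------------------------------------------------------------------------

def _batched_forward(log_b: np.ndarray, trans: np.ndarray):
    """Scaled forward pass over a batch ``log_b`` of shape ``(N, T, S)``.

    Returns ``alpha (N,T,S)`` (rows normalized), ``log_c (N,T)`` with
    ``loglik = log_c.sum(axis=1)``.
    """
    n, T, S = log_b.shape
    offset = log_b.max(axis=2, keepdims=True)         # (N, T, 1)
    if np.any(offset < -745.0):  # exp() underflows to 0.0 for every state
        raise UnderflowError(
            "observation density underflows under every state; "
            "consider raising the variance floor"
        )
    b = np.exp(log_b - offset)
    alpha = np.zeros((n, T, S))
    log_c = np.empty((n, T))
    a = b[:, 0, :] * np.eye(S)[0]                     # start in state 0
    c = a.sum(axis=1)
    if np.any(c <= 0):
        raise UnderflowError(
            "zero forward mass at t=0; consider raising the variance floor"
        )
    alpha[:, 0, :] = a / c[:, None]
    log_c[:, 0] = np.log(c)
    for t in range(1, T):
        a = (alpha[:, t - 1, :] @ trans) * b[:, t, :]
        c = a.sum(axis=1)
        if np.any(c <= 0):
            raise UnderflowError(
                f"zero forward mass at t={t}; consider raising the "
                "variance floor"
            )
        alpha[:, t, :] = a / c[:, None]
        log_c[:, t] = np.log(c)
    log_c += offset[:, :, 0]
    return alpha, log_c, b


def forward_backward(model: HmmModel, obs: np.ndarray | FeatureSequence) -> Trellis:
    """Scaled forward-backward for one observation sequence.

    ``obs`` is ``(T, D)``.  Raises :class:`UnderflowError` when the
    observation has zero density under every state at some frame.
    """
    if isinstance(obs, FeatureSequence):
        obs = obs.frames
    obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
    log_b = state_log_likelihoods(obs, model)[None, :, :]   # (1, T, S)
    alpha, log_c, b = _batched_forward(log_b, model.trans)
    beta = _scaled_backward_from_forward(b, model.trans, log_b, log_c)
    loglik = float(log_c.sum())
    return Trellis(alpha=alpha[0], beta=beta[0],
                   scales=np.exp(log_c[0]), loglik=loglik)


def _scaled_backward_from_forward(b, trans, log_b, log_c):
    """Backward pass scaled by the forward's per-frame normalizers.

    In the offset-removed emission domain used by the forward pass the
    effective scale at frame t is ``exp(log_c[t] - offset[t])``; using
    it here guarantees ``sum_i alpha[t,i] beta[t,i] == 1`` for all t.
    """
    n, T, S = b.shape
    offset = log_b.max(axis=2)                         # (N, T)
    c_eff = np.exp(log_c - offset)                     # (N, T)
    beta = np.zeros((n, T, S))
    beta[:, T - 1, :] = 1.0
    for t in range(T - 2, -1, -1):
        unsc = (b[:, t + 1, :] * beta[:, t + 1, :]) @ trans.T
        beta[:, t, :] = unsc / c_eff[:, t + 1, None]
    return beta


def transition_posteriors(
    trellis: Trellis, model: HmmModel, obs: np.ndarray | FeatureSequence
) -> np.ndarray:
    """Pairwise state posteriors ``xi[t, i, j]`` for ``t = 1..T-1``.

    ``xi[t]`` is the posterior probability of being in state i at frame
    t-1 and state j at frame t; each ``xi[t]`` sums to 1.
    """
    if isinstance(obs, FeatureSequence):
        obs = obs.frames
    obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
    T = obs.shape[0]
    log_b = state_log_likelihoods(obs, model)
    b = np.exp(log_b - log_b.max(axis=1, keepdims=True))
    xi = np.zeros((T, model.n_states, model.n_states))
    for t in range(1, T):
        m = (trellis.alpha[t - 1][:, None] * model.trans
             * (b[t] * trellis.beta[t])[None, :])
        tot = m.sum()
        xi[t] = m / tot if tot > 0 else m
    return xi


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def _left_right_trans(n_states: int) -> np.ndarray:
    trans = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        trans[i, i] = 0.6
        trans[i, i + 1] = 0.4
    trans[-1, -1] = 1.0
    return trans


def flat_start(
    data: np.ndarray, config: HmmTrainConfig, label: ClassLabel | None = None
) -> HmmModel:
    """Initialize a single-component model from global statistics.

    State means get small deterministic perturbations (seeded) so the
    states can differentiate during EM.
    """
    flat = data.reshape(-1, data.shape[-1])
    g_mean = flat.mean(axis=0)
    g_var = np.maximum(flat.var(axis=0), 1e-8)
    rng = np.random.default_rng(config.seed)
    S = config.n_states
    means = np.empty((S, 1, flat.shape[1]))
    for s in range(S):
        means[s, 0] = g_mean + 0.05 * np.sqrt(g_var) * rng.standard_normal(
            flat.shape[1]
        )
    variances = np.tile(g_var, (S, 1, 1))
    weights = np.ones((S, 1))
    return HmmModel(_left_right_trans(S), weights, means, variances, label)


def _estep_stats(model: HmmModel, data: np.ndarray):
    """Accumulate EM statistics over a batch ``data (N, T, D)``.

    Returns (trans_num (S,S), occupancy gamma sums, first/second moment
    sums per component, total loglik).
    """
    log_b_comp = _log_gauss_comp(data, model)          # (N, T, S, L)
    logw = np.where(model.weights > 0,
                    np.log(np.maximum(model.weights, 1e-300)), LOG_ZERO)
    log_b = logsumexp(log_b_comp + logw, axis=-1)      # (N, T, S)
    alpha, log_c, b = _batched_forward(log_b, model.trans)
    beta = _scaled_backward_from_forward(b, model.trans, log_b, log_c)
    total_ll = float(log_c.sum())

    # state occupancy; rows of alpha*beta already sum to 1
    gamma = alpha * beta                               # (N, T, S)
    gamma = gamma / np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)

    # transition counts
    N, T, S = log_b.shape
    trans_num = np.zeros((S, S))
    for t in range(1, T):
        m = (alpha[:, t - 1, :, None] * model.trans[None, :, :]
             * (b[:, t, None, :] * beta[:, t, None, :]))
        m_sum = np.maximum(m.sum(axis=(1, 2), keepdims=True), 1e-300)
        trans_num += (m / m_sum).sum(axis=0)

    # per-component responsibilities within each state
    log_resp = log_b_comp + logw - log_b[..., None]
    resp = np.exp(np.clip(log_resp, -700, 0)) * gamma[..., None]  # (N,T,S,L)
    occ = resp.sum(axis=(0, 1))                                   # (S, L)
    flat = data.reshape(-1, data.shape[-1])                       # (NT, D)
    r = resp.reshape(-1, S, model.n_components)                   # (NT, S, L)
    first = np.einsum("nsl,nd->sld", r, flat)
    second = np.einsum("nsl,nd->sld", r, flat ** 2)
    return trans_num, occ, first, second, total_ll


def baum_welch_update(
    model: HmmModel,
    batch: np.ndarray | list[np.ndarray],
    var_floor: np.ndarray | float = 1e-6,
) -> tuple[HmmModel, float]:
    """One EM iteration over a batch of equal-length sequences.

    Returns the re-estimated model and the batch log-likelihood under
    the *input* model (so EM monotonicity shows as a non-decreasing
    sequence of returned values).  States with zero occupancy keep
    their previous parameters.
    """
    data = np.asarray(batch, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    trans_num, occ, first, second, total_ll = _estep_stats(model, data)

    denom = np.maximum(trans_num.sum(axis=1, keepdims=True), 1e-300)
    new_trans = trans_num / denom
    # keep the left-to-right mask exact and rows stochastic
    mask = (model.trans > 0).astype(float)
    new_trans = new_trans * mask
    rowsum = new_trans.sum(axis=1, keepdims=True)
    dead_rows = rowsum[:, 0] <= 0
    new_trans[dead_rows] = model.trans[dead_rows]
    rowsum = new_trans.sum(axis=1, keepdims=True)
    new_trans = new_trans / rowsum

    new_w = model.weights.copy()
    new_mu = model.means.copy()
    new_var = model.variances.copy()
    state_occ = occ.sum(axis=1)
    for s in range(model.n_states):
        if state_occ[s] <= 1e-8:
            logger.warning("state %d has zero occupancy; keeping parameters", s)
            continue
        new_w[s] = occ[s] / state_occ[s]
        for l in range(model.n_components):
            if occ[s, l] <= 1e-8:
                continue
            mu = first[s, l] / occ[s, l]
            var = second[s, l] / occ[s, l] - mu ** 2
            new_mu[s, l] = mu
            new_var[s, l] = np.maximum(var, var_floor)
    new_model = HmmModel(new_trans, new_w, new_mu, new_var, model.label)
    return new_model, total_ll


def batch_loglik(model: HmmModel, data: np.ndarray) -> float:
    """Total log-likelihood of a batch ``(N, T, D)`` under ``model``."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    log_b = state_log_likelihoods(data, model)
    _, log_c, _ = _batched_forward(log_b, model.trans)
    return float(log_c.sum())


def _split_mixtures(model: HmmModel, perturb: float = 0.2) -> HmmModel:
    """Binary mixture split: each component becomes two, means nudged
    by ``+-perturb * sigma`` along every dimension."""
    sd = np.sqrt(model.variances)
    means = np.concatenate(
        [model.means + perturb * sd, model.means - perturb * sd], axis=1
    )
    variances = np.concatenate([model.variances, model.variances], axis=1)
    weights = np.concatenate([model.weights / 2, model.weights / 2], axis=1)
    return HmmModel(model.trans.copy(), weights, means, variances, model.label)


def train_model(
    data: np.ndarray, config: HmmTrainConfig, label: ClassLabel | None = None
) -> HmmModel:
    """Train one class model: flat start, mixture splitting, EM.

    ``data`` is ``(N, T, D)`` — pooled equal-length training segments.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    flat = data.reshape(-1, data.shape[-1])
    var_floor = config.var_floor_frac * np.maximum(flat.var(axis=0), 1e-8)
    model = flat_start(data, config, label)

    def run_em(m: HmmModel, iters: int) -> HmmModel:
        prev_ll = -np.inf
        for _ in range(iters):
            m, ll = baum_welch_update(m, data, var_floor)
            if abs(ll - prev_ll) < config.tol * max(1.0, abs(ll)):
                break
            prev_ll = ll
        return m

    model = run_em(model, config.iters_per_stage)
    while model.n_components < config.n_components:
        model = _split_mixtures(model)
        model = run_em(model, config.iters_per_stage)
    return run_em(model, config.final_iters)


def train_class_models(
    segments_by_class: dict[ClassLabel, np.ndarray],
    config: HmmTrainConfig | None = None,
) -> dict[ClassLabel, HmmModel]:
    """Train all six per-class models from pooled channel segments.

    ``segments_by_class[label]`` is an ``(N, T, D)`` array of 1 s
    epochs cut from every channel of the training corpus (channel
    independent models).  Every class must be represented.
    """
    config = config or HmmTrainConfig()
    missing = [c.name for c in CLASS_ORDER if
               c not in segments_by_class or len(segments_by_class[c]) == 0]
    if missing:
        raise ValueError(f"no training segments for class(es): {missing}")
    models = {}
    for cls in CLASS_ORDER:
        logger.info("training HMM for %s on %d segments",
                    cls.name, len(segments_by_class[cls]))
        models[cls] = train_model(segments_by_class[cls], config, cls)
    return models


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def viterbi(model: HmmModel, obs: np.ndarray | FeatureSequence):
    """Most likely state path and its joint log score.

    Ties break toward the lower state index.
    """
    if isinstance(obs, FeatureSequence):
        obs = obs.frames
    obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
    T = obs.shape[0]
    S = model.n_states
    log_b = state_log_likelihoods(obs, model)
    log_a = np.where(model.trans > 0,
                     np.log(np.maximum(model.trans, 1e-300)), LOG_ZERO)
    delta = np.full(S, LOG_ZERO)
    delta[0] = log_b[0, 0]
    back = np.zeros((T, S), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_a          # (from, to)
        back[t] = np.argmax(cand, axis=0)      # first max -> lower index
        delta = cand[back[t], np.arange(S)] + log_b[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    score = float(delta[path[-1]])
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    if score <= LOG_ZERO / 2:
        raise UnderflowError("no admissible state path for the observation")
    return path, score


def score_epochs(
    models: dict[ClassLabel, HmmModel],
    features: list[FeatureSequence],
    epoch_duration: float = 1.0,
) -> EpochPosteriorGrid:
    """Posterior grid ``(n_epochs, n_channels, n_classes)``.

    Each channel is cut into consecutive epochs of
    ``epoch_duration / frame_step`` frames; every epoch is scored under
    all six class models and the log-likelihoods are normalized with
    log-sum-exp into a posterior vector.
    """
    step = features[0].frame_step
    fpe = epoch_duration / step
    if abs(fpe - round(fpe)) > 1e-9:
        raise ValueError("frame_step must divide epoch_duration")
    fpe = int(round(fpe))
    n_epochs = min(f.n_frames for f in features) // fpe
    n_ch = len(features)
    logliks = np.empty((n_epochs, n_ch, N_CLASSES))
    for ch, feat in enumerate(features):
        segs = feat.frames[: n_epochs * fpe].reshape(n_epochs, fpe, -1)
        for k, cls in enumerate(CLASS_ORDER):
            log_b = state_log_likelihoods(segs, models[cls])
            _, log_c, _ = _batched_forward(log_b, models[cls].trans)
            logliks[:, ch, k] = log_c.sum(axis=1)
    post = np.exp(logliks - logsumexp(logliks, axis=2, keepdims=True))
    return EpochPosteriorGrid(scores=post, epoch_duration=epoch_duration)
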