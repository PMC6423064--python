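"""Second pass: stacked denoising autoencoders over epoch supervectors.

The first pass leaves a 6-class posterior per channel per 1 s epoch.
Concatenating the 22 channels channel-major gives a 132-dimensional
epoch supervector.  Three parallel networks then integrate spatial and
temporal context:

* ``SPSW2way`` — epileptiform vs. non-epileptiform detector; PCA to 13
  dimensions, sliding-triplet averaging, a 3-epoch context window
  (39 inputs, 2 outputs);
* ``EYEM2way`` — eye-movement detector with the same 39/2 geometry;
* ``SIXWAY`` — full 6-class classifier; PCA to 20 dimensions and a
  41-epoch context window (820 inputs, 6 outputs).

Each network is a stack of tied-weight denoising autoencoder layers
(sigmoid units, masking corruption) pre-trained greedily on the
reconstruction cross-entropy, then fine-tuned end-to-end with a softmax
head by minibatch SGD.  An *enhancer* merges the three outputs: the
6-way posterior is overridden whenever a binary detector confidently
disagrees, reallocating probability mass to the detector's class block
while preserving within-block ratios.

PCA outputs are min-max scaled into [0, 1] so that sigmoid
reconstruction with a cross-entropy loss is well posed.  Rare classes
(SPSW, EYEM) can be augmented by convex interpolation between same-class
nearest neighbours plus small Gaussian jitter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .edf_io import CLASS_ORDER, N_CLASSES, N_MONTAGE_CHANNELS, ClassLabel
from .hmm import EpochPosteriorGrid

logger = logging.getLogger(__name__)

EPS = 1e-7  # clip for logs inside the cross-entropy

#: Class indices of the epileptiform block {SPSW, GPED, PLED}.
EPILEPTIFORM_IDX = (ClassLabel.SPSW.value, ClassLabel.PLED.value,
                    ClassLabel.GPED.value)
EYEM_IDX = (ClassLabel.EYEM.value,)

#: Priority used to reduce per-channel labels to one epoch label:
#: clinically significant classes win over background classes.
LABEL_PRIORITY = (ClassLabel.SPSW, ClassLabel.PLED, ClassLabel.GPED,
                  ClassLabel.EYEM, ClassLabel.ARTF, ClassLabel.BCKG)


class SdaRole(Enum):
    SPSW2way = "spsw"
    EYEM2way = "eyem"
    SIXWAY = "sixway"


@dataclass(frozen=True)
class SdaHyperparams:
    """Architecture and optimization settings for one SdA role."""

    pca_dim: int
    window_length: int
    hidden: tuple[int, ...]
    n_out: int
    corruption: float = 0.3
    triplet_average: bool = False
    pretrain_lr: float = 0.5
    pretrain_epochs: int = 150
    pretrain_batch: int = 300
    finetune_lr: float = 0.1
    finetune_epochs: int = 300
    finetune_batch: int = 100

    @property
    def input_dim(self) -> int:
        return self.pca_dim * self.window_length


#: Published operating points for the three roles.
DEFAULT_HYPERPARAMS: dict[SdaRole, SdaHyperparams] = {
    SdaRole.SPSW2way: SdaHyperparams(
        pca_dim=13, window_length=3, hidden=(100, 100, 100), n_out=2,
        triplet_average=True, pretrain_lr=0.5, pretrain_epochs=200,
        pretrain_batch=300, finetune_lr=0.2, finetune_epochs=800,
        finetune_batch=100,
    ),
    SdaRole.EYEM2way: SdaHyperparams(
        pca_dim=13, window_length=3, hidden=(100, 100, 100), n_out=2,
        triplet_average=True, pretrain_lr=0.5, pretrain_epochs=200,
        pretrain_batch=300, finetune_lr=0.2, finetune_epochs=100,
        finetune_batch=100,
    ),
    SdaRole.SIXWAY: SdaHyperparams(
        pca_dim=20, window_length=41, hidden=(800, 500, 300), n_out=6,
        triplet_average=False, pretrain_lr=0.5, pretrain_epochs=150,
        pretrain_batch=300, finetune_lr=0.1, finetune_epochs=300,
        finetune_batch=100,
    ),
}


def fast_hyperparams(role: SdaRole) -> SdaHyperparams:
    """Scaled-down training profile for desk-scale experiments.

    Keeps the published geometry (PCA dims, window lengths, hence the
    input dimensions) but shrinks hidden layers and epoch counts so a
    full pipeline trains in seconds on one CPU core.
    """
    base = DEFAULT_HYPERPARAMS[role]
    hidden = (80, 50) if role is SdaRole.SIXWAY else (40, 30)
    epochs = 400 if role is SdaRole.SIXWAY else 150
    return SdaHyperparams(
        pca_dim=base.pca_dim, window_length=base.window_length,
        hidden=hidden, n_out=base.n_out, corruption=base.corruption,
        triplet_average=base.triplet_average,
        pretrain_lr=0.2, pretrain_epochs=20, pretrain_batch=64,
        finetune_lr=0.1, finetune_epochs=epochs, finetune_batch=64,
    )


# ---------------------------------------------------------------------------
# Epoch vectors, context windows, PCA
# ---------------------------------------------------------------------------

def build_epoch_vectors(grid: EpochPosteriorGrid) -> np.ndarray:
    """Flatten the posterior grid into per-epoch supervectors.

    Channel-major concatenation: ``[ch0 classes 0..5, ch1 classes
    0..5, ...]`` giving ``22 * 6 = 132`` values per epoch.
    """
    scores = grid.scores
    if scores.shape[1] != N_MONTAGE_CHANNELS or scores.shape[2] != N_CLASSES:
        raise ValueError(
            f"expected (epochs, {N_MONTAGE_CHANNELS}, {N_CLASSES}) grid, "
            f"got {scores.shape}"
        )
    return scores.reshape(scores.shape[0], -1)


def stack_window(vectors: np.ndarray, window_length: int) -> np.ndarray:
    """Stack a centered context window around every epoch.

    Epoch k gets the concatenation of epochs ``k - (w-1)/2 ..
    k + (w-1)/2``; epochs beyond the record boundary are replicated
    from the edge.  Output shape ``(n_epochs, w * dim)``.
    """
    if window_length % 2 != 1:
        raise ValueError("window_length must be odd")
    vectors = np.asarray(vectors, dtype=np.float64)
    n, d = vectors.shape
    half = (window_length - 1) // 2
    cols = []
    for off in range(-half, half + 1):
        idx = np.clip(np.arange(n) + off, 0, n - 1)
        cols.append(vectors[idx])
    return np.concatenate(cols, axis=1)


def average_triplets(vectors: np.ndarray) -> np.ndarray:
    """Sliding mean of three consecutive epochs (edges clipped).

    Output t is the mean of inputs t-1, t, t+1 where they exist; length
    and dimension are unchanged.
    """
    v = np.asarray(vectors, dtype=np.float64)
    n = v.shape[0]
    sums = v.copy()
    counts = np.ones((n, 1))
    if n > 1:
        sums[1:] += v[:-1]
        counts[1:] += 1
        sums[:-1] += v[1:]
        counts[:-1] += 1
    return sums / counts


@dataclass
class PcaTransform:
    """Mean-centered orthonormal projection plus [0, 1] min-max scaling."""

    mean: np.ndarray          # (in_dim,)
    components: np.ndarray    # (out_dim, in_dim), orthonormal rows
    lo: np.ndarray            # (out_dim,) training minima
    hi: np.ndarray            # (out_dim,) training maxima

    @property
    def out_dim(self) -> int:
        return self.components.shape[0]


def fit_pca(vectors: np.ndarray, out_dim: int) -> PcaTransform:
    """Fit the rank-``out_dim`` PCA projection with [0, 1] scaling bounds."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if out_dim > vectors.shape[1]:
        raise ValueError(
            f"out_dim {out_dim} exceeds input dimension {vectors.shape[1]}"
        )
    if vectors.shape[0] < out_dim:
        raise ValueError("need at least out_dim training vectors")
    pca = PCA(n_components=out_dim, svd_solver="full")
    reduced = pca.fit_transform(vectors)
    lo = reduced.min(axis=0)
    hi = reduced.max(axis=0)
    span = hi - lo
    hi = np.where(span <= 0, lo + 1.0, hi)  # constant dims map to 0
    return PcaTransform(mean=pca.mean_, components=pca.components_,
                        lo=lo, hi=hi)


def apply_pca(transform: PcaTransform, vectors: np.ndarray) -> np.ndarray:
    """Project and min-max scale into [0, 1] (clipped at apply time)."""
    vectors = np.asarray(vectors, dtype=np.float64)
    reduced = (vectors - transform.mean) @ transform.components.T
    scaled = (reduced - transform.lo) / (transform.hi - transform.lo)
    return np.clip(scaled, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Rare-class augmentation
# ---------------------------------------------------------------------------

def augment_rare_class(
    vectors: np.ndarray,
    labels: np.ndarray,
    target: int,
    factor: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-sample augmentation for a rare class.

    Synthesizes ``(factor - 1) * n_target`` new vectors by convex
    interpolation between a random target-class example and its nearest
    same-class neighbour, plus Gaussian jitter with standard deviation
    0.05 of the per-dimension class standard deviation.  Original data
    are untouched; synthetic rows are appended.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    labels = np.asarray(labels)
    cls_idx = np.flatnonzero(labels == target)
    if factor <= 1:
        return vectors, labels
    if cls_idx.size < 2:
        raise ValueError(
            f"class {target} has {cls_idx.size} example(s); augmentation "
            "needs at least 2"
        )
    X = vectors[cls_idx]
    n_new = int(round((factor - 1) * cls_idx.size))
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, neigh = nn.kneighbors(X)
    jitter_sd = 0.05 * X.std(axis=0)
    picks = rng.integers(0, X.shape[0], size=n_new)
    lam = rng.uniform(0.0, 1.0, size=(n_new, 1))
    partners = X[neigh[picks, 1]]
    synth = (1 - lam) * X[picks] + lam * partners
    synth += rng.normal(0.0, 1.0, synth.shape) * jitter_sd
    out_v = np.vstack([vectors, synth])
    out_l = np.concatenate([labels, np.full(n_new, target, dtype=labels.dtype)])
    return out_v, out_l


# ---------------------------------------------------------------------------
# Denoising autoencoder layers
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class DenoisingAutoencoderLayer:
    """One tied-weight denoising autoencoder.

    Encoder ``y = sigmoid(W x + b)``; decoder ``z = sigmoid(W' y + b')``
    with ``W' = W.T`` (tied weights).  ``corruption`` is the masking
    probability applied to the input during pre-training.
    """

    W: np.ndarray        # (d_out, d_in)
    b: np.ndarray        # (d_out,)
    b_prime: np.ndarray  # (d_in,)
    corruption: float = 0.3

    def encode(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(x @ self.W.T + self.b)

    def decode(self, y: np.ndarray) -> np.ndarray:
        return _sigmoid(y @ self.W + self.b_prime)


def init_layer(
    d_in: int, d_out: int, corruption: float, rng: np.random.Generator
) -> DenoisingAutoencoderLayer:
    """Uniform Glorot-style initialization (the sigmoid convention)."""
    bound = 4.0 * np.sqrt(6.0 / (d_in + d_out))
    W = rng.uniform(-bound, bound, size=(d_out, d_in))
    return DenoisingAutoencoderLayer(
        W=W, b=np.zeros(d_out), b_prime=np.zeros(d_in), corruption=corruption
    )


def corrupt(x: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: each coordinate zeroed independently with prob ``level``."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("corruption level must be in [0, 1]")
    if level == 0.0:
        return np.array(x, copy=True)
    mask = rng.random(np.shape(x)) >= level
    return np.asarray(x) * mask


def dae_loss(x: np.ndarray, z: np.ndarray) -> float:
    """Reconstruction cross-entropy, averaged over the batch.

    ``L = -sum_d [x log z + (1 - x) log(1 - z)]`` with ``z`` clipped to
    ``[eps, 1 - eps]``.
    """
    x = np.atleast_2d(x)
    z = np.clip(np.atleast_2d(z), EPS, 1.0 - EPS)
    per_row = -(x * np.log(z) + (1.0 - x) * np.log(1.0 - z)).sum(axis=1)
    return float(per_row.mean())


def _dae_grads(layer: DenoisingAutoencoderLayer, x: np.ndarray,
               x_tilde: np.ndarray):
    """Batch-averaged gradients of the reconstruction cross-entropy.

    With a sigmoid decoder and cross-entropy loss the output-delta is
    simply ``z - x``; the tied weight gets both encoder- and
    decoder-side contributions.
    """
    y = layer.encode(x_tilde)
    z = layer.decode(y)
    B = x.shape[0]
    dz = z - x                              # (B, d_in)
    dy = dz @ layer.W.T                     # (B, d_out)
    dy_pre = dy * y * (1.0 - y)
    gW = (dy_pre.T @ x_tilde + y.T @ dz) / B
    gb = dy_pre.mean(axis=0)
    gbp = dz.mean(axis=0)
    loss = dae_loss(x, z)
    return gW, gb, gbp, loss


@dataclass
class SdaNetwork:
    """Encoder stack plus a softmax classification head."""

    layers: list[DenoisingAutoencoderLayer]
    head_W: np.ndarray    # (n_out, d_last)
    head_b: np.ndarray    # (n_out,)
    window_length: int
    role: SdaRole
    val_accuracy: float | None = None   # set by finetune_sda when val_frac > 0

    def encode(self, x: np.ndarray) -> np.ndarray:
        h = np.atleast_2d(x)
        for layer in self.layers:
            h = layer.encode(h)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.encode(x) @ self.head_W.T + self.head_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def build_network(
    hyper: SdaHyperparams, role: SdaRole, rng: np.random.Generator
) -> SdaNetwork:
    dims = [hyper.input_dim, *hyper.hidden]
    layers = [
        init_layer(dims[i], dims[i + 1], hyper.corruption, rng)
        for i in range(len(dims) - 1)
    ]
    bound = np.sqrt(6.0 / (dims[-1] + hyper.n_out))
    head_W = rng.uniform(-bound, bound, size=(hyper.n_out, dims[-1]))
    return SdaNetwork(layers=layers, head_W=head_W,
                      head_b=np.zeros(hyper.n_out),
                      window_length=hyper.window_length, role=role)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def pretrain_sda(
    network: SdaNetwork,
    inputs: np.ndarray,
    hyper: SdaHyperparams,
    rng: np.random.Generator,
    holdout_frac: float = 0.1,
) -> list[list[float]]:
    """Greedy layer-wise unsupervised pre-training.

    Each layer is trained as a denoising autoencoder on the previous
    layer's (uncorrupted) code by minibatch SGD on the reconstruction
    cross-entropy.  Labels are never consulted.  Returns per-layer
    held-out loss histories ``[loss_epoch_0, ..., loss_final]``.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    if X.shape[1] != network.layers[0].W.shape[1]:
        raise ValueError(
            f"input dim {X.shape[1]} does not match layer 0 "
            f"({network.layers[0].W.shape[1]})"
        )
    n_hold = max(1, int(round(holdout_frac * X.shape[0])))
    perm = rng.permutation(X.shape[0])
    hold, train = X[perm[:n_hold]], X[perm[n_hold:]]
    histories: list[list[float]] = []
    for li, layer in enumerate(network.layers):
        history = []
        for epoch in range(hyper.pretrain_epochs):
            order = rng.permutation(train.shape[0])
            for start in range(0, train.shape[0], hyper.pretrain_batch):
                xb = train[order[start : start + hyper.pretrain_batch]]
                xt = corrupt(xb, layer.corruption, rng)
                gW, gb, gbp, loss = _dae_grads(layer, xb, xt)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"divergence (NaN loss) in layer {li}, epoch {epoch}"
                    )
                layer.W -= hyper.pretrain_lr * gW
                layer.b -= hyper.pretrain_lr * gb
                layer.b_prime -= hyper.pretrain_lr * gbp
            hold_loss = dae_loss(hold, layer.decode(layer.encode(hold)))
            history.append(hold_loss)
        histories.append(history)
        # feed the next layer with this layer's clean code
        train = layer.encode(train)
        hold = layer.encode(hold)
    return histories


def _snapshot(network: SdaNetwork):
    return ([(l.W.copy(), l.b.copy(), l.b_prime.copy())
             for l in network.layers],
            network.head_W.copy(), network.head_b.copy())


def _restore(network: SdaNetwork, snap) -> None:
    layers, head_W, head_b = snap
    for layer, (W, b, bp) in zip(network.layers, layers):
        layer.W, layer.b, layer.b_prime = W.copy(), b.copy(), bp.copy()
    network.head_W, network.head_b = head_W.copy(), head_b.copy()


def finetune_sda(
    network: SdaNetwork,
    inputs: np.ndarray,
    labels: np.ndarray,
    hyper: SdaHyperparams,
    rng: np.random.Generator,
    val_frac: float = 0.0,
) -> SdaNetwork:
    """Supervised fine-tuning of the full encoder + softmax head.

    Minimizes the negative log-likelihood of the softmax head by
    backpropagation through all encoder layers (minibatch SGD,
    initialized from the pre-trained weights).  With ``val_frac > 0``
    a held-out split is scored every few epochs and the best-scoring
    parameters are restored at the end (standard early-stopping
    hygiene); the achieved validation accuracy is recorded on
    ``network.val_accuracy``.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    y = np.asarray(labels, dtype=np.intp)
    n_out = network.head_W.shape[0]
    if y.min() < 0 or y.max() >= n_out:
        raise ValueError(
            f"labels must be in [0, {n_out}); got range "
            f"[{y.min()}, {y.max()}]"
        )
    X_val = y_val = None
    if val_frac > 0:
        n_val = max(1, int(round(val_frac * X.shape[0])))
        perm = rng.permutation(X.shape[0])
        X_val, y_val = X[perm[:n_val]], y[perm[:n_val]]
        X, y = X[perm[n_val:]], y[perm[n_val:]]
    best_acc, best_snap = -1.0, None
    check_every = max(1, hyper.finetune_epochs // 20)
    lr = hyper.finetune_lr
    for epoch in range(hyper.finetune_epochs):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], hyper.finetune_batch):
            idx = order[start : start + hyper.finetune_batch]
            xb, yb = X[idx], y[idx]
            B = xb.shape[0]
            # forward, keeping activations
            acts = [xb]
            h = xb
            for layer in network.layers:
                h = layer.encode(h)
                acts.append(h)
            logits = h @ network.head_W.T + network.head_b
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            delta = probs
            delta[np.arange(B), yb] -= 1.0        # dNLL/dlogits
            gW_head = delta.T @ h / B
            gb_head = delta.mean(axis=0)
            dh = delta @ network.head_W
            network.head_W -= lr * gW_head
            network.head_b -= lr * gb_head
            for li in range(len(network.layers) - 1, -1, -1):
                layer = network.layers[li]
                a_out = acts[li + 1]
                dpre = dh * a_out * (1.0 - a_out)
                gW = dpre.T @ acts[li] / B
                gb = dpre.mean(axis=0)
                if li > 0:
                    dh = dpre @ layer.W
                layer.W -= lr * gW
                layer.b -= lr * gb
        if X_val is not None and (
            epoch % check_every == 0 or epoch == hyper.finetune_epochs - 1
        ):
            acc = float(
                (network.predict_proba(X_val).argmax(axis=1) == y_val).mean()
            )
            if acc > best_acc:
                best_acc = acc
                best_snap = _snapshot(network)
    if X_val is not None and best_snap is not None:
        _restore(network, best_snap)
        network.val_accuracy = best_acc
    return network


# ---------------------------------------------------------------------------
# Enhancer
# ---------------------------------------------------------------------------

def _reallocate(p: np.ndarray, block: tuple[int, ...], mass: float) -> np.ndarray:
    """Give ``block`` total probability ``mass`` preserving internal ratios."""
    out = p.copy()
    block = list(block)
    rest = [i for i in range(p.size) if i not in block]
    bsum = p[block].sum()
    rsum = p[rest].sum()
    if bsum > 0:
        out[block] = p[block] / bsum * mass
    else:
        out[block] = mass / len(block)
    if rsum > 0:
        out[rest] = p[rest] / rsum * (1.0 - mass)
    else:
        out[rest] = (1.0 - mass) / len(rest)
    return out


def enhancer_combine(
    p6: np.ndarray, p_spsw: np.ndarray, p_eyem: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Merge the three SdA outputs into the final per-epoch posterior.

    Starts from the 6-way posterior.  If the epileptiform detector is
    confident (``p > threshold``) while the 6-way argmax is outside the
    {SPSW, GPED, PLED} block, that block is rescaled to the detector's
    probability mass (internal ratios preserved) and the complement to
    the remainder; the analogous rule applies for the EYEM detector and
    the {EYEM} block.  Rows are renormalized to sum to one.

    ``p_spsw`` and ``p_eyem`` are ``(n, 2)`` with column 1 the positive
    (epileptiform / eye movement) class.
    """
    p6 = np.atleast_2d(np.asarray(p6, dtype=np.float64))
    p_spsw = np.atleast_2d(p_spsw)
    p_eyem = np.atleast_2d(p_eyem)
    out = p6.copy()

    def disagrees(p: np.ndarray, block: tuple[int, ...]) -> bool:
        # the 6-way output agrees with a detector only when the block
        # holds the strict maximum; ties count as disagreement
        rest = [i for i in range(p.size) if i not in block]
        return p[list(block)].max() <= p[rest].max()

    for i in range(out.shape[0]):
        pe = float(p_spsw[i, 1])
        if pe > threshold and disagrees(out[i], EPILEPTIFORM_IDX):
            out[i] = _reallocate(out[i], EPILEPTIFORM_IDX, pe)
        py = float(p_eyem[i, 1])
        if py > threshold and disagrees(out[i], EYEM_IDX):
            out[i] = _reallocate(out[i], EYEM_IDX, py)
    out /= out.sum(axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Epoch-level reference labels
# ---------------------------------------------------------------------------

def priority_vote(channel_labels: np.ndarray) -> np.ndarray:
    """Reduce per-channel epoch labels to one label per epoch.

    ``channel_labels`` holds class indices, shape ``(n_epochs,
    n_channels)``.  The highest-priority class present on any channel
    wins (SPSW > PLED > GPED > EYEM > ARTF > BCKG) so that rare focal
    events remain visible at the epoch level.
    """
    channel_labels = np.atleast_2d(np.asarray(channel_labels))
    out = np.full(channel_labels.shape[0], ClassLabel.BCKG.value, dtype=np.intp)
    for cls in reversed(LABEL_PRIORITY):
        present = (channel_labels == cls.value).any(axis=1)
        out[present] = cls.value
    return out
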