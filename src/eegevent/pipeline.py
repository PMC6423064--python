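"""End-to-end orchestration of the three-pass classifier.

Training (:func:`run_train`): read the annotated training records,
extract LFCC features, cut per-channel 1 s epochs, train the six
GMM-HMMs (pass 1), score the training data into posterior grids, fit
the two PCA front ends, train the three denoising-autoencoder networks
(pass 2), and package the bigram grammar (pass 3) into a versioned
model bundle.

Decoding (:func:`run_decode`): canonicalize the input record, run the
three passes in order, and return every intermediate artifact — the
per-channel posterior grid, the merged per-epoch posteriors, and the
grammar-smoothed final labels.

A single pipeline seed deterministically derives the seeds of every
stochastic stage, so identical inputs and configuration reproduce
identical bundles and decodes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .edf_io import (
    CLASS_ORDER,
    N_CLASSES,
    N_MONTAGE_CHANNELS,
    ChannelAnnotation,
    ClassLabel,
    SignalRecord,
    canonicalize,
    read_annotations,
    read_edf,
)
from .features import FeatureConfig, FeatureSequence, extract_features
from .grammar import BigramGrammar, GrammarConfig, SmoothedSequence, \
    default_grammar, run_grammar_pass
from .hmm import EpochPosteriorGrid, HmmModel, HmmTrainConfig, \
    score_epochs, train_class_models
from .sda import (
    DEFAULT_HYPERPARAMS,
    DenoisingAutoencoderLayer,
    PcaTransform,
    SdaHyperparams,
    SdaNetwork,
    SdaRole,
    apply_pca,
    augment_rare_class,
    average_triplets,
    build_epoch_vectors,
    build_network,
    enhancer_combine,
    fast_hyperparams,
    finetune_sda,
    fit_pca,
    pretrain_sda,
    priority_vote,
    stack_window,
)

logger = logging.getLogger(__name__)

EPOCH_DURATION = 1.0  # seconds; fixed pipeline-wide


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a training run needs besides the corpus itself."""

    features: FeatureConfig = field(default_factory=FeatureConfig)
    hmm: HmmTrainConfig = field(default_factory=HmmTrainConfig)
    grammar: GrammarConfig = field(default_factory=GrammarConfig)
    sda_profile: str = "paper"        # "paper" or "fast"
    max_segments_per_class: int = 2000
    augment_factor: float = 3.0       # rare-class oversampling multiple
    seed: int = 0

    def sda_hyperparams(self, role: SdaRole) -> SdaHyperparams:
        if self.sda_profile == "fast":
            return fast_hyperparams(role)
        return DEFAULT_HYPERPARAMS[role]


def fast_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Desk-scale training profile: published geometry, smaller models.

    HMMs use 2 mixture components instead of 8 and the SdAs use the
    reduced "fast" profile, so a full pipeline trains in well under a
    minute per corpus on one CPU core.
    """
    defaults: dict = dict(
        hmm=HmmTrainConfig(n_states=3, n_components=2, iters_per_stage=3,
                           final_iters=5, seed=seed + 101),
        sda_profile="fast",
        max_segments_per_class=600,
        seed=seed,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


# ---------------------------------------------------------------------------
# Reference labels on the epoch grid
# ---------------------------------------------------------------------------

def epoch_label_grid(
    annotations: list[ChannelAnnotation],
    n_epochs: int,
    n_channels: int = N_MONTAGE_CHANNELS,
) -> np.ndarray:
    """Per-channel epoch labels from interval annotations.

    Each (epoch, channel) cell takes the label covering the majority of
    the epoch; coverage ties break toward the clinically
    higher-priority class.  Unannotated spans default to BCKG.
    """
    coverage = np.zeros((n_epochs, n_channels, N_CLASSES))
    for a in annotations:
        if a.channel_index >= n_channels:
            raise ValueError(
                f"annotation channel {a.channel_index} out of range"
            )
        e0 = int(np.floor(a.start))
        e1 = min(int(np.ceil(a.stop)), n_epochs)
        for e in range(e0, e1):
            overlap = min(a.stop, e + 1.0) - max(a.start, float(e))
            if overlap > 0:
                coverage[e, a.channel_index, a.label.value] += overlap
    # unannotated time counts as background
    total = coverage.sum(axis=2)
    coverage[..., ClassLabel.BCKG.value] += np.maximum(1.0 - total, 0.0)
    # break coverage ties toward higher clinical priority (lower enum value
    # == higher priority under the canonical ordering)
    prio = 1e-9 * np.arange(N_CLASSES, 0, -1)
    return (coverage + prio).argmax(axis=2)


# ---------------------------------------------------------------------------
# Model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to decode: HMMs, PCA fronts, SdAs, grammar."""

    hmms: dict[ClassLabel, HmmModel]
    pca13: PcaTransform
    pca20: PcaTransform
    sdas: dict[SdaRole, SdaNetwork]
    grammar: BigramGrammar
    config: PipelineConfig
    config_hash: str = ""

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for cls, m in self.hmms.items():
            p = f"hmm_{cls.name}"
            arrays[f"{p}_trans"] = m.trans
            arrays[f"{p}_weights"] = m.weights
            arrays[f"{p}_means"] = m.means
            arrays[f"{p}_variances"] = m.variances
        for name, pca in (("pca13", self.pca13), ("pca20", self.pca20)):
            arrays[f"{name}_mean"] = pca.mean
            arrays[f"{name}_components"] = pca.components
            arrays[f"{name}_lo"] = pca.lo
            arrays[f"{name}_hi"] = pca.hi
        meta_sdas = {}
        for role, net in self.sdas.items():
            p = f"sda_{role.value}"
            for i, layer in enumerate(net.layers):
                arrays[f"{p}_l{i}_W"] = layer.W
                arrays[f"{p}_l{i}_b"] = layer.b
                arrays[f"{p}_l{i}_bp"] = layer.b_prime
            arrays[f"{p}_head_W"] = net.head_W
            arrays[f"{p}_head_b"] = net.head_b
            meta_sdas[role.value] = {
                "n_layers": len(net.layers),
                "window_length": net.window_length,
                "corruption": net.layers[0].corruption,
            }
        arrays["grammar"] = self.grammar.probs
        np.savez(out / "params.npz", **arrays)
        meta = {
            "package_version": _pkg_version,
            "config": _config_to_jsonable(self.config),
            "config_hash": self.config_hash,
            "sdas": meta_sdas,
            "classes": [c.name for c in CLASS_ORDER],
        }
        with open(out / "bundle.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        return out

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "ModelBundle":
        bundle_dir = Path(bundle_dir)
        with open(bundle_dir / "bundle.json") as fh:
            meta = json.load(fh)
        z = np.load(bundle_dir / "params.npz")
        hmms = {}
        for c in CLASS_ORDER:
            p = f"hmm_{c.name}"
            hmms[c] = HmmModel(z[f"{p}_trans"], z[f"{p}_weights"],
                               z[f"{p}_means"], z[f"{p}_variances"], c)
        pcas = {}
        for name in ("pca13", "pca20"):
            pcas[name] = PcaTransform(
                mean=z[f"{name}_mean"], components=z[f"{name}_components"],
                lo=z[f"{name}_lo"], hi=z[f"{name}_hi"])
        sdas = {}
        for role in SdaRole:
            p = f"sda_{role.value}"
            info = meta["sdas"][role.value]
            layers = [
                DenoisingAutoencoderLayer(
                    W=z[f"{p}_l{i}_W"], b=z[f"{p}_l{i}_b"],
                    b_prime=z[f"{p}_l{i}_bp"],
                    corruption=info["corruption"])
                for i in range(info["n_layers"])
            ]
            sdas[role] = SdaNetwork(
                layers=layers, head_W=z[f"{p}_head_W"],
                head_b=z[f"{p}_head_b"],
                window_length=info["window_length"], role=role)
        config = _config_from_jsonable(meta["config"])
        return cls(hmms=hmms, pca13=pcas["pca13"], pca20=pcas["pca20"],
                   sdas=sdas, grammar=BigramGrammar(z["grammar"]),
                   config=config, config_hash=meta["config_hash"])


def _config_to_jsonable(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["features"]["band"] = list(d["features"]["band"])
    return d


def _config_from_jsonable(d: dict) -> PipelineConfig:
    feats = dict(d["features"])
    feats["band"] = tuple(feats["band"])
    return PipelineConfig(
        features=FeatureConfig(**feats),
        hmm=HmmTrainConfig(**d["hmm"]),
        grammar=GrammarConfig(**d["grammar"]),
        sda_profile=d["sda_profile"],
        max_segments_per_class=d["max_segments_per_class"],
        augment_factor=d["augment_factor"],
        seed=d["seed"],
    )


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_config_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _load_corpus(corpus_dir: Path, names: list[str], config: PipelineConfig):
    """Features and reference label grids for the named records."""
    out = []
    for stem in names:
        record = canonicalize(read_edf(corpus_dir / f"{stem}.edf"))
        annots = read_annotations(corpus_dir / f"{stem}.csv")
        feats = extract_features(record, config.features)
        fpe = int(round(EPOCH_DURATION / config.features.frame_step))
        n_epochs = min(f.n_frames for f in feats) // fpe
        labels = epoch_label_grid(annots, n_epochs, record.n_channels)
        out.append((stem, feats, labels))
    return out


def _collect_segments(
    corpus, config: PipelineConfig, rng: np.random.Generator
) -> dict[ClassLabel, np.ndarray]:
    """Pool per-channel 1 s feature epochs by reference class."""
    fpe = int(round(EPOCH_DURATION / config.features.frame_step))
    pools: dict[ClassLabel, list[np.ndarray]] = {c: [] for c in CLASS_ORDER}
    for _, feats, labels in corpus:
        n_epochs = labels.shape[0]
        for ch, feat in enumerate(feats):
            segs = feat.frames[: n_epochs * fpe].reshape(n_epochs, fpe, -1)
            for cls in CLASS_ORDER:
                sel = labels[:, ch] == cls.value
                if sel.any():
                    pools[cls].append(segs[sel])
    out = {}
    for cls, chunks in pools.items():
        if not chunks:
            out[cls] = np.empty((0, fpe, 0))
            continue
        data = np.concatenate(chunks, axis=0)
        cap = config.max_segments_per_class
        if data.shape[0] > cap:
            idx = rng.choice(data.shape[0], size=cap, replace=False)
            data = data[np.sort(idx)]
        out[cls] = data
    return out


def _augment_toward_balance(
    X: np.ndarray, y: np.ndarray, cap: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample minority classes toward the majority count.

    Each class with at least two examples is augmented by
    neighbour-interpolation (see :func:`eegevent.sda.augment_rare_class`)
    up to ``cap`` times its original count, never past the majority
    class size.  Addresses the heavy class imbalance of event corpora
    without touching the original examples.
    """
    if cap <= 1:
        return X, y
    y = np.asarray(y, dtype=np.intp)
    counts = np.bincount(y)
    n_max = counts.max()
    for cls in np.flatnonzero((counts >= 2) & (counts < n_max)):
        factor = min(cap, n_max / counts[cls])
        if factor > 1:
            X, y = augment_rare_class(X, y, int(cls), factor, rng)
    return X, y


def _branch_inputs(vectors: np.ndarray, bundle_pca13: PcaTransform,
                   bundle_pca20: PcaTransform):
    """Per-record second-pass inputs for the three networks."""
    r13 = average_triplets(apply_pca(bundle_pca13, vectors))
    x2 = stack_window(r13, DEFAULT_HYPERPARAMS[SdaRole.SPSW2way].window_length)
    r20 = apply_pca(bundle_pca20, vectors)
    x6 = stack_window(r20, DEFAULT_HYPERPARAMS[SdaRole.SIXWAY].window_length)
    return x2, x6


def run_train(
    corpus_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> ModelBundle:
    """Train the full three-pass system from an annotated corpus.

    ``corpus_dir`` must contain ``manifest.json`` plus EDF/CSV record
    pairs (as written by :func:`eegevent.synthdata.generate_corpus`).
    Trains on the manifest's ``train`` split only.
    """
    config = config or PipelineConfig()
    corpus_dir = Path(corpus_dir)
    with open(corpus_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    seeds = _child_seeds(config.seed)
    rng_seg = np.random.default_rng(seeds[0])

    logger.info("pass 1: loading corpus and training HMMs")
    corpus = _load_corpus(corpus_dir, manifest["train"], config)
    segments = _collect_segments(corpus, config, rng_seg)
    empty = [c.name for c, v in segments.items() if v.shape[0] == 0]
    if empty:
        raise ValueError(f"training corpus has no epochs for: {empty}")
    hmm_config = config.hmm
    hmms = train_class_models(segments, hmm_config)

    logger.info("pass 2: scoring training corpus and training SdAs")
    grids, vec_list, label_list = [], [], []
    for _, feats, labels in corpus:
        grid = score_epochs(hmms, feats, EPOCH_DURATION)
        grids.append(grid)
        vec_list.append(build_epoch_vectors(grid))
        label_list.append(priority_vote(labels[: grid.n_epochs]))
    all_vecs = np.concatenate(vec_list, axis=0)
    pca13 = fit_pca(all_vecs, DEFAULT_HYPERPARAMS[SdaRole.SPSW2way].pca_dim)
    pca20 = fit_pca(all_vecs, DEFAULT_HYPERPARAMS[SdaRole.SIXWAY].pca_dim)

    x2_list, x6_list = [], []
    for vecs in vec_list:   # window within record boundaries
        x2, x6 = _branch_inputs(vecs, pca13, pca20)
        x2_list.append(x2)
        x6_list.append(x6)
    X2 = np.concatenate(x2_list, axis=0)
    X6 = np.concatenate(x6_list, axis=0)
    y6 = np.concatenate(label_list)
    y_spsw = np.isin(
        y6, [ClassLabel.SPSW.value, ClassLabel.PLED.value,
             ClassLabel.GPED.value]).astype(np.intp)
    y_eyem = (y6 == ClassLabel.EYEM.value).astype(np.intp)

    sdas: dict[SdaRole, SdaNetwork] = {}
    tasks = [
        (SdaRole.SPSW2way, X2, y_spsw),
        (SdaRole.EYEM2way, X2, y_eyem),
        (SdaRole.SIXWAY, X6, y6),
    ]
    for i, (role, X, y) in enumerate(tasks):
        hyper = config.sda_hyperparams(role)
        rng = np.random.default_rng(seeds[1 + i])
        Xa, ya = _augment_toward_balance(X, y, config.augment_factor, rng)
        # two independent restarts; keep the better validation accuracy
        # (minibatch SGD on these small corpora can land in a poor basin)
        best = None
        for restart_seed in np.random.SeedSequence(seeds[1 + i]).spawn(2):
            r = np.random.default_rng(restart_seed)
            net = build_network(hyper, role, r)
            pretrain_sda(net, Xa, hyper, r)
            finetune_sda(net, Xa, ya, hyper, r, val_frac=0.1)
            if best is None or (net.val_accuracy or 0) > (best.val_accuracy or 0):
                best = net
        logger.info("%s SdA validation accuracy %.3f", role.value,
                    best.val_accuracy or float("nan"))
        sdas[role] = best

    bundle = ModelBundle(
        hmms=hmms, pca13=pca13, pca20=pca20, sdas=sdas,
        grammar=default_grammar(), config=config,
        config_hash=config_hash(config),
    )
    if out_dir is not None:
        bundle.save(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodeResult:
    """All three passes' outputs for one record."""

    grid: EpochPosteriorGrid            # pass 1, (E, C, K)
    epoch_vectors: np.ndarray           # (E, 132)
    p6: np.ndarray                      # 6-way SdA posteriors (E, 6)
    p_spsw: np.ndarray                  # epileptiform detector (E, 2)
    p_eyem: np.ndarray                  # eye-movement detector (E, 2)
    enhanced: np.ndarray                # merged pass-2 posteriors (E, 6)
    smoothed: SmoothedSequence          # pass 3

    @property
    def pass1_channel_labels(self) -> np.ndarray:
        """Per-channel argmax labels, shape (E, C)."""
        return self.grid.scores.argmax(axis=2)

    @property
    def pass1_epoch_labels(self) -> np.ndarray:
        """Priority-vote epoch labels from the pass-1 grid."""
        return priority_vote(self.pass1_channel_labels)

    @property
    def pass2_epoch_labels(self) -> np.ndarray:
        return self.enhanced.argmax(axis=1)

    @property
    def pass3_epoch_labels(self) -> np.ndarray:
        return self.smoothed.labels


def run_decode(
    record: SignalRecord | str | Path,
    bundle: ModelBundle,
) -> DecodeResult:
    """Run all three passes on one record (path or in-memory)."""
    if not isinstance(record, SignalRecord):
        record = read_edf(record)
    record = canonicalize(record)
    if record.n_channels != N_MONTAGE_CHANNELS:
        raise ValueError(
            f"record has {record.n_channels} channels after "
            f"canonicalization; the bundle expects {N_MONTAGE_CHANNELS}"
        )
    config = bundle.config
    feats = extract_features(record, config.features)
    grid = score_epochs(bundle.hmms, feats, EPOCH_DURATION)
    vecs = build_epoch_vectors(grid)
    x2, x6 = _branch_inputs(vecs, bundle.pca13, bundle.pca20)
    p_spsw = bundle.sdas[SdaRole.SPSW2way].predict_proba(x2)
    p_eyem = bundle.sdas[SdaRole.EYEM2way].predict_proba(x2)
    p6 = bundle.sdas[SdaRole.SIXWAY].predict_proba(x6)
    enhanced = enhancer_combine(p6, p_spsw, p_eyem)
    smoothed = run_grammar_pass(enhanced, bundle.grammar, config.grammar)
    return DecodeResult(grid=grid, epoch_vectors=vecs, p6=p6,
                        p_spsw=p_spsw, p_eyem=p_eyem,
                        enhanced=enhanced, smoothed=smoothed)


def hypothesis_annotations(result: DecodeResult) -> list[ChannelAnnotation]:
    """Epoch-level hypothesis as per-channel annotations (all channels)."""
    out = []
    labels = result.pass3_epoch_labels
    for e, lab in enumerate(labels):
        for ch in range(result.grid.n_channels):
            out.append(ChannelAnnotation(ch, float(e), float(e + 1),
                                         CLASS_ORDER[int(lab)]))
    return out
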