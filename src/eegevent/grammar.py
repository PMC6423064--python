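"""Third pass: iterative Bayesian smoothing with a bigram class grammar.

Neurologists impose long-range consistency on EEG interpretations —
periodic lateralized discharges persist for many seconds, spikes do not
appear in the middle of a run of generalized discharges, and so on.
This pass encodes such constraints in a 6x6 bigram transition table
``Prob(i, j)`` (probability that class i is followed by class j) and
uses it to smooth the per-epoch posterior sequence produced by the
second pass.

Each iteration n blends three ingredients for every epoch k:

* a file-level prior, the average posterior over the whole file with a
  small additive prior;
* exponentially decaying left and right context distributions (LPP,
  RPP) over a window of N neighbouring epochs;
* the grammar, which scores each candidate class against the left and
  right context through ``Prob``.

The grammar factor is raised to ``gamma / n`` so its influence anneals
over iterations; iteration stops when the per-epoch argmax labels stop
changing (or after ``n_max`` iterations).  The shipped default table
is stored verbatim (two rows sum to 1.02 due to rounding in the
source table; a flag renormalizes on load).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .edf_io import CLASS_ORDER, N_CLASSES, ClassLabel

logger = logging.getLogger(__name__)

_CLASS_NAMES = [c.name for c in CLASS_ORDER]


@dataclass
class BigramGrammar:
    """6x6 class-transition probabilities in canonical class order."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"grammar must be {N_CLASSES}x{N_CLASSES}")
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError("grammar entries must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if np.any(rows < 0.98) or np.any(rows > 1.02 + 1e-12):
            raise ValueError(
                f"grammar rows must sum to 1 within rounding; got {rows}"
            )

    def prob(self, i: ClassLabel, j: ClassLabel) -> float:
        return float(self.probs[i.value, j.value])


def default_grammar(renormalize: bool = False) -> BigramGrammar:
    """The packaged clinical bigram table.

    Stored verbatim by default; ``renormalize=True`` rescales each row
    to sum exactly to one.
    """
    with resources.files("eegevent.data").joinpath(
        "bigram_default.csv"
    ).open() as fh:
        return _grammar_from_frame(pd.read_csv(fh, index_col=0), renormalize)


def _grammar_from_frame(df: pd.DataFrame, renormalize: bool) -> BigramGrammar:
    try:
        mat = df.loc[_CLASS_NAMES, _CLASS_NAMES].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"grammar CSV must index all six classes: {exc}")
    if renormalize:
        mat = mat / mat.sum(axis=1, keepdims=True)
    return BigramGrammar(mat)


def load_grammar(path: str | Path, renormalize: bool = False) -> BigramGrammar:
    """Load a grammar CSV (class names as header row and index column)."""
    return _grammar_from_frame(pd.read_csv(path, index_col=0), renormalize)


def save_grammar(grammar: BigramGrammar, path: str | Path) -> Path:
    df = pd.DataFrame(grammar.probs, index=_CLASS_NAMES, columns=_CLASS_NAMES)
    df.to_csv(path)
    return Path(path)


def estimate_bigram(
    label_sequences: list[np.ndarray], smoothing: float = 0.0
) -> BigramGrammar:
    """Count-based bigram estimate from label sequences (a utility).

    The packaged clinical table is the intended production grammar;
    this estimator exists for experiments on synthetic corpora.
    """
    counts = np.full((N_CLASSES, N_CLASSES), smoothing, dtype=float)
    for seq in label_sequences:
        seq = np.asarray(seq, dtype=np.intp)
        for a, b in zip(seq[:-1], seq[1:]):
            counts[a, b] += 1
    rowsums = counts.sum(axis=1, keepdims=True)
    unseen = rowsums[:, 0] <= 0
    counts[unseen] = 1.0  # classes never observed get a uniform row
    rowsums = counts.sum(axis=1, keepdims=True)
    return BigramGrammar(counts / rowsums)


@dataclass(frozen=True)
class GrammarConfig:
    """Smoothing parameters (defaults are the published operating point).

    ``eps_prior`` additive prior inside the file-level average;
    ``M`` its weight; ``lam`` the exponential context decay; ``alpha``
    the file-prior blend weight; ``gamma`` the grammar weight; ``n_max``
    the iteration cap; ``N`` the context half-window in epochs.
    ``anneal`` selects the ``gamma / n`` exponent (iteration-annealed);
    switching it off uses ``gamma * n``.
    """

    eps_prior: float = 0.1
    M: float = 1.0
    lam: float = 0.2
    alpha: float = 0.1
    gamma: float = 1.0
    n_max: int = 20
    N: int = 10
    anneal: bool = True

    def __post_init__(self) -> None:
        if self.N < 1 or self.n_max < 1:
            raise ValueError("N and n_max must be >= 1")
        if min(self.eps_prior, self.M, self.lam, self.alpha, self.gamma) < 0:
            raise ValueError("grammar weights must be non-negative")


@dataclass
class SmoothedSequence:
    """Final smoothed posteriors, labels, and the iteration count."""

    probs: np.ndarray          # (L, 6)
    labels: np.ndarray         # (L,) class indices
    iterations_used: int


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else v


def file_prior(posteriors: np.ndarray, config: GrammarConfig) -> np.ndarray:
    """File-level prior: smoothed average posterior over all L epochs.

    ``(sum_i P_i + eps_prior * M) / (L + M)`` per class, renormalized.
    """
    P = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
    L = P.shape[0]
    raw = (P.sum(axis=0) + config.eps_prior * config.M) / (L + config.M)
    return _normalize(raw)


def context_probability(
    posteriors: np.ndarray,
    k: int,
    side: str,
    gprior: np.ndarray,
    config: GrammarConfig,
) -> np.ndarray:
    """Left or right context distribution for epoch ``k``.

    Exponentially decayed sum of up to ``N`` neighbours on the given
    side (neighbours beyond the record boundary are skipped), blended
    with ``alpha * gprior`` and normalized to a distribution.
    """
    P = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
    L = P.shape[0]
    sign = {"left": -1, "right": +1}[side]
    acc = np.zeros(P.shape[1])
    for i in range(1, config.N + 1):
        idx = k + sign * i
        if 0 <= idx < L:
            acc += np.exp(-i * config.lam) * P[idx]
    blended = (acc + config.alpha * gprior) / (1.0 + config.alpha)
    return _normalize(blended)


def smooth_epoch(
    p_k: np.ndarray,
    lpp: np.ndarray,
    rpp: np.ndarray,
    grammar: BigramGrammar,
    config: GrammarConfig,
    iteration: int,
) -> np.ndarray:
    """One grammar update of a single epoch's posterior.

    ``factor(c) = [sum_i LPP(i) Prob(i, c)] * [sum_j Prob(c, j) RPP(j)]``
    raised to ``gamma / n`` (annealed) and multiplied into the prior
    posterior, then renormalized.
    """
    p_k = np.asarray(p_k, dtype=np.float64)
    left = lpp @ grammar.probs          # (6,): sum_i LPP(i) Prob(i, c)
    right = grammar.probs @ rpp         # (6,): sum_j Prob(c, j) RPP(j)
    factor = left * right
    if np.all(factor <= 0):
        logger.warning("degenerate grammar: all-zero factor; epoch unchanged")
        return p_k.copy()
    expo = config.gamma / iteration if config.anneal else config.gamma * iteration
    updated = p_k * np.power(factor, expo)
    s = updated.sum()
    if s <= 0:
        return p_k.copy()
    return updated / s


def run_grammar_pass(
    posteriors: np.ndarray,
    grammar: BigramGrammar | None = None,
    config: GrammarConfig | None = None,
) -> SmoothedSequence:
    """Iterate the grammar smoother to label convergence.

    The file prior and the left/right contexts are recomputed each
    iteration from the current posterior estimates; all epochs update
    simultaneously from that snapshot.  Stops when argmax labels are
    unchanged between successive iterations or at ``n_max``.
    """
    grammar = grammar or default_grammar()
    config = config or GrammarConfig()
    P = np.atleast_2d(np.asarray(posteriors, dtype=np.float64)).copy()
    if P.shape[0] < 1:
        raise ValueError("need at least one epoch")
    labels = P.argmax(axis=1)
    iterations = 0
    for n in range(1, config.n_max + 1):
        iterations = n
        gprior = file_prior(P, config)
        new_P = np.empty_like(P)
        for k in range(P.shape[0]):
            lpp = context_probability(P, k, "left", gprior, config)
            rpp = context_probability(P, k, "right", gprior, config)
            new_P[k] = smooth_epoch(P[k], lpp, rpp, grammar, config, n)
        P = new_P
        new_labels = P.argmax(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return SmoothedSequence(probs=P, labels=labels, iterations_used=iterations)
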