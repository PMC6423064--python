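"""Confusion matrices, class collapses, sensitivity/false-alarm rates,
and DET curves.

Two scoring granularities are supported.  *Event-based* scoring counts
every (channel, epoch) pair as an independent scored unit — the
forced-choice convention natural for per-channel hypotheses.
*Epoch-based* scoring counts each epoch once, with the reference label
reduced from the per-channel annotations by the clinical priority vote.

Three class granularities: the native six classes; a four-way collapse
where the three non-pathological classes (EYEM, ARTF, BCKG) merge into
BCKG; and a two-way collapse into a target class TARG = {SPSW, GPED,
PLED} versus BCKG.

A terminology caution that this module makes explicit: clinical EEG
detection papers often report a quantity called "specificity" that is
the fraction of background units flagged as targets — a *false-alarm
rate*, where lower is better.  Both that rate and the conventional
specificity (background correctly rejected) are computed, under
unambiguous names.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .edf_io import CLASS_ORDER, ClassLabel

TARG = "TARG"
BCKG = "BCKG"

#: Target block of the two-way collapse.
TARGET_CLASSES = frozenset({ClassLabel.SPSW, ClassLabel.GPED, ClassLabel.PLED})


class ScoringMode(Enum):
    EVENT_BASED = "event_based"   # one unit per (channel, epoch)
    EPOCH_BASED = "epoch_based"   # one unit per epoch


class Collapse(Enum):
    SIX = "six"
    FOUR = "four"
    TWO = "two"


def collapse_labels(label: ClassLabel, scheme: Collapse | str) -> str:
    """Map a six-way label into the four- or two-way scheme.

    four: EYEM/ARTF/BCKG -> BCKG, pathological classes unchanged.
    two: SPSW/GPED/PLED -> TARG, everything else -> BCKG.
    """
    scheme = Collapse(scheme)
    if scheme is Collapse.SIX:
        return label.name
    if scheme is Collapse.FOUR:
        return BCKG if label in (ClassLabel.EYEM, ClassLabel.ARTF,
                                 ClassLabel.BCKG) else label.name
    return TARG if label in TARGET_CLASSES else BCKG


def _scheme_classes(scheme: Collapse) -> list[str]:
    if scheme is Collapse.SIX:
        return [c.name for c in CLASS_ORDER]
    if scheme is Collapse.FOUR:
        return ["SPSW", "PLED", "GPED", BCKG]
    return [TARG, BCKG]


@dataclass
class ConfusionMatrix:
    """Reference x hypothesis counts with row-percentage views."""

    counts: pd.DataFrame
    mode: ScoringMode
    collapse: Collapse

    @property
    def percentages(self) -> pd.DataFrame:
        """Row-normalized percentages (each row sums to 100)."""
        totals = self.counts.sum(axis=1).replace(0, np.nan)
        return self.counts.div(totals, axis=0) * 100.0

    @property
    def accuracy(self) -> float:
        """Fraction of units on the diagonal, as a percentage."""
        total = self.counts.to_numpy().sum()
        diag = np.trace(self.counts.to_numpy())
        return 100.0 * diag / total if total else float("nan")

    # Two-way detection rates -------------------------------------------------
    def _require_two_way(self) -> None:
        if self.collapse is not Collapse.TWO:
            raise ValueError("detection rates require the two-way collapse")

    @property
    def sensitivity(self) -> float:
        """% of TARG reference units hypothesized TARG."""
        self._require_two_way()
        row = self.counts.loc[TARG]
        return 100.0 * row[TARG] / row.sum() if row.sum() else float("nan")

    @property
    def false_alarm_rate(self) -> float:
        """% of BCKG reference units hypothesized TARG.

        This is the quantity clinical detection tables often print
        under the name "specificity" (lower is better).
        """
        self._require_two_way()
        row = self.counts.loc[BCKG]
        return 100.0 * row[TARG] / row.sum() if row.sum() else float("nan")

    @property
    def specificity_conventional(self) -> float:
        """% of BCKG reference units correctly hypothesized BCKG."""
        self._require_two_way()
        return 100.0 - self.false_alarm_rate


def score_run(
    reference: np.ndarray,
    hypothesis: np.ndarray,
    mode: ScoringMode | str = ScoringMode.EPOCH_BASED,
    collapse: Collapse | str = Collapse.SIX,
) -> ConfusionMatrix:
    """Confusion matrix over aligned reference/hypothesis label grids.

    ``reference`` and ``hypothesis`` hold class indices (canonical
    order) and must have identical shape; every element is one scored
    unit (flatten per-channel grids for event-based scoring, per-epoch
    sequences for epoch-based scoring).
    """
    mode = ScoringMode(mode)
    collapse = Collapse(collapse)
    ref = np.asarray(reference)
    hyp = np.asarray(hypothesis)
    if ref.shape != hyp.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {hyp.shape}")
    classes = _scheme_classes(collapse)
    lut = np.array(
        [classes.index(collapse_labels(c, collapse)) for c in CLASS_ORDER]
    )
    ref_c = lut[ref.ravel()]
    hyp_c = lut[hyp.ravel()]
    n = len(classes)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (ref_c, hyp_c), 1)
    df = pd.DataFrame(counts, index=classes, columns=classes)
    df.index.name = "reference"
    df.columns.name = "hypothesis"
    return ConfusionMatrix(counts=df, mode=mode, collapse=collapse)


@dataclass
class DetCurve:
    """Detection error tradeoff points swept over a score penalty.

    Each point is (false-alarm %, miss %) at one penalty subtracted
    from the target-class score before thresholding at 0.5;
    ``zero_penalty_index`` marks the unmodified operating point.
    """

    points: pd.DataFrame          # columns: penalty, false_alarm, miss
    zero_penalty_index: int


def det_curve(
    target_scores: np.ndarray,
    reference_binary: np.ndarray,
    penalties: np.ndarray | None = None,
    threshold: float = 0.5,
) -> DetCurve:
    """Sweep an operating-point penalty over target-class scores.

    A unit is hypothesized TARG iff ``score - penalty > threshold``.
    ``reference_binary`` is 1 for target units, 0 for background;
    both classes must occur.  ``false_alarm`` and ``miss`` are
    percentages.
    """
    scores = np.asarray(target_scores, dtype=np.float64).ravel()
    ref = np.asarray(reference_binary).ravel().astype(bool)
    if ref.all() or not ref.any():
        raise ValueError("DET curve needs both target and background units")
    if penalties is None:
        penalties = np.linspace(-threshold, 1.0 - threshold, 61)
    penalties = np.asarray(penalties, dtype=np.float64)
    if not np.any(penalties == 0.0):
        penalties = np.sort(np.append(penalties, 0.0))
    rows = []
    for p in penalties:
        hyp = scores - p > threshold
        fa = 100.0 * np.mean(hyp[~ref])
        miss = 100.0 * np.mean(~hyp[ref])
        rows.append((float(p), fa, miss))
    df = pd.DataFrame(rows, columns=["penalty", "false_alarm", "miss"])
    zero_idx = int(np.flatnonzero(df["penalty"].to_numpy() == 0.0)[0])
    return DetCurve(points=df, zero_penalty_index=zero_idx)


def render_table(matrix: ConfusionMatrix, percentages: bool = True) -> str:
    """Plain-text rendering of a confusion matrix (row percentages)."""
    df = matrix.percentages if percentages else matrix.counts
    header = f"{matrix.mode.value}, {matrix.collapse.value}-way"
    return f"{header}\n{df.round(2).to_string()}"
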