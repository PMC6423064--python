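"""Synthetic annotated EEG corpora with the statistical structure the
pipeline assumes.

The generator emits 22-channel TCP-montage records at 250 Hz:
pink (1/f) background noise everywhere, with stylized events injected
on class-appropriate channel subsets and annotated per channel:

* ``SPSW`` — isolated biphasic transients (20-70 ms) on a small focal
  channel subset;
* ``PLED`` — spike trains repeating every 1.5-3 s, lateralized to one
  hemisphere's derivations;
* ``GPED`` — bilaterally symmetric, synchronized spike trains at the
  shorter 0.5-1 s intervals of diffuse periodic discharges;
* ``EYEM`` — slow high-amplitude deflections on the frontal
  derivations;
* ``ARTF`` — broadband noise bursts on a random channel subset;
* ``BCKG`` — everything else.

Waveforms are parameterized shapes, not biophysical simulations: the
goal is class-separable structure carrying the right temporal (periodic
intervals, transient widths) and spatial (lateralized / diffuse /
frontal) signatures, together with a realistic class imbalance
(background dominates; spikes are rare).  Event intervals are aligned
to the 1 s epoch grid that all downstream scoring uses.

Records never mix PLED and GPED: each record that carries periodic
discharges is designated as one or the other, mirroring the clinical
rule that the two patterns do not co-occur in a session.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edf_io import (
    CANONICAL_RATE,
    TCP_CHANNEL_NAMES,
    ChannelAnnotation,
    ClassLabel,
    SignalRecord,
    write_annotations,
    write_edf,
)

logger = logging.getLogger(__name__)

#: Montage channel groups (indices into :data:`TCP_CHANNEL_NAMES`).
LEFT_CHANNELS = (0, 1, 2, 3, 8, 9, 14, 15, 16, 17)
RIGHT_CHANNELS = (4, 5, 6, 7, 12, 13, 18, 19, 20, 21)
FRONTAL_CHANNELS = (0, 4, 14, 18)   # derivations involving FP1/FP2
N_CHANNELS = len(TCP_CHANNEL_NAMES)


@dataclass(frozen=True)
class EventTemplate:
    """Shape and spatial-rule parameters for one event class."""

    label: ClassLabel
    amplitude: float            # peak amplitude, uV
    duration: tuple[int, int]   # whole-second event length range
    spike_width: tuple[float, float] = (0.02, 0.07)   # s, biphasic transient
    discharge_interval: tuple[float, float] = (0.0, 0.0)  # s, 0 = aperiodic
    channel_policy: str = "focal"   # focal | hemisphere | bilateral | frontal | burst


def default_templates(amplitude_scale: float = 1.0) -> dict[ClassLabel, EventTemplate]:
    """Stylized event templates (the "easy", high-SNR profile at scale 1)."""
    a = amplitude_scale
    return {
        ClassLabel.SPSW: EventTemplate(
            ClassLabel.SPSW, amplitude=150.0 * a, duration=(1, 1),
            channel_policy="focal"),
        ClassLabel.PLED: EventTemplate(
            ClassLabel.PLED, amplitude=120.0 * a, duration=(8, 14),
            discharge_interval=(1.5, 3.0), channel_policy="hemisphere"),
        ClassLabel.GPED: EventTemplate(
            ClassLabel.GPED, amplitude=120.0 * a, duration=(8, 14),
            discharge_interval=(0.5, 1.0), channel_policy="bilateral"),
        ClassLabel.EYEM: EventTemplate(
            ClassLabel.EYEM, amplitude=180.0 * a, duration=(1, 2),
            channel_policy="frontal"),
        ClassLabel.ARTF: EventTemplate(
            ClassLabel.ARTF, amplitude=60.0 * a, duration=(1, 3),
            channel_policy="burst"),
    }


#: Default epoch-time class mix, mirroring the strong imbalance of
#: clinical event corpora (background dominates, spikes are rare).
DEFAULT_CLASS_MIX: dict[ClassLabel, float] = {
    ClassLabel.SPSW: 0.010,
    ClassLabel.PLED: 0.130,
    ClassLabel.GPED: 0.075,
    ClassLabel.EYEM: 0.015,
    ClassLabel.ARTF: 0.130,
    ClassLabel.BCKG: 0.640,
}


@dataclass(frozen=True)
class CorpusSpec:
    """What to generate: sizes, class mix, noise, reproducibility seed.

    ``class_mix`` gives target fractions of record time per class and
    must sum to 1.  ``noise_level`` is the background RMS in uV —
    10 uV is the easy (high-SNR) profile; raise it toward the event
    amplitudes for a hard profile.
    """

    n_records: int = 12
    duration: float = 60.0
    class_mix: "dict[ClassLabel, float] | None" = None
    noise_level: float = 10.0
    amplitude_scale: float = 1.0
    train_frac: float = 0.8
    seed: int = 0

    def mix(self) -> dict[ClassLabel, float]:
        mix = dict(self.class_mix) if self.class_mix else dict(DEFAULT_CLASS_MIX)
        for cls in ClassLabel:
            mix.setdefault(cls, 0.0)
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class mix must sum to 1, got {total}")
        return mix


def hard_spec(**overrides) -> CorpusSpec:
    """The low-SNR, heavier-imbalance evaluation profile."""
    defaults = dict(noise_level=35.0, amplitude_scale=0.7)
    defaults.update(overrides)
    return CorpusSpec(**defaults)


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator, rate: float) -> np.ndarray:
    """1/f-amplitude noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if n > 1 else 1.0))
    shaped = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(shaped ** 2))
    return shaped / max(rms, 1e-12)


def _biphasic_spike(width_s: float, rate: float) -> np.ndarray:
    """Gaussian-derivative transient, peak amplitude 1."""
    sigma = width_s / 6.0
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / rate)
    w = -t * np.exp(-(t ** 2) / (2 * sigma ** 2))
    return w / np.max(np.abs(w))


def _slow_wave(dur_s: float, rate: float) -> np.ndarray:
    """Single-cycle raised-cosine deflection, peak amplitude 1."""
    n = max(int(round(dur_s * rate)), 4)
    t = np.linspace(0.0, np.pi, n)
    return np.sin(t) ** 2


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------

def _pick_channels(policy: str, rng: np.random.Generator,
                   hemisphere: tuple[int, ...]) -> np.ndarray:
    if policy == "focal":
        k = int(rng.integers(2, 5))
        return rng.choice(hemisphere, size=k, replace=False)
    if policy == "hemisphere":
        return np.asarray(hemisphere)
    if policy == "bilateral":
        return np.arange(N_CHANNELS)
    if policy == "frontal":
        return np.asarray(FRONTAL_CHANNELS)
    if policy == "burst":
        k = int(rng.integers(4, 9))
        return rng.choice(N_CHANNELS, size=k, replace=False)
    raise ValueError(f"unknown channel policy {policy!r}")


_GOLDEN = 0.6180339887498949


def _stratified_uniform(record_index: int) -> float:
    """Low-discrepancy pseudo-uniform in [0, 1) per record.

    Record-level attributes (periodic pattern type, lateralization)
    use this instead of iid draws so that even very small corpora
    cover both alternatives at the intended marginal rates.
    """
    return ((record_index + 1) * _GOLDEN) % 1.0


def _schedule_events(
    spec: CorpusSpec, rng: np.random.Generator,
    templates: dict[ClassLabel, EventTemplate],
    record_index: int,
) -> list[tuple[ClassLabel, int, int]]:
    """Non-overlapping whole-second (label, start_s, stop_s) slots."""
    mix = spec.mix()
    dur = int(round(spec.duration))
    # one periodic pattern per record, never both
    p_pled, p_gped = mix[ClassLabel.PLED], mix[ClassLabel.GPED]
    periodic_share = p_pled + p_gped
    periodic_cls = None
    if periodic_share > 0:
        periodic_cls = ClassLabel.PLED if _stratified_uniform(
            record_index
        ) < (p_pled / periodic_share) else ClassLabel.GPED
    def draw_events(cls: ClassLabel, target: float) -> list[int]:
        """Event durations totalling ``target`` seconds in expectation.

        A fractional remainder becomes one more event with probability
        remainder/duration, keeping the corpus-level class mix unbiased
        even when a class's share of one record is under a second.
        """
        lo, hi = templates[cls].duration
        out = []
        while target > 0:
            d = min(int(rng.integers(lo, hi + 1)), dur)
            if target < d:
                # shrink the final event to the remaining budget and emit
                # it with the matching probability, keeping the corpus
                # mix unbiased even for sub-second class shares
                d = max(1, int(np.ceil(target)))
                if rng.random() < target / d:
                    out.append(d)
                break
            out.append(d)
            target -= d
        return out

    wanted: list[tuple[ClassLabel, int]] = []   # (class, event seconds)
    if periodic_cls is not None:
        wanted += [(periodic_cls, d)
                   for d in draw_events(periodic_cls, periodic_share * dur)]
    for cls in (ClassLabel.SPSW, ClassLabel.EYEM, ClassLabel.ARTF):
        wanted += [(cls, d) for d in draw_events(cls, mix[cls] * dur)]
    total_event = sum(d for _, d in wanted)
    if total_event > dur:
        raise ValueError(
            f"class mix requires {total_event} event seconds in a "
            f"{dur} s record"
        )
    # place longest first into random whole-second gaps
    order = sorted(range(len(wanted)), key=lambda i: -wanted[i][1])
    occupied = np.zeros(dur, dtype=bool)
    placed: list[tuple[ClassLabel, int, int]] = []
    for i in order:
        cls, d = wanted[i]
        starts = [s for s in range(0, dur - d + 1)
                  if not occupied[s : s + d].any()]
        if not starts:
            logger.warning("no room for a %s event of %d s; skipped",
                           cls.name, d)
            continue
        s = int(rng.choice(starts))
        occupied[s : s + d] = True
        placed.append((cls, s, s + d))
    return sorted(placed, key=lambda e: e[1])


def generate_record(
    spec: CorpusSpec,
    record_index: int = 0,
    templates: dict[ClassLabel, EventTemplate] | None = None,
) -> tuple[SignalRecord, list[ChannelAnnotation]]:
    """One annotated 22-channel montage record.

    Deterministic in ``(spec.seed, record_index)``.  Annotations
    exactly cover injected event intervals on the affected channels;
    every remaining (channel, time) span is annotated BCKG.
    """
    templates = templates or default_templates(spec.amplitude_scale)
    rng = np.random.default_rng([spec.seed, record_index])
    rate = CANONICAL_RATE
    n = int(round(spec.duration * rate))
    data = np.empty((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        data[ch] = spec.noise_level * _pink_noise(n, rng, rate)

    # lateralization alternates across records (50% marginal, full
    # coverage of both sides in any corpus of two or more records)
    hemisphere = LEFT_CHANNELS if record_index % 2 == 0 else RIGHT_CHANNELS
    events = _schedule_events(spec, rng, templates, record_index)
    annotations: list[ChannelAnnotation] = []
    event_spans: dict[int, list[tuple[float, float]]] = {
        ch: [] for ch in range(N_CHANNELS)
    }
    for cls, start_s, stop_s in events:
        tpl = templates[cls]
        chans = _pick_channels(tpl.channel_policy, rng, hemisphere)
        s0, s1 = int(start_s * rate), int(stop_s * rate)
        span = s1 - s0
        if cls in (ClassLabel.PLED, ClassLabel.GPED):
            # synchronized periodic spike train, per-channel amplitude jitter
            interval = rng.uniform(*tpl.discharge_interval)
            width = rng.uniform(*tpl.spike_width)
            wave = _biphasic_spike(width, rate)
            t = int(0.1 * rate)
            positions = []
            while t + wave.size < span:
                positions.append(t)
                t += int(interval * rate)
            gains = rng.uniform(0.7, 1.0, size=chans.size)
            for g, ch in zip(gains, chans):
                for p in positions:
                    data[ch, s0 + p : s0 + p + wave.size] += (
                        tpl.amplitude * g * wave
                    )
        elif cls is ClassLabel.SPSW:
            width = rng.uniform(*tpl.spike_width)
            wave = _biphasic_spike(width, rate)
            p = int(rng.integers(0, max(span - wave.size, 1)))
            for ch in chans:
                data[ch, s0 + p : s0 + p + wave.size] += tpl.amplitude * wave
        elif cls is ClassLabel.EYEM:
            wave = _slow_wave(rng.uniform(0.4, 0.7), rate)
            p = int(rng.integers(0, max(span - wave.size, 1)))
            sign = rng.choice([-1.0, 1.0])
            for ch in chans:
                data[ch, s0 + p : s0 + p + wave.size] += (
                    sign * tpl.amplitude * wave
                )
        elif cls is ClassLabel.ARTF:
            burst = rng.standard_normal((chans.size, span))
            env = _slow_wave(stop_s - start_s, rate)[:span]
            data[np.asarray(chans), s0:s1] += tpl.amplitude * burst * env
        for ch in chans:
            annotations.append(
                ChannelAnnotation(int(ch), float(start_s), float(stop_s), cls)
            )
            event_spans[int(ch)].append((float(start_s), float(stop_s)))

    # background annotations fill the complement on every channel
    for ch in range(N_CHANNELS):
        cursor = 0.0
        for a, b in sorted(event_spans[ch]):
            if a > cursor:
                annotations.append(
                    ChannelAnnotation(ch, cursor, a, ClassLabel.BCKG)
                )
            cursor = max(cursor, b)
        if cursor < spec.duration:
            annotations.append(
                ChannelAnnotation(ch, cursor, spec.duration, ClassLabel.BCKG)
            )

    record = SignalRecord(data, rate, list(TCP_CHANNEL_NAMES))
    annotations.sort(key=lambda a: (a.channel_index, a.start))
    return record, annotations


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> dict:
    """Write ``n_records`` EDF + annotation CSV pairs with a train/eval
    split and a manifest.

    Records are disjoint pseudo-patients; the first ``train_frac`` of
    them form the training set.  Returns the manifest dict (also
    written as ``manifest.json``).
    """
    if spec.n_records < 2:
        raise ValueError("need at least 2 records for a train/eval split")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    event_counts = {c.name: 0 for c in ClassLabel}
    for i in range(spec.n_records):
        stem = f"rec_{i:03d}"
        record, annots = generate_record(spec, i)
        write_edf(record, out / f"{stem}.edf")
        write_annotations(annots, out / f"{stem}.csv")
        for a in annots:
            event_counts[a.label.name] += 1
        names.append(stem)
    n_train = max(1, int(round(spec.train_frac * spec.n_records)))
    n_train = min(n_train, spec.n_records - 1)
    manifest = {
        "train": names[:n_train],
        "eval": names[n_train:],
        "event_counts": event_counts,
        "n_records": spec.n_records,
        "duration": spec.duration,
        "noise_level": spec.noise_level,
        "seed": spec.seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
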