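"""EDF signal I/O, TCP montage, resampling, and per-channel annotations.

Clinical EEG is exchanged as EDF (European Data Format): a fixed ASCII
header followed by 16-bit little-endian sample records.  Reading goes
through :mod:`mne`; writing is implemented directly against the EDF
header layout since no writer is available in the scientific stack this
package targets.

All amplitudes are physical microvolts.  Time intervals are half-open
``[start, stop)`` seconds from record start.  The pipeline's canonical
sampling rate is 250 Hz and its canonical spatial representation is the
22-channel TCP (temporal-central-parasagittal) bipolar montage derived
from the standard 10/20 electrode set.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

CANONICAL_RATE = 250.0
N_MONTAGE_CHANNELS = 22


class EdfFormatError(ValueError):
    """Malformed EDF content; the message names the offending field."""


class AnnotationError(ValueError):
    """Invalid annotation row (bad label, bad interval, bad index)."""


class MontageError(KeyError):
    """Montage references an electrode absent from the record."""


class ClassLabel(Enum):
    """The six clinical EEG event classes.

    The member order is the canonical class ordering used everywhere a
    class axis appears (posterior vectors, confusion matrices, the
    bigram transition table): SPSW, PLED, GPED, EYEM, ARTF, BCKG.
    """

    SPSW = 0  # spike and/or sharp wave
    PLED = 1  # periodic lateralized epileptiform discharges
    GPED = 2  # generalized periodic epileptiform discharges
    EYEM = 3  # eye movement
    ARTF = 4  # artifact (non-cerebral)
    BCKG = 5  # background

    @classmethod
    def from_string(cls, token: str) -> "ClassLabel":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise AnnotationError(
                f"unknown class label {token!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: Canonical label ordering as a list (index == posterior-vector position).
CLASS_ORDER: tuple[ClassLabel, ...] = tuple(ClassLabel)
N_CLASSES = len(CLASS_ORDER)


@dataclass
class SignalRecord:
    """Multichannel sampled EEG.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    rate
        Sampling rate in samples/second.
    channel_names
        Ordered electrode names (referential record) or ``"A-B"``
        derivation names (montaged record).
    start_time
        Offset of the first sample in seconds, recording-relative.
    """

    samples: np.ndarray
    rate: float
    channel_names: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows vs "
                f"{len(self.channel_names)} channel names"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError:
            raise MontageError(name) from None


@dataclass(frozen=True)
class ChannelAnnotation:
    """A labeled half-open interval ``[start, stop)`` on one channel."""

    channel_index: int
    start: float
    stop: float
    label: ClassLabel

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.stop:
            raise AnnotationError(
                f"require 0 <= start < stop, got [{self.start}, {self.stop})"
            )
        if self.channel_index < 0:
            raise AnnotationError(f"negative channel_index {self.channel_index}")


# ---------------------------------------------------------------------------
# TCP montage
# ---------------------------------------------------------------------------

#: The 22 bipolar derivations of the standard TCP montage (ACNS/TUH
#: convention).  The exact pair list is not universal across vendors;
#: this default follows the published ACNS temporal-central-parasagittal
#: layout and can be overridden with a YAML pair list.
STANDARD_TCP_MONTAGE: tuple[tuple[str, str], ...] = (
    ("FP1", "F7"), ("F7", "T3"), ("T3", "T5"), ("T5", "O1"),
    ("FP2", "F8"), ("F8", "T4"), ("T4", "T6"), ("T6", "O2"),
    ("A1", "T3"), ("T3", "C3"), ("C3", "CZ"), ("CZ", "C4"),
    ("C4", "T4"), ("T4", "A2"), ("FP1", "F3"), ("F3", "C3"),
    ("C3", "P3"), ("P3", "O1"), ("FP2", "F4"), ("F4", "C4"),
    ("C4", "P4"), ("P4", "O2"),
)

#: Electrode names required by the standard montage.
TCP_ELECTRODES: tuple[str, ...] = tuple(
    dict.fromkeys(e for pair in STANDARD_TCP_MONTAGE for e in pair)
)

#: Derivation names of the standard montage, e.g. ``"FP1-F7"``.
TCP_CHANNEL_NAMES: tuple[str, ...] = tuple(
    f"{a}-{b}" for a, b in STANDARD_TCP_MONTAGE
)


def load_montage(path: str | Path) -> list[tuple[str, str]]:
    """Load a montage pair list from a YAML file (list of 2-item lists)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pairs = []
    for item in raw:
        if len(item) != 2:
            raise EdfFormatError(f"montage entry {item!r} is not a pair")
        pairs.append((str(item[0]).upper(), str(item[1]).upper()))
    return pairs


def apply_tcp_montage(
    record: SignalRecord,
    montage_spec: "list[tuple[str, str]] | None" = None,
) -> SignalRecord:
    """Derive bipolar montage channels ``A - B`` from a referential record.

    Each output channel is the sample-wise difference of two electrode
    channels; channel names become ``"A-B"``.  With the default spec a
    conforming 10/20 record yields exactly 22 channels.
    """
    pairs = list(montage_spec) if montage_spec is not None else list(
        STANDARD_TCP_MONTAGE
    )
    names_upper = [n.upper() for n in record.channel_names]
    missing = sorted(
        {e for pair in pairs for e in pair if e.upper() not in names_upper}
    )
    if missing:
        raise MontageError(
            f"montage electrodes missing from record: {', '.join(missing)}"
        )
    index = {n: i for i, n in enumerate(names_upper)}
    out = np.empty((len(pairs), record.n_samples))
    names = []
    for row, (a, b) in enumerate(pairs):
        out[row] = record.samples[index[a.upper()]] - record.samples[index[b.upper()]]
        names.append(f"{a}-{b}")
    return SignalRecord(out, record.rate, names, record.start_time)


def is_montaged(record: SignalRecord) -> bool:
    """True if every channel name looks like a bipolar derivation."""
    return all("-" in n for n in record.channel_names)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_record(record: SignalRecord, target_rate: float) -> SignalRecord:
    """Polyphase-resample all channels to ``target_rate``.

    Uses a zero-phase anti-alias FIR (scipy's polyphase resampler), so
    downsampling is alias-protected and the duration is preserved to
    within one sample period.  Records below the target rate are
    upsampled with a warning, since clinical sources are expected at
    250 Hz or above.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if math.isclose(record.rate, target_rate):
        return record
    if record.rate < target_rate:
        logger.warning(
            "upsampling record from %.6g Hz to %.6g Hz", record.rate, target_rate
        )
    frac = Fraction(target_rate / record.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(record.samples, up, down, axis=1)
    return SignalRecord(out, target_rate, list(record.channel_names),
                        record.start_time)


def canonicalize(
    record: SignalRecord,
    montage_spec: "list[tuple[str, str]] | None" = None,
) -> SignalRecord:
    """Bring a record to the pipeline's canonical form: 250 Hz, montaged.

    Records whose channels are already bipolar derivations are only
    resampled; referential records additionally get the TCP montage.
    """
    rec = resample_record(record, CANONICAL_RATE)
    if not is_montaged(rec):
        rec = apply_tcp_montage(rec, montage_spec)
    return rec


# ---------------------------------------------------------------------------
# EDF reading (via mne) and writing (native)
# ---------------------------------------------------------------------------

def read_edf(path: str | Path) -> SignalRecord:
    """Read an EDF file into a :class:`SignalRecord` (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise EdfFormatError(f"cannot parse EDF header of {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise EdfFormatError(f"{path}: EDF contains zero signal channels")
    data = raw.get_data() * 1e6  # mne holds volts; EDF EEG is written in uV
    return SignalRecord(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _fit_field(value: str, width: int) -> bytes:
    out = value[:width].ljust(width)
    return out.encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical bound into EDF's 8-char field."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    return ("%.2g" % v)[:8]


def write_edf(record: SignalRecord, path: str | Path) -> Path:
    """Write a :class:`SignalRecord` as a 16-bit EDF file.

    Physical min/max headers are chosen symmetric about zero to cover
    the data, so quantization error is at most one least-significant bit
    of the 16-bit range.  Sampling rate must be a positive integer and
    the record is zero-padded to a whole number of 1-second data
    records.
    """
    path = Path(path)
    data = np.asarray(record.samples, dtype=np.float64)
    if data.size == 0:
        raise ValueError("cannot write an empty record")
    if not np.all(np.isfinite(data)):
        raise ValueError("record contains NaN or Inf samples")
    rate = record.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer rate, got {rate}")
    spr = int(round(rate))  # samples per 1 s data record
    n_ch, n_samp = data.shape
    n_records = int(math.ceil(n_samp / spr))
    if n_records * spr != n_samp:
        logger.warning("zero-padding record tail to a whole second for EDF")
        pad = n_records * spr - n_samp
        data = np.pad(data, ((0, 0), (0, pad)))

    dig_min, dig_max = -32768, 32767
    phys_bounds = []
    scaled = np.empty_like(data, dtype=np.int16)
    for i in range(n_ch):
        amp = float(np.max(np.abs(data[i])))
        pmax = float(_fmt_phys(amp if amp > 0 else 1.0))
        if pmax < amp:  # rounding down must not clip the data
            pmax = float(_fmt_phys(amp * 1.001 + 1e-12))
        phys_bounds.append(pmax)
        # invert the reader's linear map: phys = (dig - dmin)*gain + pmin
        gain = 2.0 * pmax / (dig_max - dig_min)
        scaled[i] = np.clip(
            np.round((data[i] + pmax) / gain + dig_min), dig_min, dig_max
        ).astype(np.int16)

    header = b"".join([
        _fit_field("0", 8),
        _fit_field("X X X X", 80),          # patient id
        _fit_field("Startdate X X X X", 80),  # recording id
        _fit_field("01.01.00", 8),
        _fit_field("00.00.00", 8),
        _fit_field(str(256 * (1 + n_ch)), 8),
        _fit_field("", 44),
        _fit_field(str(n_records), 8),
        _fit_field("1", 8),                  # data record duration, s
        _fit_field(str(n_ch), 4),
    ])
    sig_fields = []
    for width, values in (
        (16, record.channel_names),
        (80, [""] * n_ch),                      # transducer
        (8, ["uV"] * n_ch),
        (8, [_fmt_phys(-b) for b in phys_bounds]),
        (8, [_fmt_phys(b) for b in phys_bounds]),
        (8, [str(dig_min)] * n_ch),
        (8, [str(dig_max)] * n_ch),
        (80, [""] * n_ch),                      # prefiltering
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ):
        for v in values:
            sig_fields.append(_fit_field(str(v), width))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(sig_fields))
        # data records: per record, all samples of ch0, then ch1, ...
        blocks = scaled.reshape(n_ch, n_records, spr)
        interleaved = np.ascontiguousarray(blocks.transpose(1, 0, 2))
        fh.write(interleaved.astype("<i2").tobytes())
    return path


# ---------------------------------------------------------------------------
# Annotation CSV I/O
# ---------------------------------------------------------------------------

_ANNOT_COLUMNS = ("channel_index", "start", "stop", "label")


def read_annotations(path: str | Path) -> list[ChannelAnnotation]:
    """Read per-channel annotations from CSV.

    Expected columns: ``channel_index,start,stop,label`` with a header
    row; labels must be one of the six class names.
    """
    out: list[ChannelAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_ANNOT_COLUMNS) - set(
            reader.fieldnames
        ):
            raise AnnotationError(
                f"annotation CSV must have columns {_ANNOT_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            out.append(
                ChannelAnnotation(
                    channel_index=int(row["channel_index"]),
                    start=float(row["start"]),
                    stop=float(row["stop"]),
                    label=ClassLabel.from_string(row["label"]),
                )
            )
    return out


def write_annotations(
    annotations: list[ChannelAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_COLUMNS)
        for a in annotations:
            writer.writerow(
                [a.channel_index, repr(a.start), repr(a.stop), a.label.name]
            )
    return path
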