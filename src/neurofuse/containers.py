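"""Standardized multimodal signal containers and alignment.

The central object is :class:`SignalBlock`, one modality's channels x samples
matrix with its sampling rate and channel labels.  Blocks live in a
:class:`Recording` together with an :class:`EventTable`; trials cut around
events form an :class:`EpochSet`, whose across-trial average is an *evoked*
block.  Heterogeneous acquisition rates are harmonized either by time-point
alignment (synchronous clocks) or by event-based alignment (a shared marker).

Conventions: time in seconds, 0-based sample indexing, half-open epoch
windows ``[tmin, tmax)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import AlignmentError, InputError, ParameterError

MODALITIES = ("eeg", "fnirs_intensity", "fnirs_hb", "emg", "ecg", "eog", "aux")
STAGES = ("raw", "epoch", "evoked")
CHROMOPHORES = ("HbO", "HbR", "none")


@dataclass
class SignalBlock:
    """One modality's multichannel time series.

    Parameters
    ----------
    modality : str
        One of ``eeg, fnirs_intensity, fnirs_hb, emg, ecg, eog, aux``.
        Amplitudes are in microvolts for eeg/emg/ecg/eog, arbitrary intensity
        units for raw fNIRS, and micromolar concentration change for
        ``fnirs_hb``.
    data : ndarray, shape (n_channels, n_samples)
    rate : float
        Sampling rate in Hz, > 0.
    labels : sequence of str
        Per-channel names; length must equal the number of rows of ``data``.
    chromophore : sequence of str, optional
        Per-channel tag in ``{"HbO", "HbR", "none"}``; only meaningful (and
        only allowed to differ from "none") for ``fnirs_hb``.
    start_time : float
        Seconds relative to the session origin.
    stage : str
        ``raw``, ``epoch`` or ``evoked``.
    """

    modality: str
    data: np.ndarray
    rate: float
    labels: list[str]
    chromophore: list[str] | None = None
    start_time: float = 0.0
    stage: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be 2-D (channels x samples)")
        if self.modality not in MODALITIES:
            raise ParameterError(f"unknown modality {self.modality!r}")
        if self.stage not in STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise ParameterError("rate must be a positive finite number")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise InputError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise InputError("data contains non-finite samples")
        if self.chromophore is None:
            self.chromophore = ["none"] * self.n_channels
        self.chromophore = [str(c) for c in self.chromophore]
        if len(self.chromophore) != self.n_channels:
            raise InputError("chromophore length must match channel count")
        for c in self.chromophore:
            if c not in CHROMOPHORES:
                raise ParameterError(f"unknown chromophore tag {c!r}")
            if c != "none" and self.modality != "fnirs_hb":
                raise InputError("chromophore tags require modality fnirs_hb")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the block in seconds."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the session origin."""
        return self.start_time + np.arange(self.n_samples) / self.rate

    def copy(self, **changes) -> "SignalBlock":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        if "labels" not in changes:
            out.labels = list(self.labels)
        if "chromophore" not in changes:
            out.chromophore = list(self.chromophore)
        return out

    def crop(self, t_start: float, t_stop: float) -> "SignalBlock":
        """Return the sub-block covering session time ``[t_start, t_stop)``."""
        i0 = int(round((t_start - self.start_time) * self.rate))
        i1 = int(round((t_stop - self.start_time) * self.rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise AlignmentError("crop window does not overlap the block")
        return self.copy(data=self.data[:, i0:i1],
                         start_time=self.start_time + i0 / self.rate)


class EventTable:
    """Table of (onset s, duration s, label) rows, kept sorted by onset."""

    def __init__(self, onsets, durations, labels):
        onsets = np.asarray(onsets, dtype=float)
        durations = np.asarray(durations, dtype=float)
        labels = np.asarray([str(x) for x in labels], dtype=object)
        if not (len(onsets) == len(durations) == len(labels)):
            raise InputError("onsets, durations and labels must have equal length")
        if np.any(durations < 0):
            raise InputError("durations must be >= 0")
        order = np.argsort(onsets, kind="stable")
        self.onsets = onsets[order]
        self.durations = durations[order]
        self.labels = labels[order]

    def __len__(self) -> int:
        return len(self.onsets)

    def __eq__(self, other) -> bool:
        return (isinstance(other, EventTable)
                and np.array_equal(self.onsets, other.onsets)
                and np.array_equal(self.durations, other.durations)
                and np.array_equal(self.labels, other.labels))

    def select(self, label: str) -> "EventTable":
        m = self.labels == label
        return EventTable(self.onsets[m], self.durations[m], self.labels[m])

    def shift(self, offset: float) -> "EventTable":
        return EventTable(self.onsets + offset, self.durations, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset": self.onsets, "duration": self.durations,
                             "trial_type": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        cols = {c.lower(): c for c in df.columns}
        label_col = next((cols[k] for k in ("trial_type", "label", "value", "event")
                          if k in cols), None)
        if "onset" not in cols or label_col is None:
            raise InputError("event table needs onset and trial_type/label columns")
        dur = df[cols["duration"]] if "duration" in cols else np.zeros(len(df))
        return cls(df[cols["onset"]].to_numpy(float), np.asarray(dur, float),
                   df[label_col].astype(str).to_numpy())

    @classmethod
    def read_tsv(cls, path) -> "EventTable":
        """Read a BIDS-style events TSV (onset / duration / trial_type)."""
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Recording:
    """Aligned multi-modality bundle of signal blocks plus events.

    ``blocks`` maps a modality key (usually the modality name) to a
    :class:`SignalBlock`.  ``events_by_key`` optionally carries a separate
    event stream per block for event-based alignment of asynchronously
    recorded signals; when absent, the shared ``events`` table applies.
    """

    blocks: dict[str, SignalBlock] = field(default_factory=dict)
    events: EventTable = field(default_factory=lambda: EventTable([], [], []))
    meta: dict[str, str] = field(default_factory=dict)
    aligned: bool = False
    events_by_key: dict[str, EventTable] = field(default_factory=dict)

    def events_for(self, key: str) -> EventTable:
        return self.events_by_key.get(key, self.events)


@dataclass
class EpochSet:
    """Fixed-length trials cut around events: epochs x channels x samples."""

    data: np.ndarray
    labels: list[str]
    tmin: float
    tmax: float
    rate: float
    source_modality: str
    ch_names: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InputError("EpochSet data must be 3-D")
        if len(self.labels) != self.data.shape[0]:
            raise InputError("one label per epoch required")
        expected = int(round((self.tmax - self.tmin) * self.rate))
        if self.data.shape[2] != expected:
            raise InputError(
                f"expected {expected} samples per epoch, got {self.data.shape[2]}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Alignment


def _integer_ratio_rate(r_high: float, r_low: float) -> float:
    """Target rate for a slow block: r_high / ceil(r_high / r_low).

    Never exceeds the native low rate and guarantees an integer ratio with
    the fastest block.
    """
    return r_high / math.ceil(r_high / r_low - 1e-12)


def resample(block: SignalBlock, new_rate: float) -> SignalBlock:
    """Polyphase resampling with anti-aliasing; identity if the rate matches."""
    if not (np.isfinite(new_rate) and new_rate > 0):
        raise InputError("new_rate must be > 0")
    if new_rate == block.rate:
        return block.copy()
    frac = Fraction(new_rate / block.rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(block.data, up, down, axis=1)
    # duration preserved within one output sample
    n_expected = int(round(block.n_samples * new_rate / block.rate))
    out = out[:, :n_expected] if out.shape[1] > n_expected else out
    return block.copy(data=out, rate=new_rate)


def align_timepoint(recording: Recording) -> Recording:
    """Harmonize synchronously acquired blocks to integer rate ratios.

    Blocks whose rate does not divide the fastest rate by an integer factor
    are resampled down to ``r_high / ceil(r_high / r_low)``; all blocks are
    then cropped to the common duration.
    """
    if not recording.blocks:
        raise InputError("recording has no blocks")
    starts = {b.start_time for b in recording.blocks.values()}
    if len(starts) > 1:
        raise AlignmentError(
            "blocks have different start times; use align_event instead")
    r_high = max(b.rate for b in recording.blocks.values())
    new_blocks = {}
    for key, b in recording.blocks.items():
        ratio = r_high / b.rate
        if abs(ratio - round(ratio)) > 1e-9:
            b = resample(b, _integer_ratio_rate(r_high, b.rate))
        new_blocks[key] = b.copy()
    t_stop = min(b.start_time + b.duration for b in new_blocks.values())
    t_start = next(iter(new_blocks.values())).start_time
    for key, b in new_blocks.items():
        n_keep = int(round((t_stop - t_start) * b.rate))
        new_blocks[key] = b.copy(data=b.data[:, :n_keep])
    return Recording(blocks=new_blocks, events=recording.events,
                     meta=dict(recording.meta), aligned=True,
                     events_by_key=dict(recording.events_by_key))


def align_event(recording: Recording, marker_label: str) -> Recording:
    """Align asynchronously recorded blocks on a shared marker event.

    Each block is shifted so its marker sits at t = 0, cropped to the
    overlapping span, then rate-harmonized as in :func:`align_timepoint`.
    """
    if not recording.blocks:
        raise InputError("recording has no blocks")
    shifted = {}
    shifted_events = {}
    for key, b in recording.blocks.items():
        ev = recording.events_for(key).select(marker_label)
        if len(ev) != 1:
            raise AlignmentError(
                f"block {key!r} must contain exactly one {marker_label!r} "
                f"event (found {len(ev)})")
        marker = float(ev.onsets[0])
        shifted[key] = b.copy(start_time=b.start_time - marker)
        shifted_events[key] = recording.events_for(key).shift(-marker)
    t0 = max(b.start_time for b in shifted.values())
    t1 = min(b.start_time + b.duration for b in shifted.values())
    # crop from the marker itself so it lands on sample 0 in every modality
    t0 = max(t0, 0.0)
    if t1 <= t0:
        raise AlignmentError("blocks have no overlapping time span")
    cropped = {k: b.crop(t0, t1).copy(start_time=t0)
               for k, b in shifted.items()}
    rec = Recording(blocks=cropped, events=shifted_events[next(iter(cropped))],
                    meta=dict(recording.meta), events_by_key=shifted_events)
    return align_timepoint(rec)


# ---------------------------------------------------------------------------
# Epoching


def epoch(block: SignalBlock, events: EventTable, tmin: float, tmax: float,
          label_map: Mapping[str, str] | None = None) -> EpochSet:
    """Cut one epoch per event over the half-open window ``[tmin, tmax)``.

    Windows that touch a recording boundary are dropped, never padded.
    ``label_map`` restricts epoching to the mapped event labels and renames
    them to class labels.
    """
    if tmax <= tmin:
        raise ParameterError("tmax must exceed tmin")
    if block.stage != "raw":
        raise InputError("epoching requires a raw-stage block")
    n_per = int(round((tmax - tmin) * block.rate))
    trials, labels = [], []
    for onset, lab in zip(events.onsets, events.labels):
        if label_map is not None and lab not in label_map:
            continue
        i0 = int(round((onset + tmin - block.start_time) * block.rate))
        if i0 < 0 or i0 + n_per > block.n_samples:
            continue
        trials.append(block.data[:, i0:i0 + n_per])
        labels.append(label_map[lab] if label_map is not None else lab)
    if not trials:
        raise InputError("no events produced a full in-bounds epoch")
    return EpochSet(np.stack(trials), labels, tmin, tmax, block.rate,
                    block.modality, ch_names=list(block.labels))


def evoked(epochs: EpochSet) -> SignalBlock:
    """Per-sample mean across epochs, returned as an evoked-stage block."""
    if epochs.n_epochs < 1:
        raise InputError("need at least one epoch")
    mean = epochs.data.mean(axis=0)
    names = epochs.ch_names or [f"ch{i}" for i in range(mean.shape[0])]
    return SignalBlock(epochs.source_modality, mean, epochs.rate, names,
                       start_time=epochs.tmin, stage="evoked")
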