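"""Peri-event epoching and sliding-window binning of electrode signals.

Around every event onset a 4000 ms window of activity is extracted (2000 ms
before to 2000 ms after the onset) and reduced to the mean amplitude inside
200 ms sub-windows advanced in 25 ms steps.  Bin START offsets span
[-pre_ms, +post_ms] inclusive, so the default grid has 161 bins and epochs
extend to ``post_ms + bin_ms`` past the onset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinGrid:
    """Sliding-window bin grid for peri-event epochs (times in ms)."""

    pre_ms: float = 2000.0
    post_ms: float = 2000.0
    bin_ms: float = 200.0
    stride_ms: float = 25.0

    def __post_init__(self) -> None:
        for name in ("pre_ms", "post_ms", "bin_ms", "stride_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        span = self.pre_ms + self.post_ms
        n, rem = divmod(span, self.stride_ms)
        if rem:
            raise ValueError(
                f"window span {span} ms is not divisible by stride {self.stride_ms} ms"
            )

    @property
    def starts_ms(self) -> np.ndarray:
        n = int(round((self.pre_ms + self.post_ms) / self.stride_ms))
        return -self.pre_ms + self.stride_ms * np.arange(n + 1)

    @property
    def n_bins(self) -> int:
        return int(round((self.pre_ms + self.post_ms) / self.stride_ms)) + 1

    @property
    def epoch_span_ms(self) -> tuple[float, float]:
        """Epoch extent [start, stop) relative to onset, covering every bin."""
        return (-self.pre_ms, self.post_ms + self.bin_ms)


def make_bin_grid(
    pre_ms: float = 2000.0,
    post_ms: float = 2000.0,
    bin_ms: float = 200.0,
    stride_ms: float = 25.0,
) -> BinGrid:
    """Construct a :class:`BinGrid`; the defaults yield 161 bins."""
    return BinGrid(pre_ms=pre_ms, post_ms=post_ms, bin_ms=bin_ms, stride_ms=stride_ms)


@dataclass
class Recording:
    """Continuous multi-electrode signal at a fixed sample rate."""

    data: np.ndarray  # (n_electrodes, n_samples)
    sample_rate_hz: float = 2000.0
    electrode_ids: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.electrode_ids:
            self.electrode_ids = [f"E{i:03d}" for i in range(self.data.shape[0])]
        if len(self.electrode_ids) != self.data.shape[0]:
            raise ValueError("electrode_ids length does not match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sample_rate_hz * 1000.0


class MarginError(ValueError):
    """Raised when an event sits too close to a recording edge to epoch."""


def _epoch_sample_bounds(onset_ms: float, grid: BinGrid, fs: float) -> tuple[int, int]:
    start_ms, stop_ms = grid.epoch_span_ms
    i0 = int(round((onset_ms + start_ms) * fs / 1000.0))
    i1 = int(round((onset_ms + stop_ms) * fs / 1000.0))
    return i0, i1


def extract_epoch(
    recording: Recording,
    onset_ms: float,
    grid: BinGrid,
    electrode: int | None = None,
) -> np.ndarray:
    """Extract the peri-event sample window around ``onset_ms``.

    Returns an array of shape (n_electrodes, n_epoch_samples), or
    (n_epoch_samples,) when a single ``electrode`` index is given.  Raises
    :class:`MarginError` when the window is not fully inside the recording.
    """
    i0, i1 = _epoch_sample_bounds(onset_ms, grid, recording.sample_rate_hz)
    if i0 < 0 or i1 > recording.n_samples:
        raise MarginError(
            f"event at {onset_ms} ms needs samples [{i0}, {i1}) but recording "
            f"has {recording.n_samples}"
        )
    if electrode is None:
        return recording.data[:, i0:i1]
    return recording.data[electrode, i0:i1]


def bin_epoch(samples: np.ndarray, grid: BinGrid, sample_rate_hz: float = 2000.0) -> np.ndarray:
    """Mean amplitude inside every bin of ``grid``.

    ``samples`` covers the full epoch span; entry ``k`` of the result is the
    arithmetic mean of the samples in ``[starts_ms[k], starts_ms[k] + bin_ms)``.
    Works on a 1-d epoch or on a stacked (..., n_samples) array.
    """
    samples = np.asarray(samples, dtype=float)
    fs = sample_rate_hz
    bin_len = int(round(grid.bin_ms * fs / 1000.0))
    step = grid.stride_ms * fs / 1000.0
    offsets = np.round(np.arange(grid.n_bins) * step).astype(int)
    if offsets[-1] + bin_len > samples.shape[-1]:
        raise ValueError(
            f"epoch of {samples.shape[-1]} samples does not cover the last bin "
            f"(needs {offsets[-1] + bin_len})"
        )
    # cumulative-sum rolling mean: mean over [o, o+bin_len)
    csum = np.cumsum(samples, axis=-1, dtype=float)
    csum = np.concatenate([np.zeros(samples.shape[:-1] + (1,)), csum], axis=-1)
    return (csum[..., offsets + bin_len] - csum[..., offsets]) / bin_len


@dataclass
class BinnedResponses:
    """Mean activity per (electrode, event, bin) on a fixed grid."""

    data: np.ndarray  # (n_electrodes, n_events, n_bins)
    grid: BinGrid
    electrode_ids: Sequence[str]
    event_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (electrodes, events, bins)")
        if self.data.shape[2] != self.grid.n_bins:
            raise ValueError(
                f"bin axis has length {self.data.shape[2]}, grid has {self.grid.n_bins}"
            )
        if len(self.electrode_ids) != self.data.shape[0]:
            raise ValueError("electrode_ids length mismatch")
        if len(self.event_ids) != self.data.shape[1]:
            raise ValueError("event_ids length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("binned responses must be finite")

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_events(self) -> int:
        return self.data.shape[1]

    def electrode(self, index: int) -> np.ndarray:
        """(n_events, n_bins) slice for one electrode."""
        return self.data[index]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("binned", data=self.data)
            ds.attrs["pre_ms"] = self.grid.pre_ms
            ds.attrs["post_ms"] = self.grid.post_ms
            ds.attrs["bin_ms"] = self.grid.bin_ms
            ds.attrs["stride_ms"] = self.grid.stride_ms
            f.create_dataset("electrode_ids", data=np.array(self.electrode_ids, dtype="S"))
            f.create_dataset("event_ids", data=np.array(self.event_ids, dtype="S"))

    @classmethod
    def from_hdf5(cls, path) -> "BinnedResponses":
        with h5py.File(path, "r") as f:
            ds = f["binned"]
            grid = BinGrid(
                pre_ms=float(ds.attrs["pre_ms"]),
                post_ms=float(ds.attrs["post_ms"]),
                bin_ms=float(ds.attrs["bin_ms"]),
                stride_ms=float(ds.attrs["stride_ms"]),
            )
            data = ds[()]
            electrode_ids = [s.decode() for s in f["electrode_ids"][()]]
            event_ids = [s.decode() for s in f["event_ids"][()]]
        return cls(data=data, grid=grid, electrode_ids=electrode_ids, event_ids=event_ids)


def bin_events(
    recording: Recording,
    onsets_ms: Sequence[float],
    grid: BinGrid,
    event_ids: Sequence[str] | None = None,
) -> tuple[BinnedResponses, list[int]]:
    """Epoch and bin every event; events without full margin are excluded.

    Returns the binned responses for the retained events and the list of
    excluded event indices (logged).
    """
    onsets = np.asarray(onsets_ms, dtype=float)
    if event_ids is None:
        event_ids = [f"ev{i:05d}" for i in range(len(onsets))]
    kept, excluded, epochs = [], [], []
    for i, onset in enumerate(onsets):
        try:
            epochs.append(extract_epoch(recording, onset, grid))
            kept.append(i)
        except MarginError:
            excluded.append(i)
    if excluded:
        logger.info("excluded %d events without full epoch margin", len(excluded))
    if not kept:
        raise ValueError("no event has a full epoch inside the recording")
    stacked = np.stack(epochs, axis=1)  # (n_elec, n_events, n_samples)
    data = bin_epoch(stacked, grid, recording.sample_rate_hz)
    binned = BinnedResponses(
        data=data,
        grid=grid,
        electrode_ids=list(recording.electrode_ids),
        event_ids=[event_ids[i] for i in kept],
    )
    return binned, excluded
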