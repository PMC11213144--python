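"""Stimulus alignment datasets.

A movie is parsed into *event structures*: image-text pairs anchored either at
word onsets (the language-aligned dataset) or at scene cuts (the vision-aligned
dataset).  Each event pairs a text snippet with a movie frame and carries the
onset time used to epoch the neural recording around it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALIGNMENTS = ("language", "vision")

EVENT_COLUMNS = ["event_id", "alignment", "onset_ms", "text", "image_ref", "movie_id"]


@dataclass(frozen=True)
class EventStructure:
    """One image-text pair with its onset time."""

    event_id: str
    alignment: str
    onset_ms: float
    text: str
    image_ref: str
    movie_id: str = ""

    def __post_init__(self) -> None:
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if not np.isfinite(self.onset_ms) or self.onset_ms < 0:
            raise ValueError(f"onset_ms must be finite and >= 0, got {self.onset_ms}")
        if not self.text:
            raise ValueError("text must be non-empty")
        if not self.image_ref:
            raise ValueError("image_ref must be non-empty")


@dataclass
class AlignmentDataset:
    """An ordered collection of events sharing one alignment tag."""

    alignment: str
    events: list[EventStructure] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"unknown alignment {self.alignment!r}")
        self.events = sorted(self.events, key=lambda e: e.onset_ms)
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            raise ValueError("event_id values must be unique within a dataset")
        for ev in self.events:
            if ev.alignment != self.alignment:
                raise ValueError(
                    f"event {ev.event_id} has alignment {ev.alignment!r}, "
                    f"expected {self.alignment!r}"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event_id": e.event_id,
                    "alignment": e.alignment,
                    "onset_ms": e.onset_ms,
                    "text": e.text,
                    "image_ref": e.image_ref,
                    "movie_id": e.movie_id,
                }
                for e in self.events
            ],
            columns=EVENT_COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AlignmentDataset":
        alignments = frame["alignment"].unique()
        if len(alignments) != 1:
            raise ValueError("frame must contain a single alignment")
        events = [
            EventStructure(
                event_id=str(r.event_id),
                alignment=str(r.alignment),
                onset_ms=float(r.onset_ms),
                text=str(r.text),
                image_ref=str(r.image_ref),
                movie_id="" if pd.isna(r.movie_id) else str(r.movie_id),
            )
            for r in frame.itertuples()
        ]
        return cls(alignment=str(alignments[0]), events=events)


def _check_finite(values: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite times")
    return arr


def nearest_frame(onset_ms: float, frame_times_ms: np.ndarray) -> int:
    """Index of the frame nearest to ``onset_ms``; ties go to the earlier frame.

    ``frame_times_ms`` must be sorted ascending.
    """
    times = np.asarray(frame_times_ms, dtype=float)
    pos = int(np.searchsorted(times, onset_ms))
    if pos == 0:
        return 0
    if pos == len(times):
        return len(times) - 1
    before, after = times[pos - 1], times[pos]
    # tie -> earlier frame (<=)
    return pos - 1 if onset_ms - before <= after - onset_ms else pos


def build_language_events(
    word_table: pd.DataFrame,
    frame_index: pd.DataFrame,
    movie_id: str = "",
) -> AlignmentDataset:
    """Build the language-aligned dataset: one event per word utterance.

    Each word, together with its sentence context, is paired with the movie
    frame closest in time to the word onset.

    Parameters
    ----------
    word_table
        Columns ``word``, ``sentence_text`` (optional), ``onset_ms``.
    frame_index
        Columns ``frame_id``, ``time_ms``.
    """
    if word_table.empty:
        raise ValueError("word_table is empty")
    if frame_index.empty:
        raise ValueError("no frames to align")
    onsets = _check_finite(word_table["onset_ms"], "word_table.onset_ms")
    frame_times = _check_finite(frame_index["time_ms"], "frame_index.time_ms")

    order = np.argsort(frame_times, kind="stable")
    frame_times_sorted = frame_times[order]
    frame_ids_sorted = frame_index["frame_id"].to_numpy()[order]

    events = []
    for i, row in enumerate(word_table.itertuples()):
        word = str(row.word)
        sentence = str(getattr(row, "sentence_text", "") or "")
        text = f"{word} | {sentence}" if sentence else word
        j = nearest_frame(onsets[i], frame_times_sorted)
        events.append(
            EventStructure(
                event_id=f"lang{i:05d}",
                alignment="language",
                onset_ms=float(onsets[i]),
                text=text,
                image_ref=str(frame_ids_sorted[j]),
                movie_id=movie_id,
            )
        )
    return AlignmentDataset(alignment="language", events=events)


def build_vision_events(
    scene_cut_table: pd.DataFrame,
    word_table: pd.DataFrame,
    movie_id: str = "",
) -> AlignmentDataset:
    """Build the vision-aligned dataset: one event per scene cut.

    Each cut frame is paired with the first sentence whose onset is at or
    after the cut time (closed boundary).  Cuts with no following sentence
    are dropped with a logged count.

    Parameters
    ----------
    scene_cut_table
        Columns ``cut_id``, ``time_ms``.
    word_table
        Columns ``word``, ``sentence_id``, ``sentence_text``, ``onset_ms``;
        a sentence's onset is the onset of its first word.
    """
    if scene_cut_table.empty:
        raise ValueError("scene_cut_table is empty")
    if word_table.empty:
        raise ValueError("word_table is empty")
    cut_times = _check_finite(scene_cut_table["time_ms"], "scene_cut_table.time_ms")
    _check_finite(word_table["onset_ms"], "word_table.onset_ms")

    sentences = (
        word_table.groupby("sentence_id", sort=False)
        .agg(onset_ms=("onset_ms", "min"), sentence_text=("sentence_text", "first"))
        .sort_values("onset_ms")
    )
    s_onsets = sentences["onset_ms"].to_numpy(dtype=float)
    s_texts = sentences["sentence_text"].astype(str).to_numpy()

    events = []
    n_dropped = 0
    for i, row in enumerate(scene_cut_table.itertuples()):
        t = cut_times[i]
        j = int(np.searchsorted(s_onsets, t, side="left"))  # onset >= cut
        if j == len(s_onsets):
            n_dropped += 1
            continue
        events.append(
            EventStructure(
                event_id=f"vis{i:05d}",
                alignment="vision",
                onset_ms=float(t),
                text=s_texts[j],
                image_ref=str(row.cut_id),
                movie_id=movie_id,
            )
        )
    if n_dropped:
        logger.warning("dropped %d scene cuts with no following sentence", n_dropped)
    if not events:
        logger.warning("no scene cut has a following sentence; dataset is empty")
    return AlignmentDataset(alignment="vision", events=events)


def write_events_csv(dataset: AlignmentDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_events_csv(path) -> AlignmentDataset:
    return AlignmentDataset.from_frame(pd.read_csv(path, keep_default_na=False))
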