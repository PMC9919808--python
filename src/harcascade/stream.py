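"""Real-time inference loop with event semantics for the risk activities.

Each incoming sample is featurized against its immediate predecessor,
classified, and turned into a per-activity indicator message, the contract
an IoT dashboard consumes: ``{"t": ..., "cough": 0/1, "fall": 0/1,
"sit": 0/1, "walk": 0/1, "sleep": 0/1}``.  Exactly one indicator reflects
the current prediction; the fall channel may additionally stay at 1 while
the fall alarm is latched.

Event semantics:

* **Fall latching** — the first fall prediction raises the fall indicator
  and keeps it raised, whatever is predicted afterwards, until an explicit
  :func:`reset_fall` (the wearer's restart button or a manual
  intervention).  Ongoing activity is still classified and reported
  normally while the alarm is up.
* **Cough episodes** — a maximal run of consecutive cough predictions
  counts as one cough toward the daily total; counting raw 10 Hz samples
  would inflate the tally roughly tenfold per second of coughing.  The
  daily counter resets when the sample timestamp crosses a day boundary
  (stream time, not wall clock).

Transport is deliberately abstract: anything with a
``publish(topic, payload)`` method works.  A file-based publisher is
included; wiring a broker client (e.g. MQTT) in is a deployment concern,
not a library one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Protocol

import pandas as pd

from .cascade import TrainedCascade, predict_labels
from .errors import InvalidStateError
from .features import AccelSample, featurize_stream
from .io import read_stream
from .taxonomy import ACTIVITIES

__all__ = [
    "EventState",
    "Publisher",
    "FilePublisher",
    "step",
    "reset_fall",
    "replay",
    "ReplayResult",
]

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class EventState:
    """Accumulated event state of one monitored stream."""

    fall_latched: bool = False
    cough_count_today: int = 0
    current_activity: str | None = None
    day_key: int | None = None
    in_cough_run: bool = False


class Publisher(Protocol):
    def publish(self, topic: str, payload: dict) -> None: ...


class FilePublisher:
    """JSON-lines publisher: one message object per line."""

    def __init__(self, path):
        self._fh = open(path, "w")

    def publish(self, topic: str, payload: dict) -> None:
        self._fh.write(json.dumps({"topic": topic, **payload}) + "\n")

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def _check_model(model) -> None:
    if isinstance(model, TrainedCascade):
        if model.model1 is None or model.model2 is None or model.model3 is None:
            raise InvalidStateError("cascade is not fully trained")
    elif not hasattr(model, "predict"):
        raise InvalidStateError(f"object of type {type(model).__name__} cannot predict")


def _featurize_pair(sample: AccelSample, prev: AccelSample | None) -> pd.DataFrame:
    if prev is None:
        df = pd.DataFrame({"t": [sample.t], "x": [sample.x], "y": [sample.y], "z": [sample.z]})
        return featurize_stream(df)
    df = pd.DataFrame(
        {
            "t": [prev.t, sample.t],
            "x": [prev.x, sample.x],
            "y": [prev.y, sample.y],
            "z": [prev.z, sample.z],
        }
    )
    return featurize_stream(df).iloc[[1]].reset_index(drop=True)


def step(
    state: EventState,
    sample: AccelSample,
    model,
    prev_sample: AccelSample | None = None,
) -> tuple[EventState, dict]:
    """Process one sample: featurize, classify, update events, emit message."""
    _check_model(model)
    feats = _featurize_pair(sample, prev_sample)
    pred = str(predict_labels(model, feats)[0])

    day = int(sample.t // _SECONDS_PER_DAY)
    cough_count = state.cough_count_today
    if state.day_key is not None and day != state.day_key:
        cough_count = 0
    in_run = state.in_cough_run
    if pred == "cough":
        if not in_run:
            cough_count += 1
        in_run = True
    else:
        in_run = False

    new_state = EventState(
        fall_latched=state.fall_latched or pred == "fall",
        cough_count_today=cough_count,
        current_activity=pred,
        day_key=day,
        in_cough_run=in_run,
    )
    message = {"t": float(sample.t)}
    for act in ACTIVITIES:
        message[act] = 1 if act == pred else 0
    if new_state.fall_latched:
        message["fall"] = 1
    return new_state, message


def reset_fall(state: EventState) -> EventState:
    """Clear the fall alarm; everything else unchanged.  Idempotent."""
    return replace(state, fall_latched=False)


@dataclass(frozen=True)
class ReplayResult:
    messages: tuple[dict, ...]
    predictions: tuple[str, ...]
    summary: dict
    final_state: EventState


def _iter_samples(df: pd.DataFrame) -> Iterable[AccelSample]:
    for t, x, y, z in zip(df["t"], df["x"], df["y"], df["z"]):
        yield AccelSample(float(t), float(x), float(y), float(z))


def replay(
    source,
    model,
    out=None,
    publisher: Publisher | None = None,
    topic: str = "activity",
) -> ReplayResult:
    """Run the streaming loop over a recorded stream, in order.

    ``source`` is a stream file path (CSV/JSONL) or a DataFrame with
    columns ``t, x, y, z``.  When ``out`` is given, every message is
    written as a JSON line followed by one ``{"summary": ...}`` line.
    """
    df = read_stream(source) if isinstance(source, (str, Path)) else source
    _check_model(model)
    state = EventState()
    prev: AccelSample | None = None
    messages: list[dict] = []
    predictions: list[str] = []
    fall_latch_time: float | None = None
    for sample in _iter_samples(df):
        state, msg = step(state, sample, model, prev_sample=prev)
        if state.fall_latched and fall_latch_time is None:
            fall_latch_time = sample.t
        messages.append(msg)
        predictions.append(state.current_activity)
        if publisher is not None:
            publisher.publish(topic, msg)
        prev = sample
    summary = {
        "n_samples": len(messages),
        "cough_episodes": state.cough_count_today,
        "fall_latched": state.fall_latched,
        "fall_latch_time": fall_latch_time,
        "final_activity": state.current_activity,
        "prediction_counts": {a: predictions.count(a) for a in ACTIVITIES},
    }
    if out is not None:
        with open(out, "w") as fh:
            for msg in messages:
                fh.write(json.dumps(msg) + "\n")
            fh.write(json.dumps({"summary": summary}) + "\n")
    return ReplayResult(tuple(messages), tuple(predictions), summary, state)
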