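"""Trial-level spike data: reading, windowing, exclusion filters, triplet assembly.

A *trial* is one stimulus presentation for one unit, labelled with its
condition (stimulus A alone, B alone, or both together, "AB").  A *triplet*
collects the spike counts of the matched A-alone, B-alone and AB conditions
for one unit and one stimulus pair; it is the unit of all downstream
screening and model comparison.

Trials arrive either as spike timestamps (seconds relative to stimulus
onset), which are converted to counts through a :class:`CountWindow`, or as
precomputed counts.  Trials flagged incorrect are dropped, and — when an eye
speed trace is attached — trials containing microsaccades during the
stimulus epoch are dropped as well.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountWindow",
    "WINDOW_PRESETS",
    "EyeTrace",
    "Trial",
    "Triplet",
    "count_spikes",
    "detect_microsaccades",
    "build_triplets",
    "read_trials",
    "write_trials",
    "read_eye_traces",
]


@dataclass(frozen=True)
class CountWindow:
    """Spike-counting window, offset from stimulus onset.

    The window is the half-open interval ``[latency_offset,
    latency_offset + duration)`` so that adjacent windows never double-count
    a spike.  ``rate_factor`` converts a count in this window to a rate in
    spikes/s (x5 for the standard 200 ms window).
    """

    latency_offset: float
    duration: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.latency_offset) and np.isfinite(self.duration)):
            raise ValueError("window parameters must be finite")
        if self.duration <= 0:
            raise ValueError("window duration must be positive")
        if self.latency_offset < 0:
            raise ValueError("window latency offset must be non-negative")

    @property
    def end(self) -> float:
        return self.latency_offset + self.duration

    @property
    def rate_factor(self) -> float:
        return 1.0 / self.duration


#: Standard windows: counting starts at the area's typical response latency
#: (30 ms for MT, 50 ms for IT) and lasts 200 ms; ``IT_long`` extends the IT
#: window to 400 ms for the longer stimulus presentations.
WINDOW_PRESETS: Mapping[str, CountWindow] = {
    "MT": CountWindow(0.030, 0.200),
    "IT": CountWindow(0.050, 0.200),
    "IT_long": CountWindow(0.050, 0.400),
}


@dataclass(frozen=True)
class EyeTrace:
    """Sampled eye-speed trace with marked fixation and stimulus epochs.

    Epochs are half-open sample-index ranges ``[start, stop)`` into
    ``speed``.
    """

    speed: np.ndarray
    fixation_epoch: tuple[int, int]
    stimulus_epoch: tuple[int, int]
    dt: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "speed", np.asarray(self.speed, dtype=float))
        for name, (lo, hi) in (
            ("fixation_epoch", self.fixation_epoch),
            ("stimulus_epoch", self.stimulus_epoch),
        ):
            if not (0 <= lo <= hi <= self.speed.size):
                raise ValueError(f"{name} {lo, hi} out of bounds for trace of "
                                 f"length {self.speed.size}")


@dataclass
class Trial:
    """One stimulus presentation for one unit."""

    trial_id: str
    unit_id: str
    condition: str  # "A", "B" or "AB"
    stimulus_a_id: str | None = None
    stimulus_b_id: str | None = None
    spike_times: np.ndarray | None = None
    spike_count: int | None = None
    eye: EyeTrace | None = None
    correct: bool = True

    def __post_init__(self) -> None:
        if self.condition not in ("A", "B", "AB"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.spike_times is None and self.spike_count is None:
            raise ValueError(f"trial {self.trial_id}: needs spike_times or spike_count")
        if self.spike_times is not None:
            times = np.asarray(self.spike_times, dtype=float)
            if not np.all(np.isfinite(times)):
                raise ValueError(f"trial {self.trial_id}: non-finite spike timestamp")
            self.spike_times = times
        if self.spike_count is not None:
            if self.spike_count < 0 or int(self.spike_count) != self.spike_count:
                raise ValueError(f"trial {self.trial_id}: spike_count must be a "
                                 "non-negative integer")
            self.spike_count = int(self.spike_count)

    def count_in(self, window: CountWindow) -> int:
        """Spike count for this trial; timestamps take precedence when present."""
        if self.spike_times is not None:
            return count_spikes(self.spike_times, window)
        assert self.spike_count is not None
        return self.spike_count


@dataclass(frozen=True)
class Triplet:
    """Matched A-alone / B-alone / AB spike-count samples for one unit and pair.

    The A/B labels are arbitrary but consistent across the three conditions.
    """

    unit_id: str
    stimulus_pair_id: str
    a_counts: np.ndarray
    b_counts: np.ndarray
    ab_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a_counts", "b_counts", "ab_counts"):
            arr = np.asarray(getattr(self, name))
            if arr.size and (np.any(arr < 0) or not np.issubdtype(np.asarray(arr).dtype, np.number)):
                raise ValueError(f"{name} must be non-negative")
            if arr.size and np.any(arr != np.floor(arr)):
                raise ValueError(f"{name} must be integers")
            object.__setattr__(self, name, arr.astype(np.int64))

    def swapped(self) -> "Triplet":
        """The same triplet with the A and B labels exchanged."""
        return Triplet(self.unit_id, self.stimulus_pair_id,
                       self.b_counts, self.a_counts, self.ab_counts)


def count_spikes(spike_times: Sequence[float], window: CountWindow) -> int:
    """Count timestamps in the half-open window ``[offset, offset+duration)``."""
    times = np.asarray(spike_times, dtype=float)
    if times.size and not np.all(np.isfinite(times)):
        raise ValueError("non-finite spike timestamp")
    return int(np.count_nonzero((times >= window.latency_offset) & (times < window.end)))


def detect_microsaccades(
    eye_speed: Sequence[float],
    fixation_epoch: tuple[int, int],
    stimulus_epoch: tuple[int, int],
    n_sd: float = 6.0,
) -> list[tuple[int, int]]:
    """Find microsaccade episodes during the stimulus epoch.

    A sample is flagged when its eye speed exceeds (strictly) the mean of the
    fixation-epoch speed by more than ``n_sd`` standard deviations (unbiased
    estimator).  Returns maximal contiguous runs of flagged samples as
    half-open absolute index ranges; an empty list means the trial is clean.
    A constant fixation trace has sd 0, so only samples strictly above the
    mean would be flagged — degenerate traces do not nuke trials.
    """
    speed = np.asarray(eye_speed, dtype=float)
    f_lo, f_hi = fixation_epoch
    s_lo, s_hi = stimulus_epoch
    if f_hi <= f_lo:
        raise ValueError("fixation epoch is empty")
    if n_sd <= 0:
        raise ValueError("n_sd must be positive")
    fix = speed[f_lo:f_hi]
    sd = float(np.std(fix, ddof=1)) if fix.size > 1 else 0.0
    threshold = float(np.mean(fix)) + n_sd * sd
    flagged = speed[s_lo:s_hi] > threshold

    runs: list[tuple[int, int]] = []
    start = None
    for i, hit in enumerate(flagged):
        if hit and start is None:
            start = i
        elif not hit and start is not None:
            runs.append((s_lo + start, s_lo + i))
            start = None
    if start is not None:
        runs.append((s_lo + start, s_lo + flagged.size))
    return runs


def _include_trial(trial: Trial, n_sd: float) -> bool:
    if not trial.correct:
        return False
    if trial.eye is not None:
        runs = detect_microsaccades(
            trial.eye.speed, trial.eye.fixation_epoch, trial.eye.stimulus_epoch, n_sd
        )
        if runs:
            return False
    return True


def build_triplets(
    trials: Iterable[Trial],
    window: CountWindow,
    microsaccade_n_sd: float = 6.0,
) -> list[Triplet]:
    """Assemble triplets from trial-level data.

    Trials are filtered first (correct-only; microsaccade-free when an eye
    trace is attached), grouped by unit, and one triplet is emitted per
    (unit, stimulus pair) that retains at least one trial of each of the A,
    B and AB conditions.  Stimulus pairs are defined by the AB trials;
    single-stimulus trials are matched by their stimulus identity, or by
    condition alone when they carry no identity and the unit has a single
    pair.  Count vectors are ordered by ``trial_id`` for determinism.
    """
    by_unit: dict[str, list[Trial]] = {}
    for trial in trials:
        by_unit.setdefault(trial.unit_id, []).append(trial)

    triplets: list[Triplet] = []
    for unit_id in sorted(by_unit):
        unit_trials = [t for t in by_unit[unit_id] if _include_trial(t, microsaccade_n_sd)]
        ab_trials = [t for t in unit_trials if t.condition == "AB"]
        pairs: dict[tuple[str, str], None] = {}
        for t in ab_trials:
            if t.stimulus_a_id is None or t.stimulus_b_id is None:
                logger.warning("AB trial %s lacks stimulus identities; skipped", t.trial_id)
                continue
            pairs.setdefault((t.stimulus_a_id, t.stimulus_b_id))
        if not pairs and ab_trials:
            logger.warning("unit %s: no resolvable stimulus pair", unit_id)
        for stim_a, stim_b in sorted(pairs):
            sel: dict[str, list[Trial]] = {"A": [], "B": [], "AB": []}
            for t in unit_trials:
                if t.condition == "AB":
                    if (t.stimulus_a_id, t.stimulus_b_id) == (stim_a, stim_b):
                        sel["AB"].append(t)
                elif t.condition == "A":
                    if t.stimulus_a_id == stim_a or (t.stimulus_a_id is None and len(pairs) == 1):
                        sel["A"].append(t)
                elif t.condition == "B":
                    if t.stimulus_b_id == stim_b or (t.stimulus_b_id is None and len(pairs) == 1):
                        sel["B"].append(t)
            if not all(sel.values()):
                continue
            counts = {
                cond: np.array(
                    [t.count_in(window) for t in sorted(ts, key=lambda t: t.trial_id)],
                    dtype=np.int64,
                )
                for cond, ts in sel.items()
            }
            triplets.append(
                Triplet(unit_id, f"{stim_a}|{stim_b}", counts["A"], counts["B"], counts["AB"])
            )
    return triplets


# ---------------------------------------------------------------------------
# Tabular I/O.
#
# One row per trial with columns:
#   unit_id, trial_id, condition (A|B|AB), stimulus_a_id, stimulus_b_id,
#   correct (0/1), spike_count, spike_times (semicolon-separated seconds).
# Either spike_count or spike_times must be non-empty.  Eye traces live in a
# companion file keyed by trial_id with columns:
#   trial_id, dt, fix_start, fix_end, stim_start, stim_end, speeds
# where speeds is a semicolon-separated sample list and the epochs are
# half-open sample-index ranges.
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = ["unit_id", "trial_id", "condition", "stimulus_a_id",
                  "stimulus_b_id", "correct", "spike_count", "spike_times"]


def _parse_float_list(cell) -> np.ndarray | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return None
    return np.array([float(x) for x in str(cell).split(";") if x != ""], dtype=float)


def read_trials(path: str | Path, eye_path: str | Path | None = None,
                sep: str = ",") -> list[Trial]:
    """Read trials from the delimited trial table (see module docstring)."""
    df = pd.read_csv(path, sep=sep, dtype={"unit_id": str, "trial_id": str,
                                           "stimulus_a_id": str, "stimulus_b_id": str})
    missing = {"unit_id", "trial_id", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    eyes = read_eye_traces(eye_path, sep=sep) if eye_path is not None else {}

    trials = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        count = d.get("spike_count")
        if count is not None and (isinstance(count, float) and np.isnan(count)):
            count = None
        times = _parse_float_list(d.get("spike_times"))
        stim_a = d.get("stimulus_a_id")
        stim_b = d.get("stimulus_b_id")
        trials.append(Trial(
            trial_id=str(d["trial_id"]),
            unit_id=str(d["unit_id"]),
            condition=str(d["condition"]),
            stimulus_a_id=None if stim_a in (None, "") or pd.isna(stim_a) else str(stim_a),
            stimulus_b_id=None if stim_b in (None, "") or pd.isna(stim_b) else str(stim_b),
            spike_times=times,
            spike_count=None if count is None else int(count),
            eye=eyes.get(str(d["trial_id"])),
            correct=bool(int(d.get("correct", 1))),
        ))
    return trials


def write_trials(trials: Iterable[Trial], path: str | Path, sep: str = ",") -> None:
    """Write trials in the same dialect :func:`read_trials` consumes."""
    rows = []
    for t in trials:
        rows.append({
            "unit_id": t.unit_id,
            "trial_id": t.trial_id,
            "condition": t.condition,
            "stimulus_a_id": t.stimulus_a_id or "",
            "stimulus_b_id": t.stimulus_b_id or "",
            "correct": int(t.correct),
            "spike_count": "" if t.spike_count is None else t.spike_count,
            "spike_times": "" if t.spike_times is None
                           else ";".join(f"{x:.6g}" for x in t.spike_times),
        })
    pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(path, sep=sep, index=False)


def read_eye_traces(path: str | Path | None, sep: str = ",") -> dict[str, EyeTrace]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep=sep, dtype={"trial_id": str})
    traces: dict[str, EyeTrace] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        speed = _parse_float_list(d["speeds"])
        if speed is None:
            warnings.warn(f"eye trace for trial {d['trial_id']} is empty; skipped")
            continue
        dt = d.get("dt")
        traces[str(d["trial_id"])] = EyeTrace(
            speed=speed,
            fixation_epoch=(int(d["fix_start"]), int(d["fix_end"])),
            stimulus_epoch=(int(d["stim_start"]), int(d["stim_end"])),
            dt=None if dt is None or pd.isna(dt) else float(dt),
        )
    return traces
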