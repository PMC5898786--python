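"""Transition kinetics between conformational states.

Given the per-frame state labels of one contiguous MD segment, the mean
transition time from state a to state b is the mean first-passage time:
over every frame in state a, the time until the trajectory next visits b.
The kinetic rate is the inverse of this mean time. Frames of a with no
subsequent visit to b (censored passages) are excluded from the mean and
reported separately — silently treating them as zero would bias rates of
poorly connected state pairs. Replica-exchange label sequences are not
valid input: exchanges disrupt the dynamics, so the estimator only
accepts plain MD segments.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["TransitionKinetics", "transition_kinetics"]


@dataclasses.dataclass
class TransitionKinetics:
    """Mean first-passage times (ps), rates (ps⁻¹) and event counts.

    ``mean_time[a, b]`` is NaN for unreached pairs and on the diagonal;
    ``rate`` is its elementwise inverse where defined. ``n_events`` counts
    uncensored passages, ``n_censored`` source frames whose passage never
    completed before the trajectory ended.
    """

    states: np.ndarray
    mean_time: np.ndarray
    rate: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    frame_interval: float

    def reached(self, a: int, b: int) -> bool:
        return bool(np.isfinite(self.mean_time[a, b]))


def transition_kinetics(
    labels,
    frame_interval: float,
    is_replica_exchange: bool = False,
) -> TransitionKinetics:
    """Mean first-passage times and rates from a contiguous label sequence.

    ``mean_time(a→b)`` averages, over all frames t with label a that have a
    later frame labelled b, the elapsed time to the first such frame.
    """
    if is_replica_exchange:
        raise ValueError(
            "replica-exchange label sequences are not valid kinetics input: "
            "exchanges disrupt the dynamics"
        )
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size < 2:
        raise ValueError("need a 1-D label sequence of at least 2 frames")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    states = np.unique(labels)
    k = states.size
    index_of = {s: i for i, s in enumerate(states)}
    n = labels.size

    # next_occurrence[b][t] = smallest t' > t with labels[t'] == b, else -1
    mean_time = np.full((k, k), np.nan)
    n_events = np.zeros((k, k), dtype=int)
    n_censored = np.zeros((k, k), dtype=int)
    for bi, b in enumerate(states):
        nxt = np.full(n, -1, dtype=int)
        last = -1
        for t in range(n - 1, -1, -1):
            nxt[t] = last
            if labels[t] == b:
                last = t
        for ai, a in enumerate(states):
            if ai == bi:
                continue
            src = np.flatnonzero(labels == a)
            passages = nxt[src]
            ok = passages >= 0
            n_events[ai, bi] = int(ok.sum())
            n_censored[ai, bi] = int((~ok).sum())
            if ok.any():
                mean_time[ai, bi] = float(
                    np.mean(passages[ok] - src[ok]) * frame_interval
                )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1.0 / mean_time
    if k == 1:
        # single state observed: every pair (there are none off-diagonal)
        # is unreached by construction; nothing further to flag
        pass
    return TransitionKinetics(
        states=states,
        mean_time=mean_time,
        rate=rate,
        n_events=n_events,
        n_censored=n_censored,
        frame_interval=float(frame_interval),
    )
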