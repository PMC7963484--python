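"""Detection of network events in simulated cortical rate traces and the
sparsification statistics derived from them.

A cell is active when its rate exceeds the global threshold
``nu = vmax / r`` (``vmax`` the highest rate in the recording, r = 8); an
event is a maximal interval during which any cell is active.  As receptive
fields refine and H-event amplitudes adapt downward, events shrink, their
amplitudes fall and cortical cells decorrelate — the developmental
sparsification trend, probed here with the input threshold ``theta_u``
serving as a proxy for age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DetectedEvent",
    "SparsificationSummary",
    "detect_events",
    "events_to_frame",
    "amplitude_participation_regression",
    "mean_pairwise_correlation",
    "sparsification_summary",
]


@dataclass(frozen=True)
class DetectedEvent:
    start: float
    end: float
    participation: float
    amplitude: float
    active_set: tuple[int, ...]

    @property
    def n_active(self) -> int:
        return len(self.active_set)


def detect_events(
    traces: np.ndarray,
    r: float = 8.0,
    dt: float = 0.01,
    amplitude: Literal["mean", "peak"] = "mean",
) -> list[DetectedEvent]:
    """Threshold-crossing event detection on an Nv x T rate matrix.

    Per event the participation is the maximum simultaneous active count
    over Nv, and the amplitude averages, over the cells active in the
    event, each cell's mean (or peak) rate during its own active samples.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be Nv x T")
    vmax = traces.max(initial=0.0)
    if vmax <= 0:
        return []
    nu = vmax / r
    x = traces >= nu
    X = x.sum(axis=0)
    active = X > 0
    if not active.any():
        return []
    # maximal runs of active samples
    padded = np.concatenate([[False], active, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive sample index
    n_ctx = traces.shape[0]
    out: list[DetectedEvent] = []
    for s, e in zip(starts, ends):
        xs = x[:, s:e]
        cells = np.nonzero(xs.any(axis=1))[0]
        amps = []
        for j in cells:
            vals = traces[j, s:e][xs[j]]
            amps.append(vals.max() if amplitude == "peak" else vals.mean())
        out.append(
            DetectedEvent(
                start=float(s * dt),
                end=float(e * dt),
                participation=float(X[s:e].max() / n_ctx),
                amplitude=float(np.mean(amps)),
                active_set=tuple(int(j) for j in cells),
            )
        )
    return out


def events_to_frame(events: Sequence[DetectedEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "participation": [e.participation for e in events],
            "amplitude": [e.amplitude for e in events],
            "n_active": [e.n_active for e in events],
        }
    )


def amplitude_participation_regression(
    events: Sequence[DetectedEvent], participation_min: float = 0.8
) -> tuple[float, float] | None:
    """OLS slope/intercept of amplitude on participation for large events.

    Returns None with fewer than three qualifying events.
    """
    big = [e for e in events if e.participation > participation_min]
    if len(big) < 3:
        return None
    x = np.array([e.participation for e in big])
    y = np.array([e.amplitude for e in big])
    if np.ptp(x) == 0:
        return None
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def mean_pairwise_correlation(traces: np.ndarray) -> float | None:
    """Mean Pearson correlation over unordered pairs of cortical cells.

    Cells with zero rate variance are excluded; returns None if fewer than
    two informative cells remain.
    """
    traces = np.asarray(traces, dtype=float)
    var = traces.var(axis=1)
    keep = var > 0
    if keep.sum() < 2:
        return None
    c = np.corrcoef(traces[keep])
    iu = np.triu_indices_from(c, k=1)
    return float(c[iu].mean())


@dataclass(frozen=True)
class SparsificationSummary:
    """Per-theta_u sparsification statistics (mean and SEM over runs)."""

    table: pd.DataFrame

    def trend(self, column: str) -> np.ndarray:
        return self.table.sort_values("theta_u")[column].to_numpy()


def _per_run_stats(
    events: Sequence[DetectedEvent],
    traces: np.ndarray,
    duration: float,
) -> dict:
    mids = [
        e for e in events if 0.2 <= e.participation <= 0.8
    ]
    slope = amplitude_participation_regression(events)
    return {
        "slope_large": np.nan if slope is None else slope[0],
        "mean_corr": mean_pairwise_correlation(traces),
        "mean_event_size": (
            np.mean([e.participation for e in events]) if events else np.nan
        ),
        "mid_frequency": len(mids) / duration,
        "mid_amplitude": (
            np.mean([e.amplitude for e in mids]) if mids else np.nan
        ),
    }


def sparsification_summary(
    runs: Mapping[float, Sequence[tuple[Sequence[DetectedEvent], np.ndarray, float]]]
) -> SparsificationSummary:
    """Aggregate sparsification statistics over runs keyed by theta_u.

    ``runs[theta_u]`` is a sequence of ``(events, traces, duration)``
    triples, one per simulation.  Means and standard errors over the runs
    are reported per threshold.
    """
    rows = []
    for theta_u, triples in runs.items():
        per = pd.DataFrame(
            [_per_run_stats(ev, tr, dur) for ev, tr, dur in triples]
        )
        row = {"theta_u": theta_u, "n_runs": len(per)}
        for col in per.columns:
            vals = per[col].astype(float)
            row[col] = vals.mean()
            row[f"{col}_sem"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return SparsificationSummary(pd.DataFrame(rows))
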