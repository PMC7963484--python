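"""Monte Carlo grid experiments over plasticity and event parameters.

Each grid samples per-run parameters independently and uniformly from the
configured ranges (input threshold theta_u and mean H inter-event interval
for the Hebbian rules; target rate v0 for BCM), runs the full simulation
with a child seed derived from the master seed, and classifies the outcome
of the final weight matrix as selective / non-selective / decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTrainConfig
from .metrics import compute_metrics
from .network import NetworkParams
from .plasticity import PlasticityParams, SimConfig, run_simulation

__all__ = ["GridSpec", "GridResult", "run_grid", "compare_topography",
           "l_size_sweep"]


@dataclass(frozen=True)
class GridSpec:
    rule: Literal["hebb", "hebb_adaptive", "bcm"] = "hebb"
    n_runs: int = 500
    master_seed: int = 0
    theta_u_range: tuple[float, float] = (0.3, 0.7)
    h_int_mean_range: tuple[float, float] | None = (1.0, 6.0)
    v0_range: tuple[float, float] = (0.4, 1.0)
    l_pct_max_range: tuple[float, float] | None = None
    events: EventTrainConfig = field(default_factory=EventTrainConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    engine: Literal["numba", "numpy"] = "numba"

    def __post_init__(self) -> None:
        if self.n_runs <= 0:
            raise ValueError("n_runs must be positive")


@dataclass
class GridResult:
    runs: pd.DataFrame
    spec: GridSpec

    @property
    def percentages(self) -> dict[str, float]:
        ok = self.runs[self.runs["failed"] == False]  # noqa: E712
        counts = ok["outcome"].value_counts()
        n = len(ok)
        return {
            k: 100.0 * counts.get(k, 0) / n if n else np.nan
            for k in ("selective", "non_selective", "decoupled")
        }

    def count(self, outcome: str) -> int:
        ok = self.runs[self.runs["failed"] == False]  # noqa: E712
        return int((ok["outcome"] == outcome).sum())

    def selective_topographies(self) -> np.ndarray:
        ok = self.runs[
            (self.runs["failed"] == False)  # noqa: E712
            & (self.runs["outcome"] == "selective")
        ]
        return ok["topography"].to_numpy(float)


def _run_one(spec: GridSpec, rng: np.random.Generator, seed: int) -> dict:
    row: dict = {"seed": seed}
    events = spec.events
    plast = PlasticityParams(rule=spec.rule)
    if spec.h_int_mean_range is not None:
        h_mean = float(rng.uniform(*spec.h_int_mean_range))
        events = events.with_h_int_mean(h_mean)
        row["h_int_mean"] = h_mean
    else:
        row["h_int_mean"] = events.h_int_mean
    if spec.rule == "bcm":
        v0 = float(rng.uniform(*spec.v0_range))
        plast = replace(plast, v0=v0)
        row["v0"] = v0
    else:
        theta_u = float(rng.uniform(*spec.theta_u_range))
        plast = replace(plast, theta_u=theta_u)
        row["theta_u"] = theta_u
    if spec.l_pct_max_range is not None:
        lmax = float(rng.uniform(*spec.l_pct_max_range))
        events = replace(events, l_pct_range=(events.l_pct_range[0], lmax))
        row["l_pct_max"] = lmax
    cfg = SimConfig(
        events=events, network=spec.network, plasticity=plast,
        engine=spec.engine,
    )
    try:
        sim = run_simulation(cfg, np.random.default_rng(seed), keep_schedule=False)
        m = compute_metrics(sim.weights)
        row.update(
            rf_size=m.rf_size,
            topography=np.nan if m.topography is None else m.topography,
            decoupling=m.decoupling,
            outcome=m.outcome,
            failed=False,
        )
    except FloatingPointError as exc:  # pragma: no cover - defensive
        row.update(
            rf_size=np.nan, topography=np.nan, decoupling=np.nan,
            outcome="failed", failed=True, error=str(exc),
        )
    return row


def run_grid(spec: GridSpec, progress: bool = False) -> GridResult:
    """Run ``spec.n_runs`` independent simulations with sampled parameters.

    Child seeds derive deterministically from the master seed via
    ``SeedSequence.spawn``, so any row can be re-derived in isolation.
    """
    ss = np.random.SeedSequence(spec.master_seed)
    children = ss.spawn(spec.n_runs)
    rows = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        seed = int(child.generate_state(1)[0] % (2**31))
        row = _run_one(spec, rng, seed)
        row["run"] = k
        rows.append(row)
        if progress and (k + 1) % 50 == 0:  # pragma: no cover
            print(f"  {k + 1}/{spec.n_runs} runs done", flush=True)
    return GridResult(runs=pd.DataFrame(rows), spec=spec)


def compare_topography(
    selective_a: np.ndarray, selective_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on topography scores."""
    a = np.asarray(selective_a, float)
    b = np.asarray(selective_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both topography samples must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def l_size_sweep(
    spec: GridSpec,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Grid over the maximum L-event participation at fixed mean Hint.

    Requires ``spec.l_pct_max_range``; receptive-field size and the
    topography of selective runs are binned by the sampled maximum L size.
    """
    if spec.l_pct_max_range is None:
        raise ValueError("spec.l_pct_max_range must be set for the sweep")
    result = run_grid(spec)
    df = result.runs[result.runs["failed"] == False].copy()  # noqa: E712
    if bins is None:
        lo, hi = spec.l_pct_max_range
        bins = np.linspace(lo, hi, 6)
    df["l_max_bin"] = pd.cut(df["l_pct_max"], bins, include_lowest=True)
    sel = df[df["outcome"] == "selective"]
    out = df.groupby("l_max_bin", observed=True).agg(
        mean_rf_size=("rf_size", "mean"),
        n=("rf_size", "size"),
    )
    topo = sel.groupby("l_max_bin", observed=True).agg(
        mean_topography=("topography", "mean"),
        n_selective=("topography", "size"),
    )
    return out.join(topo).reset_index()
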