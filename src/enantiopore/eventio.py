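"""Baseline estimation, threshold event detection and event featurization.

The analysis convention: the open-pore level I0 and its sd sigma are
estimated robustly per recording; an event spans the contiguous samples
below the threshold I0 - 7 sigma; five parameters are measured per event
(dwell time T_t, mean/max/min in-event current and in-event sd), from which
the blockade depths dI_b = I0 - I_b (and min/max variants) and the
normalized blockade dI_b/I0 are derived. Events shorter than 200 µs,
quieter than 1 pA in-event sd (bumping) or shallower than 0.2 normalized
blockade are excluded from further analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trace_sim import CurrentTrace, filter_sigma_samples

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineStats",
    "EventTable",
    "estimate_baseline",
    "detect_events",
    "extract_features",
    "filter_events",
    "events_to_csv",
    "events_from_csv",
]

EVENT_CSV_COLUMNS = [
    "start_index",
    "end_index",
    "t_t_us",
    "i0_pA",
    "i_b_pA",
    "i_bmax_pA",
    "i_bmin_pA",
    "i_bs_pA",
    "di_b_pA",
    "di_bmin_pA",
    "di_bmax_pA",
    "norm_di_b",
    "flags",
]


@dataclass
class BaselineStats:
    """Open-pore current statistics and the derived event threshold (pA)."""

    i0: float
    sigma: float
    k: float = 7.0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def threshold(self) -> float:
        return self.i0 - self.k * self.sigma


@dataclass
class EventTable:
    """Detected events (one row each) plus the recording-level baseline."""

    events: pd.DataFrame
    baseline: BaselineStats
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def with_events(self, events: pd.DataFrame, **meta) -> "EventTable":
        return EventTable(
            events.reset_index(drop=True),
            self.baseline,
            self.sampling_rate,
            {**self.metadata, **meta},
        )


def estimate_baseline(
    trace: CurrentTrace, k: float = 7.0, clip: float = 3.0, max_iter: int = 50
) -> BaselineStats:
    """Estimate I0 and sigma by iterative sigma-clipping around the dominant
    current level, robust to the downward excursions caused by events.

    Raises if the trace has no identifiable dominant level (less than half
    of the samples retained after clipping) or is degenerate (zero spread).
    """
    x = np.asarray(trace.samples, dtype=np.float64)
    if x.size < 10_000:
        raise ValueError("baseline estimation requires at least 1e4 samples")
    m = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - m)))
    if s == 0.0:
        raise ValueError("degenerate trace: zero spread around the dominant level")
    for _ in range(max_iter):
        mask = np.abs(x - m) < clip * s
        m_new = float(x[mask].mean())
        s_new = float(x[mask].std(ddof=1))
        if s_new == 0.0:
            raise ValueError("degenerate trace: zero spread around the dominant level")
        if abs(m_new - m) < 1e-9 * max(1.0, abs(m)) and abs(s_new - s) < 1e-9 * s:
            m, s = m_new, s_new
            break
        m, s = m_new, s_new
    mask = np.abs(x - m) < clip * s
    retained = float(mask.mean())
    if retained < 0.5:
        raise ValueError(
            "no identifiable dominant current level (bimodal trace?); "
            "supply i0 manually"
        )
    # a two-level trace clipped around its midpoint is platykurtic
    kept = x[mask]
    kurtosis = float(np.mean((kept - m) ** 4) / s**4)
    if kurtosis < 2.0:
        raise ValueError(
            "no identifiable dominant current level (bimodal with comparable "
            "masses); supply i0 manually"
        )
    return BaselineStats(i0=m, sigma=s, k=k)


def detect_events(trace: CurrentTrace, baseline: BaselineStats, k: float | None = None) -> EventTable:
    """Threshold detection: an event is a maximal run of samples below
    I0 - k sigma; runs touching the trace ends are discarded (unknown span).
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    kk = baseline.k if k is None else float(k)
    if kk <= 0:
        raise ValueError("k must be > 0")
    thr = baseline.i0 - kk * baseline.sigma
    below = np.asarray(trace.samples, dtype=np.float64) < thr

    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # end exclusive

    # discard events touching the trace ends
    keep = (starts > 0) & (ends < trace.n_samples)
    starts, ends = starts[keep], ends[keep]

    dt_us = trace.dt_us
    df = pd.DataFrame(
        {
            "start_index": starts.astype(np.int64),
            "end_index": ends.astype(np.int64),
            "t_t_us": (ends - starts) * dt_us,
        }
    )
    bl = replace(baseline, k=kk)
    logger.info("detected %d events at threshold %.2f pA", len(df), thr)
    return EventTable(df, bl, trace.sampling_rate, dict(trace.metadata))


def _edge_trim_samples(trace: CurrentTrace) -> int:
    """Samples to trim at each event edge so the in-event statistics are
    measured on the settled portion of the filtered blockade (about 3.6
    time-domain sigmas of the acquisition filter)."""
    fc = trace.metadata.get("filter_cutoff") or 0.0
    if not fc:
        return 0
    return int(math.ceil(3.6 * filter_sigma_samples(trace.sampling_rate, fc)))


def extract_features(
    trace: CurrentTrace, table: EventTable, edge_trim: int | None = None
) -> EventTable:
    """Compute the five event parameters and the derived blockade depths.

    In-event statistics are taken over a core that excludes up to
    ``edge_trim`` samples at each edge (default: the acquisition-filter rise
    region, from the trace metadata), but never less than 8 central samples,
    so the filter's edge ramps do not bias the blockade level. Events
    spanning fewer than 2 samples get NaN i_bs and the flag ``short``.
    Idempotent: recomputing on an already-featurized table yields the same
    values.
    """
    x = np.asarray(trace.samples, dtype=np.float64)
    trim_max = _edge_trim_samples(trace) if edge_trim is None else int(edge_trim)
    i0 = table.baseline.i0

    cols: dict[str, list] = {c: [] for c in ("i_b", "i_bmax", "i_bmin", "i_bs", "flags")}
    for a, b in zip(table.events["start_index"], table.events["end_index"]):
        span = b - a
        flag = ""
        if span < 2:
            seg = x[a:b]
            cols["i_b"].append(seg.mean())
            cols["i_bmax"].append(seg.max())
            cols["i_bmin"].append(seg.min())
            cols["i_bs"].append(np.nan)
            cols["flags"].append("short")
            continue
        trim = min(trim_max, max(0, (span - 8) // 2))
        core = x[a + trim : b - trim]
        cols["i_b"].append(core.mean())
        cols["i_bmax"].append(core.max())
        cols["i_bmin"].append(core.min())
        cols["i_bs"].append(core.std(ddof=1))
        cols["flags"].append(flag)

    df = table.events.copy()
    df["i0_pA"] = i0
    df["i_b_pA"] = cols["i_b"]
    df["i_bmax_pA"] = cols["i_bmax"]
    df["i_bmin_pA"] = cols["i_bmin"]
    df["i_bs_pA"] = cols["i_bs"]
    df["di_b_pA"] = i0 - df["i_b_pA"]
    df["di_bmin_pA"] = i0 - df["i_bmax_pA"]
    df["di_bmax_pA"] = i0 - df["i_bmin_pA"]
    df["norm_di_b"] = df["di_b_pA"] / i0
    df["flags"] = cols["flags"]
    return table.with_events(df)


def filter_events(
    table: EventTable,
    min_dwell_us: float = 200.0,
    min_sigma_pa: float = 1.0,
    min_norm_blockade: float = 0.2,
) -> EventTable:
    """Apply the standard event filters (order-preserving).

    Removes events with dwell below ``min_dwell_us`` (inclusive comparison:
    exactly 200 µs is retained), in-event sd below ``min_sigma_pa`` (bumping)
    or normalized blockade below ``min_norm_blockade``. Per-criterion removal
    counts are logged and stored in the returned table's metadata under
    ``filter_counts``.
    """
    df = table.events
    ok_dwell = df["t_t_us"] >= min_dwell_us
    ok_sigma = df["i_bs_pA"] >= min_sigma_pa  # NaN (short events) fails
    ok_block = df["norm_di_b"] >= min_norm_blockade
    keep = ok_dwell & ok_sigma & ok_block
    counts = {
        "input": int(len(df)),
        "removed_dwell": int((~ok_dwell).sum()),
        "removed_sigma": int((~ok_sigma).sum()),
        "removed_blockade": int((~ok_block).sum()),
        "retained": int(keep.sum()),
    }
    logger.info("event filters: %s", counts)
    return table.with_events(df[keep], filter_counts=counts)


# ---------------------------------------------------------------------------
# Event table CSV round-trip
# ---------------------------------------------------------------------------

def events_to_csv(table: EventTable, path) -> None:
    df = table.events.copy()
    for col in EVENT_CSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "flags" else ""
    out = df[EVENT_CSV_COLUMNS].copy()
    # header carries the recording-level baseline
    with open(path, "w") as fh:
        fh.write(
            f"# i0_pA={table.baseline.i0!r} sigma_pA={table.baseline.sigma!r} "
            f"k={table.baseline.k!r} sampling_rate={table.sampling_rate!r}\n"
        )
        out.to_csv(fh, index=False, float_format="%.12g")


def events_from_csv(path) -> EventTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing baseline header line")
        meta = dict(item.split("=") for item in header[1:].split())
        df = pd.read_csv(fh)
    for col in ("start_index", "end_index"):
        df[col] = df[col].astype(np.int64)
    df["flags"] = df["flags"].fillna("")
    bl = BaselineStats(float(meta["i0_pA"]), float(meta["sigma_pA"]), float(meta["k"]))
    return EventTable(df, bl, float(meta["sampling_rate"]))
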