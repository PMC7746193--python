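"""Disease-propensity hotspot calling from per-position mean scores.

A position's disease-propensity score (DPS) is the mean of its 19 possible
substitution scores. The critical value is a percentile (default 95th) of the
per-position means over the whole protein, and a hotspot is a maximal run of
at least ``min_run`` consecutive positions whose mean lies strictly above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Domain, ScoreMatrix

DEFAULT_PERCENTILE = 95.0
DEFAULT_MIN_RUN = 3
DEFAULT_DPS_CUTOFF = 50.0


def position_mean_dps(matrix: ScoreMatrix) -> pd.Series:
    """Mean of the 19 substitution scores at every position."""
    means = matrix.position_means()
    return pd.Series(means, name="dps").sort_index()


def critical_value(
    means: pd.Series | np.ndarray, percentile: float = DEFAULT_PERCENTILE,
    method: str = "linear",
) -> float:
    """Percentile threshold over per-position means.

    ``method`` is ``"linear"`` (interpolation between order statistics) or
    ``"nearest"`` (nearest-rank).
    """
    values = np.asarray(means, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no defined means to take a percentile of")
    if method not in ("linear", "nearest"):
        raise ValueError(f"unknown percentile method {method!r}")
    return float(np.percentile(values, percentile, method=method))


@dataclass(frozen=True)
class HotspotRun:
    start: int
    end: int
    mean: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class HotspotSet:
    critical_value: float
    runs: tuple[HotspotRun, ...]
    min_run: int
    percentile: float = DEFAULT_PERCENTILE

    @property
    def n_positions(self) -> int:
        return sum(r.length for r in self.runs)

    def positions_in(self, dom: Domain) -> int:
        """Number of hotspot positions falling inside a domain."""
        total = 0
        for run in self.runs:
            lo = max(run.start, dom.start)
            hi = min(run.end, dom.end)
            if lo <= hi:
                total += hi - lo + 1
        return total

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tend\tlength\trun_mean\tthreshold\n")
            for run in self.runs:
                fh.write(
                    f"{run.start}\t{run.end}\t{run.length}\t"
                    f"{run.mean:.6f}\t{self.critical_value:.6f}\n"
                )

    def to_dict(self) -> dict:
        return {
            "critical_value": self.critical_value,
            "percentile": self.percentile,
            "min_run": self.min_run,
            "runs": [
                {"start": r.start, "end": r.end, "length": r.length, "mean": r.mean}
                for r in self.runs
            ],
        }


def call_hotspots(
    means: pd.Series,
    threshold: float,
    min_run: int = DEFAULT_MIN_RUN,
    percentile: float = DEFAULT_PERCENTILE,
) -> HotspotSet:
    """Maximal runs of consecutive positions with mean strictly above threshold.

    Runs shorter than ``min_run`` are discarded. ``means`` must be indexed by
    residue position; gaps in the index break runs.
    """
    if min_run < 2:
        raise ValueError("min_run must be at least 2")
    means = means.sort_index()
    runs: list[HotspotRun] = []
    run_positions: list[int] = []
    run_values: list[float] = []

    def flush() -> None:
        if len(run_positions) >= min_run:
            runs.append(
                HotspotRun(
                    start=run_positions[0],
                    end=run_positions[-1],
                    mean=float(np.mean(run_values)),
                )
            )
        run_positions.clear()
        run_values.clear()

    previous = None
    for pos, value in means.items():
        contiguous = previous is not None and pos == previous + 1
        if not contiguous:
            flush()
        if np.isfinite(value) and value > threshold:
            run_positions.append(int(pos))
            run_values.append(float(value))
        else:
            flush()
        previous = pos
    flush()
    return HotspotSet(
        critical_value=float(threshold),
        runs=tuple(runs),
        min_run=min_run,
        percentile=percentile,
    )


def high_dps_subset(means: pd.Series, cutoff: float = DEFAULT_DPS_CUTOFF) -> pd.Series:
    """Order-preserving filter keeping means strictly greater than ``cutoff``."""
    return means[means > cutoff]
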