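"""Conformational population analysis of twist-angle series.

Frames are classified as inactive-like when their inter-domain rotation
angle is strictly below a threshold (15 degrees by default, the convention
used for beta-arrestin-1), active-like otherwise; negative signed angles
are inactive-like.  Fractions are pooled over replicate runs with every
frame weighted equally, and uncertainty comes from a circular block
bootstrap within each run, which respects the strong frame-to-frame
autocorrelation of MD trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotation import AngleSeries

__all__ = [
    "DEFAULT_THRESHOLD_DEG",
    "PopulationSummary",
    "classify_frame",
    "population_fractions",
    "bootstrap_ci",
]

DEFAULT_THRESHOLD_DEG = 15.0
DEFAULT_BLOCK_LEN = 100


@dataclass
class PopulationSummary:
    """Inactive-like/active-like frame fractions pooled across runs."""

    threshold_deg: float
    n_frames_total: int
    n_runs: int
    fraction_inactive_like: float
    fraction_active_like: float
    per_run_fractions: list[tuple[str, float]]
    ci95_inactive_like: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        # complementarity is an invariant, not a rounding accident
        assert self.fraction_inactive_like + self.fraction_active_like == 1.0

    def to_dict(self, system: str = "") -> dict:
        d = {
            "system": system,
            "threshold_deg": self.threshold_deg,
            "n_runs": self.n_runs,
            "n_frames": self.n_frames_total,
            "fraction_inactive_like": self.fraction_inactive_like,
            "fraction_active_like": self.fraction_active_like,
            "per_run": [
                {"run_id": rid, "fraction_inactive_like": f} for rid, f in self.per_run_fractions
            ],
        }
        if self.ci95_inactive_like is not None:
            d["ci95"] = {
                "fraction_inactive_like": list(self.ci95_inactive_like),
                "level": 0.95,
            }
        return d


def classify_frame(angle_deg: float, threshold_deg: float = DEFAULT_THRESHOLD_DEG) -> str:
    """Classify one frame: ``inactive_like`` iff angle < threshold (strict).

    Frames exactly at the threshold are active-like; signed angles below
    zero are inactive-like.
    """
    if not np.isfinite(angle_deg):
        raise ValueError(f"cannot classify non-finite angle {angle_deg!r}")
    return "inactive_like" if angle_deg < threshold_deg else "active_like"


def _series_angles(series: AngleSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, AngleSeries):
        return series.angle_deg
    return np.asarray(series, dtype=float)


def _series_id(series: AngleSeries | np.ndarray, i: int) -> str:
    if isinstance(series, AngleSeries) and series.run_id:
        return series.run_id
    return f"run{i}"


def population_fractions(
    series_list: list[AngleSeries] | list[np.ndarray],
    threshold_deg: float = DEFAULT_THRESHOLD_DEG,
) -> PopulationSummary:
    """Pooled and per-run inactive-like fractions over replicate runs.

    Pooling is frame-weighted: the pooled fraction equals the frame-count
    weighted mean of the per-run fractions (identical to a per-run average
    when runs have equal length, as in a 5 x 2 us replicate design).
    """
    if not series_list:
        raise ValueError("population_fractions requires at least one angle series")
    per_run = []
    n_inactive = 0
    n_total = 0
    for i, series in enumerate(series_list):
        angles = _series_angles(series)
        if angles.size == 0:
            raise ValueError(f"angle series {i} is empty")
        if not np.all(np.isfinite(angles)):
            raise ValueError(f"angle series {i} contains non-finite angles")
        inactive = int(np.count_nonzero(angles < threshold_deg))
        per_run.append((_series_id(series, i), inactive / angles.size))
        n_inactive += inactive
        n_total += angles.size
    frac_in = n_inactive / n_total
    return PopulationSummary(
        threshold_deg=threshold_deg,
        n_frames_total=n_total,
        n_runs=len(series_list),
        fraction_inactive_like=frac_in,
        fraction_active_like=1.0 - frac_in,
        per_run_fractions=per_run,
    )


def bootstrap_ci(
    series_list: list[AngleSeries] | list[np.ndarray],
    threshold_deg: float = DEFAULT_THRESHOLD_DEG,
    n_boot: int = 1000,
    block_len: int = DEFAULT_BLOCK_LEN,
    seed: int = 0,
) -> tuple[float, float]:
    """95% CI for the pooled inactive-like fraction, circular block bootstrap.

    Within each run, blocks of ``block_len`` consecutive frames are resampled
    with circular wrap-around (preserving short-range autocorrelation), runs
    are re-pooled, and the 2.5/97.5 percentiles of the ``n_boot`` replicate
    fractions are returned.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile interval")
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    indicators = []
    for series in series_list:
        angles = _series_angles(series)
        if block_len > angles.size:
            raise ValueError(
                f"block_len {block_len} exceeds shortest run length {angles.size}"
            )
        indicators.append((angles < threshold_deg).astype(float))
    n_total = sum(x.size for x in indicators)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        count = 0.0
        for x in indicators:
            n = x.size
            n_blocks = -(-n // block_len)  # ceil
            starts = rng.integers(0, n, size=n_blocks)
            offsets = (starts[:, None] + np.arange(block_len)[None, :]) % n
            resampled = x[offsets].ravel()[:n]
            count += resampled.sum()
        stats[b] = count / n_total
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)
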