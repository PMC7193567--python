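"""Cortical activity ratio (CAR) over sensorimotor ROIs.

CAR is the current-density strength summed over the nodes of one region of
interest, divided by the summed strength over the whole sensorimotor cortex,
computed in a fixed pre-movement window (−150..−100 ms before EMG onset).
Because the ROIs partition the node set, the four CARs of a map sum to one.
The pre/post contrast is a paired t-test, with an exact sign-flip permutation
p-value as a distribution-free alternative at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from dcmir._exceptions import ParameterError

SENSORIMOTOR_ROIS = ("iM1S1", "cM1S1", "iSMA-PM", "cSMA-PM")
DEFAULT_WINDOW = (-150.0, -100.0)


@dataclass
class CurrentDensityMap:
    """Node-level current-density strengths (μA/mm²) with ROI labels."""

    node_strength: np.ndarray
    node_roi: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW
    labels: dict = field(default_factory=dict)
    node_xyz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.node_strength = np.asarray(self.node_strength, dtype=float)
        self.node_roi = np.asarray(self.node_roi, dtype=object)
        if self.node_strength.shape != self.node_roi.shape:
            raise ParameterError("node_strength and node_roi must align")
        if np.any(self.node_strength < 0):
            raise ParameterError("node strengths must be nonnegative")

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.node_roi.tolist())))


def compute_car(cd_map: CurrentDensityMap, roi: str) -> float:
    """CAR of one ROI: Σ_{n∈roi} S_n / Σ_{m} S_m."""
    if roi not in set(cd_map.node_roi.tolist()):
        raise ParameterError(f"unknown ROI {roi!r}")
    total = float(cd_map.node_strength.sum())
    if total <= 0:
        raise ParameterError("total current-density strength is zero; CAR undefined")
    in_roi = cd_map.node_strength[cd_map.node_roi == roi].sum()
    return float(in_roi / total)


def car_table(maps: list[CurrentDensityMap]) -> pd.DataFrame:
    """CAR per map and ROI, as a tidy table (subject, session, task, roi, car).

    All maps must share the same ROI partition; per map the CARs sum to 1.
    """
    if not maps:
        return pd.DataFrame(columns=["subject", "session", "task", "roi", "car"])
    rois = maps[0].rois
    rows = []
    for m in maps:
        if m.rois != rois:
            raise ParameterError(f"inconsistent ROI partition: {m.rois} vs {rois}")
        cars = {roi: compute_car(m, roi) for roi in rois}
        s = sum(cars.values())
        if abs(s - 1.0) > 1e-10:
            raise ParameterError(f"CARs do not partition to 1 (sum={s})")
        for roi, value in cars.items():
            rows.append(
                {
                    "subject": m.labels.get("subject"),
                    "session": m.labels.get("session"),
                    "task": m.labels.get("task"),
                    "roi": roi,
                    "car": value,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    p: float
    mean_delta: float
    n: int
    p_signflip: float | None = None
    degenerate_variance: bool = False


def _exact_signflip_p(diff: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value for the mean of paired differences."""
    n = diff.size
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1) * 2 - 1
    null_means = np.abs((signs * diff[None, :]).mean(axis=1))
    observed = abs(diff.mean())
    return float(np.mean(null_means >= observed - 1e-12))


def paired_car_test(
    table: pd.DataFrame,
    roi: str,
    task: str | None = None,
    pre_label: str = "pre",
    post_label: str = "post",
) -> PairedTestResult:
    """Paired pre/post t-test on CAR for one ROI (and optionally one task).

    Returns the t statistic, the two-sided p from the t distribution with
    n−1 degrees of freedom, the mean post−pre difference, and — for n ≤ 12 —
    the exact sign-flip permutation p-value.  Zero variance of differences is
    flagged instead of producing an infinite t.
    """
    sel = table[table["roi"] == roi]
    if task is not None:
        sel = sel[sel["task"] == task]
    pivot = sel.pivot_table(index="subject", columns="session", values="car")
    if pre_label not in pivot.columns or post_label not in pivot.columns:
        raise ParameterError("both sessions must be present")
    pivot = pivot.dropna(subset=[pre_label, post_label])
    n = len(pivot)
    if n < 2:
        raise ParameterError("need at least 2 subjects with both sessions")
    diff = (pivot[post_label] - pivot[pre_label]).to_numpy()
    mean_delta = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean_delta)):
        return PairedTestResult(
            t=np.nan, p=np.nan, mean_delta=mean_delta, n=n,
            p_signflip=None, degenerate_variance=True,
        )
    t = mean_delta / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    p_exact = _exact_signflip_p(diff) if n <= 12 else None
    return PairedTestResult(
        t=float(t), p=float(p), mean_delta=mean_delta, n=n, p_signflip=p_exact
    )
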