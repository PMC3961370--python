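"""Liposome lipid-mixing percentage and syncytial-index summary statistics.

The lipid-mixing (dequenching) assay normalizes a fluorescence trace between
a baseline F0 and the fully dequenched reference F_MAX:

    %LM(t) = 100 * (F(t) - F0) / (F_MAX - F0)

The syncytial index summarizes syncytial-nucleus counts per microscope field
as mean +/- SEM, propagating errors within each experiment and then across
experiments in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "LipidMixResult",
    "SyncytialIndex",
    "percent_lipid_mixing",
    "syncytial_index",
]


@dataclass
class FluorescenceTrace:
    """A fluorescence time course from a liposome lipid-mixing run."""

    time: np.ndarray  # seconds, strictly increasing
    intensity: np.ndarray  # detector units
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")


@dataclass
class LipidMixResult:
    """Percent lipid mixing over time for one trace."""

    time: np.ndarray
    percent_mixing: np.ndarray
    f0: float
    f_max: float
    endpoint: float
    label: str = ""


def percent_lipid_mixing(
    trace: FluorescenceTrace, f0: float, f_max: float
) -> LipidMixResult:
    """Normalize a dequenching trace to percent lipid mixing.

    %LM is linear in F(t), equals 0 at F = f0 and 100 at F = f_max, and is
    invariant to adding a constant to, or rescaling, (F, f0, f_max) jointly.
    """
    if f_max == f0:
        raise ValueError("degenerate reference: f_max must differ from f0")
    pct = 100.0 * (trace.intensity - f0) / (f_max - f0)
    return LipidMixResult(
        time=trace.time.copy(),
        percent_mixing=pct,
        f0=float(f0),
        f_max=float(f_max),
        endpoint=float(pct[-1]) if pct.size else float("nan"),
        label=trace.label,
    )


@dataclass
class SyncytialIndex:
    """Syncytial nuclei per field, summarized as mean +/- SEM."""

    per_experiment_mean: dict
    per_experiment_sem: dict
    mean: float
    sem: float
    n_experiments: int


def syncytial_index(counts_by_experiment: Mapping[str, Sequence[int]]) -> SyncytialIndex:
    """Mean +/- SEM of per-field syncytial-nucleus counts.

    Per experiment: mean and SEM (= sample SD / sqrt(n_fields)) over fields.
    Across k experiments: overall mean is the mean of experiment means, and
    the overall SEM propagates the within-experiment SEMs in quadrature,
    sqrt(sum SEM_i**2) / k — which reduces to the single-experiment SEM when
    k = 1.
    """
    if not counts_by_experiment:
        raise ValueError("need at least one experiment")
    means, sems = {}, {}
    for exp, counts in counts_by_experiment.items():
        arr = np.asarray(list(counts), dtype=float)
        if arr.size < 2:
            raise ValueError(f"experiment {exp!r} has < 2 fields")
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError(f"experiment {exp!r}: counts must be nonnegative integers")
        means[exp] = float(np.mean(arr))
        sems[exp] = float(np.std(arr, ddof=1) / math.sqrt(arr.size))
    k = len(means)
    overall_mean = float(np.mean(list(means.values())))
    overall_sem = float(math.sqrt(sum(s**2 for s in sems.values())) / k)
    return SyncytialIndex(
        per_experiment_mean=means,
        per_experiment_sem=sems,
        mean=overall_mean,
        sem=overall_sem,
        n_experiments=k,
    )
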