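"""Conversion of branch lengths into NUMT insertion times (Ma).

The chronological distance from the human–chimp divergence to the nuclear
insertion is the mitochondrial part of the NUMT's path, measured in
substitutions and converted to time with the extant human mtDNA branch as
the clock standard:

    t_insert = D - D * (L_stem + f * L_numt) / L_human

where D is the human–chimp divergence (6 Ma by default, linearly
rescalable), L_stem the branch from the NUMT attachment point back to the
human–chimp coalescence, L_numt the NUMT terminal branch, L_human the
human branch from the coalescence to the extant reference tip, and f the
estimated mitochondrial fraction of NUMT-branch substitutions.  Confidence
intervals come from repeating the calculation on jackknife replicate trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_DIVERGENCE = 6.0


class TimingError(ValueError):
    pass


def insertion_time(
    l_numt: float,
    l_stem: float,
    l_human: float,
    f: float,
    divergence: float = DEFAULT_DIVERGENCE,
) -> tuple[float, bool]:
    """Point insertion time in Ma and whether it was clamped into [0, D]."""
    if min(l_numt, l_stem, l_human) < 0:
        raise TimingError("branch lengths must be non-negative")
    if l_human <= 0:
        raise TimingError("degenerate calibration: human branch length is zero")
    if not 0.0 <= f <= 1.0:
        raise TimingError("mitochondrial fraction must be in [0, 1]")
    if divergence <= 0:
        raise TimingError("divergence time must be positive")
    t = divergence - divergence * (l_stem + f * l_numt) / l_human
    clamped = not 0.0 <= t <= divergence
    return float(min(max(t, 0.0), divergence)), clamped


@dataclass
class InsertionTimeEstimate:
    """Point estimate plus the jackknife replicate distribution."""

    numt_id: str
    point_estimate: float
    replicate_times: np.ndarray
    divergence: float = DEFAULT_DIVERGENCE
    clamped_at_zero: bool = False
    n_failed_replicates: int = 0

    mean: float = field(init=False)
    median: float = field(init=False)
    q25: float = field(init=False)
    q75: float = field(init=False)
    variance: float = field(init=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.replicate_times, dtype=float)
        if times.size < 2:
            raise TimingError("need at least two replicate times")
        self.replicate_times = times
        self.mean = float(times.mean())
        self.median = float(np.median(times))
        self.q25, self.q75 = (float(q) for q in np.percentile(times, [25, 75]))
        self.variance = float(times.var(ddof=1))

    def rescaled(self, new_divergence: float) -> "InsertionTimeEstimate":
        times = rescale_times(self.replicate_times, new_divergence, self.divergence)
        return InsertionTimeEstimate(
            numt_id=self.numt_id,
            point_estimate=self.point_estimate * new_divergence / self.divergence,
            replicate_times=times,
            divergence=new_divergence,
            clamped_at_zero=self.clamped_at_zero,
            n_failed_replicates=self.n_failed_replicates,
        )

    def as_dict(self) -> dict:
        return {
            "numt_id": self.numt_id,
            "point_estimate": self.point_estimate,
            "mean": self.mean,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "variance": self.variance,
            "divergence": self.divergence,
            "clamped_at_zero": self.clamped_at_zero,
            "n_replicates": int(self.replicate_times.size),
            "n_failed_replicates": self.n_failed_replicates,
        }


def replicate_times(
    numt_id: str,
    point_lengths: tuple[float, float, float],
    replicate_lengths: list[tuple[float, float, float]],
    f: float,
    divergence: float = DEFAULT_DIVERGENCE,
    per_replicate_f: list[float] | None = None,
) -> InsertionTimeEstimate:
    """Insertion-time estimate with jackknife confidence intervals.

    ``point_lengths`` and each replicate tuple are (L_numt, L_stem,
    L_human).  The mitochondrial fraction ``f`` is estimated once on the
    full alignment and shared across replicates unless ``per_replicate_f``
    supplies one value per replicate.  Replicates whose calibration is
    degenerate are dropped and counted.
    """
    point, point_clamped = insertion_time(*point_lengths, f, divergence)
    times = []
    n_failed = 0
    fs = per_replicate_f or [f] * len(replicate_lengths)
    if len(fs) != len(replicate_lengths):
        raise TimingError("per-replicate fractions do not match replicates")
    for lengths, fr in zip(replicate_lengths, fs):
        try:
            t, _ = insertion_time(*lengths, fr, divergence)
        except TimingError:
            n_failed += 1
            continue
        times.append(t)
    if n_failed:
        warnings.warn(f"{n_failed} replicates dropped (degenerate calibration)")
    return InsertionTimeEstimate(
        numt_id=numt_id,
        point_estimate=point,
        replicate_times=np.array(times),
        divergence=divergence,
        clamped_at_zero=point_clamped and point == 0.0,
        n_failed_replicates=n_failed,
    )


def rescale_times(
    times: np.ndarray | list[float],
    new_divergence: float,
    old_divergence: float = DEFAULT_DIVERGENCE,
) -> np.ndarray:
    """Rescale times linearly to a different assumed human–chimp divergence."""
    if new_divergence <= 0:
        raise TimingError("divergence time must be positive")
    return np.asarray(times, dtype=float) * (new_divergence / old_divergence)
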