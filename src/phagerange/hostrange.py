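"""Inhibition scores and the host-range index.

For a strain whose untreated control reaches the OD600 detection threshold
at time t_c in an experiment of duration T, the maximal possible inhibition
time is

    T_max = T - t_c

A phage's realized inhibition time against that strain is the detection
delay of the treated culture, floored at 0 and capped at T_max; a culture
that never reaches the threshold scores the full T_max (complete
inhibition).  The inhibition score normalizes this to [0, 1]:

    Is = T_actual / T_max

and a phage's host-range index over a declared panel of HR_max strains is

    HRi = (sum of Is over the panel) / HR_max

so HRi = 1 means complete inhibition of every panel strain and HRi = 0
means no measurable delay anywhere.  Both are annotated with the assay
conditions (temperature, duration, medium) since they are only comparable
within one condition set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping


@dataclass(frozen=True)
class InhibitionScore:
    strain_id: str
    phage_id: str
    t_actual: float
    t_max: float

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError(f"{self.phage_id}/{self.strain_id}: T_max must be positive")
        if not 0 <= self.t_actual <= self.t_max + 1e-9:
            raise ValueError(
                f"{self.phage_id}/{self.strain_id}: T_actual {self.t_actual} outside"
                f" [0, {self.t_max}]"
            )

    @property
    def score(self) -> float:
        return min(self.t_actual / self.t_max, 1.0)


@dataclass
class HostRangeProfile:
    """One phage's inhibition scores over the strain panel and its HRi."""

    phage_id: str
    scores: dict[str, InhibitionScore | None]  # None = not evaluable
    hr_max: int
    conditions: str = ""

    @property
    def hri(self) -> float:
        return host_range_index(
            (s.score for s in self.scores.values() if s is not None), self.hr_max
        )

    @property
    def not_evaluable(self) -> list[str]:
        return sorted(k for k, v in self.scores.items() if v is None)


def t_max(control_detection_time: float, duration: float) -> float:
    """Maximal inhibition time: experiment duration minus control detection time."""
    if control_detection_time is None:
        raise ValueError("control never reached threshold; strain not evaluable")
    if not 0 <= control_detection_time <= duration:
        raise ValueError(
            f"control detection time {control_detection_time} outside [0, {duration}]"
        )
    return duration - control_detection_time


def t_actual(
    sample_detection_time: float | None,
    control_detection_time: float,
    tmax: float,
) -> float:
    """Realized inhibition time: detection delay floored at 0 and capped at T_max.

    A sample that never reaches the threshold realizes the full window.
    """
    if tmax <= 0:
        raise ValueError("T_max must be positive")
    if sample_detection_time is None:
        return tmax
    delay = sample_detection_time - control_detection_time
    return min(max(delay, 0.0), tmax)


def inhibition_score(t_act: float, tmax: float) -> float:
    """Is = T_actual / T_max, in [0, 1]."""
    if tmax <= 0:
        raise ValueError("T_max must be positive; strain not evaluable")
    if not 0 <= t_act <= tmax + 1e-9:
        raise ValueError(f"T_actual {t_act} outside [0, {tmax}]")
    return min(t_act / tmax, 1.0)


def host_range_index(scores: Iterable[float], hr_max: int) -> float:
    """HRi = sum(Is) / HR_max over the declared panel.

    Strains that are not evaluable (or never tested) contribute 0 while
    HR_max stays at the declared panel size, keeping HRi comparable across
    phages run on the same panel.
    """
    hr_max = int(hr_max)
    if hr_max <= 0:
        raise ValueError("HR_max must be a positive integer")
    scores = list(scores)
    if len(scores) > hr_max:
        raise ValueError(f"{len(scores)} scored strains exceed declared panel size {hr_max}")
    for s in scores:
        if not 0 <= s <= 1 + 1e-9:
            raise ValueError(f"inhibition score {s} outside [0, 1]")
    return float(sum(scores)) / hr_max


def build_profile(
    phage_id: str,
    pair_scores: Mapping[str, InhibitionScore | None],
    hr_max: int | None = None,
    conditions: str = "",
) -> HostRangeProfile:
    """Assemble a phage's profile; HR_max defaults to the panel size given."""
    if hr_max is None:
        hr_max = len(pair_scores)
    return HostRangeProfile(
        phage_id=phage_id,
        scores=dict(pair_scores),
        hr_max=int(hr_max),
        conditions=conditions,
    )


def theoretical_moi(
    phage_log10_pfu_per_ml: float = 7.0,
    host_log10_cfu_per_ml: float = 7.0,
) -> float:
    """Theoretical input multiplicity of infection at mixing.

    Equal volumes of phage and host suspensions are mixed, so the MOI is the
    ratio of the two titres; at 10^7 PFU/mL against 10^7 CFU/mL this is 1.
    """
    return 10.0 ** (phage_log10_pfu_per_ml - host_log10_cfu_per_ml)
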