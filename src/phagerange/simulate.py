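"""Synthetic 384-well turbidimetric plates with known ground truth.

Untreated growth is modelled as a logistic curve

    OD(t) = OD0 + (K - OD0) / (1 + exp(-r (t - t_mid)))

and phage effects as transformations of the strain's control curve:

- ``C``   complete inhibition: flat at the floor OD0;
- ``D``/``D+``  regrowth after killing: the midpoint shifted right by a
  delay Δ, so the threshold crossing is delayed by exactly Δ;
- ``N/L`` classes  endpoint suppression: the carrying capacity scaled by a
  factor f, with the midpoint advanced by the closed-form crossing shift so
  the threshold-crossing time stays at the control's (otherwise a reduced K
  alone would also delay detection and leak endpoint scenarios into the
  delay classes);
- ``N``   no effect: the control curve unchanged.

Gaussian read noise (i.i.d. per reading, clamped at 0 OD) is added on top.
Scenario parameters are drawn away from the classification boundaries by a
configurable margin so ground truth stays unambiguous under noise; every
generated scenario is re-classified noise-free at generation time and must
reproduce its own label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ControlSummary, Designation, classify_replicate
from .kinetics import summarize_curve
from .plate_io import (
    ExperimentConfig,
    LayoutEntry,
    PlateLayout,
    ROWS_384,
    WellCoordinate,
    WellSeries,
)

FLOOR_OD = 0.05

#: Cyclic order used to spread ground-truth labels over the strain panel so
#: every plate exercises all seven designations.
LABEL_CYCLE = (
    Designation.C,
    Designation.D_plus,
    Designation.D,
    Designation.NL,
    Designation.NL_plus,
    Designation.NL_plusplus,
    Designation.N,
)


@dataclass(frozen=True)
class GrowthScenario:
    """Effective logistic parameters for one well, plus its target label."""

    label: Designation | None  # None for controls/blanks
    od0: float = FLOOR_OD
    k: float = 1.0
    r: float = 1.2
    t_mid: float = 6.0
    delay: float = 0.0  # Δ applied to t_mid (D/D+ classes)
    endpoint_factor: float = 1.0  # f applied to K (N/L classes)
    flat: bool = False  # constant at od0 (C, sterility, blanks)

    def __post_init__(self) -> None:
        if not self.flat:
            if self.r <= 0:
                raise ValueError("growth rate r must be positive")
            if not self.k > self.od0 >= 0:
                raise ValueError("need K > OD0 >= 0")


def logistic_curve(scenario: GrowthScenario, times: np.ndarray) -> np.ndarray:
    """Noise-free OD600 readings for a scenario on a time grid (hours)."""
    times = np.asarray(times, dtype=float)
    if scenario.flat:
        return np.full_like(times, scenario.od0)
    with np.errstate(over="ignore"):  # deep-lag tail underflows to od0
        return scenario.od0 + (scenario.k - scenario.od0) / (
            1.0 + np.exp(-scenario.r * (times - scenario.t_mid))
        )


def crossing_time(scenario: GrowthScenario, threshold: float) -> float | None:
    """Exact time the noise-free logistic reaches ``threshold`` (None if never)."""
    if scenario.flat or scenario.k <= threshold or scenario.od0 >= threshold:
        return None if scenario.od0 < threshold else 0.0
    arg = (scenario.k - scenario.od0) / (threshold - scenario.od0) - 1.0
    return scenario.t_mid - np.log(arg) / scenario.r


def control_scenario(rng: np.random.Generator) -> GrowthScenario:
    """Draw a strain's untreated-control kinetics.

    Ranges bracket a typical mesophile growing to stationary phase well
    inside a 24 h window at 25 °C: floor 0.05 OD, plateau ~1 OD, threshold
    crossing at 4-6 h.
    """
    return GrowthScenario(
        label=None,
        od0=FLOOR_OD,
        k=float(rng.uniform(0.9, 1.1)),
        r=float(rng.uniform(1.0, 1.4)),
        t_mid=float(rng.uniform(5.0, 7.0)),
    )


def scenario_for(
    label: Designation,
    control: GrowthScenario,
    config: ExperimentConfig,
    rng: np.random.Generator,
    delay_margin: float = 0.5,
    factor_margin: float = 0.05,
) -> GrowthScenario:
    """Transform a control scenario into a treatment scenario for ``label``.

    Delays are drawn at least ``delay_margin`` hours from the 1 h / 5 h
    cutoffs and endpoint factors at least ``factor_margin`` from the
    0.40 / 0.70 / 0.85 bin edges; a margin of 0 yields boundary-stress
    scenarios.
    """
    thr = config.threshold
    hi, mid, lo = config.endpoint_bounds
    t_detect = crossing_time(control, thr)
    if t_detect is None or t_detect >= config.duration:
        raise ValueError("control scenario never reaches threshold within the window")

    if label is Designation.C:
        return GrowthScenario(label=label, od0=control.od0, flat=True)

    if label in (Designation.D, Designation.D_plus):
        if label is Designation.D:
            d_lo, d_hi = config.delay_minor + delay_margin, config.delay_major - delay_margin
        else:
            d_lo = config.delay_major + delay_margin
            d_hi = config.duration - t_detect - max(delay_margin, 1.0)
        if d_hi <= d_lo:
            raise ValueError(f"no admissible delay range for {label} under this control")
        delta = float(rng.uniform(d_lo, d_hi))
        return GrowthScenario(
            label=label,
            od0=control.od0,
            k=control.k,
            r=control.r,
            t_mid=control.t_mid + delta,
            delay=delta,
        )

    if label in (Designation.NL, Designation.NL_plus, Designation.NL_plusplus):
        if label is Designation.NL:
            f_lo, f_hi = mid + factor_margin, hi - factor_margin
        elif label is Designation.NL_plus:
            f_lo, f_hi = lo + factor_margin, mid - factor_margin
        else:
            # deepest bin: keep the scaled plateau clearly above the threshold
            f_lo = max((thr + 2 * factor_margin) / control.k, 0.28)
            f_hi = lo - factor_margin
        if f_hi <= f_lo:
            raise ValueError(f"no admissible endpoint-factor range for {label}")
        f = float(rng.uniform(f_lo, f_hi))
        scaled = GrowthScenario(
            label=label,
            od0=control.od0,
            k=control.k * f,
            r=control.r,
            t_mid=control.t_mid,
            endpoint_factor=f,
        )
        # advance the midpoint so the threshold crossing matches the control's
        shift = crossing_time(scaled, thr) - t_detect
        return GrowthScenario(
            label=label,
            od0=control.od0,
            k=control.k * f,
            r=control.r,
            t_mid=control.t_mid - shift,
            endpoint_factor=f,
        )

    if label is Designation.N:
        return GrowthScenario(
            label=label, od0=control.od0, k=control.k, r=control.r, t_mid=control.t_mid
        )
    raise ValueError(f"unknown designation {label}")


def _self_check(
    scenario: GrowthScenario,
    control: GrowthScenario,
    config: ExperimentConfig,
    times: np.ndarray,
) -> None:
    """Classify the noise-free curve; it must reproduce the scenario label."""
    well = WellCoordinate("A", 1)
    ctrl_summary = summarize_curve(
        WellSeries(well, times, logistic_curve(control, times)),
        config.threshold,
        config.min_growth_rate,
        config.slope_window,
    )
    ctrl = ControlSummary(
        strain_id="self-check",
        detection_time=ctrl_summary.detection_time,
        od_max=ctrl_summary.od_max,
        n_replicates=1,
        qc_pass=ctrl_summary.detection_time is not None and ctrl_summary.trend,
    )
    sample = summarize_curve(
        WellSeries(well, times, logistic_curve(scenario, times)),
        config.threshold,
        config.min_growth_rate,
        config.slope_window,
    )
    got = classify_replicate(sample, ctrl, config)
    if got is not scenario.label:
        raise RuntimeError(
            f"generated scenario for {scenario.label} classifies noise-free as {got};"
            " parameters too close to a boundary"
        )


def assign_labels(
    layout: PlateLayout,
    labels: Sequence[Designation] = LABEL_CYCLE,
) -> dict[tuple[str, str], Designation]:
    """Deterministic cyclic ground-truth assignment covering all labels."""
    pairs = sorted(
        {
            (e.strain_id, e.phage_id)
            for e in layout.entries.values()
            if e.role == "treatment"
        }
    )
    return {pair: labels[i % len(labels)] for i, pair in enumerate(pairs)}


def simulate_plate(
    layout: PlateLayout,
    config: ExperimentConfig,
    truth: Mapping[tuple[str, str], Designation] | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    delay_margin: float = 0.5,
    factor_margin: float = 0.05,
    self_check: bool = True,
) -> tuple[dict[WellCoordinate, WellSeries], pd.DataFrame]:
    """Simulate one plate; returns per-well series and the ground-truth table.

    Identical seeds give identical output.  ``truth`` maps each
    (strain, phage) treatment pair to its target designation; by default the
    label cycle is spread over the pairs.  The truth table records the drawn
    delay and endpoint factor alongside each label.
    """
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = assign_labels(layout)
    times = np.arange(config.n_readings) * config.interval_hours

    strains = layout.strains
    controls = {s: control_scenario(rng) for s in strains}

    scenarios: dict[tuple[str, str], GrowthScenario] = {}
    for (strain, phage), label in sorted(truth.items()):
        scen = scenario_for(
            label, controls[strain], config, rng, delay_margin, factor_margin
        )
        if self_check:
            _self_check(scen, controls[strain], config, times)
        scenarios[(strain, phage)] = scen

    flat = GrowthScenario(label=None, od0=FLOOR_OD, flat=True)
    series: dict[WellCoordinate, WellSeries] = {}
    for well in sorted(layout.entries):
        e = layout.entries[well]
        if e.role == "treatment":
            key = (e.strain_id, e.phage_id)
            if key not in scenarios:
                raise ValueError(f"treatment well {well}: no scenario for pair {key}")
            scen = scenarios[key]
        elif e.role == "untreated_control":
            scen = controls[e.strain_id]
        else:  # sterility control or blank: medium stays flat
            scen = flat
        clean = logistic_curve(scen, times)
        noisy = clean if noise_sd == 0 else clean + rng.normal(0.0, noise_sd, clean.shape)
        series[well] = WellSeries(well, times, np.clip(noisy, 0.0, None))

    truth_rows = [
        {
            "strain": strain,
            "phage": phage,
            "designation": str(scen.label),
            "delay_h": round(scen.delay, 6),
            "endpoint_factor": round(scen.endpoint_factor, 6),
            "control_detection_h": round(crossing_time(controls[strain], config.threshold), 6),
        }
        for (strain, phage), scen in sorted(scenarios.items())
    ]
    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "strain",
            "phage",
            "designation",
            "delay_h",
            "endpoint_factor",
            "control_detection_h",
        ],
    )
    return series, truth_df


# ---------------------------------------------------------------------------
# panel presets and the default 384-well template


def default_layout(
    n_strains: int = 22,
    n_phages: int = 4,
    n_replicates: int = 3,
    strain_prefix: str = "S",
    phage_prefix: str = "P",
    n_control_rows: int = 3,
    n_blanks: int = 3,
) -> PlateLayout:
    """The standard host-range template on a 384-well plate.

    Strains run across columns; each phage occupies a block of replicate
    rows; untreated controls sit below the treatments; the final row holds
    sterility controls (medium + phage) with phages spread across its
    columns; a few blank wells (medium only) sit in a spare column.
    """
    n_rows_needed = n_phages * n_replicates + n_control_rows + 1
    if n_rows_needed > len(ROWS_384):
        raise ValueError("template does not fit on 16 plate rows")
    if n_strains > 22:
        raise ValueError("template reserves columns 23-24; at most 22 strains")
    strains = [f"{strain_prefix}{i:02d}" for i in range(1, n_strains + 1)]
    phages = [f"{phage_prefix}{i}" for i in range(1, n_phages + 1)]
    entries: dict[WellCoordinate, LayoutEntry] = {}
    row_i = 0
    for phage in phages:
        for rep in range(1, n_replicates + 1):
            row = ROWS_384[row_i]
            row_i += 1
            for col, strain in enumerate(strains, start=1):
                entries[WellCoordinate(row, col)] = LayoutEntry(
                    "treatment", strain, phage, rep
                )
    for rep in range(1, n_control_rows + 1):
        row = ROWS_384[row_i]
        row_i += 1
        for col, strain in enumerate(strains, start=1):
            entries[WellCoordinate(row, col)] = LayoutEntry(
                "untreated_control", strain_id=strain, replicate=rep
            )
    sterility_row = ROWS_384[row_i]
    for col in range(1, n_strains + 1):
        phage = phages[(col - 1) * n_phages // n_strains]
        entries[WellCoordinate(sterility_row, col)] = LayoutEntry(
            "sterility_control", phage_id=phage
        )
    for i in range(n_blanks):
        entries[WellCoordinate(ROWS_384[i], 24)] = LayoutEntry("blank")
    return PlateLayout(entries)


PRESET_GENERA = ("listeria", "salmonella", "pseudomonas")


def preset_panel(genus: str) -> tuple[PlateLayout, ExperimentConfig]:
    """Panel preset for a genus: 22 strains, 4 phages in triplicate.

    Listeria panels run 40 h in BHI; Salmonella and Pseudomonas run 24 h in
    TSB.  All read every 30 min at 25 °C with a 0.2 OD threshold.
    """
    genus = genus.lower()
    if genus not in PRESET_GENERA:
        raise ValueError(f"unknown genus {genus!r}; expected one of {PRESET_GENERA}")
    duration = 40.0 if genus == "listeria" else 24.0
    medium = "BHI" if genus == "listeria" else "TSB"
    prefix = {"listeria": "Lm", "salmonella": "Se", "pseudomonas": "Pa"}[genus]
    layout = default_layout(strain_prefix=prefix, phage_prefix=f"{prefix}phi")
    config = ExperimentConfig(
        duration=duration,
        conditions=f"25 C, {duration:g} h, {medium}",
    )
    return layout, config
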