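"""Report tables: per-sample rows, per-pair consensus, per-phage summaries.

The sample report carries one row per analyzed well — designation, average
and maximum OD, detection time, outlier/exclusion flags — so nothing is
dropped silently.  The phage summary mirrors the stacked-fraction style of
host-range figures: per-designation strain counts and fractions plus the
host-range index, annotated with the assay conditions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Designation, PairResult, ReplicateResult
from .hostrange import HostRangeProfile

_NL_GROUP = (Designation.NL, Designation.NL_plus, Designation.NL_plusplus)

SAMPLE_COLUMNS = [
    "well",
    "strain",
    "phage",
    "replicate",
    "designation",
    "detection_time_h",
    "od_mean",
    "od_max",
    "outlier",
    "exclusion_reason",
]


def build_sample_report(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    """One row per treated well, ordered by (strain, phage, replicate)."""
    rows = []
    for r in sorted(results, key=lambda r: (r.strain_id, r.phage_id, r.replicate or 0)):
        rows.append(
            {
                "well": str(r.well),
                "strain": r.strain_id,
                "phage": r.phage_id,
                "replicate": r.replicate,
                "designation": "" if r.designation is None else str(r.designation),
                "detection_time_h": np.nan if r.detection_time is None else r.detection_time,
                "od_mean": r.od_mean,
                "od_max": r.od_max,
                "outlier": r.outlier,
                "exclusion_reason": r.exclusion_reason,
            }
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def build_pair_report(pairs: Sequence[PairResult]) -> pd.DataFrame:
    """Consensus per phage-strain pair, with replicate means and QC carry-through."""
    rows = []
    for p in sorted(pairs, key=lambda p: (p.phage_id, p.strain_id)):
        rows.append(
            {
                "phage": p.phage_id,
                "strain": p.strain_id,
                "designation": "" if p.designation is None else str(p.designation),
                "detection_time_h": np.nan if p.detection_time is None else p.detection_time,
                "od_max": np.nan if p.od_max is None else p.od_max,
                "od_max_ratio": np.nan if p.od_max_ratio is None else p.od_max_ratio,
                "n_replicates": len(p.replicates),
                "n_outliers": sum(r.outlier for r in p.replicates),
                "not_evaluable_reason": p.not_evaluable_reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phage",
            "strain",
            "designation",
            "detection_time_h",
            "od_max",
            "od_max_ratio",
            "n_replicates",
            "n_outliers",
            "not_evaluable_reason",
        ],
    )


def designation_fractions(
    pairs: Sequence[PairResult],
    profile: HostRangeProfile | None = None,
    pool_nl: bool = False,
) -> dict:
    """Counts and fractions per designation over one phage's evaluable strains.

    Fractions are stored unrounded; round only for display.  With
    ``pool_nl`` the three endpoint-effect classes collapse into one N/L
    group (the usual stacked-bar presentation).
    """
    evaluable = [p for p in pairs if p.evaluable]
    n = len(evaluable)
    if pool_nl:
        groups: list[tuple[str, tuple[Designation, ...]]] = [
            ("C", (Designation.C,)),
            ("D+", (Designation.D_plus,)),
            ("D", (Designation.D,)),
            ("N/L", _NL_GROUP),
            ("N", (Designation.N,)),
        ]
    else:
        groups = [(str(d), (d,)) for d in Designation]
    row: dict = {}
    if evaluable:
        row["phage"] = evaluable[0].phage_id
    elif pairs:
        row["phage"] = pairs[0].phage_id
    row["n_evaluable"] = n
    row["n_not_evaluable"] = len(pairs) - n
    for name, members in groups:
        count = sum(1 for p in evaluable if p.designation in members)
        row[f"count_{name}"] = count
        row[f"frac_{name}"] = count / n if n else np.nan
    if profile is not None:
        row["HRi"] = profile.hri
        row["conditions"] = profile.conditions
    return row


def build_phage_report(
    pairs: Sequence[PairResult],
    profiles: Mapping[str, HostRangeProfile],
    pool_nl: bool = False,
) -> pd.DataFrame:
    by_phage: dict[str, list[PairResult]] = {}
    for p in pairs:
        by_phage.setdefault(p.phage_id, []).append(p)
    rows = [
        designation_fractions(by_phage[phage], profiles.get(phage), pool_nl=pool_nl)
        for phage in sorted(by_phage)
    ]
    return pd.DataFrame(rows)


def build_qc_report(flags: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(flags), columns=["check", "well", "subject", "detail"])


def build_score_report(profiles: Mapping[str, HostRangeProfile]) -> pd.DataFrame:
    """Long-form inhibition scores: one row per (phage, strain)."""
    rows = []
    for phage in sorted(profiles):
        prof = profiles[phage]
        for strain in sorted(prof.scores):
            s = prof.scores[strain]
            rows.append(
                {
                    "phage": phage,
                    "strain": strain,
                    "t_actual_h": np.nan if s is None else s.t_actual,
                    "t_max_h": np.nan if s is None else s.t_max,
                    "inhibition_score": np.nan if s is None else s.score,
                    "evaluable": s is not None,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["phage", "strain", "t_actual_h", "t_max_h", "inhibition_score", "evaluable"],
    )


def export(
    tables: Mapping[str, pd.DataFrame],
    destination: str | Path,
    sep: str = "\t",
    xlsx: bool = False,
    float_format: str = "%.6g",
) -> list[Path]:
    """Write each table as delimited text; optionally a one-sheet-per-table workbook."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    written: list[Path] = []
    for name, df in tables.items():
        path = dest / f"{name}{ext}"
        df.to_csv(path, sep=sep, index=False, float_format=float_format)
        written.append(path)
    if xlsx:
        book = dest / "report.xlsx"
        with pd.ExcelWriter(book) as writer:
            for name, df in tables.items():
                df.to_excel(writer, sheet_name=name[:31], index=False)
        written.append(book)
    return written


def stacked_bar_figure(
    phage_table: pd.DataFrame,
    path: str | Path,
    pool_nl: bool = True,
) -> Path:
    """Stacked designation fractions per phage, HRi printed above each bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pool_nl:
        order = ["C", "D+", "D", "N/L", "N"]
    else:
        order = [str(d) for d in Designation]
    colors = plt.get_cmap("viridis")(np.linspace(0.1, 0.9, len(order)))
    phages = phage_table["phage"].tolist()
    fig, ax = plt.subplots(figsize=(1.2 * max(len(phages), 4) + 2, 4))
    bottom = np.zeros(len(phages))
    for name, color in zip(order, colors):
        col = f"frac_{name}"
        vals = phage_table[col].fillna(0).to_numpy() if col in phage_table else np.zeros(len(phages))
        ax.bar(phages, vals, bottom=bottom, label=name, color=color)
        bottom += vals
    if "HRi" in phage_table:
        for x, (_, row) in enumerate(phage_table.iterrows()):
            ax.text(x, 1.02, f"HRi {row['HRi']:.2f}", ha="center", fontsize=8)
    ax.set_ylabel("fraction of panel strains")
    ax.set_ylim(0, 1.12)
    ax.legend(title="designation", bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
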