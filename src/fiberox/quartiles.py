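"""Damage-quartile stratification of fibers and per-class CSA means.

For each patient and marker (carbonyl or HNE), the lower quartile,
median and upper quartile of the fiber damage values define four
classes:

* Q1 — fibers at or below the lower quartile,
* Q2 — above the lower quartile and at or below the median,
* Q3 — above the median and at or below the upper quartile,
* Q4 — above the upper quartile.

Ties fall in the lower class.  The mean CSA of each class, per patient,
quantifies whether the most damaged fibers are also the smallest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKERS = ("carbonyl", "hne")
CLASSES = ("Q1", "Q2", "Q3", "Q4")

QUARTILE_TABLE_COLUMNS = ["patient_id", "marker", "cls", "n_fibers", "mean_csa_um2"]


@dataclass
class QuartileThresholds:
    lower_quartile: float
    median: float
    upper_quartile: float
    marker: str
    patient_id: str

    def __post_init__(self) -> None:
        if not self.lower_quartile <= self.median <= self.upper_quartile:
            raise ValueError("quartile thresholds must be non-decreasing")


def quartile_thresholds(values, patient_id: str, marker: str,
                        method: str = "linear") -> QuartileThresholds:
    """25th/50th/75th percentiles of a patient's fiber damage values.

    ``method`` is any ``numpy.percentile`` interpolation convention;
    the default linear interpolation between order statistics is the
    common "type 7" rule.  Class membership of fibers lying exactly on
    a threshold depends on this choice, which is why it is exposed.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError(
            f"patient {patient_id}: need >= 4 fibers for quartiles, got {vals.size}")
    lq, med, uq = np.percentile(vals, [25, 50, 75], method=method)
    return QuartileThresholds(float(lq), float(med), float(uq), marker, patient_id)


def assign_classes(values, thresholds: QuartileThresholds) -> np.ndarray:
    """Class label (``'Q1'..'Q4'``) for each fiber damage value.

    Total over finite values; a fiber equal to a threshold falls in the
    lower class.
    """
    vals = np.asarray(values, dtype=float)
    out = np.empty(vals.shape, dtype=object)
    out[vals <= thresholds.lower_quartile] = "Q1"
    out[(vals > thresholds.lower_quartile) & (vals <= thresholds.median)] = "Q2"
    out[(vals > thresholds.median) & (vals <= thresholds.upper_quartile)] = "Q3"
    out[vals > thresholds.upper_quartile] = "Q4"
    return out.astype(str)


def class_csa_means(measurements: pd.DataFrame, classes: np.ndarray) -> pd.DataFrame:
    """Mean CSA and fiber count per class for one patient × marker.

    Empty classes are reported with ``mean_csa_um2`` missing (NaN), not
    zero, so downstream repeated-measures models drop them.
    """
    csa = measurements["csa_um2"].to_numpy()
    rows = []
    for cls in CLASSES:
        mask = classes == cls
        rows.append({
            "cls": cls,
            "n_fibers": int(mask.sum()),
            "mean_csa_um2": float(csa[mask].mean()) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)


def build_quartile_table(fibers: pd.DataFrame, method: str = "linear",
                         damage_columns: dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Per patient × marker quartile-class CSA table from a fiber table.

    Quartiles are computed per patient over all of the patient's fibers
    pooled across fields.  ``fibers`` needs columns ``patient_id``,
    ``csa_um2`` and a damage column per marker (``carbonyl_gsu`` /
    ``hne_gsu`` by default; ``damage_columns`` overrides, e.g. for
    ground-truth tables).
    """
    damage_columns = damage_columns or {m: f"{m}_gsu" for m in MARKERS}
    csa_col = "csa_um2" if "csa_um2" in fibers.columns else "true_csa_um2"
    rows = []
    for pid, sub in fibers.groupby("patient_id", sort=True):
        for marker, col in damage_columns.items():
            thr = quartile_thresholds(sub[col], str(pid), marker, method=method)
            classes = assign_classes(sub[col], thr)
            cm = class_csa_means(sub.rename(columns={csa_col: "csa_um2"}), classes)
            cm.insert(0, "marker", marker)
            cm.insert(0, "patient_id", pid)
            rows.append(cm)
    return pd.concat(rows, ignore_index=True)[QUARTILE_TABLE_COLUMNS]
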