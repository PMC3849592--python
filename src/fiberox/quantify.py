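"""Per-fiber signal quantification and specimen-level pooling.

Each fiber's damage signal is the mean pixel intensity of the marker
channel over the fiber's pixels, in grayscale units (gsu) on the 12-bit
scale, minus a background estimate; its cross-sectional area (CSA) is
pixel count × pixel_size².  Specimen summaries pool all myofibers of a
specimen across its fields — every fiber counts once, fields are never
averaged first.

Background conventions differ by marker.  HNE is absent from the
extracellular matrix (ECM), so the median extracellular intensity is a
clean estimate of the camera black level.  Carbonyl signal, by
contrast, is genuinely present in the ECM: the extracellular median
*over-corrects* that marker, and a fixed black-level background (e.g.
the HNE-channel extracellular median) should be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from fiberox.io import ImageStack
from fiberox.segment import LabelMap
from fiberox.synthdata import PatientRecord

FIBER_TABLE_COLUMNS = ["patient_id", "field_id", "fiber_id",
                       "csa_um2", "carbonyl_gsu", "hne_gsu"]


@dataclass
class SpecimenSummary:
    """One patient's fiber-weighted means pooled over fields."""

    patient_id: str
    group: str
    fontaine_stage: int | None
    abi: float
    cad: bool
    htn: bool
    n_fibers: int
    mean_carbonyl_gsu: float
    mean_hne_gsu: float
    mean_csa_um2: float


def estimate_background(channel: np.ndarray, label_map: LabelMap | np.ndarray,
                        method: str = "extracellular_median",
                        fixed_value: float | None = None) -> float:
    """Background level (gsu) of a channel for one field.

    ``extracellular_median`` is the median over label-0 pixels — correct
    for markers absent from the ECM (HNE).  For carbonyl, whose ECM
    signal is real, use ``fixed`` with the camera black level.
    """
    labels = label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        if fixed_value < 0:
            raise ValueError("background must be >= 0")
        return float(fixed_value)
    if method != "extracellular_median":
        raise ValueError(f"unknown background method {method!r}")
    zero = labels == 0
    if isinstance(label_map, LabelMap) and label_map.excluded_mask is not None:
        zero &= ~label_map.excluded_mask
    extracellular = np.asarray(channel)[zero]
    if extracellular.size == 0:
        raise ValueError("no extracellular (label 0) pixels for background estimation")
    return float(np.median(extracellular))


def measure_fibers(stack: ImageStack, label_map: LabelMap | np.ndarray,
                   background_carbonyl: float, background_hne: float,
                   patient_id: str = "", field_id: str = "") -> pd.DataFrame:
    """Measure every labeled fiber in a field.

    Returns a DataFrame with columns ``patient_id, field_id, fiber_id,
    csa_um2, carbonyl_gsu, hne_gsu``.  Corrected means may be negative;
    they are deliberately not clamped (clamping would bias group means).
    """
    if background_carbonyl < 0 or background_hne < 0:
        raise ValueError("backgrounds must be >= 0")
    labels = label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(columns=FIBER_TABLE_COLUMNS)
    counts = np.bincount(labels.ravel())[ids]
    mean_carb = ndi.mean(stack.carbonyl, labels=labels, index=ids)
    mean_hne = ndi.mean(stack.hne, labels=labels, index=ids)
    return pd.DataFrame({
        "patient_id": patient_id,
        "field_id": field_id,
        "fiber_id": ids.astype(int),
        "csa_um2": counts * stack.pixel_size_um**2,
        "carbonyl_gsu": mean_carb - background_carbonyl,
        "hne_gsu": mean_hne - background_hne,
    })


def summarize_specimen(measurements: pd.DataFrame,
                       patient: PatientRecord) -> SpecimenSummary:
    """Pool one specimen's fibers (across all its fields) into means.

    Fiber-weighted: the mean is over all fibers pooled, so a field with
    more fibers contributes proportionally more — fields are not
    averaged first.
    """
    if len(measurements) == 0:
        raise ValueError(f"specimen {patient.patient_id}: zero fibers to summarize")
    return SpecimenSummary(
        patient_id=patient.patient_id,
        group=patient.group,
        fontaine_stage=patient.fontaine_stage,
        abi=patient.abi,
        cad=patient.cad,
        htn=patient.htn,
        n_fibers=int(len(measurements)),
        mean_carbonyl_gsu=float(measurements["carbonyl_gsu"].mean()),
        mean_hne_gsu=float(measurements["hne_gsu"].mean()),
        mean_csa_um2=float(measurements["csa_um2"].mean()),
    )


def summaries_from_fiber_table(fibers: pd.DataFrame,
                               metadata: pd.DataFrame) -> pd.DataFrame:
    """Specimen summary table from a fiber table plus patient metadata.

    Accepts measured fiber tables (``carbonyl_gsu`` columns) or
    generator ground-truth tables (``true_carbonyl_gsu`` columns).
    Raises if a listed patient has no fibers.
    """
    cols = {c: c.removeprefix("true_").replace("_um2", "_um2") for c in fibers.columns}
    f = fibers.rename(columns=cols)
    grouped = f.groupby("patient_id")
    rows = []
    for _, meta in metadata.iterrows():
        pid = meta["patient_id"]
        if pid not in grouped.groups:
            raise ValueError(f"specimen {pid}: zero fibers to summarize")
        sub = grouped.get_group(pid)
        stage = meta.get("fontaine_stage")
        rows.append({
            "patient_id": pid,
            "group": meta["group"],
            "fontaine_stage": None if pd.isna(stage) else int(stage),
            "abi": float(meta["abi"]),
            "cad": int(meta["cad"]),
            "htn": int(meta["htn"]),
            "n_fibers": int(len(sub)),
            "mean_carbonyl_gsu": float(sub["carbonyl_gsu"].mean()),
            "mean_hne_gsu": float(sub["hne_gsu"].mean()),
            "mean_csa_um2": float(sub["csa_um2"].mean()),
        })
    return pd.DataFrame(rows)
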