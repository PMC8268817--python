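"""Per-patient cell densities in the tumor, stroma and whole-core compartments.

Each 1-mm TMA core contributes counts of positively classified cells and the
measured area of its tumor and stroma compartments.  Duplicate cores of the
same patient are combined by pooling counts and areas (ratio of sums), which
is unbiased when the evaluable areas of the duplicates differ.  The
whole-core density pools both compartments over the total attributed area,
so for every patient

    whole_density * total_area = tumor_density * tumor_area
                               + stroma_density * stroma_area

holds exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COMPARTMENTS = ("tumor", "stroma")
MARKERS = ("NRF2", "TrxR1")


def compute_densities(cells: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Compute CK+ and double-positive densities per patient and compartment.

    Parameters
    ----------
    cells : DataFrame
        One row per cell with columns ``patient_id, core_id, compartment,
        pos_CK, pos_NRF2, pos_TrxR1`` (boolean positivity calls).
    areas : DataFrame
        One row per (core, compartment) with columns ``core_id, compartment,
        area_mm2``; every core referenced by ``cells`` must appear.

    Returns
    -------
    DataFrame indexed by patient with columns
    ``{ck,nrf2_ck,trxr1_ck}_density_{whole,tumor,stroma}`` in cells/mm²
    plus ``area_tumor_mm2``, ``area_stroma_mm2``.  Cores whose total
    attributed area is zero or missing are excluded with a warning; a
    patient left with no cores gets missing densities.
    """
    cells = cells.copy()
    required = {"patient_id", "core_id", "compartment", "pos_CK"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    unknown = set(cells["compartment"].unique()) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"unknown compartment labels: {sorted(unknown)}")

    area_wide = (
        areas.pivot_table(
            index="core_id", columns="compartment", values="area_mm2", aggfunc="sum"
        )
        .reindex(columns=COMPARTMENTS)
        .fillna(0.0)
    )
    missing_cores = set(cells["core_id"].unique()) - set(area_wide.index)
    if missing_cores:
        raise ValueError(f"cores absent from area table: {sorted(missing_cores)}")
    if (area_wide < 0).any().any():
        raise ValueError("negative compartment area")

    patients = pd.Index(sorted(cells["patient_id"].unique()), name="patient_id")
    total = area_wide.sum(axis=1)
    bad = total[(total <= 0) | ~np.isfinite(total)].index
    if len(bad):
        logger.warning("excluding %d core(s) with zero/missing area", len(bad))
        cells = cells[~cells["core_id"].isin(bad)]
        area_wide = area_wide.drop(index=bad)

    core_owner = cells.drop_duplicates("core_id").set_index("core_id")["patient_id"]
    area_by_patient = (
        area_wide.join(core_owner).groupby("patient_id")[list(COMPARTMENTS)].sum()
    ).reindex(patients, fill_value=0.0)

    pos_cols = {"ck": "pos_CK"}
    for m in MARKERS:
        col = f"pos_{m}"
        if col in cells.columns:
            cells[f"dp_{m}"] = cells["pos_CK"] & cells[col]
            pos_cols[f"{m.lower()}_ck"] = f"dp_{m}"

    counts = (
        cells.groupby(["patient_id", "compartment"], observed=True)[
            list(pos_cols.values())
        ]
        .sum()
        .unstack("compartment", fill_value=0)
        .reindex(patients, fill_value=0)
    )

    out = pd.DataFrame(index=patients)
    for comp in COMPARTMENTS:
        out[f"area_{comp}_mm2"] = area_by_patient[comp]
    total_area = area_by_patient.sum(axis=1)
    for name, col in pos_cols.items():
        for comp in COMPARTMENTS:
            n = counts[col][comp] if (col, comp) in counts.columns else 0.0
            denom = area_by_patient[comp]
            out[f"{name}_density_{comp}"] = np.where(denom > 0, n / denom, np.nan)
        n_whole = sum(
            counts[col][c] for c in COMPARTMENTS if (col, c) in counts.columns
        )
        out[f"{name}_density_whole"] = np.where(
            total_area > 0, n_whole / total_area, np.nan
        )
    return out
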