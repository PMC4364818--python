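"""Farming-intensity (Extensive Practices) and Crop Diversity indicators,
plus Kendall's tau redundancy screening of the indicator set.

The Extensive Practices indicators proxy land-use intensity, which a land
cover map alone cannot convey: ``LSI`` (livestock units per hectare of
utilized agricultural area) and ``Irrig`` (irrigated share of UAA, %).
Crop Diversity summarises the census crop-area table per unit as Shannon
diversity/evenness and crop richness.  Redundant indicators are screened
pairwise with tie-corrected Kendall's tau-b; of a pair with |tau| above the
threshold the lower-priority indicator is dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import AgrarianRecord, IndicatorTable, LandscapeUnit, LsuCoefficients
from .landscape_metrics import shannon_diversity, shannon_evenness

logger = logging.getLogger("hnvf")

#: default ecological-priority order for redundancy screening:
#: Extensive Practices, then Landscape Elements, then Crop Diversity
DEFAULT_PRIORITY = [
    "lsi_p", "irrig_p",
    "sdi_p", "sei_p", "np_p", "msi_p", "ed_p",
    "sdi_c", "sei_c", "scrop_p",
]


def livestock_density(
    record: AgrarianRecord, coeffs: LsuCoefficients, unit: LandscapeUnit
) -> float:
    """Livestock density LSI = sum(head * LSU coefficient) / UAA, in LSU/ha.

    Linear in head counts; an empty herd gives 0.  A unit without UAA has no
    defined stocking rate and raises.
    """
    if unit.uaa_ha <= 0:
        raise ValueError(f"unit {unit.unit_id!r}: no utilized agricultural area")
    lsu = sum(heads * coeffs[cat] for cat, heads in record.livestock.items())
    return lsu / unit.uaa_ha


def irrigation_share(
    record: AgrarianRecord, unit: LandscapeUnit, cap: bool = True
) -> float:
    """Irrigated share of UAA in percent: 100 * irrigated_ha / uaa_ha.

    Census irrigation occasionally exceeds the mapped UAA (different survey
    frames); such values warn and are capped at 100 % unless ``cap=False``.
    """
    if unit.uaa_ha <= 0:
        raise ValueError(f"unit {unit.unit_id!r}: no utilized agricultural area")
    share = 100.0 * record.irrigated_ha / unit.uaa_ha
    if record.irrigated_ha > unit.uaa_ha:
        logger.warning(
            "unit %s: irrigated area %.2f ha exceeds UAA %.2f ha%s",
            unit.unit_id, record.irrigated_ha, unit.uaa_ha,
            "; capped at 100%" if cap else "",
        )
        if cap:
            return 100.0
    return share


def crop_diversity(record: AgrarianRecord) -> tuple[float, float, int]:
    """Crop-diversity triple (SDI_c, SEI_c, SCrop).

    SCrop counts crop types with positive area; SDI_c is Shannon diversity of
    the crop-area shares; SEI_c = SDI_c / ln(SCrop) (0 when SCrop <= 1).
    An all-zero crop table yields (0, 0, 0) with a warning.
    """
    areas = [a for a in record.crops.values() if a > 0]
    scrop = len(areas)
    if scrop == 0:
        logger.warning("unit %s: no crops with positive area", record.unit_id)
        return 0.0, 0.0, 0
    total = sum(areas)
    sdi_c = shannon_diversity([a / total for a in areas])
    sei_c = shannon_evenness(sdi_c, scrop)
    return sdi_c, sei_c, scrop


@dataclass
class ScreenResult:
    """Outcome of the redundancy screen: retained column names (in priority
    order), the tau-b matrix, and which indicator each drop was redundant with."""

    retained: list[str]
    tau_matrix: pd.DataFrame
    dropped: dict[str, str]


def kendall_tau_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise tie-corrected Kendall's tau-b across units.

    Constant columns have undefined correlation; their entries are NaN
    (diagonal stays 1 by convention for non-constant columns).
    """
    cols = list(table.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        xa = table[a].to_numpy(dtype=float)
        if np.nanstd(xa) == 0:
            mat.loc[a, :] = np.nan
            mat.loc[:, a] = np.nan
            continue
        for b in cols[i + 1:]:
            xb = table[b].to_numpy(dtype=float)
            if np.nanstd(xb) == 0:
                tau = np.nan
            else:
                mask = ~(np.isnan(xa) | np.isnan(xb))
                tau = stats.kendalltau(xa[mask], xb[mask], variant="b").statistic
            mat.loc[a, b] = mat.loc[b, a] = tau
    return mat


def kendall_screen(
    table: IndicatorTable | pd.DataFrame,
    tau_max: float = 0.7,
    priority: list[str] | None = None,
) -> ScreenResult:
    """Drop redundant indicators by pairwise |tau-b| >= *tau_max*.

    Columns are visited in *priority* order; a candidate is dropped when it
    correlates (in absolute value — anti-correlation is equally redundant)
    at or above the threshold with an already-retained, higher-priority
    indicator.  Constant columns (tau undefined) are retained with a warning.
    Requires at least 3 units.
    """
    df = table.data if isinstance(table, IndicatorTable) else table
    if len(df) < 3:
        raise ValueError("redundancy screening needs at least 3 units")
    priority = list(priority) if priority is not None else [
        c for c in DEFAULT_PRIORITY if c in df.columns
    ]
    missing = [c for c in df.columns if c not in priority]
    if missing:
        raise ValueError(f"priority list does not cover columns: {missing}")
    tau = kendall_tau_matrix(df[priority])
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for col in priority:
        if np.isnan(tau.loc[col].drop(col)).all():
            logger.warning("indicator %s is constant; tau undefined, retained", col)
            retained.append(col)
            continue
        redundant_with = None
        for kept in retained:
            t = tau.loc[col, kept]
            if not np.isnan(t) and abs(t) >= tau_max:
                redundant_with = kept
                break
        if redundant_with is None:
            retained.append(col)
        else:
            dropped[col] = redundant_with
    return ScreenResult(retained=retained, tau_matrix=tau, dropped=dropped)
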