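"""Body-composition indices derived from the raw tissue volumes.

Five indices summarise a subject's thoracic body composition:

========================  =============================  =========
index                     definition                     unit
========================  =============================  =========
Sarcopenia index          muscle / bone                  ratio
Fat index                 TAT / bone                     ratio
Myosteatosis index        100 x IMAT / TAT               percent
Mediastinal fat index     MAT / bone                     ratio
Pulmonary fat index       100 x CTpfav / lung volume     percent
========================  =============================  =========

All are scale-invariant: multiplying every volume of a subject by the same
positive factor leaves the panel unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import DegenerateInputError
from .imaging import BCAVolumes

__all__ = ["IndexPanel", "INDEX_NAMES", "compute_indices", "panel_for_cohort"]

#: canonical column order for index tables
INDEX_NAMES = (
    "sarcopenia_index",
    "fat_index",
    "myosteatosis_index",
    "mediastinal_fat_index",
    "pulmonary_fat_index",
)


@dataclass(frozen=True)
class IndexPanel:
    sarcopenia_index: float
    fat_index: float
    myosteatosis_index: float  # percent
    mediastinal_fat_index: float
    pulmonary_fat_index: float  # percent

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def compute_indices(vols: BCAVolumes) -> IndexPanel:
    """Compute the five indices for one subject.

    Raises :class:`~ctbca.errors.DegenerateInputError` naming the offending
    denominator if bone, TAT or lung volume is zero.
    """
    for denom in ("bone_ml", "tat_ml", "lung_ml"):
        if getattr(vols, denom) <= 0:
            raise DegenerateInputError(f"zero denominator: {denom}")
    return IndexPanel(
        sarcopenia_index=vols.muscle_ml / vols.bone_ml,
        fat_index=vols.tat_ml / vols.bone_ml,
        myosteatosis_index=100.0 * vols.imat_ml / vols.tat_ml,
        mediastinal_fat_index=vols.mat_ml / vols.bone_ml,
        pulmonary_fat_index=100.0 * vols.ctpfav_ml / vols.lung_ml,
    )


def panel_for_cohort(
    rows: Iterable[BCAVolumes] | Mapping[str, BCAVolumes],
) -> pd.DataFrame:
    """Index panels for a cohort, one row per subject, order preserved.

    ``rows`` may be a mapping keyed by subject id or a plain iterable (ids
    are then positional).  A degenerate subject raises with its id named.
    """
    if isinstance(rows, Mapping):
        items = list(rows.items())
    else:
        items = [(str(i), v) for i, v in enumerate(rows)]
    if not items:
        raise DegenerateInputError("empty cohort")
    records = []
    for sid, vols in items:
        try:
            panel = compute_indices(vols)
        except DegenerateInputError as e:
            raise DegenerateInputError(f"subject {sid!r}: {e}") from e
        records.append({"subject_id": sid, **panel.as_dict()})
    return pd.DataFrame.from_records(records, columns=("subject_id", *INDEX_NAMES))
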