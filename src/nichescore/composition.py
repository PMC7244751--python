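"""Subtype composition per time point and composition-switch detection.

Proportions are computed within each cell type: a cell type's subtypes
sum to 100% at every time point. A subtype is called changed between two
time points when the absolute difference of its proportions exceeds the
cutoff in percentage points (strictly greater than 10 points by
default). No statistical test is attached to the call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def subtype_proportions(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per (cell_type, time_point): subtype cell counts and within-type
    proportions. Cell types absent at a time point simply have no rows."""
    required = {"cell_type", "subtype", "time_point"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing column(s): {sorted(missing)}")
    counts = (metadata.groupby(["cell_type", "time_point", "subtype"], sort=True)
              .size().rename("n_cells").reset_index())
    totals = counts.groupby(["cell_type", "time_point"])["n_cells"].transform("sum")
    counts["proportion"] = counts["n_cells"] / totals
    return counts[["cell_type", "subtype", "time_point", "n_cells", "proportion"]]


def changed_subtypes(comp: pd.DataFrame, t0: str, t1: str,
                     cutoff: float = 0.10) -> pd.DataFrame:
    """Flag subtypes whose within-type proportion moves by strictly more
    than ``cutoff`` (fraction; 0.10 = 10 percentage points) from t0 to t1.

    A subtype absent at one time point is treated as proportion 0 there
    (logged). Returns rows of (cell_type, subtype, prop_t0, prop_t1,
    delta_points, direction, changed).
    """
    for tp in (t0, t1):
        if tp not in set(comp["time_point"]):
            raise ValueError(f"time point {tp!r} absent from composition table")
    pivot = comp.pivot_table(index=["cell_type", "subtype"], columns="time_point",
                             values="proportion", aggfunc="first")
    rows = []
    for (cell_type, subtype), row in pivot.iterrows():
        p0 = row.get(t0)
        p1 = row.get(t1)
        if pd.isna(p0) or pd.isna(p1):
            log.info("subtype %s/%s absent at one time point; proportion 0 used",
                     cell_type, subtype)
        p0 = 0.0 if pd.isna(p0) else float(p0)
        p1 = 0.0 if pd.isna(p1) else float(p1)
        delta = 100.0 * (p1 - p0)
        changed = abs(delta) > cutoff * 100.0
        if delta > 0:
            direction = "increased"
        elif delta < 0:
            direction = "decreased"
        else:
            direction = "unchanged"
        rows.append((cell_type, subtype, p0, p1, delta, direction, changed))
    out = pd.DataFrame(rows, columns=["cell_type", "subtype", "prop_t0", "prop_t1",
                                      "delta_points", "direction", "changed"])
    return out.sort_values(["cell_type", "subtype"]).reset_index(drop=True)
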