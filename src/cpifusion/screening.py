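"""Virtual-screening table operations: rank, top-fraction, property filters.

Pipeline order mirrors practice: rank a compound library by predicted
affinity (pEC50), keep the top fraction (default 10%), then apply
docking-score and drug-likeness filters supplied as externally computed
columns.  Docking scores and QikProp #stars are consumed, never computed.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("compound_id", "predicted_affinity")

#: Default selection thresholds: docking score strictly below -7 (more
#: negative = stronger docking) and QikProp #stars strictly below 5.
DOCKING_THRESHOLD = -7.0
STARS_THRESHOLD = 5


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screening table missing columns {missing}")
    if table["compound_id"].duplicated().any():
        raise ValueError("screening table has duplicate compound_id values")
    if not table["predicted_affinity"].map(math.isfinite).all():
        raise ValueError("predicted_affinity must be finite")


def select_top_fraction(table: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep the floor(fraction * n) rows with highest predicted affinity.

    Ties at the cut are broken by compound_id lexicographic order so the
    selection is deterministic; every selected score is >= every unselected
    score.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("cannot rank an empty screening table")
    _check_table(table)
    k = math.floor(fraction * len(table))
    if k == 0:
        logger.warning(
            "top fraction %.3g of %d rows selects 0 compounds", fraction, len(table)
        )
    ranked = table.sort_values(
        ["predicted_affinity", "compound_id"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)


def apply_candidate_filters(
    table: pd.DataFrame,
    docking_threshold: float = DOCKING_THRESHOLD,
    stars_threshold: float = STARS_THRESHOLD,
    strict: bool = True,
) -> pd.DataFrame:
    """Keep rows passing both the docking and the #stars rule.

    Default semantics are strict inequalities (docking_score < -7 AND
    qikprop_stars < 5), so boundary rows are excluded; ``strict=False``
    switches both to <= for parity with tools that include the boundary.
    Rows with missing values in either column are dropped and counted.
    """
    for t in (docking_threshold, stars_threshold):
        if not isinstance(t, (int, float)) or isinstance(t, bool):
            raise TypeError(f"thresholds must be numeric, got {t!r}")
    for col in ("docking_score", "qikprop_stars"):
        if col not in table.columns:
            raise ValueError(f"screening table missing column {col!r}")
    values = table[["docking_score", "qikprop_stars"]].apply(pd.to_numeric, errors="coerce")
    present = values.notna().all(axis=1)
    n_missing = int((~present).sum())
    if n_missing:
        logger.info("dropped %d rows with missing docking/#stars values", n_missing)
    if strict:
        keep = (values["docking_score"] < docking_threshold) & (
            values["qikprop_stars"] < stars_threshold
        )
    else:
        keep = (values["docking_score"] <= docking_threshold) & (
            values["qikprop_stars"] <= stars_threshold
        )
    return table[present & keep].reset_index(drop=True)


def lipinski_violations(mw: float, logp: float, hbd: float, hba: float) -> int:
    """Count of Rule-of-Five violations: MW > 500, logP > 5, HBD > 5, HBA > 10.

    Boundary values are compliant (the rule uses inclusive limits).
    """
    for name, value in (("MW", mw), ("logP", logp), ("HBD", hbd), ("HBA", hba)):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"missing Lipinski property {name!r}")
    return int(mw > 500) + int(logp > 5) + int(hbd > 5) + int(hba > 10)


def add_lipinski_column(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate a screening table with a ``lipinski_violations`` column."""
    needed = ("mw", "logp", "hbd", "hba")
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"screening table missing Lipinski columns {missing}")
    out = table.copy()
    out["lipinski_violations"] = [
        lipinski_violations(r.mw, r.logp, r.hbd, r.hba) for r in table.itertuples()
    ]
    return out


def screen(
    table: pd.DataFrame,
    fraction: float = 0.10,
    docking_threshold: float = DOCKING_THRESHOLD,
    stars_threshold: float = STARS_THRESHOLD,
    strict: bool = True,
) -> pd.DataFrame:
    """Full cascade: rank by predicted affinity, keep the top fraction,
    then apply the docking/#stars filters."""
    return apply_candidate_filters(
        select_top_fraction(table, fraction),
        docking_threshold=docking_threshold,
        stars_threshold=stars_threshold,
        strict=strict,
    )
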