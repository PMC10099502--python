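"""Choice-set construction and supply-environment descriptives.

A respondent's choice set is every outlet within a fixed Euclidean radius of her
residence (3 km for Kenya-like sites, 2 km for Uganda-like sites), plus — when a
chosen outlet is known — that outlet even if it lies beyond the radius, flagged
``out_of_radius`` so the retention is auditable.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DataError

#: outlet columns copied into the choice-set table (estimation attributes)
OUTLET_ATTRIBUTE_COLUMNS = (
    "n_methods",
    "open7",
    "stockout_injectables",
    "trained_provider",
    "fp_signage",
    "is_public",
    "is_pharmacy",
)


def euclidean_distance(p, q) -> float:
    """Straight-line distance between two planar points in km."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise DataError("non-finite coordinates")
    return float(np.hypot(*(p - q)))


def _distance_matrix(respondents: pd.DataFrame, outlets: pd.DataFrame) -> np.ndarray:
    r = respondents[["x_km", "y_km"]].to_numpy(dtype=float)
    o = outlets[["x_km", "y_km"]].to_numpy(dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(o))):
        raise DataError("non-finite coordinates in input tables")
    return cdist(r, o)


def build_choice_sets(
    respondents: pd.DataFrame,
    outlets: pd.DataFrame,
    choice_radius: float,
    chosen_links: pd.Series | dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the long respondent-by-outlet choice-set table.

    Parameters
    ----------
    chosen_links : mapping respondent_id -> outlet_id, optional
        Observed choices.  Chosen outlets beyond the radius are retained and
        flagged rather than dropped; a chosen id absent from the outlet table is
        a hard error.

    Returns
    -------
    (table, report) : the table has one row per (respondent, in-radius outlet)
    plus flagged out-of-radius chosen rows; the report counts respondents with
    empty sets and out-of-radius chosen outlets.
    """
    if chosen_links is not None and not isinstance(chosen_links, pd.Series):
        chosen_links = pd.Series(chosen_links)
    if chosen_links is not None:
        missing = set(chosen_links.dropna()) - set(outlets["outlet_id"])
        if missing:
            raise DataError(f"chosen outlet id(s) absent from outlets table: {sorted(missing)}")

    dmat = _distance_matrix(respondents, outlets)
    within = dmat <= choice_radius
    rid = respondents["respondent_id"].to_numpy()
    oid = outlets["outlet_id"].to_numpy()

    if chosen_links is not None:
        chosen_col = np.asarray(
            [chosen_links.get(r, None) for r in rid], dtype=object
        )
        oid_index = pd.Index(oid)
        has_choice = np.array([c is not None and not pd.isna(c) for c in chosen_col])
        chosen_j = np.full(len(rid), -1)
        if has_choice.any():
            chosen_j[has_choice] = oid_index.get_indexer(chosen_col[has_choice])
        # force-include the chosen outlet
        keep = within.copy()
        keep[np.nonzero(has_choice)[0], chosen_j[has_choice]] = True
    else:
        keep = within
        chosen_j = np.full(len(rid), -1)

    ri, oj = np.nonzero(keep)
    table = pd.DataFrame(
        {
            "respondent_id": rid[ri],
            "outlet_id": oid[oj],
            "distance_km": dmat[ri, oj],
            "out_of_radius": (dmat[ri, oj] > choice_radius).astype(int),
        }
    )
    attrs = outlets.set_index("outlet_id").loc[table["outlet_id"], list(OUTLET_ATTRIBUTE_COLUMNS)]
    table = pd.concat([table.reset_index(drop=True), attrs.reset_index(drop=True)], axis=1)
    if chosen_links is not None:
        table["chosen"] = (chosen_j[ri] == oj).astype(int)

    set_sizes = keep.sum(axis=1)
    report = {
        "n_respondents": len(rid),
        "n_rows": int(len(table)),
        "empty_choice_sets": list(rid[set_sizes == 0]),
        "out_of_radius_chosen": list(
            rid[(chosen_j >= 0) & (dmat[np.arange(len(rid)), np.maximum(chosen_j, 0)] > choice_radius)]
        )
        if chosen_links is not None
        else [],
    }
    return table, report


def summarize_environment(
    respondents: pd.DataFrame, outlets: pd.DataFrame, choice_radius: float
) -> pd.DataFrame:
    """Per-respondent supply environment within the radius: outlet counts by type,
    count offering outreach, and mean number of methods offered (NaN when no
    outlet is in radius)."""
    dmat = _distance_matrix(respondents, outlets)
    within = dmat <= choice_radius
    is_pub = outlets["is_public"].to_numpy(dtype=float)
    is_pha = outlets["is_pharmacy"].to_numpy(dtype=float)
    is_pri = 1.0 - is_pub - is_pha
    outreach = outlets["outreach"].to_numpy(dtype=float)
    methods = outlets["n_methods"].to_numpy(dtype=float)

    n_in = within.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_methods = np.where(n_in > 0, (within * methods).sum(axis=1) / np.maximum(n_in, 1), np.nan)
    return pd.DataFrame(
        {
            "respondent_id": respondents["respondent_id"].to_numpy(),
            "n_outlets": n_in,
            "n_pharmacies": (within * is_pha).sum(axis=1).astype(int),
            "n_public": (within * is_pub).sum(axis=1).astype(int),
            "n_private": (within * is_pri).sum(axis=1).astype(int),
            "n_outreach": (within * outreach).sum(axis=1).astype(int),
            "mean_methods": mean_methods,
        }
    )


def linkage_rate(n_users: int, n_linked: int) -> float:
    """Share of method users linked to their source outlet, in percent, rounded
    half-up to one decimal (the descriptive-table convention)."""
    if n_users < 1:
        raise DataError("n_users must be >= 1")
    if not 0 <= n_linked <= n_users:
        raise DataError("n_linked must be in [0, n_users]")
    pct = decimal.Decimal(100 * n_linked) / decimal.Decimal(n_users)
    return float(pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))
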