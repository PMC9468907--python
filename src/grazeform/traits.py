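"""Species-level trait indices from quadrat records.

Four indices summarise how a grass species behaves under frequent grazing:

culm orientation index
    mean of a 1–5 code per record (1 = lateral/prostrate culms, 5 = upright).
lateral index
    proportion of records in which the species had stolons or long rhizomes
    (capacity for lateral vegetative spread).
tuft index
    proportion of records in which the species had a tufted base.
grazer use index
    mean over all the species' records of ``min(r, 1/r)`` where
    ``r = height / site median height``; species much taller *or* much
    shorter than the local grazing sward both score low, species held at the
    sward median score near 1.
"""

from __future__ import annotations

import logging

import pandas as pd

from .survey import CULM_CATEGORIES, Survey

logger = logging.getLogger(__name__)

#: Culm orientation category -> numeric code.  Geniculate and decumbent share
#: code 3 (both intermediate between prostrate and upright).
CULM_CODES = {
    "lateral": 1,
    "geniculate-lateral": 2,
    "geniculate": 3,
    "decumbent": 3,
    "geniculate-upright": 4,
    "upright": 5,
}

TRAIT_COLUMNS = [
    "culm_orientation_index",
    "lateral_index",
    "tuft_index",
    "grazer_use_index",
]

#: Species must occur in more than this many quadrats to enter the formal
#: clustering; rarer species are assigned manually.
CLUSTER_MIN_QUADRATS = 10


def encode_culm_orientation(category: str) -> int:
    """Map a culm orientation category to its 1–5 code."""
    try:
        return CULM_CODES[category]
    except KeyError:
        raise ValueError(
            f"unknown culm orientation {category!r}; legal categories: "
            f"{list(CULM_CATEGORIES)}"
        ) from None


def site_median_height(survey: Survey) -> pd.Series:
    """Median leaf table height per site over all species x quadrat records.

    Every record counts once (unweighted, not cover-weighted); the pandas
    median (midpoint of the two central values for even counts) is used.
    Sites without observations are simply absent from the result.
    """
    med = survey.observations.groupby("site_id")["leaf_table_height_mm"].median()
    missing = set(survey.sites["site_id"]) - set(med.index)
    if missing:
        logger.warning("sites with no observations have no median height: %s", sorted(missing))
    med.name = "median_height_mm"
    return med


def grazer_use_index(records: pd.DataFrame, medians: pd.Series) -> float:
    """Grazer use index for one species from its height records.

    Parameters
    ----------
    records
        DataFrame with columns ``site_id`` and ``leaf_table_height_mm``,
        one row per species x quadrat record.
    medians
        Site median heights as returned by :func:`site_median_height`.

    Returns
    -------
    float in (0, 1]: mean of the ratio height/site-median, with ratios
    above 1 replaced by their reciprocal, pooled over all records across
    sites (a flat mean over records, not a mean of site means).
    """
    med = records["site_id"].map(medians)
    if med.isna().any():
        missing = sorted(records.loc[med.isna(), "site_id"].unique())
        raise ValueError(f"no site median height for site(s) {missing}")
    r = records["leaf_table_height_mm"] / med
    r = r.where(r <= 1.0, 1.0 / r)
    return float(r.mean())


def build_trait_table(survey: Survey) -> pd.DataFrame:
    """Compute the four trait indices for every species in the survey.

    Returns a DataFrame indexed by species with columns
    ``culm_orientation_index, lateral_index, tuft_index, grazer_use_index,
    n_quadrats, clustered``; ``clustered`` marks species occurring in more
    than :data:`CLUSTER_MIN_QUADRATS` quadrats.
    """
    obs = survey.observations.copy()
    obs["culm_code"] = obs["culm_orientation"].map(CULM_CODES)
    obs["spreads"] = obs["stolons"] | (obs["rhizome"] == "long")

    medians = site_median_height(survey)
    med = obs["site_id"].map(medians)
    r = obs["leaf_table_height_mm"] / med
    obs["use_ratio"] = r.where(r <= 1.0, 1.0 / r)

    g = obs.groupby("species")
    table = pd.DataFrame(
        {
            "culm_orientation_index": g["culm_code"].mean(),
            "lateral_index": g["spreads"].mean(),
            "tuft_index": g["tufted_base"].mean(),
            "grazer_use_index": g["use_ratio"].mean(),
            "n_quadrats": g.size(),
        }
    )
    table["clustered"] = table["n_quadrats"] > CLUSTER_MIN_QUADRATS
    table.index.name = "species"
    return table.sort_index()
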