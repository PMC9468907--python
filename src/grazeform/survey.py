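"""Quadrat-survey data model, validation and file I/O.

A survey of frequently grazed grass communities consists of three tables:

``observations``
    one row per species-in-quadrat record with the raw field traits
    (% aerial cover, median leaf table height, culm orientation,
    stolons, rhizomes, tufted base);
``meta``
    one row per quadrat with % bare ground and dung presence;
``sites``
    one row per site with the four environment variables (mean annual
    rainfall, % sand, cation exchange capacity, pH).

All tables are plain :class:`pandas.DataFrame` objects; :class:`Survey`
bundles them and enforces referential integrity.  Validation is total: every
out-of-range or out-of-enumeration value is reported with its row index and
field name, and nothing is silently coerced.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Legal culm orientation categories (prostrate to upright, incl. hybrids).
CULM_CATEGORIES = (
    "lateral",
    "geniculate-lateral",
    "geniculate",
    "decumbent",
    "geniculate-upright",
    "upright",
)

#: Legal rhizome categories.  "short" rhizomes build a tuft; "long" rhizomes
#: found spatially separate ramets.
RHIZOME_CATEGORIES = ("none", "short", "long")

#: The four growth-form / life-history-strategy labels.
GROWTH_FORMS = ("lateral_attractor", "avoider", "tufted_attractor", "resister")

QUADRAT_COLUMNS = [
    "site_id",
    "quadrat_id",
    "species",
    "cover_pct",
    "leaf_table_height_mm",
    "culm_orientation",
    "stolons",
    "rhizome",
    "tufted_base",
]
META_COLUMNS = ["site_id", "quadrat_id", "bare_ground_pct", "dung_present"]
SITE_COLUMNS = ["site_id", "map_mm", "sand_pct", "cec", "ph"]

#: Minimum quadrats per site before a warning is raised (smallest site in a
#: well-designed survey of this kind).
MIN_QUADRATS_PER_SITE = 15


class SurveyError(ValueError):
    """Base class for survey input problems."""


class SchemaError(SurveyError):
    """A required column is missing from an input table."""


class ValidationError(SurveyError):
    """A value is out of range or outside its enumeration."""


class ReferentialError(SurveyError):
    """A quadrat or site is referenced but has no metadata/environment row."""


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table}: missing required column(s) {missing}; "
            f"expected header {required}"
        )


def _check_range(df, field, lo, hi, table, lo_open=False, hi_open=False):
    x = pd.to_numeric(df[field], errors="coerce")
    bad = x.isna()
    bad |= (x <= lo) if lo_open else (x < lo)
    bad |= (x >= hi) if hi_open else (x > hi)
    if bad.any():
        row = int(df.index[bad][0])
        lob, hib = ("(" if lo_open else "["), (")" if hi_open else "]")
        raise ValidationError(
            f"{table} row {row}: field '{field}' value {df[field].iloc[df.index.get_loc(row)]!r} "
            f"outside {lob}{lo}, {hi}{hib}"
        )
    df[field] = x.astype(float)


def _check_enum(df, field, legal, table):
    vals = df[field].astype(str).str.strip()
    bad = ~vals.isin(legal)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"{table} row {row}: field '{field}' value {df[field].loc[row]!r} "
            f"not one of {list(legal)}"
        )
    df[field] = vals


_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _check_bool(df, field, table):
    raw = df[field]
    if raw.dtype == bool:
        return
    vals = raw.astype(str).str.strip().str.lower()
    bad = ~vals.isin(_TRUE | _FALSE)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"{table} row {row}: field '{field}' value {raw.loc[row]!r} "
            f"is not a boolean (use 0/1 or true/false)"
        )
    df[field] = vals.isin(_TRUE)


@dataclass
class Survey:
    """A validated quadrat survey: observations, quadrat metadata, sites."""

    observations: pd.DataFrame
    meta: pd.DataFrame
    sites: pd.DataFrame

    def validate(self) -> "Survey":
        """Check schemas, value ranges, enumerations and referential integrity.

        Returns ``self`` so that ``Survey(...).validate()`` chains.  Raises
        :class:`SchemaError`, :class:`ValidationError` or
        :class:`ReferentialError` on the first problem found, naming the
        table, row index and field.
        """
        obs, meta, sites = self.observations, self.meta, self.sites
        _require_columns(obs, QUADRAT_COLUMNS, "quadrats")
        _require_columns(meta, META_COLUMNS, "quadrat_meta")
        _require_columns(sites, SITE_COLUMNS, "sites")

        _check_range(obs, "cover_pct", 0.0, 100.0, "quadrats")
        _check_range(obs, "leaf_table_height_mm", 0.0, np.inf, "quadrats", lo_open=True)
        _check_enum(obs, "culm_orientation", CULM_CATEGORIES, "quadrats")
        _check_enum(obs, "rhizome", RHIZOME_CATEGORIES, "quadrats")
        _check_bool(obs, "stolons", "quadrats")
        _check_bool(obs, "tufted_base", "quadrats")

        dup = obs.duplicated(subset=["site_id", "quadrat_id", "species"])
        if dup.any():
            row = int(obs.index[dup][0])
            raise ValidationError(
                f"quadrats row {row}: duplicate (site_id, quadrat_id, species) record"
            )

        _check_range(meta, "bare_ground_pct", 0.0, 100.0, "quadrat_meta")
        _check_bool(meta, "dung_present", "quadrat_meta")
        if meta.duplicated(subset=["site_id", "quadrat_id"]).any():
            raise ValidationError("quadrat_meta: duplicate (site_id, quadrat_id) row")

        _check_range(sites, "map_mm", 0.0, np.inf, "sites", lo_open=True)
        _check_range(sites, "sand_pct", 0.0, 100.0, "sites")
        _check_range(sites, "cec", 0.0, np.inf, "sites")
        _check_range(sites, "ph", 0.0, 14.0, "sites", lo_open=True, hi_open=True)
        if sites.duplicated(subset=["site_id"]).any():
            raise ValidationError("sites: duplicate site_id row")
        if sites[["map_mm", "sand_pct", "cec", "ph"]].isna().any().any():
            raise ValidationError("sites: missing environment value")

        # referential integrity
        quad_keys = set(map(tuple, meta[["site_id", "quadrat_id"]].itertuples(index=False)))
        obs_keys = set(map(tuple, obs[["site_id", "quadrat_id"]].itertuples(index=False)))
        dangling = obs_keys - quad_keys
        if dangling:
            raise ReferentialError(
                f"quadrats reference (site, quadrat) pairs with no quadrat_meta row: "
                f"{sorted(dangling)[:5]}"
            )
        site_ids = set(sites["site_id"])
        dangling_sites = set(obs["site_id"]) - site_ids
        if dangling_sites:
            raise ReferentialError(
                f"quadrats reference sites with no environment row: "
                f"{sorted(dangling_sites)[:5]}"
            )
        dangling_meta = set(meta["site_id"]) - site_ids
        if dangling_meta:
            raise ReferentialError(
                f"quadrat_meta references sites with no environment row: "
                f"{sorted(dangling_meta)[:5]}"
            )

        small = meta.groupby("site_id").size()
        small = small[small < MIN_QUADRATS_PER_SITE]
        if len(small):
            warnings.warn(
                f"sites with fewer than {MIN_QUADRATS_PER_SITE} quadrats: "
                f"{dict(small)}", stacklevel=2,
            )
        return self

    def __eq__(self, other) -> bool:  # value equality on the three tables
        if not isinstance(other, Survey):
            return NotImplemented
        return all(
            a.reset_index(drop=True).equals(b.reset_index(drop=True))
            for a, b in (
                (self.observations, other.observations),
                (self.meta, other.meta),
                (self.sites, other.sites),
            )
        )


def load_survey(quadrats_path, meta_path, sites_path) -> Survey:
    """Read and validate the three survey CSVs.

    Parameters
    ----------
    quadrats_path, meta_path, sites_path
        Paths to ``quadrats.csv``, ``quadrat_meta.csv`` and ``sites.csv``
        (comma-delimited, UTF-8, headers as in the module docstring).
    """
    obs = pd.read_csv(quadrats_path, dtype={"site_id": str, "quadrat_id": str, "species": str})
    meta = pd.read_csv(meta_path, dtype={"site_id": str, "quadrat_id": str})
    sites = pd.read_csv(sites_path, dtype={"site_id": str})
    return Survey(obs, meta, sites).validate()


#: Float formatting for all CSV output.  ``None`` selects pandas' shortest
#: round-trip representation: lossless (load(write(x)) == x) and
#: deterministic, so identical inputs reproduce byte-identical files.
FLOAT_FORMAT = None


def write_survey(survey: Survey, out_dir) -> dict[str, str]:
    """Write a survey back to ``quadrats.csv``/``quadrat_meta.csv``/``sites.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("quadrats.csv", survey.observations),
        ("quadrat_meta.csv", survey.meta),
        ("sites.csv", survey.sites),
    ):
        p = out_dir / name
        df.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths[name] = str(p)
    return paths


def summarize_survey(survey: Survey) -> pd.DataFrame:
    """Per-site summary: quadrat count, species count, mean bare ground, dung proportion.

    Dung proportion is the fraction of quadrats with dung present; mean bare
    ground is the unweighted mean over quadrats.  Sites present in the
    environment table but with no quadrats are excluded with a logged warning.
    """
    meta = survey.meta
    g = meta.groupby("site_id")
    out = pd.DataFrame(
        {
            "n_quadrats": g.size(),
            "bare_ground_mean": g["bare_ground_pct"].mean(),
            "dung_proportion": g["dung_present"].mean(),
        }
    )
    n_species = survey.observations.groupby("site_id")["species"].nunique()
    out["n_species"] = n_species.reindex(out.index).fillna(0).astype(int)
    empty = set(survey.sites["site_id"]) - set(out.index)
    if empty:
        logger.warning("sites with no quadrats excluded from summary: %s", sorted(empty))
    out.index.name = "site_id"
    return out[["n_quadrats", "n_species", "bare_ground_mean", "dung_proportion"]]


def load_overrides(path) -> pd.Series:
    """Read a species -> growth-form override table (``overrides.csv``)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["species", "growth_form"], "overrides")
    bad = ~df["growth_form"].isin(GROWTH_FORMS)
    if bad.any():
        row = int(df.index[bad][0])
        raise ValidationError(
            f"overrides row {row}: growth_form {df['growth_form'].loc[row]!r} "
            f"not one of {list(GROWTH_FORMS)}"
        )
    return df.set_index("species")["growth_form"]


def write_results(results: dict, out_dir) -> dict:
    """Write a dictionary of pipeline products and return a manifest.

    Each value must either expose ``to_files(out_dir) -> dict[name, path]``
    (the result dataclasses of the analysis modules do) or be a
    :class:`pandas.DataFrame`/`dict`, written as ``<key>.csv``/``<key>.json``.
    Re-running with identical inputs reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"files": {}}
    for key, value in results.items():
        if hasattr(value, "to_files"):
            manifest["files"].update(value.to_files(out_dir))
        elif isinstance(value, Survey):
            manifest["files"].update(write_survey(value, out_dir))
        elif isinstance(value, pd.DataFrame):
            p = out_dir / f"{key}.csv"
            value.to_csv(p, float_format=FLOAT_FORMAT)
            manifest["files"][f"{key}.csv"] = str(p)
        elif isinstance(value, dict):
            p = out_dir / f"{key}.json"
            p.write_text(json.dumps(value, indent=2, sort_keys=True, default=_json_default))
            manifest["files"][f"{key}.json"] = str(p)
        else:
            raise TypeError(f"do not know how to write result {key!r} of type {type(value)}")
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["files"]["manifest.json"] = str(mpath)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
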