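"""Site-level bare-ground analyses.

Bare ground is the field's degradation indicator: the analyses here (1)
split sites by whether lateral or tufted attractor grasses dominate, (2)
compare mean bare ground between the two groups with a one-way F test, and
(3) regress percentage bare ground on rainfall x sand x grazing pressure
(dung proportion) within each group, ranking every marginality-respecting
sub-model by small-sample-corrected AICc.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survey import Survey, summarize_survey

logger = logging.getLogger(__name__)

PREDICTORS = ["map_mm", "sand_pct", "dung_proportion"]


def site_summaries(survey: Survey, cover_by_form: pd.DataFrame) -> pd.DataFrame:
    """Per-site table joining bare ground, dung proportion, environment and
    growth-form cover, with the lateral/tufted dominance class."""
    base = summarize_survey(survey)
    env = survey.sites.set_index("site_id")[["map_mm", "sand_pct", "cec", "ph"]]
    out = base.join(env).join(cover_by_form, how="left")
    for form in ("lateral_attractor", "tufted_attractor"):
        if form not in out.columns:
            out[form] = 0.0
    diff = out["lateral_attractor"] - out["tufted_attractor"]
    out["dominance"] = np.where(diff > 0, "lateral", np.where(diff < 0, "tufted", "tie"))
    return out


def dominance_split(summaries: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sites into lateral- vs tufted-attractor-dominated groups.

    Sites where the two attractor covers are exactly equal are flagged and
    excluded with a warning.
    """
    ties = summaries.index[summaries["dominance"] == "tie"]
    if len(ties):
        warnings.warn(f"sites with tied attractor cover excluded: {list(ties)}", stacklevel=2)
    lateral = summaries[summaries["dominance"] == "lateral"]
    tufted = summaries[summaries["dominance"] == "tufted"]
    return lateral, tufted


def compare_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way F test for a difference in mean bare ground between two groups.

    Returns ``(F, (df1, df2), p)`` with ``df = (1, n - 2)``.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 sites")
    n = len(a) + len(b)
    grand = (a.sum() + b.sum()) / n
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def _marginal_term_sets() -> list[tuple[str, ...]]:
    """All sub-models of the three-way factorial that respect marginality
    (an interaction only enters with all its constituent main effects),
    plus the intercept-only model (empty tuple)."""
    mains = PREDICTORS
    all_terms = []
    for order in (1, 2, 3):
        all_terms += [":".join(c) for c in combinations(mains, order)]
    sets = []
    for mask in range(2 ** len(all_terms)):
        chosen = [t for i, t in enumerate(all_terms) if mask >> i & 1]
        ok = True
        for t in chosen:
            parts = t.split(":")
            if len(parts) > 1:
                for sub_order in range(1, len(parts)):
                    for sub in combinations(parts, sub_order):
                        if ":".join(sub) not in chosen:
                            ok = False
        if ok:
            sets.append(tuple(chosen))
    return sorted(sets, key=lambda s: (len(s), s))


def _design_matrix(df: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for t in terms:
        parts = t.split(":")
        col = df[parts[0]].astype(float).copy()
        for pp in parts[1:]:
            col = col * df[pp].astype(float)
        X[t] = col
    return X


def _gaussian_aicc(rss: float, n: int, n_coef: int) -> float:
    """AICc of a least-squares fit; the residual variance counts as a parameter."""
    p = n_coef + 1
    if rss <= 0 or n - p - 1 <= 0:
        return np.inf
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


@dataclass
class ModelComparison:
    """AICc ladder over the bare-ground regression sub-models of one group."""

    group: str
    ladder: pd.DataFrame  # terms, n_coef, rss, AICc, delta_AICc
    best_terms: tuple[str, ...]
    best_coefficients: pd.Series
    best_f: float | None  # overall regression F of the best model
    best_f_df: tuple[int, int] | None
    best_f_p: float | None
    n_sites: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_sites": self.n_sites,
            "ladder": [
                {
                    "terms": list(r["terms"]),
                    "n_coef": int(r["n_coef"]),
                    "AICc": float(r["AICc"]),
                    "delta_AICc": float(r["delta_AICc"]),
                }
                for _, r in self.ladder.iterrows()
            ],
            "best": {
                "terms": list(self.best_terms),
                "coefficients": {k: float(v) for k, v in self.best_coefficients.items()},
                "F": self.best_f,
                "df": list(self.best_f_df) if self.best_f_df else None,
                "p": self.best_f_p,
            },
        }


def fit_bareground_subsets(
    group_sites: pd.DataFrame, group: str = "", response: str = "bare_ground_mean"
) -> ModelComparison:
    """All-subsets OLS of bare ground on rainfall x sand x dung proportion.

    Fits every marginality-respecting sub-model (including intercept-only)
    by ordinary least squares, ranks them by Gaussian AICc, and reports the
    best model's coefficients with its overall regression F test.
    Collinear candidates are flagged and skipped; fewer than 5 sites
    triggers a warning and the higher-order models are skipped as saturated.
    """
    df = group_sites
    n = len(df)
    if n < 5:
        warnings.warn(
            f"group {group!r} has only {n} sites; near-saturated models skipped",
            stacklevel=2,
        )
    y = df[response].to_numpy(dtype=float)
    rows = []
    fits = {}
    for terms in _marginal_term_sets():
        X = _design_matrix(df, terms)
        if X.shape[1] + 2 >= n:  # leave >= 1 residual df after counting sigma
            continue
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            logger.warning("collinear design for terms %s; candidate skipped", terms)
            continue
        res = sm.OLS(y, X).fit()
        aicc = _gaussian_aicc(float(res.ssr), n, X.shape[1])
        rows.append({"terms": terms, "n_coef": X.shape[1], "rss": float(res.ssr), "AICc": aicc})
        fits[terms] = res
    if not rows:
        raise ValueError(f"no candidate model could be fitted for group {group!r}")
    ladder = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    ladder["delta_AICc"] = ladder["AICc"] - ladder["AICc"].min()
    best_terms = ladder.loc[0, "terms"]
    best = fits[best_terms]
    if best_terms:
        f, fp = float(best.fvalue), float(best.f_pvalue)
        fdf = (int(best.df_model), int(best.df_resid))
    else:
        f = fp = fdf = None
    return ModelComparison(
        group=group,
        ladder=ladder,
        best_terms=best_terms,
        best_coefficients=pd.Series(best.params, index=_design_matrix(df, best_terms).columns),
        best_f=f,
        best_f_df=fdf,
        best_f_p=fp,
        n_sites=n,
    )


@dataclass
class BareGroundAnalysis:
    """The full bare-ground stage: group comparison plus per-group ladders."""

    overall_mean: float
    group_means: dict[str, float]
    f_statistic: float
    f_df: tuple[int, int]
    f_p: float
    comparisons: dict[str, ModelComparison]

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / "bareground_models.json"
        payload = {
            "overall_mean_bare_ground_pct": self.overall_mean,
            "group_means": self.group_means,
            "group_comparison": {
                "F": self.f_statistic,
                "df": list(self.f_df),
                "p": self.f_p,
            },
            "groups": {k: v.to_dict() for k, v in self.comparisons.items()},
        }
        p.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return {"bareground_models.json": str(p)}


def analyze_bare_ground(summaries: pd.DataFrame) -> BareGroundAnalysis:
    """Run the complete bare-ground stage on a site-summary table."""
    lateral, tufted = dominance_split(summaries)
    F, df, p = compare_groups(
        lateral["bare_ground_mean"].to_numpy(), tufted["bare_ground_mean"].to_numpy()
    )
    comparisons = {
        "lateral_dominated": fit_bareground_subsets(lateral, "lateral_dominated"),
        "tufted_dominated": fit_bareground_subsets(tufted, "tufted_dominated"),
    }
    used = pd.concat([lateral, tufted])
    return BareGroundAnalysis(
        overall_mean=float(used["bare_ground_mean"].mean()),
        group_means={
            "lateral": float(lateral["bare_ground_mean"].mean()),
            "tufted": float(tufted["bare_ground_mean"].mean()),
        },
        f_statistic=F,
        f_df=df,
        f_p=p,
        comparisons=comparisons,
    )
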