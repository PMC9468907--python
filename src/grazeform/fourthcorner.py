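"""Fourth-corner trait-environment analysis.

Links three matrices — site x species presence (L), site x environment (R)
and species x trait (Q) — through a single binomial GLM on the vectorized
presence matrix:

    logit P(species s present at site i)
        = alpha_s + sum_e gamma_e * env_e(i)
          + sum_{q,e} beta_{qe} * trait_q(s) * env_e(i)

The beta matrix is the "fourth corner": trait x environment association
coefficients.  Presence is defined on each site's minimal set of species
jointly making up 90% of summed cover, so the model describes which kinds
of species *dominate* where.  Environment subsets are compared by AICc, and
the overall trait-environment interaction is tested by a site-block
permutation ANOVA of the likelihood-ratio deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .survey import FLOAT_FORMAT, Survey

logger = logging.getLogger(__name__)

ENV_VARS = ["map_mm", "sand_pct", "cec", "ph"]
TRAITS = ["culm_orientation_index", "lateral_index", "tuft_index", "grazer_use_index"]

#: Cumulative share of summed site cover the retained dominant species reach.
COVER_THRESHOLD = 0.90


def minimal_cover_set(site_community: pd.Series) -> list[str]:
    """Smallest set of species jointly comprising 90% of a site's cover.

    Species are ranked by descending cover (ties alphabetical) and the
    shortest prefix whose cumulative share of total site cover reaches
    :data:`COVER_THRESHOLD` is returned.
    """
    cov = site_community[site_community > 0]
    total = cov.sum()
    if len(cov) == 0 or total <= 0:
        raise ValueError("all species covers are zero at this site")
    ranked = cov.sort_index().sort_values(ascending=False, kind="stable")
    share = ranked.cumsum() / total
    n_keep = int(np.searchsorted(share.to_numpy(), COVER_THRESHOLD - 1e-12) + 1)
    return list(ranked.index[:n_keep])


@dataclass
class CommunityTriplet:
    """The three matrices of a fourth-corner analysis, aligned and scaled.

    ``L`` is sites x species 0/1 presence (dominant species only), ``R``
    sites x environment and ``Q`` species x trait, both centered and
    unit-variance scaled (scalers recorded in ``R_scaler``/``Q_scaler``
    with rows ``center`` and ``scale``).  ``site_cover`` keeps the raw
    site-mean per-species cover the presence matrix was derived from.
    """

    L: pd.DataFrame
    R: pd.DataFrame
    Q: pd.DataFrame
    R_scaler: pd.DataFrame
    Q_scaler: pd.DataFrame
    site_cover: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.L.size


def _standardize(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    center, scale = df.mean(), df.std(ddof=0)
    if (scale == 0).any():
        raise ValueError(f"constant column(s): {list(df.columns[scale == 0])}")
    return (df - center) / scale, pd.DataFrame({"center": center, "scale": scale}).T


def site_species_cover(survey: Survey) -> pd.DataFrame:
    """Site x species mean aerial cover (mean over all quadrats at the site,
    quadrats where the species is absent counting as zero)."""
    obs = survey.observations
    tot = obs.pivot_table(
        index="site_id", columns="species", values="cover_pct", aggfunc="sum", fill_value=0.0
    )
    n_quadrats = survey.meta.groupby("site_id").size()
    return tot.div(n_quadrats.reindex(tot.index), axis=0)


def build_triplet(survey: Survey, trait_table: pd.DataFrame) -> CommunityTriplet:
    """Assemble the L, R, Q matrices from a survey and its trait table."""
    cover = site_species_cover(survey)
    presence = pd.DataFrame(0, index=cover.index, columns=cover.columns, dtype=int)
    for site in cover.index:
        keep = minimal_cover_set(cover.loc[site])
        presence.loc[site, keep] = 1
    presence = presence.loc[:, presence.sum(axis=0) > 0]

    missing = [s for s in presence.columns if s not in trait_table.index]
    if missing:
        raise ValueError(f"retained species missing from trait table: {missing}")

    R_raw = survey.sites.set_index("site_id")[ENV_VARS].loc[presence.index]
    Q_raw = trait_table.loc[presence.columns, TRAITS]
    R, R_scaler = _standardize(R_raw)
    Q, Q_scaler = _standardize(Q_raw)
    return CommunityTriplet(
        L=presence, R=R, Q=Q, R_scaler=R_scaler, Q_scaler=Q_scaler, site_cover=cover
    )


# ---------------------------------------------------------------------------
# binomial GLM by iteratively reweighted least squares
# ---------------------------------------------------------------------------

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-10
#: L2 penalty used when a fit separates; scaled by the cell count.
RIDGE_ALPHA = 1e-2


class GLMConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trajectory."""

    def __init__(self, trajectory):
        super().__init__(
            f"IRLS did not converge in {MAX_IRLS_ITER} iterations; "
            f"deviance trajectory tail: {trajectory[-5:]}"
        )
        self.trajectory = trajectory


def _logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Newton/IRLS fit of a Bernoulli logit GLM.

    Returns ``(beta, deviance)``.  With ``ridge > 0`` a quadratic penalty
    ``ridge * ||beta||^2 / 2`` stabilizes separated fits (the reported
    deviance remains the unpenalized one).
    """
    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    dev_prev = np.inf
    trajectory = []
    for _ in range(MAX_IRLS_ITER):
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X
        if ridge > 0:
            H = H + ridge * np.eye(p)
        try:
            beta_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H, XtW @ z, rcond=None)[0]
        eta = X @ beta_new
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        trajectory.append(dev)
        if abs(dev_prev - dev) < IRLS_TOL * (abs(dev) + 1.0):
            return beta_new, dev
        dev_prev, beta = dev, beta_new
    if ridge > 0:
        raise GLMConvergenceError(trajectory)
    # likely separation: retry with ridge stabilization
    logger.warning("IRLS not converged (possible separation); ridge-stabilized refit")
    return _logistic_irls(X, y, ridge=RIDGE_ALPHA * n / max(n, 1))


def _design(triplet: CommunityTriplet, env_subset: list[str], interactions: bool = True):
    """Vectorized design matrix for the fourth-corner GLM.

    Rows are site-major (site, species) cells.  Columns: one indicator per
    species (absorbing the intercept and any trait main effects), one main
    effect per environment variable, and, when ``interactions``, one
    ``trait x env`` product column per pair.
    """
    n_sites, n_species = triplet.L.shape
    R = triplet.R[env_subset].to_numpy() if env_subset else np.empty((n_sites, 0))
    Q = triplet.Q.to_numpy()
    y = triplet.L.to_numpy(dtype=float).ravel()

    sp_block = np.tile(np.eye(n_species), (n_sites, 1))
    env_block = np.repeat(R, n_species, axis=0)
    cols = [f"sp:{s}" for s in triplet.L.columns] + [f"env:{e}" for e in env_subset]
    blocks = [sp_block, env_block]
    if interactions:
        q_rep = np.tile(Q, (n_sites, 1))
        inter = q_rep[:, :, None] * env_block[:, None, :]
        blocks.append(inter.reshape(len(y), -1))
        cols += [f"{t}:{e}" for t in TRAITS for e in env_subset]
    return np.hstack(blocks), y, cols


def _aicc(loglik: float, p: int, n: int) -> float:
    if n - p - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n - p - 1)


@dataclass
class FourthCornerModel:
    """Fitted fourth-corner GLM for one environment subset."""

    coefficients: pd.DataFrame  # traits x env interaction matrix
    species_intercepts: pd.Series
    env_main: pd.Series
    deviance: float
    loglik: float
    aicc: float
    n_params: int
    n_cells: int
    env_subset: list[str]

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / "fourthcorner_coefs.csv"
        long = self.coefficients.stack().rename("coefficient").reset_index()
        long.columns = ["trait", "env_variable", "coefficient"]
        long.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        return {"fourthcorner_coefs.csv": str(p)}


def fit_fourth_corner(
    triplet: CommunityTriplet, env_subset: list[str] | None = None
) -> FourthCornerModel:
    """Maximum-likelihood fit of the fourth-corner binomial GLM.

    ``env_subset`` defaults to all four environment variables.  The AICc is
    computed with ``n`` equal to the number of site x species cells.
    """
    if env_subset is None:
        env_subset = list(ENV_VARS)
    if not env_subset:
        raise ValueError("env_subset must be a non-empty subset of the environment variables")
    bad = [e for e in env_subset if e not in triplet.R.columns]
    if bad:
        raise ValueError(f"unknown environment variable(s): {bad}")

    X, y, cols = _design(triplet, env_subset, interactions=True)
    beta, dev = _logistic_irls(X, y)
    coef = pd.Series(beta, index=cols)
    inter = pd.DataFrame(
        coef[len(triplet.L.columns) + len(env_subset):].to_numpy().reshape(
            len(TRAITS), len(env_subset)
        ),
        index=TRAITS,
        columns=env_subset,
    )
    n, p = len(y), X.shape[1]
    loglik = -dev / 2.0  # saturated log-likelihood is 0 for 0/1 responses
    return FourthCornerModel(
        coefficients=inter,
        species_intercepts=coef[: len(triplet.L.columns)],
        env_main=coef[len(triplet.L.columns): len(triplet.L.columns) + len(env_subset)],
        deviance=dev,
        loglik=loglik,
        aicc=_aicc(loglik, p, n),
        n_params=p,
        n_cells=n,
        env_subset=list(env_subset),
    )


@dataclass
class SubsetSelection:
    """AICc ladder over all non-empty environment subsets."""

    ladder: pd.DataFrame  # env_subset, AICc, delta_AICc, n_params
    best: FourthCornerModel
    models: dict[tuple, FourthCornerModel]
    null_reference_aicc: float  # intercept-only (species effects, no environment)

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = self.best.to_files(out_dir)
        p = out_dir / "aicc_ladder.csv"
        self.ladder.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths["aicc_ladder.csv"] = str(p)
        return paths


def _all_subsets(items: list[str]):
    for mask in range(1, 2 ** len(items)):
        yield [v for i, v in enumerate(items) if mask >> i & 1]


def select_env_subset(triplet: CommunityTriplet) -> SubsetSelection:
    """Fit all 15 non-empty environment subsets and rank them by AICc.

    The species-intercepts-only model (no environment terms) is fitted too,
    as a null reference reported separately — it cannot answer the
    trait-environment question so it never competes for "best".  A subset
    whose fit fails is annotated in the ladder and skipped.
    """
    models: dict[tuple, FourthCornerModel] = {}
    rows = []
    for subset in _all_subsets(ENV_VARS):
        try:
            m = fit_fourth_corner(triplet, subset)
            models[tuple(subset)] = m
            rows.append(
                {"env_subset": "+".join(subset), "AICc": m.aicc, "n_params": m.n_params}
            )
        except (GLMConvergenceError, np.linalg.LinAlgError) as e:  # pragma: no cover
            rows.append({"env_subset": "+".join(subset), "AICc": np.nan, "n_params": np.nan})
            logger.warning("subset %s failed to fit: %s", subset, e)
    ladder = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    ladder["delta_AICc"] = ladder["AICc"] - ladder["AICc"].min()
    best_key = tuple(ladder.loc[0, "env_subset"].split("+"))
    # intercept-only reference
    X0, y, _ = _design(triplet, [], interactions=False)
    _, dev0 = _logistic_irls(X0, y)
    null_aicc = _aicc(-dev0 / 2.0, X0.shape[1], len(y))
    return SubsetSelection(
        ladder=ladder[["env_subset", "AICc", "delta_AICc", "n_params"]],
        best=models[best_key],
        models=models,
        null_reference_aicc=null_aicc,
    )


@dataclass
class ResamplingTest:
    """Permutation ANOVA of the overall trait-environment interaction."""

    statistic: float
    n_iterations: int
    null_statistics: np.ndarray
    p_value: float
    seed: int

    def to_files(self, out_dir) -> dict[str, str]:
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / "anova.json"
        p.write_text(
            json.dumps(
                {
                    "statistic": self.statistic,
                    "n_iterations": self.n_iterations,
                    "p": self.p_value,
                    "seed": self.seed,
                },
                indent=2,
            )
        )
        return {"anova.json": str(p)}


def anova_resampling(
    triplet: CommunityTriplet,
    env_subset: list[str] | None = None,
    n_iterations: int = 999,
    seed: int = 0,
) -> ResamplingTest:
    """Site-block permutation test of the trait-environment interaction.

    The statistic is the likelihood-ratio deviance between the fourth-corner
    model and the same model with all trait x environment terms removed.
    Under the null the environment rows are exchangeable against the
    community rows, so each iteration permutes sites' environments en bloc
    (keeping within-site species co-occurrence intact) and refits both
    models.  ``p = (1 + #{null >= observed}) / (1 + n_iterations)``.
    """
    if env_subset is None:
        env_subset = list(ENV_VARS)
    if n_iterations < 99:
        logger.warning("n_iterations=%d gives coarse p-value resolution", n_iterations)

    def stat(perm: np.ndarray | None) -> float:
        t = triplet
        if perm is not None:
            R_perm = triplet.R.iloc[perm].set_index(triplet.R.index)
            t = CommunityTriplet(
                L=triplet.L, R=R_perm, Q=triplet.Q,
                R_scaler=triplet.R_scaler, Q_scaler=triplet.Q_scaler,
                site_cover=triplet.site_cover,
            )
        X1, y, _ = _design(t, env_subset, interactions=True)
        X0, _, _ = _design(t, env_subset, interactions=False)
        _, dev1 = _logistic_irls(X1, y)
        _, dev0 = _logistic_irls(X0, y)
        return dev0 - dev1

    observed = stat(None)
    rng = np.random.default_rng(seed)
    n_sites = len(triplet.R)
    null = np.array([stat(rng.permutation(n_sites)) for _ in range(n_iterations)])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iterations)
    return ResamplingTest(
        statistic=float(observed),
        n_iterations=n_iterations,
        null_statistics=null,
        p_value=float(p),
        seed=seed,
    )
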