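"""Environmental ordination of sites and growth-form cover surfaces.

Sites are ordinated by PCA of the four environment variables (rainfall,
% sand, CEC, pH); the percentage cover of each growth form is then
interpolated across the first two principal axes by piecewise-linear
barycentric interpolation over a Delaunay triangulation of the site scores.
No extrapolation is performed outside the convex hull of the sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .growthform import PCAResult, pca
from .survey import FLOAT_FORMAT, Survey


@dataclass
class SiteOrdination:
    """Environment PCA of sites: scores (sites x 2), loadings, variance shares."""

    scores: pd.DataFrame  # sites x [PC1, PC2]
    loadings: pd.DataFrame  # 4 env vars x 2
    variance_pct: np.ndarray  # all components
    pca: PCAResult

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / "site_pca.csv"
        out = self.scores.rename(columns={"PC1": "pc1", "PC2": "pc2"}).copy()
        out.index.name = "site_id"
        with open(p, "w") as fh:
            out.to_csv(fh, float_format=FLOAT_FORMAT)
            fh.write("# loadings\n")
            self.loadings.to_csv(fh, float_format=FLOAT_FORMAT)
        return {"site_pca.csv": str(p)}


def site_environment_pca(sites: pd.DataFrame) -> SiteOrdination:
    """Centered, unit-variance PCA of the four site environment variables."""
    env = sites.set_index("site_id")[["map_mm", "sand_pct", "cec", "ph"]]
    if len(env) < 3:
        raise ValueError("need at least 3 sites for a site ordination")
    res = pca(env, unit_variance=True)
    return SiteOrdination(
        scores=res.scores[["PC1", "PC2"]],
        loadings=res.loadings[["PC1", "PC2"]],
        variance_pct=res.variance_pct,
        pca=res,
    )


def growthform_site_cover(survey: Survey, assignments: pd.DataFrame) -> pd.DataFrame:
    """Site x growth-form percentage cover.

    For every quadrat the per-species covers of each form's species are
    summed (all species at the site, not only the dominant set); the site
    value is the mean over all the site's quadrats, quadrats without any
    grass of a form contributing zero.
    """
    obs = survey.observations.copy()
    obs["growth_form"] = obs["species"].map(assignments["growth_form"])
    obs["growth_form"] = obs["growth_form"].fillna("unassigned")
    per_site = obs.pivot_table(
        index="site_id", columns="growth_form", values="cover_pct",
        aggfunc="sum", fill_value=0.0,
    )
    n_quadrats = survey.meta.groupby("site_id").size()
    cover = per_site.div(n_quadrats.reindex(per_site.index), axis=0)
    # sites with quadrats but no grass at all
    cover = cover.reindex(n_quadrats.index, fill_value=0.0)
    cover.columns.name = None
    cover.index.name = "site_id"
    return cover


@dataclass
class CoverSurface:
    """Interpolated cover of one growth form over the (PC1, PC2) plane.

    ``grid`` holds the evaluation points with interpolated cover (NaN
    outside the convex hull of the sites); ``contour_levels`` are the 10%
    steps spanning the observed cover range.
    """

    growth_form: str
    grid: pd.DataFrame  # pc1, pc2, cover
    contour_levels: list[float]

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p = out_dir / f"cover_surface_{self.growth_form}.csv"
        self.grid.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        return {p.name: str(p)}


def interpolate_cover_surface(
    ordination: SiteOrdination, cover: pd.DataFrame, grid_n: int = 100
) -> dict[str, CoverSurface]:
    """Linear barycentric interpolation of each form's cover over PC1/PC2.

    Evaluates on a ``grid_n`` x ``grid_n`` grid spanning the site scores;
    points outside the convex hull are NaN, interpolated values are clipped
    at zero, and contour levels run 0, 10, 20, ... up to the observed
    maximum.  Exact at the sites themselves.
    """
    pts = ordination.scores.to_numpy()
    cover = cover.loc[ordination.scores.index]
    x = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_n)
    y = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_n)
    gx, gy = np.meshgrid(x, y)
    surfaces = {}
    for form in cover.columns:
        try:
            interp = LinearNDInterpolator(pts, cover[form].to_numpy())
        except QhullError as e:
            raise ValueError(
                "site scores are collinear; cannot triangulate "
                "(consider jittering the scores)"
            ) from e
        z = np.clip(interp(gx, gy), 0.0, None)
        grid = pd.DataFrame(
            {"pc1": gx.ravel(), "pc2": gy.ravel(), "cover": z.ravel()}
        )
        top = float(np.nanmax(z)) if np.isfinite(z).any() else 0.0
        levels = [float(v) for v in np.arange(0.0, top + 10.0, 10.0)]
        surfaces[form] = CoverSurface(growth_form=form, grid=grid, contour_levels=levels)
    return surfaces
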