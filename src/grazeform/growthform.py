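"""Growth-form classification: PCA of range-standardized trait indices,
Ward agglomeration on the principal-component scores, a k-group cut, and
v-test cluster description (hierarchical clustering on principal components).

The classification pipeline (:func:`assign_growth_forms`) is
range-standardize -> PCA (all components retained) -> Ward clustering on PC
scores -> cut at ``k`` groups -> v-tests on the raw indices, with the four
named growth forms (lateral attractor, tufted attractor, resister, avoider)
assigned from each cluster's v-test signature.  Species too rare to cluster
stably are labelled from a manual override table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survey import FLOAT_FORMAT

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# standardization and PCA
# ---------------------------------------------------------------------------

def range_standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each column linearly onto [0, 1] via (x - min) / (max - min).

    Returns the standardized table and a two-row DataFrame recording the
    min and max used per column.  A constant column cannot be
    range-standardized and raises ``ValueError`` naming it.
    """
    lo, hi = table.min(), table.max()
    flat = hi <= lo
    if flat.any():
        raise ValueError(
            f"cannot range-standardize constant variable(s): {list(table.columns[flat])}"
        )
    out = (table - lo) / (hi - lo)
    ranges = pd.DataFrame({"min": lo, "max": hi}).T
    return out, ranges


@dataclass
class PCAResult:
    """Principal components of an items x variables table.

    ``loadings`` are variables x components (unit-norm right singular
    vectors), ``scores`` items x components, and ``variance_pct`` the
    percentage of total variance per component (sums to 100).  ``center``
    and ``scale`` record the per-variable shift and divisor applied before
    decomposition, so the input can be reconstructed exactly.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_pct: np.ndarray
    center: pd.Series
    scale: pd.Series


def pca(table: pd.DataFrame, unit_variance: bool = True) -> PCAResult:
    """Centered (and optionally unit-variance) PCA via singular value decomposition.

    Scaling uses the population standard deviation (``ddof=0``), so results
    are invariant to duplicating every row.  The sign of each component is
    fixed deterministically: the largest-magnitude loading is made positive.

    Raises ``ValueError`` for fewer than 2 items/variables, missing values,
    a constant variable under ``unit_variance``, or rank-0 input.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 items and 2 variables")
    if table.isna().any().any():
        raise ValueError("PCA input contains missing values")
    center = table.mean()
    X = table - center
    if unit_variance:
        scale = table.std(ddof=0)
        if (scale == 0).any():
            raise ValueError(
                f"constant variable(s) cannot be unit-variance scaled: "
                f"{list(table.columns[scale == 0])}"
            )
    else:
        scale = pd.Series(1.0, index=table.columns)
    X = X / scale
    if not np.isfinite(X.to_numpy()).all() or (X.to_numpy() == 0).all():
        raise ValueError("degenerate (rank-0) PCA input")

    U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comp = [f"PC{j + 1}" for j in range(len(s))]
    ev = s**2
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=table.columns, columns=comp),
        scores=pd.DataFrame(U * s, index=table.index, columns=comp),
        variance_pct=100.0 * ev / ev.sum(),
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Ward agglomeration
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Agglomerative merge history.

    ``merges`` lists ``(a, b, height)`` triples; leaves are numbered
    ``0..n-1`` and the cluster created by merge ``i`` gets id ``n + i``.
    Heights are Ward distances on the (root-squared) Euclidean scale, so
    ``height**2 / 2`` is the increase in within-cluster sum of squares at
    that merge.  ``leaf_order`` is the dendrogram leaf ordering.
    """

    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    labels: list = field(default_factory=list)  # item names, optional

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1


def ward_cluster(points: np.ndarray) -> ClusterTree:
    """Ward minimum-variance agglomeration of row vectors.

    Implements the Lance–Williams recurrence on squared Euclidean
    distances (the modern "Ward.D2" criterion); the pair with the smallest
    Ward distance is merged at each step, with exact ties broken by the
    lexicographically smallest pair of cluster ids for determinism.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")

    # squared distances between active clusters, keyed by cluster id
    d2 = {}
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = sq[i, j]
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    children: dict[int, tuple[int, int]] = {}

    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (a, b) if a < b else (b, a)
                v = d2[key]
                if best is None or v < best[0] or (v == best[0] and key < best[1]):
                    best = (v, key)
        v, (a, b) = best
        new = n + step
        merges.append((a, b, float(np.sqrt(v))))
        children[new] = (a, b)
        # Lance-Williams update for Ward on squared distances
        na, nb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            nc = size[c]
            dac = d2[(a, c) if a < c else (c, a)]
            dbc = d2[(b, c) if b < c else (c, b)]
            d2[(c, new)] = (
                (na + nc) * dac + (nb + nc) * dbc - nc * v
            ) / (na + nb + nc)
        size[new] = na + nb
        active = [c for c in active if c not in (a, b)] + [new]

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return _leaves(a) + _leaves(b)

    return ClusterTree(merges=merges, leaf_order=_leaves(n + n - 2))


def cut_tree(tree: ClusterTree, k: int) -> np.ndarray:
    """Cluster labels from removing the ``k - 1`` highest merges.

    Labels ``0..k-1`` are assigned by decreasing cluster size, ties broken
    by first appearance in the dendrogram leaf order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _h) in enumerate(tree.merges[: n - k]):
        new = n + i
        parent[find(a)] = new
        parent[find(b)] = new

    roots = [find(i) for i in range(n)]
    uniq = {}
    for r in roots:
        uniq.setdefault(r, len(uniq))
    raw = np.array([uniq[r] for r in roots])

    # relabel: decreasing size, then leaf order of first member
    pos = {leaf: p for p, leaf in enumerate(tree.leaf_order)}
    order = sorted(
        set(raw),
        key=lambda c: (-int(np.sum(raw == c)), min(pos[i] for i in np.where(raw == c)[0])),
    )
    remap = {c: i for i, c in enumerate(order)}
    return np.array([remap[c] for c in raw])


# ---------------------------------------------------------------------------
# v-test cluster description
# ---------------------------------------------------------------------------

def vtest(values: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Cluster-description v-tests for each (cluster, trait) pair.

    For a cluster of size ``n_k`` among ``N`` items,

        v = (mean_k - mean) / sqrt((s^2 / n_k) * (N - n_k) / (N - 1))

    with ``s^2`` the population variance of all ``N`` values: the statistic
    compares the cluster mean with the mean of a random size-``n_k`` subset
    drawn without replacement.  Two-sided p-values use the standard normal.
    Degenerate cases (``s^2 = 0`` or ``n_k = N``) report ``v = 0`` with
    ``degenerate = True``.
    """
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise ValueError("labels and values must have equal length")
    N = len(values)
    rows = []
    for c in sorted(set(labels.tolist())):
        mask = labels == c
        n_k = int(mask.sum())
        for trait in values.columns:
            x = values[trait].to_numpy(dtype=float)
            mu, s2 = x.mean(), x.var(ddof=0)
            mk = x[mask].mean()
            denom2 = (s2 / n_k) * (N - n_k) / (N - 1)
            if denom2 <= 0:
                v, p, degen = 0.0, 1.0, True
            else:
                v = (mk - mu) / np.sqrt(denom2)
                p = 2.0 * stats.norm.sf(abs(v))
                degen = False
            rows.append(
                {
                    "cluster": c,
                    "trait": trait,
                    "cluster_mean": mk,
                    "overall_mean": mu,
                    "v": v,
                    "p": p,
                    "degenerate": degen,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# growth-form naming and the full pipeline
# ---------------------------------------------------------------------------

#: Precedence order in which named forms are matched to clusters.
_NAME_PRECEDENCE = ("lateral_attractor", "resister", "tufted_attractor", "avoider")


def _signature_scores(vt: pd.DataFrame) -> pd.DataFrame:
    """Score each cluster against each named growth-form signature.

    Signatures (in v-statistic space): lateral attractors have high lateral
    index; resisters high culm orientation and low grazer use; tufted
    attractors high tuft and high grazer use; avoiders low grazer use and
    low tuft.
    """
    v = vt.pivot(index="cluster", columns="trait", values="v")
    return pd.DataFrame(
        {
            "lateral_attractor": v["lateral_index"],
            "resister": (v["culm_orientation_index"] - v["grazer_use_index"]) / 2,
            "tufted_attractor": (v["tuft_index"] + v["grazer_use_index"]) / 2,
            "avoider": (-v["grazer_use_index"] - v["tuft_index"]) / 2,
        }
    )


def name_clusters(vt: pd.DataFrame) -> tuple[dict[int, str], list[int]]:
    """Map cluster ids to growth-form names by their v-test signatures.

    Forms are claimed in a fixed precedence order (lateral attractor,
    resister, tufted attractor, avoider): each form takes the unnamed
    cluster with the highest signature score.  Clusters left over (k > 4)
    keep a ``cluster_<id>`` name.  Exact score ties are reported as
    ambiguous, not guessed: the tied cluster ids are returned and the
    lexicographically smallest id wins deterministically.
    """
    scores = _signature_scores(vt)
    named: dict[int, str] = {}
    ambiguous: list[int] = []
    remaining = list(scores.index)
    for form in _NAME_PRECEDENCE:
        if not remaining:
            break
        s = scores.loc[remaining, form]
        top = s.max()
        winners = sorted(s.index[s == top])
        if len(winners) > 1:
            ambiguous.extend(winners)
        named[winners[0]] = form
        remaining.remove(winners[0])
    for c in remaining:
        named[c] = f"cluster_{c}"
    return named, sorted(set(ambiguous))


@dataclass
class GrowthFormModel:
    """Full classification result: assignments plus the fitted machinery."""

    assignments: pd.DataFrame  # species -> growth_form, provenance, cluster
    pca: PCAResult
    tree: ClusterTree
    vtests: pd.DataFrame
    cluster_names: dict[int, str]
    ambiguous_clusters: list[int]

    def to_files(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out_dir / "assignments.csv"
        self.assignments.to_csv(p, float_format=FLOAT_FORMAT)
        paths["assignments.csv"] = str(p)
        p = out_dir / "vtests.csv"
        self.vtests.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths["vtests.csv"] = str(p)
        p = out_dir / "pca_traits.csv"
        block = self.pca.loadings.T.copy()
        block.insert(0, "variance_pct", self.variance_pct_series())
        block.index.name = "component"
        block.to_csv(p, float_format=FLOAT_FORMAT)
        paths["pca_traits.csv"] = str(p)
        return paths

    def variance_pct_series(self) -> pd.Series:
        return pd.Series(self.pca.variance_pct, index=self.pca.loadings.columns)


def assign_growth_forms(
    trait_table: pd.DataFrame,
    k: int = 4,
    overrides: pd.Series | None = None,
    unit_variance: bool = True,
) -> GrowthFormModel:
    """Classify species into growth forms.

    Species occurring often enough (``clustered`` flag in the trait table)
    are range-standardized, decomposed by PCA (all components kept),
    Ward-clustered on the PC scores and cut into ``k`` groups; the groups
    are named from their v-test signatures on the raw indices.  Rarer
    species take their label from ``overrides`` (species -> growth form);
    any without an override are labelled ``"unassigned"`` with a warning.
    """
    clustered = trait_table[trait_table["clustered"]]
    if len(clustered) < k:
        raise ValueError(
            f"only {len(clustered)} species occur often enough to cluster; need >= k = {k}"
        )
    idx = clustered.index
    std, _ranges = range_standardize(clustered[
        ["culm_orientation_index", "lateral_index", "tuft_index", "grazer_use_index"]
    ])
    pc = pca(std, unit_variance=unit_variance)
    tree = ward_cluster(pc.scores.to_numpy())
    tree.labels = list(idx)
    labels = cut_tree(tree, k)
    vt = vtest(
        clustered[["culm_orientation_index", "lateral_index", "tuft_index", "grazer_use_index"]],
        labels,
    )
    names, ambiguous = name_clusters(vt)
    if ambiguous:
        logger.warning("ambiguous cluster signatures (tied scores): %s", ambiguous)

    rows = []
    for sp, lab in zip(idx, labels):
        rows.append({"species": sp, "growth_form": names[lab],
                     "cluster": int(lab), "provenance": "clustered"})
    rare = trait_table.index[~trait_table["clustered"]]
    for sp in rare:
        if overrides is not None and sp in overrides.index:
            gf = overrides.loc[sp]
        else:
            gf = "unassigned"
        rows.append({"species": sp, "growth_form": gf, "cluster": -1,
                     "provenance": "manual_override" if gf != "unassigned" else "unassigned"})
    unassigned = [r["species"] for r in rows if r["growth_form"] == "unassigned"]
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} rare species without manual override labelled "
            f"'unassigned': {unassigned[:5]}...", stacklevel=2,
        )
    assignments = pd.DataFrame(rows).set_index("species").sort_index()
    return GrowthFormModel(
        assignments=assignments,
        pca=pc,
        tree=tree,
        vtests=vt,
        cluster_names=names,
        ambiguous_clusters=ambiguous,
    )
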