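"""Design-based (Horvitz–Thompson / Hájek) estimation for spatially balanced
surveys, with the local neighborhood variance estimator.

Percent-cover estimates use the Hájek (ratio) form

    p̂_c = 100 · Σ_i (y_ic / π_i) / Σ_i (1 / π_i)

so that the three substrate-class estimates sum to exactly 100 even when the
realized number of sites is random.  Standard errors come from the local
neighborhood variance estimator of Stevens & Olsen, which contrasts each
site's weighted value against a doubly smoothed mean over its ~4 nearest
sampled neighbours; for spatially structured populations it tracks the true
design variance of spatially balanced samples far better than the simple
random sampling formula.

Biota totals follow the same pattern on two-phase inclusion probabilities
(π* = π_phase1 · π_phase2|1), scaled by the frame area, with 95% normal
intervals truncated at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import catami

__all__ = [
    "SiteRecord",
    "CategoryEstimate",
    "NeighborhoodWeights",
    "neighborhood_weights",
    "local_mean_variance",
    "ht_category_estimate",
    "two_phase_pi",
    "image_cover_scores",
    "site_mean_cover",
    "biota_total_area",
    "estimates_to_frame",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class SiteRecord:
    """One surveyed site: location, adjusted inclusion probability, and the
    per-class substrate proportions of its standardized 0.04 km² footprint."""

    site_id: object
    x: float
    y: float
    pi: float
    props: dict[str, float]
    standardized_area_km2: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.pi <= 1):
            raise ValueError(f"pi must lie in (0,1], got {self.pi}")
        total = sum(self.props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")


@dataclass
class CategoryEstimate:
    """A design-based estimate with its standard error and truncated 95% CI."""

    category: str
    estimate: float
    std_error: float
    lcb95: float
    ucb95: float
    units: str = "%"


@dataclass
class NeighborhoodWeights:
    """Doubly smoothed weights over local neighborhoods D(i).

    Rows sum to exactly 1; after the balancing iterations column sums are
    within ~1e-6 of 1 as well.
    """

    weights: np.ndarray  # dense (n, n); zero outside neighborhoods
    neighborhoods: list[np.ndarray]


def neighborhood_weights(
    x: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> NeighborhoodWeights:
    """Build the local-neighborhood weight matrix for the variance estimator.

    D(i) contains site i itself plus its ``n_neighbors`` nearest sampled
    neighbours, symmetrized (j ∈ D(i) ⇒ i ∈ D(j)).  Initial weights are
    inverse-distance (the self-distance is taken as the distance to the
    nearest neighbour so the site does not dominate its own neighborhood),
    then rows and columns are alternately normalized until both sum to 1
    within ``tol`` (ending on rows, so row sums are exact).
    """
    pts = np.stack([np.asarray(x, float), np.asarray(y, float)], axis=1)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 sites")
    d = cdist(pts, pts)
    k = min(n_neighbors, n - 1)
    mask = np.zeros((n, n), dtype=bool)
    order = np.argsort(d, axis=1, kind="stable")
    for i in range(n):
        mask[i, order[i, : k + 1]] = True  # self is always nearest (d=0)
    mask |= mask.T

    nearest = np.where(d > 0, d, np.inf).min(axis=1)
    deff = d.copy()
    np.fill_diagonal(deff, nearest)
    w = np.where(mask, 1.0 / np.maximum(deff, 1e-12), 0.0)

    for _ in range(max_iter):
        w = w / w.sum(axis=0, keepdims=True)  # columns
        rs = w.sum(axis=1, keepdims=True)
        w = w / rs  # rows
        if np.abs(w.sum(axis=0) - 1.0).max() < tol:
            break
    w = w / w.sum(axis=1, keepdims=True)
    nbrs = [np.flatnonzero(mask[i]) for i in range(n)]
    return NeighborhoodWeights(weights=w, neighborhoods=nbrs)


def local_mean_variance(
    x: np.ndarray,
    y: np.ndarray,
    pi: np.ndarray,
    values: np.ndarray,
    n_neighbors: int = 4,
) -> float:
    """Local neighborhood variance of the HT total Σ values_i / π_i.

    V̂ = c · Σ_i Σ_{j∈D(i)} w_ij (t_j − Σ_{k∈D(i)} w_ik t_k)²,  t_j = z_j/π_j,

    where c = n / (n − Σ_ij w_ij²) corrects the downward bias of the local
    quadratic form with small neighborhoods (each contrast loses a w_ij²
    share of the variance to its own neighborhood mean; c makes V̂ exactly
    unbiased for the anticipated variance under an exchangeable population).

    Non-negative; exactly 0 when all t_j are equal.  With fewer than 4 sites
    the neighborhoods are degenerate, so the simple-random-sampling variance
    formula is used instead (with a logged warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pi = np.asarray(pi, float)
    z = np.asarray(values, float)
    n = len(z)
    t = z / pi
    if n < 4:
        logger.warning(
            "local neighborhood variance needs >= 4 sites (got %d); "
            "falling back to the SRS variance formula",
            n,
        )
        if n < 2:
            return 0.0
        nhat = float(np.sum(1.0 / pi))
        return nhat**2 * float(np.var(t / nhat * n, ddof=1)) / n

    nw = neighborhood_weights(x, y, n_neighbors=n_neighbors)
    w = nw.weights
    tbar = w @ t
    v = float(np.sum(w * (t[None, :] - tbar[:, None]) ** 2))
    v *= n / (n - float(np.sum(w**2)))
    return max(v, 0.0)


def ht_category_estimate(
    sites: pd.DataFrame,
    classes: tuple[str, ...] = ("hard", "mixed", "soft"),
    prop_prefix: str = "prop_",
) -> dict[str, CategoryEstimate]:
    """Hájek percent-cover estimate per substrate class with local-variance CIs.

    ``sites`` needs columns x, y, pi and one ``prop_<class>`` column per class
    (per-site proportions in [0, 1] that sum to 1).  Estimates are percentages
    that sum to exactly 100; intervals are truncated to [0, 100].
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    pi = sites["pi"].to_numpy(float)
    if np.any(~np.isfinite(pi)) or np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("inclusion probabilities must lie in (0, 1]")
    x = sites["x"].to_numpy(float)
    y = sites["y"].to_numpy(float)
    inv = 1.0 / pi
    nhat = inv.sum()

    out: dict[str, CategoryEstimate] = {}
    for c in classes:
        yv = sites[f"{prop_prefix}{c}"].to_numpy(float)
        phat = float((yv * inv).sum() / nhat)  # in [0, 1]
        resid = yv - phat
        if np.allclose(resid, 0.0):
            var_total = 0.0
        else:
            var_total = local_mean_variance(x, y, pi, resid)
        se = 100.0 * np.sqrt(var_total) / nhat
        est = 100.0 * phat
        out[c] = CategoryEstimate(
            category=c,
            estimate=est,
            std_error=float(se),
            lcb95=float(max(0.0, est - Z95 * se)),
            ucb95=float(min(100.0, est + Z95 * se)),
            units="%",
        )
    return out


def two_phase_pi(pi_phase1, pi_phase2_given_1):
    """Overall inclusion probability of two-phase sampling: the product of the
    phase-1 probability and the conditional phase-2 probability."""
    p1 = np.asarray(pi_phase1, dtype=float)
    p2 = np.asarray(pi_phase2_given_1, dtype=float)
    if np.any(p1 <= 0) or np.any(p2 <= 0):
        raise ValueError("phase probabilities must be positive")
    if np.any(p1 > 1) or np.any(p2 > 1):
        raise ValueError("phase probabilities must be <= 1")
    out = p1 * p2
    return float(out) if np.isscalar(pi_phase1) and np.isscalar(pi_phase2_given_1) else out


def image_cover_scores(
    annotations: pd.DataFrame,
    level: int = 4,
    points_per_image: int = 25,
    vocabulary: catami.Vocabulary | None = None,
) -> pd.DataFrame:
    """Per-image percent-cover from 25-point annotations, aggregated to a
    hierarchical level.

    ``annotations`` has columns site_id, image_id, point_idx, label; every
    image must carry exactly ``points_per_image`` labels.  Cover of a group
    is (points hit)/25, summing hits over all descendant labels of that
    group.  Groups with zero hits are reported explicitly so downstream site
    means are well defined.
    """
    vocab = vocabulary or catami.default_vocabulary()
    required = {"site_id", "image_id", "point_idx", "label"}
    missing = required - set(annotations.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    counts = annotations.groupby(["site_id", "image_id"]).size()
    bad = counts[counts != points_per_image]
    if len(bad):
        sid, iid = bad.index[0]
        raise ValueError(
            f"image {iid!r} at site {sid!r} has {bad.iloc[0]} point labels, "
            f"expected {points_per_image}"
        )
    for lab in annotations["label"].unique():
        vocab.validate(lab)

    groups = vocab.codes_at_level(level)
    ann = annotations.copy()
    ann["group"] = [vocab.ancestor_at_level(lab, level) for lab in ann["label"]]
    hit = ann.dropna(subset=["group"])
    tab = (
        hit.groupby(["site_id", "image_id", "group"])
        .size()
        .rename("points_hit")
        .reset_index()
    )
    # fill in explicit zeros for every (image, group) pair
    images = annotations[["site_id", "image_id"]].drop_duplicates()
    full = images.merge(pd.DataFrame({"group": groups}), how="cross")
    tab = full.merge(tab, on=["site_id", "image_id", "group"], how="left")
    tab["points_hit"] = tab["points_hit"].fillna(0).astype(int)
    tab["cover"] = tab["points_hit"] / points_per_image
    tab["level"] = level
    return tab


def site_mean_cover(image_covers: pd.DataFrame) -> pd.DataFrame:
    """Site-level cover = unweighted mean over that site's images (images are
    GRTS-balanced within the site, so equal weights)."""
    return (
        image_covers.groupby(["site_id", "group"])["cover"]
        .mean()
        .rename("cover")
        .reset_index()
    )


def biota_total_area(
    site_covers: pd.DataFrame,
    sites: pd.DataFrame,
    frame_area_km2: float,
) -> dict[str, CategoryEstimate]:
    """Estimated total area (km²) occupied by each biological group.

    T̂_b = frame_area × Hájek mean cover of group b over sites, using two-phase
    inclusion probabilities in ``sites['pi']``; 95% CIs via the local
    neighborhood variance, truncated below at 0.
    """
    if frame_area_km2 <= 0:
        raise ValueError("frame_area_km2 must be positive")
    pi = sites["pi"].to_numpy(float)
    if np.any(pi <= 0) or np.any(pi > 1):
        raise ValueError("inclusion probabilities must lie in (0, 1]")
    x = sites["x"].to_numpy(float)
    y = sites["y"].to_numpy(float)
    inv = 1.0 / pi
    nhat = inv.sum()
    site_ids = sites["site_id"].to_numpy()

    out: dict[str, CategoryEstimate] = {}
    wide = site_covers.pivot_table(
        index="site_id", columns="group", values="cover", fill_value=0.0
    ).reindex(site_ids, fill_value=0.0)
    for group in wide.columns:
        cov = wide[group].to_numpy(float)
        mean_cover = float((cov * inv).sum() / nhat)
        total = frame_area_km2 * mean_cover
        resid = cov - mean_cover
        if np.allclose(resid, 0.0):
            var_total = 0.0
        else:
            var_total = local_mean_variance(x, y, pi, resid)
        se = frame_area_km2 * np.sqrt(var_total) / nhat
        out[group] = CategoryEstimate(
            category=group,
            estimate=float(total),
            std_error=float(se),
            lcb95=float(max(0.0, total - Z95 * se)),
            ucb95=float(total + Z95 * se),
            units="km2",
        )
    return out


def estimates_to_frame(estimates: dict[str, CategoryEstimate]) -> pd.DataFrame:
    """Tabulate estimates in the standard (category, estimate, lcb95, ucb95)
    column layout."""
    rows = [
        {
            "category": e.category,
            "estimate": e.estimate,
            "std_error": e.std_error,
            "lcb95": e.lcb95,
            "ucb95": e.ucb95,
            "units": e.units,
        }
        for e in estimates.values()
    ]
    return pd.DataFrame(rows)
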