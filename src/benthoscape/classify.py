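"""Seabed substrate classification from acoustic layers.

Two classifiers produce hard/mixed/soft rasters:

* :func:`rule_classify` encodes the decision rules an interpreter applies
  when hand-digitising multibeam layers — soft for flat (< 1° slope) seabed
  with uniform −25..−30 dB backscatter, hard for raised (~1–5 m) features
  with high (> −25 dB) backscatter over a minimum area, mixed otherwise.

* the angular-response-curve (ARC) path: a reference curve is averaged from
  known-hard training cells; every cell's curve is compared to the reference
  with a Kolmogorov–Smirnov goodness of fit, giving a probability of hard
  seabed (p-hard); sparse p-hard observations are interpolated with inverse
  distance weighting; thresholds at 10%/90% split the continuous p-hard
  layer into soft/mixed/hard.

For the KS comparison a curve is turned into a distribution over incidence
angle by shifting intensities so the joint minimum is zero and normalizing
to unit mass; the KS statistic is the maximum gap between the two cumulative
curves and p-hard is its asymptotic KS p-value (identical curves give
p-hard = 1; p-hard decreases monotonically with the gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import kolmogorov

__all__ = [
    "ARCurve",
    "ReferenceARC",
    "PHardGrid",
    "RuleThresholds",
    "build_reference_arc",
    "ks_phard",
    "idw_interpolate",
    "classify_phard",
    "rule_classify",
    "site_class_proportions",
    "map_image_labels",
    "HARD_IMAGE_LABELS",
    "SOFT_IMAGE_LABELS",
]


@dataclass
class ARCurve:
    """Backscatter intensity (dB) over an ascending incidence-angle grid."""

    angles: np.ndarray
    intensities: np.ndarray
    cell_id: object = None

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.angles) != len(self.intensities):
            raise ValueError("angles and intensities must have equal length")
        if len(self.angles) < 5:
            raise ValueError("need at least 5 angle bins")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


@dataclass
class ReferenceARC:
    """Mean curve over known-hard training cells, used as the hard template."""

    curve: ARCurve
    n_training: int
    source_class: str = "hard"


@dataclass
class PHardGrid:
    """Continuous probability-of-hard layer with per-cell provenance."""

    values: np.ndarray  # (ny, nx) in [0, 1]
    provenance: np.ndarray  # (ny, nx) of {"observed", "interpolated"}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("p-hard values must lie in [0, 1]")
        self.values = v


@dataclass
class RuleThresholds:
    """Thresholds of the manual-mapping decision rules.

    Defaults describe 2 m-resolution multibeam interpretation: soft = flat
    (< 1° slope) seabed inside the −30..−25 dB band; hard = features raised
    1–5 m above the local median depth with flank gradients of 5–15° and
    backscatter above −25 dB over at least 100 m².
    """

    soft_slope_max: float = 1.0  # degrees
    soft_bs_band: tuple[float, float] = (-30.0, -25.0)  # dB
    hard_relief: tuple[float, float] = (1.0, 5.0)  # metres above local median
    hard_gradient: tuple[float, float] = (5.0, 15.0)  # degrees, within component
    hard_bs_min: float = -25.0  # dB
    hard_min_area: float = 100.0  # m²
    mixed_relief_max: float = 2.0  # metres (documentation of the mixed band)
    relief_window: int = 25  # cells; local-median window for the relief datum

    def __post_init__(self) -> None:
        if self.soft_slope_max <= 0:
            raise ValueError("soft_slope_max must be positive")
        if self.hard_min_area <= 0:
            raise ValueError("hard_min_area must be positive")


def build_reference_arc(training: list[ARCurve]) -> ReferenceARC:
    """Average ≥ 2 training curves (common angle grid) into the hard reference."""
    if len(training) < 2:
        raise ValueError("need at least 2 training curves")
    angles = training[0].angles
    for c in training[1:]:
        if len(c.angles) != len(angles) or not np.allclose(c.angles, angles):
            raise ValueError("training curves must share one angle grid")
    mean = np.mean([c.intensities for c in training], axis=0)
    return ReferenceARC(curve=ARCurve(angles=angles, intensities=mean), n_training=len(training))


def _to_distribution(intensities: np.ndarray, shift: float) -> np.ndarray:
    a = intensities - shift
    total = a.sum()
    if total <= 0:
        raise ValueError("flat curve at the joint minimum: p-hard is undefined")
    return np.cumsum(a) / total


def ks_phard(curve: ARCurve, reference: ReferenceARC) -> float:
    """Probability of hard seabed from a KS goodness of fit to the reference.

    Both curves are shifted by their joint minimum and normalized to unit
    mass over angle; D = max |F_curve − F_ref| and p-hard is the asymptotic
    two-sample KS p-value with effective size n/2 for n shared angle bins.
    """
    ref = reference.curve
    if len(curve.angles) != len(ref.angles) or not np.allclose(curve.angles, ref.angles):
        raise ValueError("curve and reference must share one angle grid")
    shift = min(curve.intensities.min(), ref.intensities.min())
    f = _to_distribution(curve.intensities, shift)
    g = _to_distribution(ref.intensities, shift)
    d = float(np.abs(f - g).max())
    n_eff = len(curve.angles) / 2.0
    return float(kolmogorov(np.sqrt(n_eff) * d))


def idw_interpolate(
    observed: np.ndarray,
    target_x: np.ndarray,
    target_y: np.ndarray,
    power: float = 2.0,
) -> PHardGrid:
    """Inverse-distance-weighted interpolation of point p-hard values.

    ``observed`` is (n, 3) rows of (x, y, p_hard); ``target_x``/``target_y``
    are 2-D coordinate grids.  Exact at observed locations; elsewhere a
    d^(−power) weighted mean of all observations, so the output is bounded by
    the observed min/max.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3 or len(obs) == 0:
        raise ValueError("observed must be a non-empty (n, 3) array of (x, y, value)")
    tx = np.asarray(target_x, dtype=float)
    ty = np.asarray(target_y, dtype=float)
    d2 = (tx[..., None] - obs[:, 0]) ** 2 + (ty[..., None] - obs[:, 1]) ** 2
    dist = np.sqrt(d2)
    exact = dist < 1e-9
    with np.errstate(divide="ignore"):
        w = np.where(exact, 0.0, dist ** (-power))
    vals = (w * obs[:, 2]).sum(axis=-1) / np.where(w.sum(axis=-1) > 0, w.sum(axis=-1), 1.0)
    has_exact = exact.any(axis=-1)
    first_exact = exact.argmax(axis=-1)
    vals = np.where(has_exact, obs[first_exact, 2], vals)
    prov = np.where(has_exact, "observed", "interpolated").astype("<U12")
    return PHardGrid(values=vals, provenance=prov)


def classify_phard(grid: PHardGrid | np.ndarray, lo: float = 0.10, hi: float = 0.90) -> np.ndarray:
    """Threshold a p-hard layer: > hi → hard, [lo, hi] → mixed, < lo → soft."""
    if lo >= hi:
        raise ValueError("lo threshold must be below hi")
    v = grid.values if isinstance(grid, PHardGrid) else np.asarray(grid, dtype=float)
    out = np.full(v.shape, "mixed", dtype="<U5")
    out[v > hi] = "hard"
    out[v < lo] = "soft"
    return out


def rule_classify(
    depth_grid: np.ndarray,
    slope_grid: np.ndarray,
    backscatter_grid: np.ndarray,
    thresholds: RuleThresholds | None = None,
    cell_size: float = 2.0,
) -> np.ndarray:
    """Hard/mixed/soft raster from the manual-mapping decision rules.

    Hard candidates are cells raised within ``hard_relief`` above the local
    median depth with backscatter above ``hard_bs_min``; candidates are
    grouped into 8-connected components and kept hard only if the component
    covers at least ``hard_min_area`` m² and exhibits a flank gradient inside
    ``hard_gradient`` somewhere in the component — smaller or gradient-less
    components are demoted to mixed.  Soft requires slope below
    ``soft_slope_max`` and backscatter inside ``soft_bs_band``; everything
    else is mixed.  Total and deterministic.
    """
    t = thresholds or RuleThresholds()
    depth = np.asarray(depth_grid, dtype=float)
    slope = np.asarray(slope_grid, dtype=float)
    bs = np.asarray(backscatter_grid, dtype=float)
    if not (depth.shape == slope.shape == bs.shape):
        raise ValueError("depth, slope and backscatter grids must share one shape")

    local_median = ndimage.median_filter(depth, size=t.relief_window, mode="nearest")
    relief = local_median - depth  # positive where the seabed is raised

    cand = (
        (relief >= t.hard_relief[0])
        & (relief <= t.hard_relief[1])
        & (bs > t.hard_bs_min)
    )
    labels, n_comp = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    hard = np.zeros_like(cand)
    if n_comp:
        cell_area = cell_size**2
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_comp + 1))
        grad_ok = ndimage.labeled_comprehension(
            slope,
            labels,
            np.arange(1, n_comp + 1),
            lambda s: np.any((s >= t.hard_gradient[0]) & (s <= t.hard_gradient[1])),
            bool,
            False,
        )
        keep = (sizes * cell_area >= t.hard_min_area) & grad_ok
        keep_ids = np.flatnonzero(keep) + 1
        hard = np.isin(labels, keep_ids)

    soft = (
        ~hard
        & ~cand  # demoted candidates stay mixed, never soft
        & (slope < t.soft_slope_max)
        & (bs >= t.soft_bs_band[0])
        & (bs <= t.soft_bs_band[1])
    )
    out = np.full(depth.shape, "mixed", dtype="<U5")
    out[soft] = "soft"
    out[hard] = "hard"
    return out


def site_class_proportions(
    class_raster: np.ndarray,
    site_mask: np.ndarray,
    standard_area_km2: float = 0.04,
    classes: tuple[str, ...] = ("hard", "mixed", "soft"),
) -> dict:
    """Class proportions within a site, rescaled to the standard site area.

    Swath footprints differ between sites, so each site's observed class
    areas are rescaled to a common ``standard_area_km2`` using its class
    proportions; rescaled areas always sum to exactly the standard area.
    """
    mask = np.asarray(site_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty site mask")
    cells = np.asarray(class_raster)[mask]
    props = {c: float(np.mean(cells == c)) for c in classes}
    areas = {c: props[c] * standard_area_km2 for c in classes}
    return {"proportions": props, "areas_km2": areas, "standard_area_km2": standard_area_km2}


#: broadscale image labels counted as consolidated (hard) substrate
HARD_IMAGE_LABELS = frozenset({"rock", "boulders", "cobbles", "consolidated"})
#: broadscale image labels counted as unconsolidated (soft) substrate
SOFT_IMAGE_LABELS = frozenset({"sand", "mud", "pebbles", "unconsolidated"})


def map_image_labels(
    dominant: str,
    subdominant: str = "none",
    rules: dict[tuple[str, str], str] | None = None,
) -> str:
    """Collapse dominant/subdominant substrate labels to hard/mixed/soft.

    Default table: both labels consolidated → hard; dominant soft with a soft
    or absent subdominant → soft; any hard/soft combination → mixed.  An
    explicit ``rules`` mapping of (dominant, subdominant) pairs overrides the
    default and lets the table be matched to an external scheme.
    """
    if rules is not None and (dominant, subdominant) in rules:
        return rules[(dominant, subdominant)]
    vocab = HARD_IMAGE_LABELS | SOFT_IMAGE_LABELS | {"none"}
    for lab, role in ((dominant, "dominant"), (subdominant, "subdominant")):
        if lab not in vocab:
            raise ValueError(
                f"unknown {role} label {lab!r}; vocabulary: {sorted(vocab)}"
            )
    if dominant == "none":
        raise ValueError("dominant label cannot be 'none'")
    dom_hard = dominant in HARD_IMAGE_LABELS
    sub_hard = subdominant in HARD_IMAGE_LABELS
    sub_soft = subdominant in SOFT_IMAGE_LABELS or subdominant == "none"
    if dom_hard and (sub_hard or subdominant == "none"):
        return "hard"
    if not dom_hard and sub_soft:
        return "soft"
    return "mixed"
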