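"""Synthetic shelf seascapes with known substrate truth.

The generator emulates a temperate continental-shelf seascape of the kind the
survey methods in this package are designed for: a 40–160 m across-shelf
depth gradient, low-profile (1–3 m) reef patches with a "mixed" sand-veneer
halo grading into surrounding soft sediment, class-dependent acoustic
backscatter (soft ≈ −25 to −30 dB, hard > −25 dB), per-cell angular response
curves, and zero-inflated sessile-biota cover concentrated on mixed/hard
substrate with macroalgae restricted to shallow (< 50 m) water.

Reef geometry comes from thresholding a smoothed Gaussian random field:
cells above the (1 − reef_fraction) quantile are hard cores, the band below
down to (1 − reef_fraction − mixed_fraction) forms the mixed halo.  Because
the thresholds are quantiles of the realized field, the configured class
fractions are recovered exactly up to grid discreteness.

All randomness flows from one root seed through named substreams, so a fixed
config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SeascapeConfig",
    "SeascapeTruth",
    "generate_seascape",
    "simulate_arc_field",
    "simulate_biota",
    "arc_curve",
    "CLASSES",
]

CLASSES = ("hard", "mixed", "soft")


def _default_backscatter_params() -> dict:
    # dB mean/sd per class; soft inside the −30..−25 band, hard above −25
    return {
        "hard": {"mean": -22.0, "sd": 1.2},
        "mixed": {"mean": -25.0, "sd": 1.0},
        "soft": {"mean": -27.5, "sd": 0.8},
    }


def _default_arc_params() -> dict:
    # dB-vs-angle decay: intensity(θ) = offset + amp·exp(−θ/scale)
    # hard curves sit higher and decay slower than soft at every angle
    return {
        "hard": {"offset": -20.0, "amp": 10.0, "scale": 45.0},
        "mixed": {"offset": -24.0, "amp": 10.0, "scale": 40.0},
        "soft": {"offset": -31.0, "amp": 8.0, "scale": 10.0},
        "noise_sd": 0.4,
        "angle_min": 1.0,
        "angle_max": 60.0,
        "angle_step": 1.0,
    }


def _default_biota_params() -> dict:
    # per-group Bernoulli occupancy and mean Beta cover, by substrate class;
    # reef-associated groups concentrate on mixed/hard, echoing the strongly
    # zero-inflated cover seen in towed-camera imagery
    def g(occ_soft, occ_mixed, occ_hard, mean_cover):
        return {
            "occupancy": {"soft": occ_soft, "mixed": occ_mixed, "hard": occ_hard},
            "mean_cover": mean_cover,
        }

    return {
        "bryozoa": g(0.10, 0.55, 0.60, 0.20),
        "sponges": g(0.05, 0.45, 0.55, 0.12),
        "cnidaria": g(0.02, 0.25, 0.30, 0.05),
        "macroalgae": g(0.02, 0.50, 0.50, 0.25),
        "ascidians": g(0.01, 0.15, 0.20, 0.04),
        "echinoderms": g(0.02, 0.10, 0.10, 0.02),
        "molluscs": g(0.03, 0.12, 0.12, 0.03),
    }


@dataclass
class SeascapeConfig:
    """Parameters of the synthetic seascape.

    Lengths are metres, depths metres below sea level, acoustics in dB.
    ``reef_fraction``/``mixed_fraction`` are target areal fractions of hard
    and mixed substrate; the remainder is soft sediment.
    """

    grid_nx: int = 280
    grid_ny: int = 280
    cell_size: float = 50.0
    depth_range: tuple[float, float] = (40.0, 160.0)
    reef_fraction: float = 0.05
    mixed_fraction: float = 0.20
    reef_relief: tuple[float, float] = (1.0, 3.0)
    patch_scale_cells: float = 8.0  # Gaussian smoothing length of the reef field
    depth_noise_sd: float = 1.5  # smooth bathymetric roughness amplitude (m)
    backscatter_params: dict = field(default_factory=_default_backscatter_params)
    arc_params: dict = field(default_factory=_default_arc_params)
    biota_params: dict = field(default_factory=_default_biota_params)
    macroalgae_depth_limit: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx <= 0 or self.grid_ny <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (0 <= self.reef_fraction <= 1 and 0 <= self.mixed_fraction <= 1):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.reef_fraction + self.mixed_fraction > 1:
            raise ValueError("reef_fraction + mixed_fraction must be <= 1")
        if self.depth_range[0] >= self.depth_range[1]:
            raise ValueError("depth_range must be (min, max) with min < max")

    def substream(self, name: str) -> np.random.Generator:
        """Named reproducible substream of the root seed."""
        idx = {"depth": 0, "reef": 1, "backscatter": 2, "arc": 3, "biota": 4}[name]
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(5)[idx])


@dataclass
class SeascapeTruth:
    """Co-registered truth layers of a synthetic seascape (row 0 = y of 0)."""

    config: SeascapeConfig
    depth_grid: np.ndarray  # (ny, nx) metres
    backscatter_grid: np.ndarray  # (ny, nx) dB
    slope_grid: np.ndarray  # (ny, nx) degrees
    true_class_grid: np.ndarray  # (ny, nx) of {"hard","mixed","soft"}
    arc_angles: np.ndarray | None = None  # (na,) degrees
    arc_field: np.ndarray | None = None  # (ny, nx, na) dB
    biota_cover: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth_grid.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.config.cell_size / 1000.0) ** 2

    def class_fractions(self) -> dict[str, float]:
        flat = self.true_class_grid.ravel()
        return {c: float(np.mean(flat == c)) for c in CLASSES}

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x, y coordinates (m) of cell centres, matching grid indexing."""
        cs = self.config.cell_size
        xs = (np.arange(self.config.grid_nx) + 0.5) * cs
        ys = (np.arange(self.config.grid_ny) + 0.5) * cs
        return np.meshgrid(xs, ys)


def _slope_degrees(depth: np.ndarray, cell_size: float) -> np.ndarray:
    """Slope from central differences (one-sided at boundaries), in degrees."""
    dzdy, dzdx = np.gradient(depth, cell_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def arc_curve(angles: np.ndarray, offset: float, amp: float, scale: float) -> np.ndarray:
    """Noise-free class-template angular response curve (dB vs angle)."""
    return offset + amp * np.exp(-np.asarray(angles, float) / scale)


def generate_seascape(
    config: SeascapeConfig,
    with_arc: bool = True,
    with_biota: bool = True,
) -> SeascapeTruth:
    """Generate a full synthetic seascape with known truth.

    Deterministic for a fixed config (seed included); the heavy optional
    layers (per-cell ARC samples, biota cover) can be switched off for speed.
    """
    ny, nx = config.grid_ny, config.grid_nx
    dmin, dmax = config.depth_range

    # bathymetry: across-shelf gradient (deepening with x) + smooth roughness
    rng_depth = config.substream("depth")
    xfrac = np.tile(np.linspace(0.0, 1.0, nx), (ny, 1))
    depth = dmin + (dmax - dmin) * xfrac
    rough = ndimage.gaussian_filter(rng_depth.standard_normal((ny, nx)), 4.0)
    rough *= config.depth_noise_sd / max(rough.std(), 1e-12)
    depth = depth + rough

    # reef field: smoothed white noise, quantile-thresholded into hard cores
    # with a mixed halo band directly below the hard threshold
    rng_reef = config.substream("reef")
    f = ndimage.gaussian_filter(
        rng_reef.standard_normal((ny, nx)), config.patch_scale_cells
    )
    cls = np.full((ny, nx), "soft", dtype="<U5")
    if config.reef_fraction + config.mixed_fraction > 0:
        q_mixed = np.quantile(f, 1.0 - config.reef_fraction - config.mixed_fraction)
        cls[f >= q_mixed] = "mixed"
    if config.reef_fraction > 0:
        q_hard = np.quantile(f, 1.0 - config.reef_fraction)
        hard = f >= q_hard
        cls[hard] = "hard"
        # raise hard cores across the configured relief range (rank-uniform,
        # so the whole 1–3 m band is realized) with a low sand-veneer halo
        rmin, rmax = config.reef_relief
        relief = np.zeros((ny, nx))
        fh = f[hard]
        ranks = np.argsort(np.argsort(fh)) / max(len(fh) - 1, 1)
        relief[hard] = rmin + (rmax - rmin) * ranks
        if config.mixed_fraction > 0:
            mixed = cls == "mixed"
            hdenom = max(q_hard - q_mixed, 1e-12)
            relief[mixed] = 0.4 * rmin * (f[mixed] - q_mixed) / hdenom
        depth = depth - ndimage.gaussian_filter(relief, 0.8)

    slope = _slope_degrees(depth, config.cell_size)

    # backscatter: class-dependent normal draws (uniform spatial structure)
    rng_bs = config.substream("backscatter")
    bs = np.zeros((ny, nx))
    for c in CLASSES:
        p = config.backscatter_params[c]
        sel = cls == c
        bs[sel] = rng_bs.normal(p["mean"], p["sd"], int(sel.sum()))

    truth = SeascapeTruth(
        config=config,
        depth_grid=depth,
        backscatter_grid=bs,
        slope_grid=slope,
        true_class_grid=cls,
    )
    if with_arc:
        truth.arc_angles, truth.arc_field = simulate_arc_field(truth, config)
    if with_biota:
        truth.biota_cover = simulate_biota(truth, config)
    return truth


def simulate_arc_field(
    truth: SeascapeTruth, config: SeascapeConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell angular response curves: class template + seeded white noise.

    Returns (angles, field) with field shape (ny, nx, n_angles), float32.
    """
    config = config or truth.config
    p = config.arc_params
    angles = np.arange(p["angle_min"], p["angle_max"] + 0.5 * p["angle_step"], p["angle_step"])
    if len(angles) == 0:
        raise ValueError("empty incidence-angle grid")
    ny, nx = truth.shape
    rng = config.substream("arc")
    field_ = np.empty((ny, nx, len(angles)), dtype=np.float32)
    for c in CLASSES:
        tmpl = arc_curve(angles, p[c]["offset"], p[c]["amp"], p[c]["scale"])
        field_[truth.true_class_grid == c] = tmpl.astype(np.float32)
    if p["noise_sd"] > 0:
        field_ += rng.normal(0.0, p["noise_sd"], field_.shape).astype(np.float32)
    return angles, field_


def simulate_biota(
    truth: SeascapeTruth,
    config: SeascapeConfig | None = None,
    beta_concentration: float = 5.0,
) -> dict[str, np.ndarray]:
    """Zero-inflated per-cell cover per biological group.

    Cover = Bernoulli(occupancy by substrate class) × Beta(mean cover), so
    the realized group/class mean cover is occupancy × mean_cover.
    Macroalgae are forced to zero below the configured depth limit,
    reflecting the photic constraint on the shelf.
    """
    config = config or truth.config
    rng = config.substream("biota")
    ny, nx = truth.shape
    out: dict[str, np.ndarray] = {}
    for group, gp in config.biota_params.items():
        unknown = set(gp["occupancy"]) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown substrate class in biota params: {sorted(unknown)}")
        occ = np.zeros((ny, nx))
        for c in CLASSES:
            occ[truth.true_class_grid == c] = gp["occupancy"].get(c, 0.0)
        present = rng.random((ny, nx)) < occ
        mean = gp["mean_cover"]
        if mean <= 0:
            cover = np.zeros((ny, nx))
        else:
            a = mean * beta_concentration
            b = (1.0 - mean) * beta_concentration
            cover = np.where(present, rng.beta(a, b, (ny, nx)), 0.0)
        if group == "macroalgae":
            cover[truth.depth_grid > config.macroalgae_depth_limit] = 0.0
        out[group] = cover
    return out
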