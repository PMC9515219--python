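"""Synthetic parcellated data with planted, recoverable structure.

Every generator here emulates the statistical assumptions of one
downstream stage so the whole pipeline can be verified without any
imaging data:

* quasi-uniform spherical parcellations with mirror-symmetric hemispheres,
* spatially autocorrelated scalar maps (squared-exponential kernel of
  great-circle distance) — the autocorrelation the spin test must respect,
* effect matrices with a planted rank-1 shared component across
  conditions plus condition-specific smooth noise,
* unimodal depth profiles with controllable peak depth and amplitude,
* connectivity matrices with a planted one-dimensional axis,
* feature panels in which a known subset of columns carries the target.

All generators are pure functions of (config, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import (
    ConnectivityMatrix,
    EffectMatrix,
    FeaturePanel,
    ParcellationMeta,
    ParcelMap,
    ProfileSet,
)

__all__ = [
    "SimulationConfig",
    "make_parcellation",
    "simulate_smooth_map",
    "simulate_effect_matrix",
    "simulate_profiles",
    "simulate_connectivity",
    "simulate_feature_panel",
    "COMMUNITY_NAMES",
    "HIERARCHY_NAMES",
    "DEFAULT_FEATURE_NAMES",
]

# 7 functional communities and 4 hierarchy levels of the reference atlases
COMMUNITY_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
)
HIERARCHY_NAMES = ("idiotypic", "unimodal", "heteromodal", "paralimbic")

DEFAULT_CONDITIONS = ("ASD", "ADHD", "MDD", "OCD", "BD", "SCZ")

# 17-column multiscale panel: 2 gradients, 5 laminar-profile features,
# 10 transmitter maps
DEFAULT_FEATURE_NAMES = (
    "mpc_gradient1",
    "fc_gradient1",
    "profile_mean",
    "profile_sd",
    "profile_skewness",
    "profile_kurtosis",
    "externopyramidization",
    "FDOPA",
    "GABAa",
    "DAT",
    "NAT",
    "SERT",
    "D1",
    "D2",
    "5HT1a",
    "5HT1b",
    "5HT2a",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the reference design: 68 regions (34 per hemisphere),
    six conditions whose loadings on the shared component taper from 1.0
    to 0.6, and condition noise sized so the shared component carries
    about half of the total variance (sum of squared loadings 4.64
    ~= 6 * 0.88^2).
    """

    n_regions_per_hemisphere: int = 34
    seed: int = 0
    lengthscale: float = 0.6  # angular correlation scale, radians
    shared_loadings: tuple[float, ...] = (1.0, 1.0, 1.0, 0.8, 0.8, 0.6)
    condition_names: tuple[str, ...] = DEFAULT_CONDITIONS
    noise_sd: float = 0.88
    profile_depths: int = 14
    n_features: int = 17
    feature_names: tuple[str, ...] = DEFAULT_FEATURE_NAMES
    informative_features: tuple[int, ...] = (0, 4, 6)
    effect_beta: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_regions_per_hemisphere < 1:
            raise ValueError("need at least one region per hemisphere")
        if self.lengthscale <= 0:
            raise ValueError("lengthscale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.shared_loadings) != len(self.condition_names):
            raise ValueError("one loading per condition required")
        if not any(l != 0 for l in self.shared_loadings):
            raise ValueError("loadings must not all be zero")
        if len(self.effect_beta) != len(self.informative_features):
            raise ValueError("one beta per informative feature required")
        if any(j < 0 or j >= self.n_features for j in self.informative_features):
            raise ValueError("informative feature index out of range")


def _hemisphere_spiral(n: int) -> np.ndarray:
    """Quasi-uniform points on the x>0 hemisphere (golden-angle spiral)."""
    i = np.arange(n)
    x = (i + 0.5) / n  # in (0, 1): distance from the mid-sagittal plane
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - x**2)
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def _anchor_directions(k: int) -> np.ndarray:
    """k fixed anchor directions on the x>0 hemisphere for label assignment."""
    i = np.arange(k)
    x = (i + 0.5) / k
    phi = 2.399963229728653 * i + 0.7  # offset decouples anchors from centroids
    r = np.sqrt(1.0 - x**2)
    return np.column_stack([x, r * np.cos(phi), r * np.sin(phi)])


def make_parcellation(cfg: SimulationConfig) -> ParcellationMeta:
    """Deterministic two-hemisphere parcellation on the unit sphere.

    Right-hemisphere centroids follow a golden-angle spiral on the x>0
    half-sphere; the left hemisphere is its mirror image through the
    sagittal (x=0) plane.  Communities (7) and hierarchy levels (4) are
    assigned by the nearest fixed anchor direction, computed on mirrored
    coordinates so homotopic regions share labels.
    """
    n = cfg.n_regions_per_hemisphere
    right = _hemisphere_spiral(n)
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    hemis = ["L"] * n + ["R"] * n
    ids = [f"lh_region{i:03d}" for i in range(n)] + [
        f"rh_region{i:03d}" for i in range(n)
    ]
    folded = centroids.copy()
    folded[:, 0] = np.abs(folded[:, 0])  # mirror left onto right for labels
    comm_anchor = _anchor_directions(len(COMMUNITY_NAMES))
    hier_anchor = _anchor_directions(len(HIERARCHY_NAMES))
    comm = [COMMUNITY_NAMES[j] for j in np.argmax(folded @ comm_anchor.T, axis=1)]
    hier = [HIERARCHY_NAMES[j] for j in np.argmax(folded @ hier_anchor.T, axis=1)]
    return ParcellationMeta(ids, hemis, centroids, comm, hier)


_CHOL_CACHE: dict[tuple[str, float], np.ndarray] = {}


def _kernel_cholesky(meta: ParcellationMeta, lengthscale: float) -> np.ndarray:
    key = (meta.cache_key(), float(lengthscale))
    if key not in _CHOL_CACHE:
        gram = np.clip(meta.centroid @ meta.centroid.T, -1.0, 1.0)
        theta = np.arccos(gram)  # great-circle distance
        cov = np.exp(-(theta**2) / (2.0 * lengthscale**2))
        cov[np.diag_indices_from(cov)] += 1e-8
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(
                "spatial covariance not positive definite after jitter"
            ) from exc
        if len(_CHOL_CACHE) > 32:
            _CHOL_CACHE.clear()
        _CHOL_CACHE[key] = chol
    return _CHOL_CACHE[key]


def simulate_smooth_map(
    meta: ParcellationMeta,
    lengthscale: float,
    seed: int,
    name: str = "smooth_map",
) -> ParcelMap:
    """Zero-mean unit-variance draw with great-circle-distance autocorrelation.

    The covariance is a squared-exponential kernel of angular distance
    (with 1e-8 diagonal jitter); the sample is standardized so every draw
    has mean 0 and SD 1 across regions.
    """
    if lengthscale <= 0:
        raise ValueError("lengthscale must be positive")
    chol = _kernel_cholesky(meta, lengthscale)
    rng = np.random.default_rng(seed)
    x = chol @ rng.standard_normal(meta.n_regions)
    sd = x.std()
    if sd == 0:  # single-region degenerate draw
        return ParcelMap(np.zeros_like(x), meta, name=name)
    return ParcelMap((x - x.mean()) / sd, meta, name=name)


def simulate_effect_matrix(
    meta: ParcellationMeta,
    shared_map: ParcelMap,
    cfg: SimulationConfig,
) -> EffectMatrix:
    """Condition-wise effect maps: loading_c * shared + noise_sd * smooth noise.

    ``shared_map`` is the planted rank-1 component; keep a reference to it
    for recovery tests.
    """
    if shared_map.meta.region_id != meta.region_id:
        raise ValueError("shared_map is not aligned to meta")
    shared = shared_map.require_complete("simulate_effect_matrix")
    rng = np.random.default_rng(cfg.seed)
    cols = []
    for loading in cfg.shared_loadings:
        noise_seed = int(rng.integers(0, 2**31 - 1))
        noise = simulate_smooth_map(meta, cfg.lengthscale, noise_seed).values
        cols.append(loading * shared + cfg.noise_sd * noise)
    return EffectMatrix(np.column_stack(cols), cfg.condition_names, meta)


def simulate_profiles(
    meta: ParcellationMeta,
    peak_depth_map: ParcelMap,
    amplitude_map: ParcelMap,
    n_depths: int,
    seed: int,
    noise_sd: float = 0.02,
    baseline: float = 1.0,
    bump_width: float = 0.15,
) -> ProfileSet:
    """Unimodal depth profiles: baseline + amplitude * Gaussian bump + noise.

    The bump center is each region's planted peak depth (0 pial, 1 white);
    the width is fixed at 0.15 depth fractions so peak location is the one
    free shape parameter.
    """
    if n_depths < 4:
        raise ValueError("need at least 4 depths")
    peaks = peak_depth_map.require_complete("simulate_profiles")
    amps = amplitude_map.require_complete("simulate_profiles")
    if np.any((peaks < 0) | (peaks > 1)):
        raise ValueError("peak depths must lie in [0, 1]")
    if np.any(amps < 0):
        raise ValueError("amplitudes must be nonnegative")
    depths = np.linspace(0.0, 1.0, n_depths)
    bump = np.exp(-((depths[None, :] - peaks[:, None]) ** 2) / (2.0 * bump_width**2))
    rng = np.random.default_rng(seed)
    intensities = (
        baseline
        + amps[:, None] * bump
        + noise_sd * rng.standard_normal((meta.n_regions, n_depths))
    )
    return ProfileSet(intensities, depths, meta, source=f"synthetic-{n_depths}depth")


def simulate_connectivity(
    meta: ParcellationMeta,
    axis_map: ParcelMap,
    noise: float = 0.0,
    seed: int = 0,
    kernel_scale: float | None = None,
) -> ConnectivityMatrix:
    """Connectivity with a planted 1-D axis: A_ij = exp(-(axis_i-axis_j)^2 / 2s^2).

    Symmetric with unit diagonal; optional symmetric Gaussian noise.  The
    kernel scale defaults to half the axis SD so the axis ordering is
    sharply expressed.
    """
    axis = axis_map.require_complete("simulate_connectivity")
    if kernel_scale is None:
        sd = axis.std()
        kernel_scale = 0.5 * sd if sd > 0 else 1.0
    diff = axis[:, None] - axis[None, :]
    values = np.exp(-(diff**2) / (2.0 * kernel_scale**2))
    if noise > 0:
        rng = np.random.default_rng(seed)
        e = rng.standard_normal(values.shape)
        values = values + noise * 0.5 * (e + e.T)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values, meta, kind="synthetic")


def simulate_feature_panel(
    meta: ParcellationMeta,
    target: ParcelMap,
    cfg: SimulationConfig,
    feature_noise_sd: float = 1.0,
) -> FeaturePanel:
    """Multiscale panel with a known informative subset.

    Informative columns are ``beta * target + noise``; the remaining
    columns are independent smooth maps.  The ground-truth support is
    ``cfg.informative_features``.
    """
    if cfg.n_features < 1:
        raise ValueError("feature set must be non-empty")
    y = target.require_complete("simulate_feature_panel")
    rng = np.random.default_rng(cfg.seed + 1)
    betas = dict(zip(cfg.informative_features, cfg.effect_beta))
    cols = []
    for j in range(cfg.n_features):
        noise_seed = int(rng.integers(0, 2**31 - 1))
        noise = simulate_smooth_map(meta, cfg.lengthscale, noise_seed).values
        if j in betas:
            cols.append(betas[j] * y + feature_noise_sd * noise)
        else:
            cols.append(noise)
    names = (
        cfg.feature_names
        if len(cfg.feature_names) == cfg.n_features
        else tuple(f"feature{j:02d}" for j in range(cfg.n_features))
    )
    prov = tuple(
        "informative" if j in betas else "noise" for j in range(cfg.n_features)
    )
    return FeaturePanel(np.column_stack(cols), names, meta, provenance=prov)
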