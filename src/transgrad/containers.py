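"""Typed containers for parcellated cortical data.

Everything downstream operates on scalar maps, matrices and profile stacks
keyed to a cortical parcellation (e.g. Desikan-Killiany, 68 regions).  The
containers here pin region order and alignment so that every stage can
assume its inputs refer to the same regions in the same order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParcellationMeta",
    "ParcelMap",
    "EffectMatrix",
    "ProfileSet",
    "ConnectivityMatrix",
    "FeaturePanel",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Raised when objects keyed to different region sets are combined."""


def _as_str_tuple(x: Sequence[str]) -> tuple[str, ...]:
    return tuple(str(v) for v in x)


@dataclass(frozen=True)
class ParcellationMeta:
    """Region identities, hemispheres, spherical centroids and labels.

    Parameters
    ----------
    region_id : sequence of str
        Unique region names, conventionally ``lh_<name>`` / ``rh_<name>``.
    hemisphere : sequence of {'L', 'R'}
        Hemisphere of each region.
    centroid : (n, 3) array
        Unit vectors on a common sphere (used by the spin test).
    community : sequence of str
        Functional-community label per region (7 levels in the reference
        atlas).
    hierarchy : sequence of str
        Cortical-hierarchy label per region (4 levels).
    """

    region_id: tuple[str, ...]
    hemisphere: tuple[str, ...]
    centroid: np.ndarray
    community: tuple[str, ...]
    hierarchy: tuple[str, ...]

    def __init__(self, region_id, hemisphere, centroid, community, hierarchy):
        object.__setattr__(self, "region_id", _as_str_tuple(region_id))
        object.__setattr__(self, "hemisphere", _as_str_tuple(hemisphere))
        cent = np.asarray(centroid, dtype=float)
        cent.setflags(write=False)
        object.__setattr__(self, "centroid", cent)
        object.__setattr__(self, "community", _as_str_tuple(community))
        object.__setattr__(self, "hierarchy", _as_str_tuple(hierarchy))
        self._validate()

    def _validate(self) -> None:
        n = len(self.region_id)
        if n == 0:
            raise ValueError("parcellation must contain at least one region")
        if len(set(self.region_id)) != n:
            dupes = sorted({r for r in self.region_id if self.region_id.count(r) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere length does not match region count")
        bad = sorted({h for h in self.hemisphere if h not in ("L", "R")})
        if bad:
            raise ValueError(f"hemisphere labels must be 'L' or 'R', got {bad}")
        if self.centroid.shape != (n, 3):
            raise ValueError(f"centroid must be (n, 3), got {self.centroid.shape}")
        norms = np.linalg.norm(self.centroid, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("centroids must lie on the unit sphere (|v| = 1 +/- 1e-9)")
        if len(self.community) != n or len(self.hierarchy) != n:
            raise ValueError("label vectors must match region count")

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def index_of(self, region: str) -> int:
        try:
            return self.region_id.index(region)
        except ValueError:
            raise KeyError(f"unknown region: {region!r}") from None

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        return np.array([h == hemi for h in self.hemisphere])

    def subset(self, regions: Sequence[str]) -> "ParcellationMeta":
        """Restrict to ``regions``, preserving this meta's order."""
        keep = set(regions)
        unknown = keep - set(self.region_id)
        if unknown:
            raise KeyError(f"unknown regions: {sorted(unknown)}")
        idx = [i for i, r in enumerate(self.region_id) if r in keep]
        return ParcellationMeta(
            [self.region_id[i] for i in idx],
            [self.hemisphere[i] for i in idx],
            self.centroid[idx],
            [self.community[i] for i in idx],
            [self.hierarchy[i] for i in idx],
        )

    def cache_key(self) -> str:
        h = hashlib.sha1()
        h.update("|".join(self.region_id).encode())
        h.update(np.ascontiguousarray(self.centroid).tobytes())
        return h.hexdigest()

    def __eq__(self, other) -> bool:  # centroids compared by value
        if not isinstance(other, ParcellationMeta):
            return NotImplemented
        return (
            self.region_id == other.region_id
            and self.hemisphere == other.hemisphere
            and np.array_equal(self.centroid, other.centroid)
            and self.community == other.community
            and self.hierarchy == other.hierarchy
        )

    def __hash__(self) -> int:
        return hash((self.region_id, self.hemisphere))


def _check_meta(meta: ParcellationMeta, n: int, what: str) -> None:
    if meta.n_regions != n:
        raise AlignmentError(
            f"{what}: {n} rows but parcellation has {meta.n_regions} regions"
        )


@dataclass
class ParcelMap:
    """One scalar value per region, with explicit missingness.

    ``mask`` is True where the value is missing; non-finite values are
    masked automatically so missingness is never silent.
    """

    values: np.ndarray
    meta: ParcellationMeta
    name: str = "map"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        _check_meta(self.meta, self.values.shape[0], f"ParcelMap {self.name!r}")
        if self.values.ndim != 1:
            raise ValueError("ParcelMap values must be 1-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).copy()
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
            self.mask |= ~np.isfinite(self.values)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def complete(self) -> bool:
        return not self.mask.any()

    def available_regions(self) -> tuple[str, ...]:
        return tuple(r for r, m in zip(self.meta.region_id, self.mask) if not m)

    def require_complete(self, context: str = "") -> np.ndarray:
        if self.mask.any():
            missing = [r for r, m in zip(self.meta.region_id, self.mask) if m]
            hint = f" ({context})" if context else ""
            raise ValueError(
                f"map {self.name!r} has masked regions {missing}{hint}; "
                "restrict inputs with align_sources first"
            )
        return self.values

    def restrict(self, meta: ParcellationMeta) -> "ParcelMap":
        idx = [self.meta.index_of(r) for r in meta.region_id]
        return ParcelMap(self.values[idx], meta, name=self.name, mask=self.mask[idx])


@dataclass
class EffectMatrix:
    """Regions x conditions matrix of effect sizes (the PCA substrate)."""

    values: np.ndarray
    conditions: tuple[str, ...]
    meta: ParcellationMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.conditions = _as_str_tuple(self.conditions)
        if self.values.ndim != 2:
            raise ValueError("EffectMatrix values must be 2-D (regions x conditions)")
        _check_meta(self.meta, self.values.shape[0], "EffectMatrix")
        if self.values.shape[1] != len(self.conditions):
            raise ValueError("condition names must match column count")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition names must be unique")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def require_finite(self) -> np.ndarray:
        if not np.all(np.isfinite(self.values)):
            rows = np.where(~np.isfinite(self.values).all(axis=1))[0]
            missing = [self.meta.region_id[i] for i in rows]
            raise ValueError(
                f"effect matrix has non-finite entries in regions {missing}; "
                "restrict inputs with align_sources first"
            )
        return self.values

    def condition_map(self, condition: str) -> ParcelMap:
        j = self.conditions.index(condition)
        return ParcelMap(self.values[:, j], self.meta, name=condition)

    def drop_condition(self, condition: str) -> "EffectMatrix":
        j = self.conditions.index(condition)
        keep = [k for k in range(self.n_conditions) if k != j]
        return EffectMatrix(
            self.values[:, keep],
            [self.conditions[k] for k in keep],
            self.meta,
        )

    def restrict(self, meta: ParcellationMeta) -> "EffectMatrix":
        idx = [self.meta.index_of(r) for r in meta.region_id]
        return EffectMatrix(self.values[idx], self.conditions, meta)


@dataclass
class ProfileSet:
    """Regions x depths intracortical intensity profiles.

    Depth fractions run from 0 at the pial surface to 1 at the white-matter
    boundary and must be strictly increasing.
    """

    intensities: np.ndarray
    depth_fractions: np.ndarray
    meta: ParcellationMeta
    source: str = "profiles"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).copy()
        self.depth_fractions = np.asarray(self.depth_fractions, dtype=float).copy()
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (regions x depths)")
        _check_meta(self.meta, self.intensities.shape[0], "ProfileSet")
        d = self.depth_fractions
        if d.shape != (self.intensities.shape[1],):
            raise ValueError("depth_fractions length must match depth count")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depth_fractions must be strictly increasing")
        if d[0] < 0 or d[-1] > 1:
            raise ValueError("depth_fractions must lie in [0, 1]")

    @property
    def n_depths(self) -> int:
        return self.intensities.shape[1]

    def restrict(self, meta: ParcellationMeta) -> "ProfileSet":
        idx = [self.meta.index_of(r) for r in meta.region_id]
        return ProfileSet(self.intensities[idx], self.depth_fractions, meta, self.source)


@dataclass
class ConnectivityMatrix:
    """Square region x region similarity / connectivity matrix.

    ``kind`` records provenance: 'microstructural', 'functional', 'affinity'
    or a sparsified intermediate.  Builders symmetrize their outputs; the
    row-sparsification step deliberately produces an asymmetric matrix that
    the affinity kernel resolves, so symmetry is checked by consumers that
    need it rather than enforced here.
    """

    values: np.ndarray
    meta: ParcellationMeta
    kind: str = "connectivity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        _check_meta(self.meta, self.values.shape[0], "ConnectivityMatrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix must be finite")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.max(np.abs(self.values - self.values.T)) <= tol)

    def symmetrized(self) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            0.5 * (self.values + self.values.T), self.meta, kind=self.kind
        )


@dataclass
class FeaturePanel:
    """Regions x named features (gradients, moments, transmitters, ...)."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    meta: ParcellationMeta
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.feature_names = _as_str_tuple(self.feature_names)
        if self.values.ndim != 2:
            raise ValueError("FeaturePanel values must be 2-D (regions x features)")
        _check_meta(self.meta, self.values.shape[0], "FeaturePanel")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature names must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not self.provenance:
            self.provenance = tuple("other" for _ in self.feature_names)
        elif len(self.provenance) != len(self.feature_names):
            raise ValueError("provenance length must match feature count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_map(self, name: str) -> ParcelMap:
        j = self.feature_names.index(name)
        return ParcelMap(self.values[:, j], self.meta, name=name)

    def require_finite(self) -> np.ndarray:
        if not np.all(np.isfinite(self.values)):
            rows = np.where(~np.isfinite(self.values).all(axis=1))[0]
            missing = [self.meta.region_id[i] for i in rows]
            raise ValueError(
                f"feature panel has non-finite entries in regions {missing}; "
                "restrict inputs with align_sources first"
            )
        return self.values

    def restrict(self, meta: ParcellationMeta) -> "FeaturePanel":
        idx = [self.meta.index_of(r) for r in meta.region_id]
        return FeaturePanel(
            self.values[idx], self.feature_names, meta, provenance=self.provenance
        )
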