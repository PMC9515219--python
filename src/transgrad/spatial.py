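"""Spin-test spatial permutations, FDR correction and label stratification.

Correlations between cortical maps are inflated by spatial
autocorrelation, so significance is assessed against a null that
preserves it: each permutation applies a uniform random rotation to the
parcel centroids on the sphere (the mirrored rotation to the opposite
hemisphere, preserving homotopy) and reassigns each region the value of
the nearest rotated region within its hemisphere.  The rotated map keeps
its spatial smoothness while losing its alignment with the comparison
map.

Conventions pinned here: the first map passed (the target / disease map)
is the one permuted; p-values use the +1-corrected two-tailed counting
rule p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_rotations), which keeps
p > 0 at finite rotation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

from .containers import FeaturePanel, ParcellationMeta, ParcelMap

__all__ = [
    "SpinPermutations",
    "CorrelationTestResult",
    "generate_spins",
    "spin_correlation",
    "fdr_correct",
    "test_feature_panel",
    "rescale_0_100",
    "stratify_map",
]

_MIRROR = np.diag([-1.0, 1.0, 1.0])  # reflection through the sagittal plane


@dataclass
class SpinPermutations:
    """Precomputed spin assignments.

    ``assignments[k, t]`` is the source region whose value target region
    ``t`` receives under rotation ``k``.  Assignments never cross
    hemispheres; duplicates are permitted (several targets may draw from
    the same source), as in centroid-based spin schemes.
    """

    assignments: np.ndarray
    meta: ParcellationMeta
    seed: int

    @property
    def n_rotations(self) -> int:
        return self.assignments.shape[0]

    def permute(self, values: np.ndarray) -> np.ndarray:
        """All permuted versions of ``values``: (n_rotations, n_regions)."""
        return values[self.assignments]


@dataclass
class CorrelationTestResult:
    """Observed correlation with its spin-permutation null."""

    r_observed: float
    p_spin: float
    null_distribution: np.ndarray
    q_fdr: float | None = None


def generate_spins(
    meta: ParcellationMeta,
    n_rotations: int = 1000,
    seed: int = 0,
) -> SpinPermutations:
    """Draw spin permutations for a parcellation.

    Per rotation a uniform random 3-D rotation is applied to one
    hemisphere's centroids and its sagittal mirror image to the other;
    each original centroid is then assigned the nearest rotated centroid
    of the same hemisphere.
    """
    for hemi in ("L", "R"):
        if int(meta.hemisphere_mask(hemi).sum()) < 2:
            raise ValueError(f"need at least 2 regions in hemisphere {hemi}")
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_rotations, rng).as_matrix()
    assignments = np.vstack(
        [_assignment_for_rotation(meta, rots[k]) for k in range(n_rotations)]
    )
    return SpinPermutations(assignments, meta, seed)


def _assignment_for_rotation(meta: ParcellationMeta, rotation: np.ndarray) -> np.ndarray:
    """Spin assignment for one rotation matrix (mirrored across hemispheres)."""
    assignment = np.empty(meta.n_regions, dtype=np.intp)
    for hemi, rot in (("L", rotation), ("R", _MIRROR @ rotation @ _MIRROR)):
        idx = np.where(meta.hemisphere_mask(hemi))[0]
        cent = meta.centroid[idx]
        rotated = cent @ rot.T
        # nearest rotated source for each original target (unit vectors:
        # nearest <=> largest dot product)
        nearest = np.argmax(cent @ rotated.T, axis=1)
        assignment[idx] = idx[nearest]
    return assignment


def spin_correlation(
    map_a: ParcelMap,
    map_b: ParcelMap,
    spins: SpinPermutations,
) -> CorrelationTestResult:
    """Pearson correlation of two maps with a spin-permutation p-value.

    ``map_a`` (the target map) is the one permuted.
    """
    if map_a.meta.region_id != spins.meta.region_id or map_b.meta.region_id != spins.meta.region_id:
        raise ValueError("maps must be aligned to the spin permutations' parcellation")
    a = map_a.require_complete("spin_correlation")
    b = map_b.require_complete("spin_correlation")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map; correlation undefined")
    perms = spins.permute(a)  # n_rotations x n
    bc = b - b.mean()
    bnorm = np.linalg.norm(bc)

    def _corr_rows(rows: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(rc, axis=1) * bnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, (rc @ bc) / denom, 0.0)

    # observed r computed through the identical code path as the null so the
    # counting rule is exact under an identity assignment
    r_obs = float(_corr_rows(a[None, :])[0])
    null = _corr_rows(perms)
    p = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (1.0 + spins.n_rotations)
    return CorrelationTestResult(r_obs, float(p), null)


def fdr_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_feature_panel(
    target: ParcelMap,
    panel: FeaturePanel,
    spins: SpinPermutations,
) -> pd.DataFrame:
    """Spin-test the target map against every panel column, FDR as one family.

    Returns a DataFrame (feature, r, p_spin, q_fdr) in panel order; the
    null distributions are stashed in ``df.attrs['null_distributions']``.
    """
    panel.require_finite()
    results = [
        spin_correlation(target, panel.feature_map(name), spins)
        for name in panel.feature_names
    ]
    q = fdr_correct([res.p_spin for res in results])
    for res, qv in zip(results, q):
        res.q_fdr = float(qv)
    df = pd.DataFrame(
        {
            "feature": list(panel.feature_names),
            "r": [res.r_observed for res in results],
            "p_spin": [res.p_spin for res in results],
            "q_fdr": [res.q_fdr for res in results],
        }
    )
    df.attrs["null_distributions"] = np.vstack(
        [res.null_distribution for res in results]
    )
    return df


def rescale_0_100(pmap: ParcelMap) -> ParcelMap:
    """Affine rescale of a map to [0, 100] (as applied to PET maps)."""
    v = pmap.require_complete("rescale_0_100")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant map")
    return ParcelMap(100.0 * (v - lo) / (hi - lo), pmap.meta, name=pmap.name)


def stratify_map(pmap: ParcelMap, label: str = "community") -> pd.DataFrame:
    """Per-class count, mean and SD of a map over community/hierarchy labels.

    Classes absent from the parcellation appear with count 0 and masked
    statistics.
    """
    if label == "community":
        labels = pmap.meta.community
    elif label == "hierarchy":
        labels = pmap.meta.hierarchy
    else:
        raise ValueError("label must be 'community' or 'hierarchy'")
    v = pmap.require_complete("stratify_map")
    classes = sorted(set(labels))
    rows = []
    for cls in classes:
        sel = np.array([l == cls for l in labels])
        vals = v[sel]
        rows.append(
            {
                "class": cls,
                "count": int(sel.sum()),
                "mean": float(vals.mean()) if sel.any() else np.nan,
                "sd": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
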