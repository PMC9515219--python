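"""Connectome similarity matrices and their principal gradients.

Two standard similarity constructions feed the embedding:

* microstructural profile covariance (MPC): pairwise partial correlation
  of depth profiles between regions, controlling for the cortex-average
  profile, thresholded at zero and log-transformed;
* functional connectivity: time-series correlations, Fisher r-to-z.

Gradients are estimated by diffusion map embedding of a row-sparsified,
normalized-angle affinity matrix.  The embedding is controlled by alpha
(density normalization; 0.5 here) and diffusion time t (t = 0 uses the
automatic-time scaling lambda / (1 - lambda)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .containers import ConnectivityMatrix, ProfileSet

__all__ = [
    "build_mpc",
    "fisher_z_matrix",
    "sparsify_rows",
    "normalized_angle_affinity",
    "DiffusionGradients",
    "GradientResults",
    "diffusion_map_embedding",
    "connectivity_gradients",
]

logger = logging.getLogger(__name__)

_R_CAP = 1.0 - 1e-9


def build_mpc(profiles: ProfileSet) -> ConnectivityMatrix:
    """Microstructural profile covariance matrix.

    Partial correlation of region profiles controlling for the mean
    profile across all regions (correlation of residuals after regressing
    each profile on the mean profile, intercept included).  Negative
    entries are set to 0; positive entries r are mapped by
    log(r / (1 - r)) with r clipped at 1 - 1e-9.  Symmetric, zero
    diagonal.
    """
    if profiles.n_depths < 3:
        raise ValueError("need at least 3 depths")
    n = profiles.intensities.shape[0]
    if n < 3:
        raise ValueError("need at least 3 regions")
    x = profiles.intensities  # regions x depths
    mean_profile = x.mean(axis=0)
    design = np.column_stack([np.ones_like(mean_profile), mean_profile])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    resid = x.T - design @ beta  # depths x regions
    sd = resid.std(axis=0)
    dead = sd == 0
    if dead.any():
        names = [profiles.meta.region_id[i] for i in np.where(dead)[0]]
        logger.warning(
            "zero-variance residual profiles in regions %s: rows/columns set to 0",
            names,
        )
    safe = np.where(dead, 1.0, sd)
    z = (resid - resid.mean(axis=0)) / safe
    r = (z.T @ z) / resid.shape[0]
    r[dead, :] = 0.0
    r[:, dead] = 0.0
    r = np.clip(r, None, _R_CAP)
    out = np.where(r > 0, np.log(np.clip(r, 1e-300, None) / (1.0 - r)), 0.0)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, profiles.meta, kind="microstructural")


def fisher_z_matrix(corr: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise Fisher r-to-z (arctanh) with |r| clipped at 1 - 1e-9."""
    r = corr.values
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(r, -_R_CAP, _R_CAP))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, corr.meta, kind="functional")


def sparsify_rows(matrix: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep the ceil(density * n) largest off-diagonal entries per row.

    Ties break toward the lower column index.  The result is generally
    asymmetric; the downstream angle kernel compares rows, which resolves
    the asymmetry.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    a = matrix.values
    n = a.shape[0]
    k = int(np.ceil(density * n))
    out = np.zeros_like(a)
    cols = np.arange(n)
    for i in range(n):
        off = cols != i
        candidates = cols[off]
        # sort by (-value, column index): largest first, ties to lower index
        order = np.lexsort((candidates, -a[i, off]))
        keep = candidates[order[:k]]
        out[i, keep] = a[i, keep]
    return ConnectivityMatrix(out, matrix.meta, kind=f"{matrix.kind}-sparse")


def normalized_angle_affinity(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Affinity(i, j) = 1 - arccos(cosine similarity of rows i, j) / pi.

    1 for identical rows, 0.5 for orthogonal rows, 0 for opposite rows.
    """
    a = matrix.values
    norms = np.linalg.norm(a, axis=1)
    if np.any(norms == 0):
        bad = [matrix.meta.region_id[i] for i in np.where(norms == 0)[0]]
        raise ValueError(f"all-zero rows for regions {bad}")
    cos = np.clip((a @ a.T) / np.outer(norms, norms), -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = 0.5 * (aff + aff.T)
    np.fill_diagonal(aff, 1.0)
    return ConnectivityMatrix(aff, matrix.meta, kind="affinity")


class DiffusionGradients:
    """Diffusion map embedding of a symmetric nonnegative affinity matrix.

    Parameters
    ----------
    affinity : ConnectivityMatrix
        Symmetric, nonnegative, connected.
    alpha : float
        Density-normalization exponent; 0.5 balances geometry against
        sampling density.
    diffusion_time : float
        t = 0 (default) scales component k by lambda_k / (1 - lambda_k);
        t > 0 scales by lambda_k ** t.
    n_components : int
        Non-trivial components to return (trivial constant eigenvector is
        always dropped).
    """

    def __init__(
        self,
        affinity: ConnectivityMatrix,
        alpha: float = 0.5,
        diffusion_time: float = 0.0,
        n_components: int = 10,
    ):
        w = affinity.values
        if not affinity.is_symmetric(tol=1e-9):
            raise ValueError("affinity matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("affinity matrix must be nonnegative")
        n_comp, labels = connected_components(w > 0, directed=False)
        if n_comp > 1:
            groups = [
                [affinity.meta.region_id[i] for i in np.where(labels == g)[0]]
                for g in range(n_comp)
            ]
            raise ValueError(f"affinity graph is disconnected: components {groups}")
        if n_components >= w.shape[0]:
            raise ValueError("n_components must be < number of regions")
        self.affinity = affinity
        self.alpha = float(alpha)
        self.diffusion_time = float(diffusion_time)
        self.n_components = int(n_components)

    def fit(self) -> "GradientResults":
        w = self.affinity.values
        d = w.sum(axis=1)
        # density normalization W' = D^-a W D^-a
        d_a = d**-self.alpha
        w1 = w * np.outer(d_a, d_a)
        d1 = w1.sum(axis=1)
        # symmetric conjugate of the row-stochastic operator D1^-1 W'
        inv_sqrt = 1.0 / np.sqrt(d1)
        s = w1 * np.outer(inv_sqrt, inv_sqrt)
        s = 0.5 * (s + s.T)
        evals, evecs = np.linalg.eigh(s)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        # right eigenvectors of the transition operator
        psi = evecs * inv_sqrt[:, None]
        k = self.n_components
        lam = evals[1 : k + 1]  # drop the trivial lambda = 1
        comps = psi[:, 1 : k + 1]
        comps = comps / np.linalg.norm(comps, axis=0, keepdims=True)
        if self.diffusion_time == 0:
            scale = lam / (1.0 - lam)
        else:
            scale = lam**self.diffusion_time
        comps = comps * scale
        # fixed sign convention: correlation with the first centroid axis
        anchor = self.affinity.meta.centroid[:, 0]
        anchor_c = anchor - anchor.mean()
        for j in range(comps.shape[1]):
            r = float(comps[:, j] @ anchor_c)
            if r == 0.0:
                r = comps[np.argmax(np.abs(comps[:, j])), j]
            if r < 0:
                comps[:, j] *= -1
        return GradientResults(
            model=self,
            gradients=comps,
            eigenvalues=lam,
            params={
                "alpha": self.alpha,
                "t": self.diffusion_time,
                "n_components": self.n_components,
                "kernel": "normalized_angle" if self.affinity.kind == "affinity" else self.affinity.kind,
            },
        )


@dataclass
class GradientResults:
    """Fitted diffusion-map gradients.

    ``gradients[:, 0]`` is the principal gradient; ``eigenvalues`` are the
    transition-operator eigenvalues of the retained components (in
    (-1, 1], non-increasing).
    """

    model: DiffusionGradients
    gradients: np.ndarray
    eigenvalues: np.ndarray
    params: dict

    def gradient_map(self, component: int = 0):
        from .containers import ParcelMap

        return ParcelMap(
            self.gradients[:, component],
            self.model.affinity.meta,
            name=f"gradient{component + 1}",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.gradients,
            index=list(self.model.affinity.meta.region_id),
            columns=[f"gradient{j + 1}" for j in range(self.gradients.shape[1])],
        )

    def summary(self) -> str:
        lines = [
            "Diffusion map embedding",
            "=" * 40,
            f"Regions: {self.gradients.shape[0]}    Components: {self.gradients.shape[1]}",
            f"alpha = {self.params['alpha']}, t = {self.params['t']}, "
            f"kernel = {self.params['kernel']}",
            "",
            "Component   Eigenvalue",
        ]
        for j, lam in enumerate(self.eigenvalues):
            lines.append(f"G{j + 1:<10d} {lam:>10.6f}")
        return "\n".join(lines)


def diffusion_map_embedding(
    affinity: ConnectivityMatrix,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    n_components: int = 10,
) -> GradientResults:
    """Convenience wrapper: ``DiffusionGradients(...).fit()``."""
    return DiffusionGradients(affinity, alpha, diffusion_time, n_components).fit()


def connectivity_gradients(
    matrix: ConnectivityMatrix,
    density: float = 0.1,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    n_components: int = 10,
) -> GradientResults:
    """Standard pipeline: row-sparsify -> normalized-angle affinity -> embed."""
    sparse = sparsify_rows(matrix, density)
    affinity = normalized_angle_affinity(sparse)
    return diffusion_map_embedding(affinity, alpha, diffusion_time, n_components)
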