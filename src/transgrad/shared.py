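"""Shared disease dimension across condition-wise effect maps.

Given a regions x conditions matrix of effect sizes, the shared dimension
is the first principal component of the (column-centered, optionally
z-scored) matrix: one score per region describing the transdiagnostic
axis of morphological alteration, one loading per condition describing
how strongly each condition expresses it.

The eigenvector sign is arbitrary, so component 1 follows one fixed,
documented orientation rule: its correlation with the column-mean effect
map is made positive, i.e. regions with the most negative mean effect
(strongest average atrophy) receive negative scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EffectMatrix, ParcelMap

__all__ = [
    "SharedDimension",
    "SharedDimensionResults",
    "fit_shared_dimension",
    "mean_effect_map",
    "leave_one_condition_out",
]

_SCALING_MODES = ("center", "zscore")


def mean_effect_map(effects: EffectMatrix) -> ParcelMap:
    """Row-wise arithmetic mean effect size across conditions."""
    values = effects.require_finite()
    return ParcelMap(values.mean(axis=1), effects.meta, name="mean_effect")


class SharedDimension:
    """Principal-component model of a regions x conditions effect matrix.

    Parameters
    ----------
    effects : EffectMatrix
        Aligned, complete effect-size matrix with >= 2 conditions and
        >= 3 regions.
    scaling : {'center', 'zscore'}
        'center' (default) column-centers each condition; 'zscore'
        additionally divides by the condition SD.  Variance-explained
        figures depend on this choice, so it is recorded on the results.
    """

    def __init__(self, effects: EffectMatrix, scaling: str = "center"):
        if scaling not in _SCALING_MODES:
            raise ValueError(f"scaling must be one of {_SCALING_MODES}")
        values = effects.require_finite()
        if effects.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if values.shape[0] < 3:
            raise ValueError("need at least 3 regions")
        self.effects = effects
        self.scaling = scaling

    def _prepare(self) -> np.ndarray:
        x = self.effects.values - self.effects.values.mean(axis=0, keepdims=True)
        if self.scaling == "zscore":
            sd = self.effects.values.std(axis=0, ddof=1, keepdims=True)
            if np.any(sd == 0):
                bad = [
                    c
                    for c, s in zip(self.effects.conditions, sd.ravel())
                    if s == 0
                ]
                raise ValueError(f"constant condition columns cannot be z-scored: {bad}")
            x = x / sd
        return x

    def fit(self, n_components: int | None = None) -> "SharedDimensionResults":
        x = self._prepare()
        total = np.sum(x**2)
        if total == 0:
            raise ValueError("effect matrix is constant; no dimension to extract")
        k_max = min(x.shape[0] - 1, x.shape[1])
        k = k_max if n_components is None else min(n_components, k_max)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        scores = u[:, :k] * s[:k]
        loadings = vt[:k].T  # conditions x components
        var = (s**2) / total
        mean_map = self.effects.values.mean(axis=1)
        mean_c = mean_map - mean_map.mean()
        flipped = np.zeros(k, dtype=bool)
        for j in range(k):
            r = float(scores[:, j] @ mean_c)
            if r == 0.0:  # fall back: largest-|score| entry positive
                r = scores[np.argmax(np.abs(scores[:, j])), j]
            if r < 0:
                scores[:, j] *= -1
                loadings[:, j] *= -1
                flipped[j] = True
        return SharedDimensionResults(
            model=self,
            scores=scores,
            loadings=loadings,
            variance_explained=var[:k],
            scaling_mode=self.scaling,
            orientation="corr(scores, column-mean map) > 0",
        )


@dataclass
class SharedDimensionResults:
    """Fitted shared-dimension decomposition.

    Attributes
    ----------
    scores : (n_regions, k) array
        Region scores per component; component 0 is the shared dimension.
    loadings : (n_conditions, k) array
        Condition weights per component.
    variance_explained : (k,) array
        Fraction of (centered/scaled) variance per component, in [0, 1],
        non-increasing.
    """

    model: SharedDimension
    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray
    scaling_mode: str
    orientation: str

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def score_map(self, component: int = 0) -> ParcelMap:
        return ParcelMap(
            self.scores[:, component],
            self.model.effects.meta,
            name=f"shared_dimension_{component + 1}",
        )

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings,
            index=list(self.model.effects.conditions),
            columns=[f"PC{j + 1}" for j in range(self.n_components)],
        )

    def leave_one_condition_out(self) -> pd.DataFrame:
        return leave_one_condition_out(self.model.effects, self)

    def summary(self) -> str:
        lines = [
            "Shared dimension (principal components of effect matrix)",
            "=" * 58,
            f"Regions: {self.model.effects.values.shape[0]}    "
            f"Conditions: {self.model.effects.n_conditions}    "
            f"Scaling: {self.scaling_mode}",
            f"Orientation: {self.orientation}",
            "",
            "Component   Var.explained   Cumulative",
        ]
        cum = 0.0
        for j, v in enumerate(self.variance_explained):
            cum += v
            lines.append(f"PC{j + 1:<9d} {v:>12.4f} {cum:>12.4f}")
        lines.append("")
        lines.append("Condition loadings:")
        lines.append(self.loadings_frame().to_string(float_format="%.4f"))
        return "\n".join(lines)


def fit_shared_dimension(
    effects: EffectMatrix,
    scaling: str = "center",
    n_components: int | None = None,
) -> SharedDimensionResults:
    """Convenience wrapper: ``SharedDimension(effects, scaling).fit(...)``."""
    return SharedDimension(effects, scaling=scaling).fit(n_components)


def leave_one_condition_out(
    effects: EffectMatrix,
    reference: SharedDimensionResults,
) -> pd.DataFrame:
    """Refit the shared dimension without each condition in turn.

    Returns one row per held-out condition with the absolute Pearson
    correlation between the refit component-1 scores and the reference
    component-1 scores (sign-invariant, since the eigenvector sign of a
    five-condition refit is not comparable to the full fit).
    """
    if effects.n_conditions < 3:
        raise ValueError("leave-one-condition-out needs at least 3 conditions")
    ref = reference.scores[:, 0]
    rows = []
    for cond in effects.conditions:
        sub = effects.drop_condition(cond)
        refit = SharedDimension(sub, scaling=reference.scaling_mode).fit(1)
        r = np.corrcoef(refit.scores[:, 0], ref)[0, 1]
        rows.append({"held_out": cond, "abs_r": abs(float(r))})
    return pd.DataFrame(rows)
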