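"""Composite cognitive scores from the neuropsychological battery.

The battery is z-standardized (baseline parameters are stored and re-used at
follow-up), reduced by principal component analysis on the correlation
matrix with Kaiser retention (eigenvalue >= 1.0) and an oblique promax
rotation, and each retained component becomes a composite score: the
weighted average of the z-scores of the variables whose pattern loading
reaches 0.50 in magnitude, with the loadings as weights (normalized by the
sum of their magnitudes).  Raw scales on which higher values mean worse
performance (trail-making times, recall error rates) are negated before the
PCA so that every composite reads "higher = better".

At a reduced follow-up battery the baseline z parameters and loadings are
restricted to the available variables and the weights renormalized, so
follow-up composites are directly comparable to baseline ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import promax, rotate_factors

from .simulate import INVERTED_VARS

__all__ = [
    "CompositeWeights",
    "zstandardize",
    "extract_components",
    "build_composites",
    "followup_composites",
    "orient_battery",
]

LOADING_THRESHOLD = 0.50


@dataclass
class CompositeWeights:
    """Frozen PCA solution: z parameters, rotated loadings, included sets."""

    variables: tuple[str, ...]
    means: dict[str, float]
    sds: dict[str, float]
    loadings: pd.DataFrame          # variables x components (pattern matrix)
    eigenvalues: tuple[float, ...]  # all eigenvalues, descending
    rotation: str
    threshold: float = LOADING_THRESHOLD
    included: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "variables": list(self.variables),
            "means": self.means,
            "sds": self.sds,
            "loadings": {c: self.loadings[c].to_dict() for c in self.loadings},
            "eigenvalues": list(self.eigenvalues),
            "rotation": self.rotation,
            "threshold": self.threshold,
            "included": self.included,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CompositeWeights":
        d = json.loads(Path(path).read_text())
        loadings = pd.DataFrame({c: pd.Series(v) for c, v in d["loadings"].items()})
        loadings = loadings.loc[d["variables"]]
        return cls(
            variables=tuple(d["variables"]),
            means=d["means"],
            sds=d["sds"],
            loadings=loadings,
            eigenvalues=tuple(d["eigenvalues"]),
            rotation=d["rotation"],
            threshold=d["threshold"],
            included={k: list(v) for k, v in d["included"].items()},
        )


def orient_battery(
    battery: pd.DataFrame, inverted: Sequence[str] = INVERTED_VARS
) -> pd.DataFrame:
    """Negate variables on 'higher = worse' scales so every column reads
    'higher = better' before standardization and PCA."""
    out = battery.copy()
    for var in inverted:
        if var in out:
            out[var] = -out[var]
    return out


def zstandardize(
    battery: pd.DataFrame,
    params: Optional[tuple[Mapping[str, float], Mapping[str, float]]] = None,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """Per-variable (x - mean) / SD.

    Without ``params`` the battery itself is the reference sample and its
    parameters are returned for reuse; with ``params`` (e.g. baseline means
    and SDs applied to follow-up data) those are used instead.
    """
    if battery.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if params is None:
        means = battery.mean()
        sds = battery.std(ddof=1)
        zero = sds[sds == 0]
        if len(zero):
            raise ValueError(f"zero variance in variable(s): {', '.join(zero.index)}")
        means, sds = means.to_dict(), sds.to_dict()
    else:
        means, sds = dict(params[0]), dict(params[1])
    z = pd.DataFrame(
        {v: (battery[v] - means[v]) / sds[v] for v in battery.columns},
        index=battery.index,
    )
    return z, means, sds


def extract_components(
    z: pd.DataFrame,
    rotation: str = "promax",
    kappa: int = 4,
    threshold: float = LOADING_THRESHOLD,
    kaiser_eigenvalue: float = 1.0,
) -> CompositeWeights:
    """PCA on the correlation matrix with Kaiser retention and an oblique
    rotation; returns the rotated pattern loadings and the per-component
    sets of variables meeting the loading threshold.

    Components are reflected so that their included variables load
    positively (the battery is oriented 'higher = better' beforehand).
    """
    if z.isna().any().any():
        raise ValueError("complete cases required")
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("degenerate correlation matrix")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    k = int((eigvals >= kaiser_eigenvalue).sum())
    if k < 1:
        raise ValueError("no component reaches the Kaiser criterion")
    unrotated = eigvecs[:, :k] * np.sqrt(eigvals[:k])

    if k == 1 or rotation == "none":
        pattern = unrotated
    elif rotation == "promax":
        pattern, _ = promax(unrotated, k=kappa)
    else:
        pattern, _ = rotate_factors(unrotated, rotation)
    pattern = pattern.copy()
    for j in range(pattern.shape[1]):
        if pattern[:, j].sum() < 0:
            pattern[:, j] *= -1

    cols = [f"component_{j + 1}" for j in range(pattern.shape[1])]
    loadings = pd.DataFrame(pattern, index=z.columns, columns=cols)
    included = {
        c: [v for v in z.columns if abs(loadings.at[v, c]) >= threshold]
        for c in cols
    }
    means = {v: 0.0 for v in z.columns}  # z input: stored by the caller
    sds = {v: 1.0 for v in z.columns}
    return CompositeWeights(
        variables=tuple(z.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=tuple(float(e) for e in eigvals),
        rotation=rotation,
        threshold=threshold,
        included=included,
    )


def build_composites(
    z: pd.DataFrame,
    weights: CompositeWeights,
    components: Optional[Sequence[str]] = None,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Per-subject composite = sum(loading * z) / sum(|loading|) over each
    component's included variables.

    With ``allow_missing`` (follow-up mode) the included set is restricted
    to the available columns and the weights renormalize automatically;
    otherwise a missing included variable is an error.
    """
    components = list(components or weights.included)
    out = {}
    for comp in components:
        incl = weights.included.get(comp, [])
        if not incl:
            raise ValueError(f"component {comp!r} has no included variables")
        avail = [v for v in incl if v in z.columns]
        if not allow_missing and len(avail) < len(incl):
            missing = set(incl) - set(avail)
            raise ValueError(f"missing included variable(s): {', '.join(sorted(missing))}")
        if not avail:
            raise ValueError(f"no included variable of {comp!r} available")
        lam = weights.loadings.loc[avail, comp].to_numpy()
        out[comp] = (z[avail].to_numpy() @ lam) / np.abs(lam).sum()
    return pd.DataFrame(out, index=z.index)


def followup_composites(
    followup_battery: pd.DataFrame,
    weights: CompositeWeights,
    baseline_params: tuple[Mapping[str, float], Mapping[str, float]],
) -> pd.DataFrame:
    """Composites for a reduced follow-up battery using *baseline* z
    parameters and loadings, weights renormalized over the available set."""
    avail = [v for v in weights.variables if v in followup_battery.columns]
    if not avail:
        raise ValueError("follow-up battery shares no variable with baseline")
    oriented = orient_battery(followup_battery[avail])
    z, _, _ = zstandardize(
        oriented,
        params=(
            {v: baseline_params[0][v] for v in avail},
            {v: baseline_params[1][v] for v in avail},
        ),
    )
    return build_composites(z, weights, allow_missing=True)
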