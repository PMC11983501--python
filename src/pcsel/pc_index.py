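"""Economic-weight-free selection indices from correlation-matrix PCA.

The workflow: standardize the genotype x trait BLUE matrix (zero mean, unit
sample variance per trait), eigendecompose the trait correlation matrix,
retain components by the Kaiser rule (eigenvalue strictly greater than one),
rescale each retained component's loadings so the largest-magnitude weight
is exactly +/-1, orient the component so that a larger index score is more
desirable, and score genotypes by the weighted sum of their (standardized)
BLUEs.  The first component of such trials typically contrasts leaf-damage
scores against grain yield; the second picks up the ear-damage / ear-rot
axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .traits import TraitSpec, default_registry

__all__ = [
    "PcaModel",
    "IndexDefinition",
    "IndexScores",
    "PCIndexBuilder",
    "standardize",
    "correlation_pca",
    "retain_components",
    "rescale_weights",
    "index_scores",
    "build_indices",
]


@dataclass
class PcaModel:
    """Eigendecomposition of a trait correlation matrix.

    Components are 1-based throughout (component 1 = largest eigenvalue).
    ``loadings`` are eigenvector entries scaled by sqrt(eigenvalue), i.e. the
    trait-component correlations; per component their squares sum to the
    eigenvalue.
    """

    traits: list[str]
    corr: pd.DataFrame
    eigenvalues: np.ndarray  # descending
    eigenvectors: pd.DataFrame  # unit-norm columns PC1..PCk
    loadings: pd.DataFrame
    proportions: np.ndarray
    retained: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def cumulative_proportion(self, components: list[int]) -> float:
        return float(sum(self.proportions[m - 1] for m in components))


@dataclass
class IndexDefinition:
    """A named weighted-sum selection index; max |weight| = 1 by convention."""

    name: str
    weights: pd.Series  # trait -> weight
    source_component: int
    value_basis: str = "standardized_blues"  # or "raw_blues"

    def __post_init__(self) -> None:
        if self.value_basis not in ("standardized_blues", "raw_blues"):
            raise ValueError(f"unknown value_basis {self.value_basis!r}")


@dataclass
class IndexScores:
    """Per-genotype index values; larger is better."""

    index_name: str
    scores: pd.Series  # genotype -> score
    convention: str = "larger is better"


def standardize(blues: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each trait to mean 0, sample variance 1 (n-1 denominator)."""
    if len(blues) < 2:
        raise ValueError("need >= 2 genotypes to standardize")
    sd = blues.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"cannot standardize constant trait(s): {constant}")
    return (blues - blues.mean()) / sd


def correlation_pca(z: pd.DataFrame) -> PcaModel:
    """Eigendecomposition of the trait correlation matrix of a standardized matrix.

    Eigenvalues are sorted descending; each eigenvector is deterministically
    oriented so its largest-magnitude entry is positive (final index
    orientation is decided later by :func:`rescale_weights`).
    """
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("standardized matrix contains non-finite entries")
    if len(z) <= z.shape[1]:
        raise ValueError("need more genotypes than traits for a stable PCA")
    traits = list(z.columns)
    corr = z.corr()
    w, v = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for m in range(v.shape[1]):
        peak = np.argmax(np.abs(v[:, m]))
        if v[peak, m] < 0:
            v[:, m] = -v[:, m]
    names = [f"PC{m + 1}" for m in range(len(w))]
    eigenvectors = pd.DataFrame(v, index=traits, columns=names)
    loadings = eigenvectors * np.sqrt(np.clip(w, 0.0, None))
    model = PcaModel(
        traits=traits,
        corr=corr,
        eigenvalues=w,
        eigenvectors=eigenvectors,
        loadings=loadings,
        proportions=w / w.sum(),
    )
    model.retained = retain_components(model)
    return model


def retain_components(model: PcaModel, threshold: float = 1.0) -> list[int]:
    """Kaiser rule: keep components with eigenvalue strictly above ``threshold``.

    Falls back to component 1 (with a warning) if none qualifies.
    """
    kept = [m + 1 for m, lam in enumerate(model.eigenvalues) if lam > threshold]
    if not kept:
        warnings.warn(
            "no eigenvalue exceeds the retention threshold; keeping PC1 only",
            stacklevel=2,
        )
        kept = [1]
    return kept


def _orient(weights: pd.Series, registry: dict[str, TraitSpec]) -> pd.Series:
    """Flip a weight vector, if needed, so the index reads larger-is-better.

    If some higher-better trait (grain yield, typically) loads at |w| >= 0.1,
    its weight is made non-negative; otherwise the largest-|weight|
    lower-better trait is made negative.
    """
    higher = [t for t in weights.index if t in registry and not registry[t].lower_better]
    lower = [t for t in weights.index if t in registry and registry[t].lower_better]
    if higher:
        anchor = max(higher, key=lambda t: abs(weights[t]))
        if abs(weights[anchor]) >= 0.1:
            return -weights if weights[anchor] < 0 else weights
    if lower:
        anchor = max(lower, key=lambda t: abs(weights[t]))
        return -weights if weights[anchor] > 0 else weights
    return weights


def rescale_weights(
    model: PcaModel,
    component: int,
    registry: dict[str, TraitSpec] | None = None,
) -> pd.Series:
    """Rescale one component's loadings so max |weight| = 1, oriented larger-is-better.

    This reproduces the reporting convention in which each published
    component column carries a +/-1.00 entry on its dominant trait.
    """
    registry = registry if registry is not None else default_registry()
    if component not in model.retained:
        raise ValueError(
            f"component {component} is not retained (retained: {model.retained})"
        )
    load = model.loadings[f"PC{component}"]
    peak = load.abs().max()
    if peak == 0:
        raise ValueError(f"component {component} has all-zero loadings")
    return _orient(load / peak, registry).rename(f"PC{component}BI")


def index_scores(
    definition: IndexDefinition,
    blues: pd.DataFrame,
    z: pd.DataFrame | None = None,
) -> IndexScores:
    """Score genotypes: sum over traits of weight x (standardized or raw) BLUE.

    ``z`` supplies pre-computed standardized BLUEs; otherwise they are
    derived from ``blues`` on the fly.
    """
    missing = [t for t in definition.weights.index if t not in blues.columns]
    if missing:
        raise KeyError(f"index {definition.name}: traits missing from BLUEs: {missing}")
    if definition.value_basis == "standardized_blues":
        basis = z if z is not None else standardize(blues)
    else:
        basis = blues
    scores = basis[definition.weights.index] @ definition.weights
    return IndexScores(index_name=definition.name, scores=scores.rename(definition.name))


def build_indices(
    model: PcaModel,
    registry: dict[str, TraitSpec] | None = None,
    n_indices: int = 2,
    fixed_weights: dict[str, dict[str, float]] | None = None,
    value_basis: str = "standardized_blues",
) -> list[IndexDefinition]:
    """Build PC1BI, PC2BI, ... from the retained components.

    ``fixed_weights`` (name -> trait -> coefficient) bypasses the
    data-driven loadings entirely — replication mode for published
    coefficient vectors, used verbatim without re-orientation.
    """
    if fixed_weights is not None:
        return [
            IndexDefinition(
                name=name,
                weights=pd.Series(wts, dtype=float),
                source_component=i + 1,
                value_basis=value_basis,
            )
            for i, (name, wts) in enumerate(fixed_weights.items())
        ]
    if len(model.retained) < n_indices:
        raise ValueError(
            f"{n_indices} indices requested but only {len(model.retained)} "
            "component(s) retained"
        )
    out = []
    for component in model.retained[:n_indices]:
        weights = rescale_weights(model, component, registry)
        out.append(
            IndexDefinition(
                name=f"PC{component}BI",
                weights=weights,
                source_component=component,
                value_basis=value_basis,
            )
        )
    return out


class PCIndexBuilder(BaseEstimator, TransformerMixin):
    """Fit correlation-matrix PCA on a BLUE matrix; transform genotypes to index scores.

    Parameters
    ----------
    n_indices : int
        How many PC-based indices to build (PC1BI, PC2BI, ...).
    value_basis : {"standardized_blues", "raw_blues"}
        Whether scores multiply weights with standardized or raw BLUEs.
        Standardized is the default: raw-basis scores are dominated by the
        trait with the largest scale (ear-rot percent).
    fixed_weights : dict, optional
        name -> {trait: coefficient}; replication mode, skips the PCA-derived
        weights (the PCA model is still fitted and exposed).
    kaiser_threshold : float
        Eigenvalue retention threshold (strict inequality).
    strict : bool
        If True, demand that all ``n_indices`` components are retained
        (error otherwise); if False (default), build as many indices as the
        retention rule allows, with a warning.

    Attributes
    ----------
    model_ : PcaModel
    indices_ : list of IndexDefinition
    mean_, scale_ : Series
        Standardization statistics frozen at fit time and reused in
        transform, so new genotypes are scored on the fitted scale.
    """

    def __init__(
        self,
        n_indices: int = 2,
        value_basis: str = "standardized_blues",
        fixed_weights: dict[str, dict[str, float]] | None = None,
        kaiser_threshold: float = 1.0,
        strict: bool = False,
    ):
        self.n_indices = n_indices
        self.value_basis = value_basis
        self.fixed_weights = fixed_weights
        self.kaiser_threshold = kaiser_threshold
        self.strict = strict

    def fit(self, blues: pd.DataFrame, y=None) -> "PCIndexBuilder":
        blues = pd.DataFrame(blues)
        self.mean_ = blues.mean()
        self.scale_ = blues.std(ddof=1)
        z = standardize(blues)
        self.model_ = correlation_pca(z)
        self.model_.retained = retain_components(self.model_, self.kaiser_threshold)
        n_build = self.n_indices
        if not self.strict and self.fixed_weights is None:
            available = len(self.model_.retained)
            if available < self.n_indices:
                warnings.warn(
                    f"only {available} component(s) retained; building "
                    f"{available} of the {self.n_indices} requested indices",
                    stacklevel=2,
                )
                n_build = available
        self.indices_ = build_indices(
            self.model_,
            n_indices=n_build,
            fixed_weights=self.fixed_weights,
            value_basis=self.value_basis,
        )
        return self

    def transform(self, blues: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise AttributeError("PCIndexBuilder is not fitted yet; call fit first")
        blues = pd.DataFrame(blues)
        z = (blues - self.mean_) / self.scale_
        cols = {}
        for definition in self.indices_:
            cols[definition.name] = index_scores(definition, blues, z=z).scores
        out = pd.DataFrame(cols)
        out.index.name = "genotype"
        return out

    def scree(self) -> pd.DataFrame:
        """Eigenvalue / proportion table (scree-plot export)."""
        m = self.model_
        return pd.DataFrame(
            {
                "component": np.arange(1, m.n_components + 1),
                "eigenvalue": m.eigenvalues,
                "proportion": m.proportions,
                "cumulative": np.cumsum(m.proportions),
                "retained": [i + 1 in m.retained for i in range(m.n_components)],
            }
        )
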