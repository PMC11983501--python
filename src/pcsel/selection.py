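"""Ranking, selection differentials and gains, relative gains, overlaps.

A selection scheme is either an index (larger score = better) or direct
selection on a single trait in its desirable direction.  For a selected
fraction with mean Xs against the grand mean Xo of all entries, the
predicted selection gain per trait is

    GS = 100 * (Xs - Xo) * H2 / Xo    (percent of the grand mean)

and the gain is "desired" when the differential points in the trait's
desirable direction.  Relative gain compares one genotype against one check:

    RG = 100 * (genotype - check) / check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .traits import TraitSpec, default_registry

__all__ = [
    "SelectionScheme",
    "rank_genotypes",
    "select_top_k",
    "selection_gain",
    "gain_table",
    "relative_gain_table",
    "scheme_overlap",
    "threshold_count",
]

#: traits tabulated in gain reports, in report order
GAIN_TRAITS = ["LD1", "LD2", "LD3", "LD_AV", "ED", "ER", "GY"]


@dataclass(frozen=True)
class SelectionScheme:
    """Either an index scheme (scores supplied) or direct selection on a trait.

    ``criterion`` is an index-score column name for index schemes, or a
    trait name for direct schemes (conventional names: PC1BI, PC2BI vs
    GY_DS, LD_AV_DS, ...).
    """

    name: str
    criterion: str
    kind: str = "index"  # or "direct"

    def __post_init__(self) -> None:
        if self.kind not in ("index", "direct"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")

    @staticmethod
    def direct(trait: str) -> "SelectionScheme":
        return SelectionScheme(name=f"{trait}_DS", criterion=trait, kind="direct")

    @staticmethod
    def index(name: str) -> "SelectionScheme":
        return SelectionScheme(name=name, criterion=name, kind="index")


def rank_genotypes(
    values: pd.Series,
    larger_better: bool = True,
) -> list[str]:
    """Total order over genotypes: best first, ties broken by identifier ascending."""
    frame = values.rename("v").rename_axis("genotype").reset_index()
    frame = frame.sort_values(["v", "genotype"], ascending=[not larger_better, True])
    return frame["genotype"].tolist()


def _resolve_ranking(
    scheme: SelectionScheme,
    blues: pd.DataFrame,
    scores: pd.DataFrame | None,
    registry: dict[str, TraitSpec],
) -> list[str]:
    if scheme.kind == "index":
        if scores is None or scheme.criterion not in scores.columns:
            raise KeyError(f"index scores for scheme {scheme.name!r} not supplied")
        return rank_genotypes(scores[scheme.criterion], larger_better=True)
    if scheme.criterion not in blues.columns:
        raise KeyError(f"trait {scheme.criterion!r} not present in BLUEs")
    spec = registry.get(scheme.criterion)
    if spec is None:
        raise KeyError(f"trait {scheme.criterion!r} not registered")
    return rank_genotypes(blues[scheme.criterion], larger_better=not spec.lower_better)


def select_top_k(ranking: list[str], k: int) -> list[str]:
    """First k of a ranking (order retained)."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} outside [1, {len(ranking)}]")
    return ranking[:k]


def selection_gain(xs: float, xo: float, h2: float) -> float:
    """GS = 100 (Xs - Xo) H2 / Xo, percent of the grand mean."""
    if xo == 0:
        raise ValueError("grand mean Xo must be nonzero")
    if not 0 <= h2 <= 1:
        raise ValueError("H2 must lie in [0, 1]")
    return 100.0 * (xs - xo) * h2 / xo


def gain_table(
    schemes: list[SelectionScheme],
    blues: pd.DataFrame,
    heritability: pd.Series,
    ks: tuple[int, ...] = (10, 15),
    scores: pd.DataFrame | None = None,
    registry: dict[str, TraitSpec] | None = None,
    traits: list[str] | None = None,
    include_in_grand_mean: list[str] | None = None,
) -> pd.DataFrame:
    """Selection differentials and gains per scheme x k x trait.

    Xs is the mean BLUE of the selected set, Xo the grand mean over all
    entries (checks included by default; pass ``include_in_grand_mean`` to
    restrict).  The ``desired`` flag records whether the differential points
    in the trait's desirable direction; zero differentials are flagged
    neutral and counted as desired.
    """
    registry = registry if registry is not None else default_registry()
    if traits is None:
        traits = [t for t in GAIN_TRAITS if t in blues.columns]
    base = blues if include_in_grand_mean is None else blues.loc[include_in_grand_mean]
    rows = []
    for scheme in schemes:
        ranking = _resolve_ranking(scheme, blues, scores, registry)
        for k in ks:
            selected = select_top_k(ranking, k)
            whole_pool = set(selected) == set(base.index)
            for trait in traits:
                if trait not in heritability.index:
                    raise KeyError(f"no heritability available for trait {trait!r}")
                xo = float(base[trait].mean())
                # selecting the whole pool is a no-op: identical multisets
                # must give a differential of exactly zero
                xs = xo if whole_pool else float(blues.loc[selected, trait].mean())
                diff = xs - xo
                gs = selection_gain(xs, xo, float(heritability[trait]))
                lower = registry[trait].lower_better
                desired = True if diff == 0 else (diff < 0) == lower
                rows.append(
                    {
                        "scheme": scheme.name,
                        "k": k,
                        "trait": trait,
                        "selected_mean": xs,
                        "grand_mean": xo,
                        "differential": diff,
                        "H2": float(heritability[trait]),
                        "gain_percent": gs,
                        "desired": desired,
                        "neutral": diff == 0,
                    }
                )
    return pd.DataFrame(rows)


def relative_gain_table(
    selected: list[str],
    checks: list[str],
    blues: pd.DataFrame,
    traits: tuple[str, ...] = ("LD_AV", "ED", "ER", "GY"),
) -> pd.DataFrame:
    """RG per (selected genotype x check x trait); zero check values are refused."""
    if not checks:
        raise ValueError("need at least one check genotype")
    traits = [t for t in traits if t in blues.columns]
    rows = []
    for check in checks:
        for trait in traits:
            check_value = float(blues.at[check, trait])
            if check_value == 0:
                raise ValueError(
                    f"check {check!r} has zero BLUE for trait {trait!r}; "
                    "relative gain undefined"
                )
            for genotype in selected:
                value = float(blues.at[genotype, trait])
                rows.append(
                    {
                        "genotype": genotype,
                        "check": check,
                        "trait": trait,
                        "rg_percent": 100.0 * (value - check_value) / check_value,
                    }
                )
    return pd.DataFrame(rows)


def scheme_overlap(top_sets: dict[str, set[str] | list[str]]) -> pd.DataFrame:
    """Intersections over every subset of schemes of size >= 2.

    Symmetric and order-independent; scheme names within a combination are
    reported sorted.
    """
    if len(top_sets) < 2:
        raise ValueError("need >= 2 schemes for overlap analysis")
    sets = {name: set(v) for name, v in top_sets.items()}
    names = sorted(sets)
    rows = []
    for size in range(2, len(names) + 1):
        for combo in combinations(names, size):
            inter = set.intersection(*(sets[n] for n in combo))
            rows.append(
                {
                    "schemes": "&".join(combo),
                    "n_schemes": size,
                    "size": len(inter),
                    "genotypes": ",".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows)


def threshold_count(
    selected: list[str],
    blues: pd.DataFrame,
    trait: str,
    cutoff: float,
    registry: dict[str, TraitSpec] | None = None,
) -> int:
    """Count selected genotypes meeting a cutoff in the trait's desirable direction.

    >= cutoff for higher-better traits (yield floors), <= cutoff for
    lower-better traits (damage ceilings).
    """
    registry = registry if registry is not None else default_registry()
    if trait not in blues.columns:
        raise KeyError(f"trait {trait!r} not present in BLUEs")
    values = blues.loc[selected, trait]
    if registry[trait].lower_better:
        return int((values <= cutoff).sum())
    return int((values >= cutoff).sum())
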