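"""Plot-level trial data: container, validation, balance checks, CSV I/O.

A multi-environment trial is stored long-format: one row per plot with the
genotype, environment (year-season), replicate-within-environment, incomplete
block-within-replicate, a check flag, and one column per registered trait.
Missing trait values are honest ``NaN`` (written as ``NA``), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import TraitSpec, default_registry

__all__ = [
    "PhenotypeTable",
    "BalanceReport",
    "read_trial_csv",
    "write_trial_csv",
    "check_balance",
    "drop_incomplete_genotypes",
]

#: Structural (non-trait) columns, in canonical order.
ID_COLUMNS = ["genotype", "environment", "replicate", "block", "is_check"]


@dataclass
class PhenotypeTable:
    """Validated plot-level records plus the trait registry that scopes them.

    ``data`` holds one row per plot; trait columns are float with NaN for
    missing.  The design summary is recomputed from the records on demand so
    it can never drift out of sync.
    """

    data: pd.DataFrame
    traits: dict[str, TraitSpec] = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"table is missing required columns: {missing}")
        dup = self.data.duplicated(subset=["genotype", "environment", "replicate"])
        if dup.any():
            rows = self.data.loc[dup, ["genotype", "environment", "replicate"]]
            raise ValueError(
                "duplicate (genotype, environment, replicate) combinations:\n"
                f"{rows.to_string(index=False)}"
            )

    @property
    def trait_names(self) -> list[str]:
        return [t for t in self.traits if t in self.data.columns]

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def checks(self) -> list[str]:
        return sorted(self.data.loc[self.data["is_check"], "genotype"].unique())

    def design_summary(self) -> dict[str, int]:
        d = self.data
        n_rep = d.groupby("environment")["replicate"].nunique()
        block_sizes = d.groupby(["environment", "replicate", "block"]).size()
        return {
            "n_genotypes": d["genotype"].nunique(),
            "n_environments": d["environment"].nunique(),
            "n_replicates": int(n_rep.max()) if len(n_rep) else 0,
            "block_size": int(block_sizes.max()) if len(block_sizes) else 0,
            "n_records": len(d),
        }

    @property
    def balanced(self) -> bool:
        """True iff every genotype appears exactly once per (environment, replicate)."""
        d = self.data
        cells = d.groupby(["environment", "replicate"])["genotype"].agg(
            ["nunique", "size"]
        )
        if len(cells) == 0:
            return False
        n_g = d["genotype"].nunique()
        complete = (cells["nunique"] == n_g) & (cells["size"] == n_g)
        n_env = d["environment"].nunique()
        n_rep = d.groupby("environment")["replicate"].nunique()
        return bool(complete.all() and (n_rep == n_rep.iloc[0]).all()) and len(
            cells
        ) == n_env * int(n_rep.iloc[0])


@dataclass
class BalanceReport:
    """Outcome of a per-trait completeness check over the genotype x (env, rep) grid."""

    balanced: bool
    #: rows (trait, genotype, environment, replicate, n_observations) for every
    #: grid cell that does not hold exactly one non-missing value.
    deficient: pd.DataFrame


def check_balance(
    table: PhenotypeTable, traits: list[str] | None = None
) -> BalanceReport:
    """Check that each genotype x (environment, replicate) cell carries exactly
    one non-missing observation per trait.

    Missing values count as absent observations, so a structurally complete
    table with NA cells is reported unbalanced for the affected traits.
    """
    traits = traits if traits is not None else table.trait_names
    d = table.data
    genotypes = d["genotype"].unique()
    env_reps = d[["environment", "replicate"]].drop_duplicates()
    grid = env_reps.merge(pd.DataFrame({"genotype": genotypes}), how="cross")

    rows = []
    for trait in traits:
        present = d.loc[d[trait].notna(), ["genotype", "environment", "replicate"]]
        counts = (
            present.groupby(["genotype", "environment", "replicate"])
            .size()
            .rename("n_observations")
            .reset_index()
        )
        merged = grid.merge(counts, how="left", on=["genotype", "environment", "replicate"])
        merged["n_observations"] = merged["n_observations"].fillna(0).astype(int)
        bad = merged[merged["n_observations"] != 1].copy()
        bad.insert(0, "trait", trait)
        rows.append(bad)
    deficient = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["trait", "genotype", "environment", "replicate", "n_observations"])
    )
    deficient = deficient[["trait", "genotype", "environment", "replicate", "n_observations"]]
    return BalanceReport(balanced=len(deficient) == 0, deficient=deficient)


def read_trial_csv(
    path: str | Path,
    trait_registry: dict[str, TraitSpec] | None = None,
    validate_ranges: bool = True,
) -> PhenotypeTable:
    """Read a long-format trial CSV into a validated :class:`PhenotypeTable`.

    ``NA`` (case-sensitive) and the empty string denote missing trait values.
    Unregistered trait columns, out-of-range values, and duplicate
    (genotype, environment, replicate) combinations are hard errors.
    Set ``validate_ranges=False`` to admit values outside the measurement
    scale (e.g. unclamped synthetic data).
    """
    registry = trait_registry if trait_registry is not None else default_registry()
    path = Path(path)
    df = pd.read_csv(
        path,
        keep_default_na=False,
        na_values=["NA", ""],
        dtype={"genotype": str},
        float_precision="round_trip",
    )
    required = ["genotype", "environment", "replicate", "block"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "is_check" not in df.columns:
        df["is_check"] = False
    df["is_check"] = df["is_check"].astype(bool)

    unknown = [c for c in df.columns if c not in ID_COLUMNS and c not in registry]
    if unknown:
        raise ValueError(
            f"{path}: unregistered trait columns {unknown}; register them or "
            "drop them before reading"
        )
    trait_cols = [c for c in df.columns if c in registry]
    if not trait_cols:
        raise ValueError(f"{path}: no registered trait columns found")
    for col in trait_cols:
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        if validate_ranges:
            spec = registry[col]
            lo, hi = spec.valid_range
            bad = df.index[df[col].notna() & ((df[col] < lo) | (df[col] > hi))]
            if len(bad):
                i = bad[0]
                raise ValueError(
                    f"{path}: trait {col!r} value {df.at[i, col]} outside valid "
                    f"range [{lo}, {hi}] for genotype {df.at[i, 'genotype']!r}, "
                    f"environment {df.at[i, 'environment']!r}, "
                    f"replicate {df.at[i, 'replicate']!r} "
                    f"({len(bad)} offending record(s) in total)"
                )
    return PhenotypeTable(data=df, traits=registry)


def write_trial_csv(table: PhenotypeTable, path: str | Path) -> Path:
    """Write a table with deterministic column order; missing values as ``NA``.

    Floats are written at full precision so a write/read round trip is
    value-identical.
    """
    path = Path(path)
    cols = ID_COLUMNS + table.trait_names
    out = table.data[cols]
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep="NA", float_format=lambda v: repr(float(v)))
    return path


def drop_incomplete_genotypes(
    table: PhenotypeTable, traits: list[str] | None = None
) -> PhenotypeTable:
    """Drop every genotype with any missing or absent cell for the given traits.

    Preprocessing helper for the balanced-design estimators, which refuse
    unbalanced input rather than silently imputing.
    """
    report = check_balance(table, traits)
    bad = set(report.deficient["genotype"].unique())
    keep = ~table.data["genotype"].isin(bad)
    return PhenotypeTable(
        data=table.data.loc[keep].reset_index(drop=True), traits=table.traits
    )
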