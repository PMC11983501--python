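"""Across-environment analysis of balanced multi-environment trials.

Fits the additive model

    Y_ijkl = mu + G_i + E_j + R_k(E_j) + B_l(RE)_jk + GE_ij + eps_ijkl

on balanced data (every genotype exactly once per environment x replicate)
by sequential sweeps of group means.  Environment, replicate-within-
environment, genotype and genotype-x-environment are mutually orthogonal on
balanced data and are swept first; incomplete blocks are then removed from
the running residual by an exact sequential least-squares step (see
``_block_sweep``).  Sweeping blocks after genotype matters: incomplete
blocks are not orthogonal to genotypes, and removing raw between-block
variation first would fold genotypic variance into the block line and
deflate the residual mean square, biasing every variance component
downstream.  With the order used here the sums of squares add exactly to
the total and the expected mean squares keep their textbook form:

    E[MS_resid] = sigma_e2
    E[MS_GxE]   = sigma_e2 + r sigma_GE2
    E[MS_G]     = sigma_e2 + r sigma_GE2 + e r sigma_G2

so method-of-moments inversion recovers (sigma_G2, sigma_GE2, sigma_e2),
negative solutions truncated at zero.  Broad-sense heritability on an
entry-mean basis is

    H2 = sigma_G2 / (sigma_G2 + sigma_GE2 / e + sigma_e2 / (e r)).

With genotype fixed and the design balanced, the best linear unbiased
estimate (BLUE) of a genotype is its simple mean over all environment x
replicate observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .trial_data import PhenotypeTable, check_balance

__all__ = [
    "VarianceComponents",
    "MetResult",
    "MetAnalyzer",
    "anova_balanced",
    "estimate_components",
    "heritability",
    "compute_blues",
    "cv_percent",
    "derive_ld_av",
    "trait_correlations",
]

ANOVA_SOURCES = [
    "environment",
    "rep_within_env",
    "block_within_rep",
    "genotype",
    "genotype_x_env",
    "residual",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components for one trait."""

    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    n_env: int
    n_rep: int

    def __post_init__(self) -> None:
        if min(self.sigma2_G, self.sigma2_GE, self.sigma2_e) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")


@dataclass
class MetResult:
    """Per-trait summary of the combined analysis."""

    trait: str
    components: VarianceComponents
    h2: float
    grand_mean: float
    cv_percent: float
    blues: pd.Series  # genotype -> BLUE
    anova: pd.DataFrame


def _trait_frame(table: PhenotypeTable, trait: str) -> pd.DataFrame:
    if trait not in table.data.columns:
        raise KeyError(f"trait {trait!r} not present in table")
    d = table.data.loc[table.data[trait].notna()]
    report = check_balance(
        PhenotypeTable(data=d.reset_index(drop=True), traits=table.traits), [trait]
    )
    if not report.balanced:
        raise ValueError(
            f"trait {trait!r}: table is unbalanced over the genotype x "
            f"(environment, replicate) grid ({len(report.deficient)} deficient "
            "cell(s)); drop incomplete genotypes first "
            "(pcsel.trial_data.drop_incomplete_genotypes)"
        )
    return d


def _block_sweep(
    d: pd.DataFrame, trait: str, resid1: np.ndarray
) -> tuple[float, int, float, dict[str, float]]:
    """Least-squares sweep of incomplete blocks on the running residual.

    Incomplete blocks are not orthogonal to the genotype and cell-mean
    spaces already removed, so their contribution is the exact sequential
    regression SS: block indicator columns are first projected onto the
    orthocomplement of the swept spaces (the same group-mean transform that
    produced ``resid1``), then ``resid1`` is regressed on them.  A plain
    block-mean subtraction would both under-remove noise (inflating the
    residual mean square) and, swept earlier, leak genotypic variance into
    the block line.  Returns (SS_block, df_block, SS_residual).
    """
    blocks = pd.MultiIndex.from_frame(d[["environment", "replicate", "block"]])
    bcodes, _ = pd.factorize(blocks)
    n_blocks_per_rep = d.groupby(["environment", "replicate"])["block"].nunique()
    if (n_blocks_per_rep <= 1).all():
        # blocks confounded with replicates: nothing to sweep
        return 0.0, 0, float((resid1**2).sum()), {}

    n, nb = len(d), bcodes.max() + 1
    x = np.zeros((n, nb))
    x[np.arange(n), bcodes] = 1.0

    def sweep(mat: np.ndarray, labels: pd.Series | np.ndarray) -> np.ndarray:
        codes, _ = pd.factorize(labels)
        counts = np.bincount(codes).astype(float)
        sums = np.zeros((len(counts), mat.shape[1]))
        np.add.at(sums, codes, mat)
        return (sums / counts[:, None])[codes]

    cells = pd.MultiIndex.from_frame(d[["genotype", "environment"]])
    reps = pd.MultiIndex.from_frame(d[["environment", "replicate"]])
    adj = x - sweep(x, cells) - sweep(x, reps) + sweep(x, d["environment"])
    beta, _, rank, _ = np.linalg.lstsq(adj, resid1, rcond=None)
    fitted = adj @ beta
    ss_b = float((fitted**2).sum())
    ss_res = float(((resid1 - fitted) ** 2).sum())

    # Exact expected-mean-square contributions of the block variance to the
    # genotype, GxE and block lines for this particular randomization:
    # c = tr(X_B' P X_B) for each sweep projection P.  Blocks are only
    # quasi-orthogonal to genotypes, so without these traces sigma2_GE would
    # inherit a positive bias of about sigma2_B (g - s) / (r (g - 1)).
    gmean = sweep(x, d["genotype"])
    emean = sweep(x, d["environment"])
    cmean = sweep(x, cells)
    grand = x.mean(axis=0, keepdims=True)
    c_g = float(((gmean - grand) ** 2).sum())
    c_ge = float(((cmean - gmean - emean + grand) ** 2).sum())
    beta_x, _, _, _ = np.linalg.lstsq(adj, x, rcond=None)
    q_b = float(((adj @ beta_x) ** 2).sum())
    ems = {"c_G": c_g, "c_GE": c_ge, "q_B": q_b}
    return ss_b, int(rank), ss_res, ems


def anova_balanced(table: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Sequential-sweep ANOVA for one trait on balanced data.

    Returns a DataFrame indexed by source with columns df, ss, ms, F.
    Genotypes are tested against GxE and GxE against the residual (random
    interaction convention); environments against replicates-within-
    environments; replicates and blocks against the residual.
    """
    d = _trait_frame(table, trait)
    y = d[trait].to_numpy()
    n = len(y)
    env = d["environment"].to_numpy()
    g = d["genotype"].nunique()
    e = d["environment"].nunique()
    r = d.groupby("environment")["replicate"].nunique().iloc[0]

    m = y.mean()
    m_env = d.groupby("environment")[trait].transform("mean").to_numpy()
    m_er = d.groupby(["environment", "replicate"])[trait].transform("mean").to_numpy()
    m_g = d.groupby("genotype")[trait].transform("mean").to_numpy()
    m_ge = d.groupby(["genotype", "environment"])[trait].transform("mean").to_numpy()

    ss_e = float(((m_env - m) ** 2).sum())
    ss_r = float(((m_er - m_env) ** 2).sum())
    ss_g = float(((m_g - m) ** 2).sum())
    ss_ge = float(((m_ge - m_g - m_env + m) ** 2).sum())

    resid1 = y - m_ge - m_er + m_env
    ss_b, df_b, ss_res, block_ems = _block_sweep(d, trait, resid1)
    df = {
        "environment": e - 1,
        "rep_within_env": e * (r - 1),
        "block_within_rep": df_b,
        "genotype": g - 1,
        "genotype_x_env": (g - 1) * (e - 1),
    }
    df["residual"] = (n - 1) - sum(df.values())
    if df["residual"] <= 0 or df["genotype"] <= 0:
        raise ValueError(
            f"trait {trait!r}: zero degrees of freedom for "
            f"{'residual' if df['genotype'] > 0 else 'genotype'}"
        )
    ss = {
        "environment": ss_e,
        "rep_within_env": ss_r,
        "block_within_rep": ss_b,
        "genotype": ss_g,
        "genotype_x_env": ss_ge,
        "residual": ss_res,
    }
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}
    denom = {
        "environment": ms["rep_within_env"],
        "rep_within_env": ms["residual"],
        "block_within_rep": ms["residual"],
        "genotype": ms["genotype_x_env"],
        "genotype_x_env": ms["residual"],
        "residual": np.nan,
    }
    out = pd.DataFrame(
        {
            "df": [df[k] for k in ANOVA_SOURCES],
            "ss": [ss[k] for k in ANOVA_SOURCES],
            "ms": [ms[k] for k in ANOVA_SOURCES],
            "F": [
                ms[k] / denom[k] if denom[k] and np.isfinite(denom[k]) and denom[k] > 0 else np.nan
                for k in ANOVA_SOURCES
            ],
        },
        index=pd.Index(ANOVA_SOURCES, name="source"),
    )
    out.attrs["block_ems"] = block_ems
    return out


def estimate_components(anova: pd.DataFrame, e: int, r: int) -> VarianceComponents:
    """Invert the expected mean squares; negatives truncated at zero.

    On designs with non-trivial incomplete blocks the ANOVA table carries
    the design-specific block EMS traces, and the block variance estimated
    from the block line is removed from the genotype and GxE mean squares
    before the textbook inversion; with trivial blocking this reduces to

        sigma2_e  = MS_resid
        sigma2_GE = (MS_GxE - MS_resid) / r
        sigma2_G  = (MS_G - MS_GxE) / (r e)
    """
    ms_res = float(anova.at["residual", "ms"])
    ms_ge = float(anova.at["genotype_x_env", "ms"])
    ms_g = float(anova.at["genotype", "ms"])
    ems = anova.attrs.get("block_ems") or {}
    df_b = int(anova.at["block_within_rep", "df"]) if "block_within_rep" in anova.index else 0
    if ems and df_b > 0 and ems.get("q_B", 0) > 0:
        ms_b = float(anova.at["block_within_rep", "ms"])
        sigma2_b = max(0.0, (ms_b - ms_res) * df_b / ems["q_B"])
        df_g = int(anova.at["genotype", "df"])
        df_ge = int(anova.at["genotype_x_env", "df"])
        ms_g -= ems["c_G"] / df_g * sigma2_b
        ms_ge -= ems["c_GE"] / df_ge * sigma2_b
    return VarianceComponents(
        sigma2_G=max(0.0, (ms_g - ms_ge) / (r * e)),
        sigma2_GE=max(0.0, (ms_ge - ms_res) / r),
        sigma2_e=ms_res,
        n_env=e,
        n_rep=r,
    )


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability, bounded to [0, 1].

    Zero by convention when every component is zero.
    """
    denom = vc.sigma2_G + vc.sigma2_GE / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom == 0:
        return 0.0
    return float(min(1.0, max(0.0, vc.sigma2_G / denom)))


def compute_blues(table: PhenotypeTable, trait: str) -> pd.Series:
    """Per-genotype BLUE: the simple mean over all env x rep observations.

    Valid because the design is balanced and genotype is fixed; unbalanced
    input is refused with the same remedy as :func:`anova_balanced`.
    """
    d = _trait_frame(table, trait)
    return d.groupby("genotype")[trait].mean().rename(trait)


def cv_percent(vc: VarianceComponents, grand_mean: float) -> float:
    """Residual coefficient of variation, percent of the grand mean."""
    if grand_mean <= 0:
        raise ValueError("grand_mean must be > 0 for CV%")
    return 100.0 * float(np.sqrt(vc.sigma2_e)) / grand_mean


def derive_ld_av(values: pd.DataFrame) -> pd.Series:
    """Mean leaf-damage score LD_AV = (LD1 + LD2 + LD3) / 3.

    Works on plot-level records or on per-genotype BLUEs; by linearity the
    two routes agree on balanced data.  Any missing LD score propagates.
    """
    missing = [c for c in ("LD1", "LD2", "LD3") if c not in values.columns]
    if missing:
        raise KeyError(f"cannot derive LD_AV: missing columns {missing}")
    return ((values["LD1"] + values["LD2"] + values["LD3"]) / 3.0).rename("LD_AV")


def trait_correlations(blues: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among genotype-level BLUEs.

    These entry-mean correlations are what breeders usually report as
    "genotypic correlations" when components of covariance are not
    estimated; constant columns are refused.
    """
    if len(blues) < 3:
        raise ValueError("need >= 3 genotypes for trait correlations")
    sd = blues.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    corr = blues.corr()
    return (corr + corr.T) / 2.0


class MetAnalyzer(BaseEstimator):
    """Combined across-environment analysis, one trait at a time.

    sklearn-style estimator: ``fit`` consumes a :class:`PhenotypeTable` and
    exposes the ANOVA tables, variance components, heritabilities, grand
    means, CV%, and the genotype x trait BLUE matrix as fitted attributes.

    Parameters
    ----------
    traits : list of str, optional
        Traits to analyse; defaults to every registered trait present.
    add_ld_av : bool
        Derive plot-level LD_AV from LD1..LD3 before analysis when absent.

    Attributes
    ----------
    results_ : dict of str -> MetResult
    blues_ : DataFrame, genotype x trait
    heritability_ : Series per trait
    variance_components_ : DataFrame per trait
    anova_tables_ : dict of str -> DataFrame
    """

    def __init__(self, traits: list[str] | None = None, add_ld_av: bool = True):
        self.traits = traits
        self.add_ld_av = add_ld_av

    def fit(self, table: PhenotypeTable, y=None) -> "MetAnalyzer":
        data = table.data
        if (
            self.add_ld_av
            and "LD_AV" not in data.columns
            and all(c in data.columns for c in ("LD1", "LD2", "LD3"))
        ):
            data = data.assign(LD_AV=derive_ld_av(data))
            table = PhenotypeTable(data=data, traits=table.traits)
        traits = self.traits if self.traits is not None else table.trait_names

        self.results_ = {}
        for trait in traits:
            d = table.data.loc[table.data[trait].notna()]
            e = d["environment"].nunique()
            r = int(d.groupby("environment")["replicate"].nunique().max())
            anova = anova_balanced(table, trait)
            vc = estimate_components(anova, e=e, r=r)
            mean = float(d[trait].mean())
            self.results_[trait] = MetResult(
                trait=trait,
                components=vc,
                h2=heritability(vc),
                grand_mean=mean,
                cv_percent=cv_percent(vc, mean) if mean > 0 else float("nan"),
                blues=compute_blues(table, trait),
                anova=anova,
            )
        self.blues_ = pd.DataFrame({t: res.blues for t, res in self.results_.items()})
        self.blues_.index.name = "genotype"
        self.heritability_ = pd.Series(
            {t: res.h2 for t, res in self.results_.items()}, name="H2"
        )
        self.grand_means_ = pd.Series(
            {t: res.grand_mean for t, res in self.results_.items()}, name="mean"
        )
        self.cv_percent_ = pd.Series(
            {t: res.cv_percent for t, res in self.results_.items()}, name="cv_percent"
        )
        self.variance_components_ = pd.DataFrame(
            {
                t: {
                    "sigma2_G": res.components.sigma2_G,
                    "sigma2_GE": res.components.sigma2_GE,
                    "sigma2_e": res.components.sigma2_e,
                    "n_env": res.components.n_env,
                    "n_rep": res.components.n_rep,
                }
                for t, res in self.results_.items()
            }
        ).T
        self.anova_tables_ = {t: res.anova for t, res in self.results_.items()}
        return self

    def trait_correlations(self) -> pd.DataFrame:
        """Entry-mean trait correlations from the fitted BLUE matrix."""
        if not hasattr(self, "blues_"):
            raise AttributeError("MetAnalyzer is not fitted yet; call fit first")
        return trait_correlations(self.blues_)
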