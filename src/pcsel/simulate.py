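"""Synthetic multi-environment alpha-lattice trials.

Draws plot values from the additive model the downstream ANOVA assumes:

    Y_ijkl = mu_t + G_it + E_jt + R_kjt + B_ljkt + GE_ijt + eps

with genotype effects G drawn jointly across traits from MVN(0, Sigma_G),
genotype-by-environment effects independent per (genotype, environment),
environment / replicate / block effects from their configured variances, and
iid Gaussian residuals.  Under this model broad-sense heritability on an
entry-mean basis has the closed form

    H2_t = sigmaG2_t / (sigmaG2_t + sigmaGE2_t / e + sigmae2_t / (e r))

which the generator records as per-trait truth.

The default configuration mirrors a published four-season screen house trial
of 192 maize hybrids (four commercial checks) under artificial fall-armyworm
infestation: 2 replicates per season, incomplete blocks of 48, and per-trait
means and variance components taken from that trial's combined analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .traits import TraitSpec, default_registry
from .trial_data import PhenotypeTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_trial_config",
    "simulate_trial",
    "clamp_scores",
    "true_heritability",
]

#: Trait order of the default configuration (LD_AV is derived downstream,
#: never simulated).
DEFAULT_TRAITS = ["LD1", "LD2", "LD3", "ED", "ER", "GY"]

# Published per-trait grand means and variance components (combined analysis
# over four seasons): columns mean, sigmaG2, sigmaGE2, sigmae2.
_PUBLISHED_COMPONENTS = {
    "LD1": (3.52, 0.03, 0.02, 0.12),
    "LD2": (6.04, 0.04, 0.01, 0.11),
    "LD3": (5.72, 0.05, 0.00, 0.27),
    "ED": (1.98, 0.04, 0.02, 0.18),
    "ER": (8.14, 11.03, 3.33, 28.80),
    "GY": (5.11, 0.88, 0.72, 1.70),
}

# Default genetic correlation pattern among the six traits: strong positive
# correlations within the leaf-damage block, moderate damage-vs-yield
# antagonism, ED-ER association.  A documented stylised pattern consistent
# with the strong trait correlations (|r| 0.3-0.9) such trials report, not a
# reproduction of any particular dataset.
_DEFAULT_GENETIC_CORR = pd.DataFrame(
    [
        # LD1   LD2   LD3   ED    ER    GY
        [1.00, 0.80, 0.70, 0.30, 0.30, -0.40],
        [0.80, 1.00, 0.85, 0.30, 0.30, -0.40],
        [0.70, 0.85, 1.00, 0.30, 0.30, -0.40],
        [0.30, 0.30, 0.30, 1.00, 0.60, -0.30],
        [0.30, 0.30, 0.30, 0.60, 1.00, -0.30],
        [-0.40, -0.40, -0.40, -0.30, -0.30, 1.00],
    ],
    index=DEFAULT_TRAITS,
    columns=DEFAULT_TRAITS,
)

_PSD_TOL = 1e-10


@dataclass
class SimConfig:
    """Parameters of one synthetic trial.

    Per-trait vectors are dicts keyed by trait name; ``genetic_cov`` is a
    trait x trait DataFrame (symmetric, PSD up to -1e-10 eigenvalue jitter).
    """

    n_genotypes: int = 192
    n_checks: int = 4
    n_environments: int = 4
    n_replicates: int = 2
    block_size: int = 48
    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    grand_means: dict[str, float] = field(default_factory=dict)
    genetic_cov: pd.DataFrame | None = None
    ge_var: dict[str, float] = field(default_factory=dict)
    env_var: dict[str, float] = field(default_factory=dict)
    rep_var: dict[str, float] = field(default_factory=dict)
    block_var: dict[str, float] = field(default_factory=dict)
    resid_var: dict[str, float] = field(default_factory=dict)
    #: optional per-trait number of environments actually scored; traits
    #: measured in fewer environments get NA in the trailing ones.
    trait_env_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    clamp_to_range: bool = False

    def __post_init__(self) -> None:
        t = self.trait_names
        if self.genetic_cov is not None:
            cov = self.genetic_cov.loc[t, t].to_numpy()
            if not np.allclose(cov, cov.T, atol=1e-12):
                raise ValueError("genetic_cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -_PSD_TOL:
                raise ValueError("genetic_cov must be positive semi-definite")
        for name, vec in [
            ("ge_var", self.ge_var),
            ("resid_var", self.resid_var),
            ("env_var", self.env_var),
            ("rep_var", self.rep_var),
            ("block_var", self.block_var),
        ]:
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"{name} entries must be >= 0")
        if self.n_genotypes % self.block_size != 0:
            raise ValueError(
                f"n_genotypes={self.n_genotypes} is not divisible into blocks "
                f"of block_size={self.block_size}"
            )
        if not 0 <= self.n_checks <= self.n_genotypes:
            raise ValueError("n_checks must lie in [0, n_genotypes]")

    def env_count(self, trait: str) -> int:
        return self.trait_env_counts.get(trait, self.n_environments)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated trial."""

    genotype_effects: pd.DataFrame  # genotype x trait
    true_h2: pd.Series  # per trait
    realized_genetic_corr: pd.DataFrame  # trait x trait, from drawn G
    clamped: bool = False


def true_heritability(
    sigma_g2: float, sigma_ge2: float, sigma_e2: float, e: int, r: int
) -> float:
    """Entry-mean broad-sense heritability implied by the generating components."""
    denom = sigma_g2 + sigma_ge2 / e + sigma_e2 / (e * r)
    return 0.0 if denom == 0 else sigma_g2 / denom


def default_trial_config(seed: int = 0) -> SimConfig:
    """Configuration emulating the published four-season 192-hybrid trial.

    Grand means and (sigmaG2, sigmaGE2, sigmae2) per trait are the published
    combined-analysis values; genetic correlations follow the stylised
    default pattern above.  Environment SD 1.0, replicate SD 0.3 and block
    SD 0.2 per trait (scaled x10 for ER, which lives on a percent scale).
    """
    means = {t: _PUBLISHED_COMPONENTS[t][0] for t in DEFAULT_TRAITS}
    sg = np.array([_PUBLISHED_COMPONENTS[t][1] for t in DEFAULT_TRAITS])
    sd = np.sqrt(sg)
    cov = pd.DataFrame(
        _DEFAULT_GENETIC_CORR.to_numpy() * np.outer(sd, sd),
        index=DEFAULT_TRAITS,
        columns=DEFAULT_TRAITS,
    )
    scale = {t: (10.0 if t == "ER" else 1.0) for t in DEFAULT_TRAITS}
    return SimConfig(
        grand_means=means,
        genetic_cov=cov,
        ge_var={t: _PUBLISHED_COMPONENTS[t][2] for t in DEFAULT_TRAITS},
        resid_var={t: _PUBLISHED_COMPONENTS[t][3] for t in DEFAULT_TRAITS},
        env_var={t: (1.0 * scale[t]) ** 2 for t in DEFAULT_TRAITS},
        rep_var={t: (0.3 * scale[t]) ** 2 for t in DEFAULT_TRAITS},
        block_var={t: (0.2 * scale[t]) ** 2 for t in DEFAULT_TRAITS},
        seed=seed,
    )


def _truth(config: SimConfig, g_effects: np.ndarray, names: list[str]) -> SimTruth:
    t = config.trait_names
    cov = (
        config.genetic_cov.loc[t, t].to_numpy()
        if config.genetic_cov is not None
        else np.zeros((len(t), len(t)))
    )
    h2 = pd.Series(
        {
            trait: true_heritability(
                cov[i, i],
                config.ge_var.get(trait, 0.0),
                config.resid_var.get(trait, 0.0),
                config.env_count(trait),
                config.n_replicates,
            )
            for i, trait in enumerate(t)
        }
    )
    with np.errstate(invalid="ignore"):
        realized = np.corrcoef(g_effects, rowvar=False)
    return SimTruth(
        genotype_effects=pd.DataFrame(g_effects, index=names, columns=t),
        true_h2=h2,
        realized_genetic_corr=pd.DataFrame(realized, index=t, columns=t),
    )


def simulate_trial(config: SimConfig) -> tuple[PhenotypeTable, SimTruth]:
    """Draw one trial.  The same seed yields a bit-identical table.

    Draw order is fixed: genotype effects, environment effects, replicate
    effects, GxE effects, then per (environment, replicate) the block
    permutation, block effects, and residuals.
    """
    rng = np.random.default_rng(config.seed)
    t = config.trait_names
    nt = len(t)
    g, e, r = config.n_genotypes, config.n_environments, config.n_replicates
    nb = g // config.block_size

    cov = (
        config.genetic_cov.loc[t, t].to_numpy()
        if config.genetic_cov is not None
        else np.zeros((nt, nt))
    )
    # eigh-based square root tolerates semi-definite covariances
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    g_eff = rng.standard_normal((g, nt)) @ root.T

    def vec(d: dict[str, float]) -> np.ndarray:
        return np.array([d.get(trait, 0.0) for trait in t])

    env_sd = np.sqrt(vec(config.env_var))
    rep_sd = np.sqrt(vec(config.rep_var))
    blk_sd = np.sqrt(vec(config.block_var))
    ge_sd = np.sqrt(vec(config.ge_var))
    res_sd = np.sqrt(vec(config.resid_var))
    mu = vec(config.grand_means)

    env_eff = rng.standard_normal((e, nt)) * env_sd
    rep_eff = rng.standard_normal((e, r, nt)) * rep_sd
    ge_eff = rng.standard_normal((g, e, nt)) * ge_sd

    width = len(str(g))
    names = [f"G{i + 1:0{width}d}" for i in range(g - config.n_checks)] + [
        f"CHK{i + 1}" for i in range(config.n_checks)
    ]
    is_check = np.array([False] * (g - config.n_checks) + [True] * config.n_checks)

    frames = []
    for j in range(e):
        for k in range(r):
            order = rng.permutation(g)
            block_of = np.empty(g, dtype=int)
            block_of[order] = np.repeat(np.arange(nb), config.block_size)
            blk_eff = rng.standard_normal((nb, nt)) * blk_sd
            eps = rng.standard_normal((g, nt)) * res_sd
            y = (
                mu
                + g_eff
                + env_eff[j]
                + rep_eff[j, k]
                + ge_eff[:, j, :]
                + blk_eff[block_of]
                + eps
            )
            frame = pd.DataFrame(y, columns=t)
            frame.insert(0, "genotype", names)
            frame.insert(1, "environment", f"E{j + 1}")
            frame.insert(2, "replicate", f"R{k + 1}")
            frame.insert(3, "block", [f"B{b + 1}" for b in block_of])
            frame.insert(4, "is_check", is_check)
            frames.append(frame)
    data = pd.concat(frames, ignore_index=True)

    # traits scored in fewer environments: blank the trailing ones
    for trait, ecount in config.trait_env_counts.items():
        if ecount < e:
            absent = [f"E{j + 1}" for j in range(ecount, e)]
            data.loc[data["environment"].isin(absent), trait] = np.nan

    registry = default_registry()
    for trait in t:
        if trait not in registry:
            registry[trait] = TraitSpec(
                trait, "", direction=registry["GY"].direction, valid_range=(-1e9, 1e9)
            )
    table = PhenotypeTable(data=data, traits=registry)
    truth = _truth(config, g_eff, names)
    if config.clamp_to_range:
        table = clamp_scores(table, registry)
        truth.clamped = True
    return table, truth


def clamp_scores(
    table: PhenotypeTable, registry: dict[str, TraitSpec] | None = None
) -> PhenotypeTable:
    """Clip trait values into their registered valid ranges.

    Off by default in the generator: clipping truncates the Gaussian tails
    and biases variance-component recovery.
    """
    registry = registry if registry is not None else table.traits
    data = table.data.copy()
    for trait in table.trait_names:
        lo, hi = registry[trait].valid_range
        data[trait] = data[trait].clip(lo, hi)
    return PhenotypeTable(data=data, traits=table.traits)
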