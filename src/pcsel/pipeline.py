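"""End-to-end pipeline: simulate/read -> analyze -> index -> select -> report.

A run is a pure function of (input data, configuration, seed): the same
configuration and seed reproduce every numeric output byte-identically.
Results go only to files in the output directory; logging goes to stderr.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .met import MetAnalyzer
from .pc_index import PCIndexBuilder, standardize
from .selection import (
    SelectionScheme,
    _resolve_ranking,
    gain_table,
    relative_gain_table,
    scheme_overlap,
    select_top_k,
    threshold_count,
)
from .simulate import SimConfig, default_trial_config, simulate_trial
from .traits import default_registry, load_registry
from .trial_data import PhenotypeTable, read_trial_csv, write_trial_csv

__all__ = ["PipelineConfig", "run_pipeline", "export_heatmap_matrix", "load_config"]

log = logging.getLogger("pcsel")

#: CSV float precision: 6 significant digits
_FLOAT_FMT = "%.6g"

DEFAULT_SCHEMES = ["PC1BI", "PC2BI", "LD_AV_DS", "ED_DS", "ER_DS", "GY_DS"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``trial_csv`` and ``simulate`` must be set.
    """

    trial_csv: str | None = None
    simulate: SimConfig | None = None
    registry_path: str | None = None
    value_basis: str = "standardized_blues"
    fixed_weights: dict[str, dict[str, float]] | None = None
    schemes: list[str] = field(default_factory=lambda: list(DEFAULT_SCHEMES))
    ks: tuple[int, ...] = (10, 15)
    checks: list[str] | None = None  # default: the table's is_check entries
    gy_cutoff: float = 7.0
    exclude_checks: bool = False
    out_dir: str = "pcsel_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.trial_csv is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of trial_csv and simulate must be provided"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (JSON accepted); unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    if "simulate" in raw and raw["simulate"] is not None:
        sim = raw["simulate"]
        if sim == "default":
            raw["simulate"] = default_trial_config(seed=raw.get("seed", 0))
        else:
            base = default_trial_config(seed=raw.get("seed", 0))
            for key, value in sim.items():
                if not hasattr(base, key):
                    raise ValueError(f"{path}: unknown simulate key {key!r}")
                setattr(base, key, value)
            raw["simulate"] = base
    if "ks" in raw:
        raw["ks"] = tuple(raw["ks"])
    return PipelineConfig(**raw)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, float_format=_FLOAT_FMT, index=index)
    return path


def _build_schemes(names: list[str]) -> list[SelectionScheme]:
    out = []
    for name in names:
        if name.endswith("_DS"):
            out.append(SelectionScheme.direct(name[:-3]))
        else:
            out.append(SelectionScheme.index(name))
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns the manifest of written files."""
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    registry = (
        load_registry(config.registry_path)
        if config.registry_path
        else default_registry()
    )

    # stage 1: data
    if config.simulate is not None:
        config.simulate.seed = config.seed
        table, truth = simulate_trial(config.simulate)
        written["trial"] = write_trial_csv(table, out / "trial.csv")
        truth_df = truth.genotype_effects.copy()
        truth_df.loc["__true_H2__"] = truth.true_h2
        written["truth"] = _write(truth_df.rename_axis("genotype"), out / "truth.csv")
    else:
        table = read_trial_csv(config.trial_csv, registry)
    log.info("stage data: %d records", len(table.data))

    # stage 2: combined analysis
    met = MetAnalyzer().fit(table)
    met_summary = pd.concat(
        [
            met.variance_components_,
            met.heritability_,
            met.grand_means_,
            met.cv_percent_,
        ],
        axis=1,
    ).rename_axis("trait")
    written["met_result"] = _write(met_summary, out / "met_result.csv")
    written["blues"] = _write(met.blues_, out / "blues.csv")
    for trait, anova in met.anova_tables_.items():
        written[f"anova_{trait}"] = _write(anova, out / f"anova_{trait}.csv")
    log.info("stage analyze: %d traits", len(met.results_))

    # stage 3: PC indices (built on the six measured traits, LD_AV excluded
    # from the PCA as a linear combination of LD1..LD3)
    pca_traits = [t for t in table.trait_names if t != "LD_AV"]
    builder = PCIndexBuilder(
        value_basis=config.value_basis, fixed_weights=config.fixed_weights
    )
    blues = met.blues_
    builder.fit(blues[pca_traits])
    scores = builder.transform(blues[pca_traits])
    model_df = pd.concat(
        [
            builder.model_.loadings.rename(columns=lambda c: f"loading_{c}"),
            pd.concat(
                {d.name: d.weights for d in builder.indices_}, axis=1
            ).rename(columns=lambda c: f"weight_{c}"),
        ],
        axis=1,
    ).rename_axis("trait")
    written["pca_model"] = _write(model_df, out / "pca_model.csv")
    written["scree"] = _write(builder.scree(), out / "scree.csv", index=False)
    written["index_scores"] = _write(scores, out / "index_scores.csv")
    log.info("stage index: retained %s", builder.model_.retained)

    # stage 4: selection
    schemes = _build_schemes(config.schemes)
    dropped = [
        s.name for s in schemes if s.kind == "index" and s.criterion not in scores.columns
    ]
    if dropped:
        log.warning("index scheme(s) %s not available (component not retained)", dropped)
        schemes = [s for s in schemes if s.name not in dropped]
    checks = config.checks if config.checks is not None else table.checks
    grand_pool = None
    if config.exclude_checks:
        grand_pool = [g for g in blues.index if g not in set(checks)]
    gains = gain_table(
        schemes,
        blues,
        met.heritability_,
        ks=config.ks,
        scores=scores,
        registry=registry,
        include_in_grand_mean=grand_pool,
    )
    written["gains"] = _write(gains, out / "gains.csv", index=False)

    top_frames, top_sets = [], {}
    k_top = max(config.ks)
    for scheme in schemes:
        ranking = _resolve_ranking(scheme, blues, scores, registry)
        top = select_top_k(ranking, min(k_top, len(ranking)))
        top_sets[scheme.name] = top
        frame = blues.loc[top].copy()
        frame.insert(0, "rank", range(1, len(top) + 1))
        frame.insert(0, "scheme", scheme.name)
        top_frames.append(frame.rename_axis("genotype").reset_index())
    written["topk"] = _write(pd.concat(top_frames, ignore_index=True), out / "topk.csv", index=False)

    if checks:
        rg_frames = []
        for scheme_name, top in top_sets.items():
            rg = relative_gain_table(
                [g for g in top if g not in set(checks)], checks, blues
            )
            rg.insert(0, "scheme", scheme_name)
            rg_frames.append(rg)
        written["relative_gains"] = _write(
            pd.concat(rg_frames, ignore_index=True), out / "relative_gains.csv", index=False
        )

    overlaps = scheme_overlap(top_sets)
    written["overlaps"] = _write(overlaps, out / "overlaps.csv", index=False)

    cutoff_counts = pd.DataFrame(
        [
            {
                "scheme": name,
                "trait": "GY",
                "cutoff": config.gy_cutoff,
                "count": threshold_count(top, blues, "GY", config.gy_cutoff, registry),
            }
            for name, top in top_sets.items()
            if "GY" in blues.columns
        ]
    )
    written["cutoff_counts"] = _write(cutoff_counts, out / "cutoff_counts.csv", index=False)
    log.info("stage select: %d schemes", len(schemes))

    # stage 5: heatmap matrices
    z = standardize(blues)
    for scheme in schemes:
        ranking = _resolve_ranking(scheme, blues, scores, registry)
        matrix = export_heatmap_matrix(ranking, 15, 5, z)
        written[f"heatmap_{scheme.name}"] = _write(matrix, out / f"heatmap_{scheme.name}.csv")

    manifest = {
        "seed": config.seed,
        "pcsel_version": __version__,
        "elapsed_seconds": round(time.perf_counter() - t0, 3),
        "outputs": {k: str(v) for k, v in written.items()},
        "config": {
            "value_basis": config.value_basis,
            "schemes": config.schemes,
            "ks": list(config.ks),
            "gy_cutoff": config.gy_cutoff,
            "exclude_checks": config.exclude_checks,
            "simulated": config.simulate is not None,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return written


def export_heatmap_matrix(
    ranking: list[str],
    k_top: int,
    k_bottom: int,
    z_blues: pd.DataFrame,
) -> pd.DataFrame:
    """Standardized BLUEs of the top-k and bottom-m genotypes of a ranking.

    Rows keep rank order (top block then bottom block); the values are the
    full-population standardized BLUEs restricted to those rows — no
    re-standardization over the subset.  Rendering is left to external
    heatmap tools.
    """
    n = len(ranking)
    if k_top + k_bottom > n:
        raise ValueError(
            f"k_top + k_bottom = {k_top + k_bottom} exceeds population size {n}"
        )
    chosen = ranking[:k_top] + (ranking[-k_bottom:] if k_bottom else [])
    matrix = z_blues.loc[chosen].copy()
    ranks = list(range(1, k_top + 1)) + list(range(n - k_bottom + 1, n + 1))
    matrix.insert(0, "rank", ranks)
    return matrix.rename_axis("genotype")
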