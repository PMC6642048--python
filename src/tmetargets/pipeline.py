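"""End-to-end orchestration: simulate -> co-expression -> complementarity ->
enrichment -> responder analysis, with a reproducibility manifest.

All randomness is confined to the synthetic-data generator and the
enrichment permutation null; both are driven deterministically from the
single master seed, so identical config + seed yields byte-identical output
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    CorrelationProfile,
    marker_correlation_profile,
    median_across_types,
    rank_genes,
)
from .complementarity import complementarity_table
from .enrichment import RankedList, preranked_gsea, results_to_frame
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    read_expression_tsv,
    read_responder_table,
    write_expression_tsv,
    write_gmt,
    write_responder_table,
    write_rnk,
)
from .responders import exclude_and_rerun
from .simulate import (
    GeneSpec,
    ResponderSimConfig,
    SimulationConfig,
    default_gene_specs,
    simulate_pan_cancer,
    simulate_responder_cohort,
)

__all__ = ["PipelineConfig", "run_full_pipeline", "write_table"]

logger = logging.getLogger("tmetargets.pipeline")


def _fmt6(v: float) -> str:
    """6-significant-digit table formatting ('NA' for missing)."""
    if pd.isna(v):
        return "NA"
    return f"{v:.6g}"


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Deterministic TSV table writer (header row, 6 significant digits)."""
    with open(Path(path), "w") as fh:
        fh.write(index_label + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in df.iterrows():
            cells = [
                _fmt6(v) if isinstance(v, (float, np.floating)) else str(v)
                for v in row
            ]
            fh.write(str(idx) + "\t" + "\t".join(cells) + "\n")


@dataclass
class PipelineConfig:
    """One config to drive the whole pipeline.

    Cohorts either come from ``cohort_dir`` (expression TSVs, one per
    cancer type) or are simulated from ``simulation``; likewise the
    responder cohort from ``responder_path`` or ``responder_sim``.
    """

    marker: str = "CD3E"
    pd1_gene: str = "PDCD1"
    ctla4_gene: str = "CTLA4"
    excluded_types: tuple[str, ...] = ()
    min_samples: int = 10
    simulation: SimulationConfig | None = None
    cohort_dir: str | None = None
    responder_sim: ResponderSimConfig | None = None
    responder_path: str | None = None
    gmt_path: str | None = None
    n_perm: int = 1000
    weight_exponent: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    excluded_samples: tuple[str, ...] = ()

    @classmethod
    def default_synthetic(
        cls,
        seed: int = 0,
        n_cancer_types: int | None = None,
        n_samples_per_type: int | None = None,
        n_signal: int = 40,
        n_null: int = 60,
    ) -> "PipelineConfig":
        sim_kwargs = {}
        if n_cancer_types is not None:
            sim_kwargs["n_cancer_types"] = n_cancer_types
        if n_samples_per_type is not None:
            sim_kwargs["n_samples_per_type"] = n_samples_per_type
        sim = SimulationConfig(
            gene_specs=default_gene_specs(n_signal=n_signal, n_null=n_null),
            seed=seed,
            **sim_kwargs,
        )
        return cls(simulation=sim, responder_sim=ResponderSimConfig(seed=seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "marker", "pd1_gene", "ctla4_gene", "min_samples", "cohort_dir",
            "responder_path", "gmt_path", "n_perm", "weight_exponent",
            "gsea_min_size", "gsea_max_size",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "excluded_types" in raw:
            kwargs["excluded_types"] = tuple(raw["excluded_types"])
        if "excluded_samples" in raw:
            kwargs["excluded_samples"] = tuple(raw["excluded_samples"])
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            specs = sim.pop("gene_specs", None)
            if specs is None:
                gene_specs = default_gene_specs(
                    n_signal=sim.pop("n_signal", 40), n_null=sim.pop("n_null", 60)
                )
            else:
                gene_specs = [GeneSpec(**s) for s in specs]
            kwargs["simulation"] = SimulationConfig(gene_specs=gene_specs, **sim)
        if "responder_sim" in raw:
            kwargs["responder_sim"] = ResponderSimConfig(**raw["responder_sim"])
        return cls(**kwargs)


def _load_cohorts(config: PipelineConfig, seed: int) -> dict[str, ExpressionMatrix]:
    if config.cohort_dir is not None:
        cohorts = {}
        for path in sorted(Path(config.cohort_dir).glob("*.tsv")):
            m = read_expression_tsv(path)
            cohorts[m.cancer_type] = m
        if not cohorts:
            raise ValueError(f"no .tsv cohort files in {config.cohort_dir}")
        return cohorts
    if config.simulation is None:
        raise ValueError("config needs either cohort_dir or simulation")
    sim = config.simulation
    if seed is not None:
        from dataclasses import replace

        sim = replace(sim, seed=seed)
    return simulate_pan_cancer(sim)


def _default_gene_sets(
    config: PipelineConfig, universe: Sequence[str], seed: int
) -> GeneSetCollection:
    """Toy gene-set collection for synthetic runs.

    One set of the most strongly infiltration-loaded genes (planted
    signal), one of the weaker signal tail, plus seeded random draws from
    the whole universe as negative controls.
    """
    signal = [g for g in universe if g.startswith("TGENE")]
    sets: list[GeneSet] = []
    if len(signal) >= 10:
        half = len(signal) // 2
        sets.append(GeneSet("TCELL_PROGRAM_TOP", "planted strong signal",
                            tuple(signal[:half])))
        sets.append(GeneSet("TCELL_PROGRAM_TAIL", "planted weak signal",
                            tuple(signal[half:])))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 911)))
    pool = np.array(sorted(universe), dtype=object)
    size = max(config.gsea_min_size, min(20, len(pool) // 4))
    for i in range(1, 4):
        members = tuple(rng.choice(pool, size=size, replace=False))
        sets.append(GeneSet(f"RANDOM_SET_{i}", "seeded random control", members))
    return GeneSetCollection(sets=sets)


def run_full_pipeline(
    config: PipelineConfig, outdir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Run every stage and write all artifacts into ``outdir``.

    Returns a name -> path mapping of the written artifacts. Any stage
    failure is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return name

    stage = "simulate/load cohorts"
    try:
        cohorts = _load_cohorts(config, seed)
        cohort_dir = outdir / "cohorts"
        cohort_dir.mkdir(exist_ok=True)
        for label in sorted(cohorts):
            write_expression_tsv(cohorts[label], cohort_dir / f"{label}.tsv")
        artifacts["cohorts"] = cohort_dir

        stage = "coexpression"
        _stage(stage)
        profiles: dict[str, CorrelationProfile] = {}
        for gene in (config.marker, config.pd1_gene, config.ctla4_gene):
            profiles[gene] = marker_correlation_profile(
                cohorts,
                marker=gene,
                min_samples=config.min_samples,
                excluded_types=config.excluded_types,
            )
            path = outdir / f"correlation_profile_{gene}.tsv"
            write_table(profiles[gene].correlations, path)
            artifacts[f"profile_{gene}"] = path
        ranked = rank_genes(median_across_types(profiles[config.marker]),
                            profile=profiles[config.marker])
        ranked_path = outdir / "ranked_genes.tsv"
        write_table(ranked.table, ranked_path)
        artifacts["ranked_genes"] = ranked_path
        rnk_path = outdir / "median_coexpression.rnk"
        write_rnk(ranked, rnk_path)
        artifacts["rnk"] = rnk_path

        stage = "complementarity"
        _stage(stage)
        for kind in ("pdcd1", "joint"):
            table = complementarity_table(
                profiles[config.marker],
                profiles[config.pd1_gene],
                profiles[config.ctla4_gene],
                score_kind=kind,
            )
            path = outdir / f"complementarity_{kind}.tsv"
            write_table(table.table, path)
            artifacts[f"complementarity_{kind}"] = path

        stage = "enrichment"
        _stage(stage)
        if config.gmt_path is not None:
            gene_sets: GeneSetCollection | str = config.gmt_path
        else:
            gene_sets = _default_gene_sets(config, ranked.table.index, seed)
            write_gmt(gene_sets, outdir / "gene_sets.gmt")
            artifacts["gene_sets"] = outdir / "gene_sets.gmt"
        results = preranked_gsea(
            RankedList.from_series(ranked.medians.dropna()),
            gene_sets,
            n_perm=config.n_perm,
            weight_exponent=config.weight_exponent,
            seed=seed,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
        )
        gsea_path = outdir / "enrichment_results.tsv"
        frame = results_to_frame(results)
        write_table(frame.set_index("name"), gsea_path, index_label="name")
        artifacts["enrichment"] = gsea_path

        stage = "responder analysis"
        _stage(stage)
        if config.responder_path is not None:
            cohort = read_responder_table(config.responder_path)
        elif config.responder_sim is not None:
            from dataclasses import replace

            cohort = simulate_responder_cohort(
                replace(config.responder_sim, seed=seed)
            )
            write_responder_table(cohort, outdir / "responder_cohort.tsv")
            artifacts["responder_cohort"] = outdir / "responder_cohort.tsv"
        else:
            cohort = None
        if cohort is not None:
            excluded = list(config.excluded_samples)
            if not excluded and cohort.outlier_id is not None:
                excluded = [cohort.outlier_id]
            rerun = exclude_and_rerun(cohort, excluded)
            resp_path = outdir / "responder_comparison.json"
            resp_path.write_text(json.dumps(_comparison_dict(rerun), indent=2) + "\n")
            artifacts["responder_comparison"] = resp_path
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tool": "tmetargets",
        "version": __version__,
        "seed": seed,
        "marker": config.marker,
        "checkpoints": [config.pd1_gene, config.ctla4_gene],
        "excluded_types": list(config.excluded_types),
        "min_samples": config.min_samples,
        "n_perm": config.n_perm,
        "weight_exponent": config.weight_exponent,
        "artifacts": {k: str(v.relative_to(outdir)) for k, v in artifacts.items()},
    }
    if config.simulation is not None:
        manifest["simulation"] = {
            "n_cancer_types": config.simulation.n_cancer_types,
            "n_samples_per_type": config.simulation.n_samples_per_type,
            "n_genes": len(config.simulation.gene_specs),
            "missing_rate": config.simulation.missing_rate,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    artifacts["manifest"] = outdir / "manifest.json"
    return artifacts


def _summary_dict(comp) -> dict:
    def grp(g):
        return {
            "label": g.label,
            "n": g.n,
            "slope": g.fit.slope,
            "intercept": g.fit.intercept,
            "r": g.fit.r_value,
            "r_squared": g.fit.r_squared,
        }

    return {
        "responders": grp(comp.responders),
        "nonresponders": grp(comp.nonresponders),
        "mann_whitney_u": comp.residual_test.u_statistic,
        "pvalue": comp.residual_test.pvalue,
        "test_method": comp.residual_test.method,
        "lower_residual_group": comp.lower_residual_group,
    }


def _comparison_dict(rerun) -> dict:
    return {
        "excluded_sample_ids": list(rerun.excluded_sample_ids),
        "full_cohort": _summary_dict(rerun.full),
        "after_exclusion": _summary_dict(rerun.reduced),
    }
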