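"""Latent-factor simulation of pan-cancer cohorts and responder cohorts.

Every downstream statistic in this package is exercised against synthetic
data with planted, analytically known correlation structure. The bulk
generator is a two-factor linear-Gaussian model: per sample i a latent
T-cell infiltration level f_i and an independent latent PD-1 program level
g_i are drawn from standard normals, and gene g's expression is

    x_gi = lambda_g * f_i + kappa_g * g_i + eps_gi,   eps_gi ~ N(0, sigma_g^2)

The marker gene (CD3E stand-in) is the noiseless factor itself
(lambda = 1, kappa = 0, sigma = 0), so the population correlation of any
gene with the marker has the closed form

    corr(x_g, marker) = lambda_g / sqrt(lambda_g^2 + kappa_g^2 + sigma_g^2)

which is the recovery target for the co-expression ranking. A PDCD1
stand-in is a gene with both lambda and kappa large: it tracks infiltration
but also carries the second axis, which is exactly what the complementarity
score penalises.

The responder generator draws marker expression (CD3E, TPM-like) from a
log-normal and couples checkpoint expression linearly with group-specific
noise — tight for responders, loose for non-responders — optionally
planting one very-high-expression responder outlier.

Pearson correlation is invariant to per-gene positive affine transforms, so
the unit scale of the bulk model is irrelevant to every statistic computed
from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NONRESPONDER, RESPONDER, ExpressionMatrix, ResponderCohort

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "ResponderSimConfig",
    "simulate_cancer_cohort",
    "simulate_pan_cancer",
    "simulate_responder_cohort",
    "zscore_normalize",
    "default_gene_specs",
]

#: Cohort scale of the emulated pan-cancer study: 31 tumor types, 9601
#: samples total (~310 per type).
DEFAULT_N_TYPES = 31
DEFAULT_N_SAMPLES = 310


@dataclass(frozen=True)
class GeneSpec:
    """Loadings of one simulated gene.

    tcell_loading (lambda): coupling to the latent infiltration factor.
    pd1_axis_loading (kappa): coupling to the latent PD-1 program factor.
    noise_sd (sigma): independent Gaussian noise, >= 0.
    """

    symbol: str
    tcell_loading: float
    pd1_axis_loading: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0 for gene {self.symbol!r}")

    @property
    def population_marker_correlation(self) -> float:
        """Closed-form corr with the noiseless-marker factor."""
        denom = np.sqrt(
            self.tcell_loading**2 + self.pd1_axis_loading**2 + self.noise_sd**2
        )
        if denom == 0:
            return float("nan")
        return self.tcell_loading / denom


@dataclass
class SimulationConfig:
    """Pan-cancer simulation: cohort sizes, gene loadings, marker, seed."""

    gene_specs: list[GeneSpec]
    n_cancer_types: int = DEFAULT_N_TYPES
    n_samples_per_type: int = DEFAULT_N_SAMPLES
    marker: str = "CD3E"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer_types < 1:
            raise ValueError("n_cancer_types must be >= 1")
        if self.n_samples_per_type < 1:
            raise ValueError("n_samples_per_type must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        symbols = [g.symbol for g in self.gene_specs]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate gene symbols in gene_specs")
        markers = [g for g in self.gene_specs if g.symbol == self.marker]
        if len(markers) != 1:
            raise ValueError(
                f"exactly one gene must be the marker {self.marker!r}; "
                f"found {len(markers)}"
            )
        m = markers[0]
        if (m.tcell_loading, m.pd1_axis_loading, m.noise_sd) != (1.0, 0.0, 0.0):
            raise ValueError(
                "marker gene must be the noiseless infiltration factor "
                "(tcell_loading=1, pd1_axis_loading=0, noise_sd=0)"
            )


@dataclass
class ResponderSimConfig:
    """Responder-cohort simulation emulating the 26-patient melanoma cohort.

    14 responders (10 partial + 4 complete) vs 12 non-responders; PDCD1 is
    linearly coupled to CD3E with group-specific noise, tighter in
    responders; one very-high-expression responder outlier is planted by
    default. CD3E draws are log-normal (TPM-like, strictly positive) and
    PDCD1 is clamped at zero.
    """

    n_responders: int = 14
    n_nonresponders: int = 12
    slope: float = 0.6
    intercept: float = 1.0
    responder_noise_sd: float = 1.0
    nonresponder_noise_sd: float = 25.0
    cd3e_meanlog: float = 3.0
    cd3e_sdlog: float = 1.0
    include_outlier: bool = True
    outlier_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("cohort sizes must be positive")
        if self.responder_noise_sd < 0 or self.nonresponder_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.outlier_factor < 5.0 and self.include_outlier:
            raise ValueError("outlier_factor must be >= 5")


def simulate_cancer_cohort(
    config: SimulationConfig, type_label: str, seed: int | np.random.SeedSequence
) -> ExpressionMatrix:
    """Draw one cancer-type cohort from the two-factor model."""
    n = config.n_samples_per_type
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)  # latent T-cell infiltration
    g = rng.standard_normal(n)  # latent PD-1 program axis
    rows = np.empty((len(config.gene_specs), n))
    for i, spec in enumerate(config.gene_specs):
        rows[i] = spec.tcell_loading * f + spec.pd1_axis_loading * g
        if spec.noise_sd > 0:
            rows[i] += rng.normal(0.0, spec.noise_sd, size=n)
    if config.missing_rate > 0:
        mask = rng.random(rows.shape) < config.missing_rate
        rows[mask] = np.nan
    samples = [f"{type_label}-S{i:04d}" for i in range(1, n + 1)]
    data = pd.DataFrame(rows, index=[s.symbol for s in config.gene_specs],
                        columns=samples)
    return ExpressionMatrix(cancer_type=type_label, data=data)


def _type_seed(master_seed: int, label: str, sorted_labels: Sequence[str]
               ) -> np.random.SeedSequence:
    """Per-type seed: SeedSequence((master, stable index of sorted label)).

    Independent of cohort iteration/insertion order.
    """
    return np.random.SeedSequence((master_seed, sorted_labels.index(label)))


def simulate_pan_cancer(
    config: SimulationConfig, type_labels: Sequence[str] | None = None
) -> dict[str, ExpressionMatrix]:
    """One cohort per cancer type, keyed by label, deterministically seeded."""
    if type_labels is None:
        type_labels = [f"CT{i:02d}" for i in range(1, config.n_cancer_types + 1)]
    labels = list(type_labels)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate cancer-type labels")
    if len(labels) != config.n_cancer_types:
        raise ValueError(
            f"got {len(labels)} labels for {config.n_cancer_types} cancer types"
        )
    ordered = sorted(labels)
    return {
        label: simulate_cancer_cohort(config, label, _type_seed(config.seed, label, ordered))
        for label in labels
    }


def simulate_responder_cohort(config: ResponderSimConfig) -> ResponderCohort:
    """Draw a labelled responder/non-responder cohort with linear coupling."""
    rng = np.random.default_rng(config.seed)
    records: list[tuple[str, str, float, float]] = []
    for label, n_group, sd in (
        (RESPONDER, config.n_responders, config.responder_noise_sd),
        (NONRESPONDER, config.n_nonresponders, config.nonresponder_noise_sd),
    ):
        cd3e = rng.lognormal(config.cd3e_meanlog, config.cd3e_sdlog, size=n_group)
        pdcd1 = config.intercept + config.slope * cd3e + rng.normal(0, sd, size=n_group)
        pdcd1 = np.maximum(pdcd1, 0.0)  # TPM values are non-negative
        prefix = "R" if label == RESPONDER else "NR"
        for i in range(n_group):
            records.append((f"{prefix}{i + 1:02d}", label, cd3e[i], pdcd1[i]))

    df = pd.DataFrame(
        records, columns=["sample_id", "response", "CD3E_TPM", "PDCD1_TPM"]
    ).set_index("sample_id")

    outlier_id = None
    if config.include_outlier:
        outlier_id = "R01"
        k = config.outlier_factor
        cd3e_out = k * df["CD3E_TPM"].max()
        pdcd1_out = k * df["PDCD1_TPM"].max()
        if config.slope > 0:
            # keep the outlier on the coupling line while clearing k x both
            # column maxima, so a noiseless responder group stays exactly linear
            cd3e_out = max(cd3e_out, (pdcd1_out - config.intercept) / config.slope)
            pdcd1_out = config.intercept + config.slope * cd3e_out
        df.loc[outlier_id, "CD3E_TPM"] = cd3e_out
        df.loc[outlier_id, "PDCD1_TPM"] = pdcd1_out
    return ResponderCohort(data=df, outlier_id=outlier_id)


def zscore_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene to mean 0, sample SD 1 over non-missing entries.

    Genes with fewer than two non-missing values or zero variance are
    emitted all-missing with a warning. Pearson correlations are invariant
    to this per-gene affine rescaling.
    """
    values = matrix.data.to_numpy(dtype=float).copy()
    degenerate: list[str] = []
    for i, gene in enumerate(matrix.genes):
        row = values[i]
        finite = np.isfinite(row)
        n = finite.sum()
        sd = row[finite].std(ddof=1) if n >= 2 else 0.0
        if n < 2 or sd == 0:
            values[i] = np.nan
            degenerate.append(gene)
            continue
        mean = row[finite].mean()
        values[i] = (row - mean) / sd
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} gene(s) with <2 values or zero variance set to "
            f"missing: {', '.join(degenerate[:5])}"
            + ("..." if len(degenerate) > 5 else ""),
            UserWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(
        cancer_type=matrix.cancer_type,
        data=pd.DataFrame(values, index=matrix.genes, columns=matrix.samples),
    )


def default_gene_specs(
    n_signal: int = 40, n_null: int = 60, include_checkpoints: bool = True
) -> list[GeneSpec]:
    """A study-shaped default gene panel.

    The marker (CD3E) is the noiseless factor. PDCD1 and CTLA4 stand-ins
    load on both the infiltration factor and the PD-1 program axis, so
    their marker correlations are high but their complementarity is poor —
    the configuration the scoring is designed to detect. The remaining
    signal genes load only on infiltration with evenly spaced population
    marker correlations in [0.5, 0.95]; null genes are pure noise.
    """
    specs = [GeneSpec("CD3E", 1.0, 0.0, 0.0)]
    if include_checkpoints:
        specs.append(GeneSpec("PDCD1", 0.80, 0.55, 0.30))
        specs.append(GeneSpec("CTLA4", 0.70, 0.35, 0.50))
    targets = np.linspace(0.95, 0.50, n_signal)
    for i, rho in enumerate(targets, start=1):
        # kappa = 0: sigma chosen so corr(x, marker) = rho exactly
        sigma = float(np.sqrt(1.0 / rho**2 - 1.0))
        specs.append(GeneSpec(f"TGENE{i:03d}", 1.0, 0.0, round(sigma, 6)))
    for i in range(1, n_null + 1):
        specs.append(GeneSpec(f"NULL{i:04d}", 0.0, 0.0, 1.0))
    return specs
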