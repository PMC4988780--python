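"""Synthetic two-cohort study generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: two cohorts
(defaults 750 and 590 subjects) genotyped on a shared variant panel with
Hardy-Weinberg genotypes over a uniform MAF spectrum and optional
block-copy linkage disequilibrium; biomarkers built from a unit-variance
latent Gaussian trait (covariate effects + additive dosage effects +
optional latent batch factor + noise) mapped to a skewed assay scale by
exponentiation, with the LLOQ placed at a configured quantile so the
censored fraction — and hence the triage class — is controlled exactly;
and disease phenotypes generated under any of the five directed trio
models (causal, reactive, independent, collide, complete) or a null graph.

Effect sizes are specified as latent-variance fractions: a causal variant
with fraction f and allele frequency p gets dosage slope
sqrt(f / (2 p (1 - p))), so a single SNP can be budgeted to explain any
share of an analyte's variance. All randomness flows from the single
config seed through numpy SeedSequence spawning; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .types import (
    AnalyteMeta,
    BiomarkerPanel,
    CohortBundle,
    CovariateTable,
    GenotypeMatrix,
    PhenotypeTable,
    VariantInfo,
    CELL_COUNT_COLUMNS,
)

__all__ = [
    "LdBlock",
    "AnalyteSpec",
    "TrioSpec",
    "SimConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_biomarkers",
    "simulate_study",
    "default_config",
]

TRIO_GRAPHS = ("causal", "reactive", "independent", "collide", "complete", "null")
_VARIANTS_PER_CHROMOSOME = 100
_POSITION_SPACING = 10_000


@dataclass
class LdBlock:
    """A run of consecutive variants copying the block seed's haplotypes.

    Members share the seed's allele frequency; each member haplotype copies
    the seed allele with probability ``copy_prob`` (pairwise r^2 is
    approximately copy_prob^2, exactly 1 at copy_prob=1).
    """

    size: int
    copy_prob: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("LD block needs >= 2 variants")
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ValueError("copy probability must lie in [0, 1]")


@dataclass
class AnalyteSpec:
    """Generative recipe for one analyte's unit-variance latent trait."""

    analyte_id: str
    causal: list[tuple[str, float]] = field(default_factory=list)  # (variant_id, variance frac)
    covariate_frac: float = 0.10
    batch_frac: float = 0.0
    censor_quantile: float = 0.0  # LLOQ placed at this raw-scale quantile
    cellcount_frac: dict[str, float] = field(default_factory=dict)
    gene_chromosome: str = ""
    gene_start: int = 0
    gene_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censor_quantile < 1.0:
            raise ValueError(
                f"{self.analyte_id}: censoring quantile must lie in [0, 1)"
            )
        total = (
            sum(f for _, f in self.causal)
            + self.covariate_frac
            + self.batch_frac
            + sum(self.cellcount_frac.values())
        )
        if total >= 1.0:
            raise ValueError(f"{self.analyte_id}: variance fractions sum to {total} >= 1")


@dataclass
class TrioSpec:
    """Generative recipe for one (SNP, analyte, phenotype) trio."""

    snp: str
    analyte: str
    phenotype: str
    graph: str
    snp_to_pheno: float = 0.35  # dosage-scale slope g -> D
    bio_to_pheno: float = 0.60  # latent-scale slope B -> D
    pheno_to_bio: float = 0.60  # standardized-D loading on regenerated B
    cov_frac: float = 0.10
    binary: bool = False

    def __post_init__(self) -> None:
        if self.graph not in TRIO_GRAPHS:
            raise ValueError(f"unknown trio graph {self.graph!r}")


@dataclass
class SimConfig:
    seed: int
    n1: int = 750
    n2: int = 590
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_sites: int = 3
    ld_blocks: list[LdBlock] = field(default_factory=list)
    missing_rate: float = 0.0
    cell_counts: bool = False
    analytes: list[AnalyteSpec] = field(default_factory=list)
    trios: list[TrioSpec] = field(default_factory=list)
    effect_multiplier: tuple[float, float] = (1.0, 1.0)  # per-cohort heterogeneity knob

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if sum(b.size for b in self.ld_blocks) > self.n_variants:
            raise ValueError("LD blocks exceed the variant panel")
        seen_analytes = set()
        for t in self.trios:
            if t.analyte in seen_analytes:
                raise ValueError(f"analyte {t.analyte} appears in two trio specs")
            seen_analytes.add(t.analyte)
        seen_ph = set()
        for t in self.trios:
            if t.phenotype in seen_ph:
                raise ValueError(f"phenotype {t.phenotype} appears in two trio specs")
            seen_ph.add(t.phenotype)
        ids = [a.analyte_id for a in self.analytes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate analyte ids")


@dataclass
class TruthTable:
    """Planted ground truth: per-analyte causal slopes (latent scale),
    per-trio generating graph and coefficients, per-cohort batch values."""

    maf: dict[str, float]
    analyte_slopes: dict[str, dict[str, float]]  # analyte -> variant -> latent slope
    trio_graphs: dict[tuple[str, str, str], dict]
    batch: dict[str, np.ndarray]
    phenotype_latent: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# panel and genotypes


def _panel(config: SimConfig, rng: np.random.Generator):
    """Shared variant metadata, MAFs and LD-block membership."""
    m = config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    block_seed = np.full(m, -1)  # index of the block seed variant, -1 = independent
    copy_prob = np.zeros(m)
    i = 0
    for blk in config.ld_blocks:
        mafs[i:i + blk.size] = mafs[i]  # members share the seed frequency
        block_seed[i + 1:i + blk.size] = i
        copy_prob[i + 1:i + blk.size] = blk.copy_prob
        i += blk.size
    variants = []
    for j in range(m):
        chrom = str(1 + j // _VARIANTS_PER_CHROMOSOME)
        pos = 1 + (j % _VARIANTS_PER_CHROMOSOME) * _POSITION_SPACING
        variants.append(VariantInfo(f"rs{j + 1:06d}", chrom, pos, "A", "G"))
    return variants, mafs, block_seed, copy_prob


def _cohort_seeds(config: SimConfig):
    ss = np.random.SeedSequence(config.seed)
    panel_ss, c1, c2 = ss.spawn(3)
    return panel_ss, (c1.spawn(5), c2.spawn(5))  # genotype, covariate, batch, biomarker, phenotype


def simulate_genotypes(config: SimConfig, cohort: int, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """HWE genotypes for one cohort (1 or 2) on the shared variant panel."""
    panel_ss, cohort_seeds = _cohort_seeds(config)
    variants, mafs, block_seed, copy_prob = _panel(config, np.random.default_rng(panel_ss))
    if rng is None:
        rng = np.random.default_rng(cohort_seeds[cohort - 1][0])
    n = config.n1 if cohort == 1 else config.n2
    hap = np.empty((n, 2, config.n_variants), dtype=bool)
    for j in range(config.n_variants):
        fresh = rng.random((n, 2)) < mafs[j]
        s = block_seed[j]
        if s < 0:
            hap[:, :, j] = fresh
        else:
            copy = rng.random((n, 2)) < copy_prob[j]
            hap[:, :, j] = np.where(copy, hap[:, :, s], fresh)
    dosage = hap.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    subjects = [f"C{cohort}S{i:05d}" for i in range(n)]
    return GenotypeMatrix(subjects=subjects, variants=variants, dosage=dosage)


# ---------------------------------------------------------------------------
# covariates


_CELL_COUNT_MOMENTS = {
    "neutrophil": (4.5, 1.5),
    "lymphocyte": (1.8, 0.6),
    "monocyte": (0.5, 0.15),
    "eosinophil": (0.2, 0.1),
    "basophil": (0.05, 0.02),
    "red_blood_cells": (4.7, 0.45),
    "platelet": (250.0, 60.0),
}


def simulate_covariates(config: SimConfig, cohort: int, rng: np.random.Generator | None = None) -> CovariateTable:
    """Clinical covariates resembling an older smoking cohort: age ~ N(66, 8),
    BMI ~ N(28, 5), pack-years truncated N(50, 25) at >= 10, 30% current
    smokers, balanced sex, uniform sites."""
    if rng is None:
        _, cohort_seeds = _cohort_seeds(config)
        rng = np.random.default_rng(cohort_seeds[cohort - 1][1])
    n = config.n1 if cohort == 1 else config.n2
    a = (10.0 - 50.0) / 25.0
    data = pd.DataFrame(
        {
            "site": [f"S{rng.integers(config.n_sites) + 1}" for _ in range(n)],
            "sex": rng.integers(0, 2, size=n),
            "age": rng.normal(66.0, 8.0, size=n),
            "bmi": rng.normal(28.0, 5.0, size=n),
            "pack_years": truncnorm.rvs(a, np.inf, loc=50.0, scale=25.0, size=n, random_state=rng),
            "current_smoker": (rng.random(n) < 0.3).astype(int),
        }
    )
    if config.cell_counts:
        for name in CELL_COUNT_COLUMNS:
            mu, sd = _CELL_COUNT_MOMENTS[name]
            data[name] = np.maximum(rng.normal(mu, sd, size=n), mu / 10)
    subjects = [f"C{cohort}S{i:05d}" for i in range(n)]
    return CovariateTable(subjects=subjects, data=data)


# ---------------------------------------------------------------------------
# biomarker latents and panel assembly


def _standardized(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based normal scores, Phi^-1((r - 1/2)/n).

    Disease phenotypes that respond to a biomarker are generated from the
    biomarker's normal scores — the scale on which the analysis models the
    trait — so the planted conditional-independence structure is preserved
    exactly through the rank-based measurement transform.
    """
    from scipy.special import ndtri
    from scipy.stats import rankdata

    return ndtri((rankdata(x) - 0.5) / x.size)


def _analyte_latent(
    spec: AnalyteSpec,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    batch: np.ndarray,
    mafs: dict[str, float],
    rng: np.random.Generator,
    effect_multiplier: float = 1.0,
    include_genetics: bool = True,
) -> tuple[np.ndarray, dict[str, float]]:
    """Unit-variance latent trait and the realized per-variant slopes."""
    n = genotypes.n_subjects
    latent = np.zeros(n)
    slopes: dict[str, float] = {}
    genetic_frac = 0.0
    if include_genetics:
        for vid, frac in spec.causal:
            p = mafs[vid]
            slope = effect_multiplier * np.sqrt(frac / (2.0 * p * (1.0 - p)))
            dos = genotypes.dosage_of(vid)
            dos = np.where(np.isfinite(dos), dos, 2.0 * p)
            latent += slope * (dos - 2.0 * p)
            slopes[vid] = float(slope)
            genetic_frac += frac * effect_multiplier**2
    cov = covariates.data
    if spec.covariate_frac > 0:
        raw = (
            0.5 * _standardized(cov["age"].to_numpy(dtype=float))
            + 0.3 * _standardized(cov["bmi"].to_numpy(dtype=float))
            + 0.2 * (cov["sex"].to_numpy(dtype=float) - 0.5) * 2.0
        )
        latent += np.sqrt(spec.covariate_frac) * _standardized(raw)
    for name, frac in spec.cellcount_frac.items():
        latent += np.sqrt(frac) * _standardized(cov[name].to_numpy(dtype=float))
    if spec.batch_frac > 0:
        latent += np.sqrt(spec.batch_frac) * batch
    resid = 1.0 - genetic_frac - spec.covariate_frac - spec.batch_frac - sum(
        spec.cellcount_frac.values()
    )
    latent += rng.normal(0.0, np.sqrt(max(resid, 1e-6)), size=n)
    return latent, slopes


_RAW_SCALE_OFFSET = np.log(100.0)  # arbitrary assay units, ~100 at the latent mean


def _panel_from_latents(
    specs: list[AnalyteSpec], latents: dict[str, np.ndarray], subjects: list[str]
) -> BiomarkerPanel:
    metas, cols, masks = [], [], []
    for spec in specs:
        raw = np.exp(_RAW_SCALE_OFFSET + latents[spec.analyte_id])
        if spec.censor_quantile > 0:
            lloq = float(np.quantile(raw, spec.censor_quantile))
        else:
            lloq = float(raw.min() / 2.0)
        metas.append(
            AnalyteMeta(
                analyte_id=spec.analyte_id,
                gene_symbol=spec.analyte_id,
                gene_chromosome=spec.gene_chromosome,
                gene_start=spec.gene_start,
                gene_end=spec.gene_end,
                lloq=lloq,
            )
        )
        cols.append(raw)
        masks.append(raw < lloq)
    n = len(subjects)
    return BiomarkerPanel(
        subjects=list(subjects),
        analytes=metas,
        raw=np.column_stack(cols) if cols else np.empty((n, 0)),
        below_lloq=np.column_stack(masks) if masks else np.empty((n, 0), dtype=bool),
    )


def simulate_biomarkers(
    config: SimConfig,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    cohort: int,
) -> tuple[BiomarkerPanel, TruthTable]:
    """Standalone biomarker panel for one cohort (no trio feedback)."""
    panel_ss, cohort_seeds = _cohort_seeds(config)
    variants, mafs_arr, *_ = _panel(config, np.random.default_rng(panel_ss))
    mafs = {v.variant_id: float(p) for v, p in zip(variants, mafs_arr)}
    seeds = cohort_seeds[cohort - 1]
    batch = np.random.default_rng(seeds[2]).normal(size=genotypes.n_subjects)
    rng = np.random.default_rng(seeds[3])
    mult = config.effect_multiplier[cohort - 1]
    latents, slopes = {}, {}
    for spec in config.analytes:
        latents[spec.analyte_id], slopes[spec.analyte_id] = _analyte_latent(
            spec, genotypes, covariates, batch, mafs, rng, mult
        )
    panel = _panel_from_latents(config.analytes, latents, genotypes.subjects)
    truth = TruthTable(
        maf=mafs,
        analyte_slopes=slopes,
        trio_graphs={},
        batch={f"cohort{cohort}": batch},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# phenotypes under the trio graphs


def _phenotype_from_latent(name: str, d_latent: np.ndarray, binary: bool, rng) -> np.ndarray:
    if binary:
        return (rng.random(d_latent.size) < expit(-0.8 + 1.2 * d_latent)).astype(float)
    if name == "emphysema_pct":
        return np.exp(1.8 + 0.8 * d_latent)  # skewed; log(x + 0.1) restores linearity
    if name == "fev1pp":
        return 70.0 + 20.0 * d_latent
    return d_latent.copy()


def _generate_trio(
    spec: TrioSpec,
    aspec: AnalyteSpec,
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    batch: np.ndarray,
    mafs: dict[str, float],
    latents: dict[str, np.ndarray],
    rng: np.random.Generator,
    effect_multiplier: float,
) -> tuple[np.ndarray, dict]:
    """Disease latent for one trio; may regenerate the analyte latent in
    ``latents`` for graphs where the biomarker responds to disease or has
    no genetic edge."""
    p = mafs[spec.snp]
    dos = genotypes.dosage_of(spec.snp)
    dos = np.where(np.isfinite(dos), dos, 2.0 * p)
    g_c = dos - 2.0 * p
    n = g_c.size

    cov = covariates.data
    cov_raw = 0.5 * _standardized(cov["age"].to_numpy(dtype=float)) + 0.3 * _standardized(
        cov["bmi"].to_numpy(dtype=float)
    )
    C = np.sqrt(spec.cov_frac) * _standardized(cov_raw)

    def noise(explained: float) -> np.ndarray:
        return rng.normal(0.0, np.sqrt(max(1.0 - explained, 0.05)), size=n)

    B = latents[spec.analyte]
    a_g, a_b, lam = spec.snp_to_pheno, spec.bio_to_pheno, spec.pheno_to_bio
    var_g = 2.0 * p * (1.0 - p)

    if spec.graph == "causal":
        d = a_b * _normal_scores(B) + C + noise(a_b**2 + spec.cov_frac)
    elif spec.graph == "independent":
        d = a_g * g_c + C + noise(a_g**2 * var_g + spec.cov_frac)
    elif spec.graph == "complete":
        d = a_g * g_c + a_b * _normal_scores(B) + C + noise(
            a_g**2 * var_g + a_b**2 + spec.cov_frac
        )
    elif spec.graph in ("reactive", "collide", "null"):
        if spec.graph == "reactive":
            d = a_g * g_c + C + noise(a_g**2 * var_g + spec.cov_frac)
            base, _ = _analyte_latent(
                aspec, genotypes, covariates, batch, mafs, rng,
                effect_multiplier, include_genetics=False,
            )
            latents[spec.analyte] = np.sqrt(1.0 - lam**2) * base + lam * _standardized(d)
        elif spec.graph == "collide":
            d = C + noise(spec.cov_frac)
            latents[spec.analyte] = (
                np.sqrt(1.0 - lam**2) * B + lam * _standardized(d)
            )
        else:  # null: no edges anywhere in the trio
            d = C + noise(spec.cov_frac)
            base, _ = _analyte_latent(
                aspec, genotypes, covariates, batch, mafs, rng,
                effect_multiplier, include_genetics=False,
            )
            latents[spec.analyte] = base
    else:  # pragma: no cover
        raise ValueError(spec.graph)
    coeffs = {
        "graph": spec.graph,
        "snp_to_pheno": a_g if spec.graph in ("reactive", "independent", "complete") else 0.0,
        "bio_to_pheno": a_b if spec.graph in ("causal", "complete") else 0.0,
        "pheno_to_bio": lam if spec.graph in ("reactive", "collide") else 0.0,
    }
    return d, coeffs


def simulate_study(config: SimConfig) -> tuple[CohortBundle, CohortBundle, TruthTable]:
    """Generate both cohorts on a shared panel with shared true effects."""
    panel_ss, cohort_seed_pairs = _cohort_seeds(config)
    variants, mafs_arr, *_ = _panel(config, np.random.default_rng(panel_ss))
    mafs = {v.variant_id: float(p) for v, p in zip(variants, mafs_arr)}
    aspec_by_id = {a.analyte_id: a for a in config.analytes}
    for t in config.trios:
        if t.analyte not in aspec_by_id:
            raise ValueError(f"trio references unknown analyte {t.analyte}")
        if t.snp not in mafs:
            raise ValueError(f"trio references unknown variant {t.snp}")

    truth = TruthTable(maf=mafs, analyte_slopes={}, trio_graphs={}, batch={})
    bundles = []
    for cohort in (1, 2):
        seeds = cohort_seed_pairs[cohort - 1]
        geno = simulate_genotypes(config, cohort, np.random.default_rng(seeds[0]))
        cov = simulate_covariates(config, cohort, np.random.default_rng(seeds[1]))
        batch = np.random.default_rng(seeds[2]).normal(size=geno.n_subjects)
        bio_rng = np.random.default_rng(seeds[3])
        ph_rng = np.random.default_rng(seeds[4])
        mult = config.effect_multiplier[cohort - 1]

        latents = {}
        for spec in config.analytes:
            latents[spec.analyte_id], slopes = _analyte_latent(
                spec, geno, cov, batch, mafs, bio_rng, mult
            )
            if cohort == 1:
                truth.analyte_slopes[spec.analyte_id] = slopes

        ph_cols: dict[str, np.ndarray] = {}
        for t in config.trios:
            d_latent, coeffs = _generate_trio(
                t, aspec_by_id[t.analyte], geno, cov, batch, mafs, latents, ph_rng, mult
            )
            ph_cols[t.phenotype] = _phenotype_from_latent(t.phenotype, d_latent, t.binary, ph_rng)
            truth.trio_graphs[(t.snp, t.analyte, t.phenotype)] = coeffs
            truth.phenotype_latent[(f"cohort{cohort}", t.phenotype)] = d_latent
        # untargeted phenotypes: covariate-driven null columns
        defaults = {"emphysema_pct": False, "fev1pp": False,
                    "chronic_bronchitis": True, "exacerbation_any": True}
        for name, is_binary in defaults.items():
            if name not in ph_cols:
                d0 = 0.3 * _standardized(cov.data["age"].to_numpy(dtype=float)) + ph_rng.normal(
                    0.0, np.sqrt(0.91), size=geno.n_subjects
                )
                ph_cols[name] = _phenotype_from_latent(name, d0, is_binary, ph_rng)

        panel = _panel_from_latents(config.analytes, latents, geno.subjects)
        phen = PhenotypeTable(
            subjects=geno.subjects, data=pd.DataFrame(ph_cols)
        )
        truth.batch[f"cohort{cohort}"] = batch
        bundles.append(
            CohortBundle(
                name=f"cohort{cohort}",
                genotypes=geno,
                biomarkers=panel,
                covariates=cov,
                phenotypes=phen,
            )
        )
    return bundles[0], bundles[1], truth


def default_config(seed: int, **overrides) -> SimConfig:
    """Study-shaped default scenario: two cohorts of 750 and 590 subjects,
    a 100-variant panel, one strong local pQTL analyte (45% of latent
    variance, the scale of the largest single-SNP effects such a panel
    shows), one moderately censored tobit analyte with a 25%-variance
    pQTL, and one null analyte."""
    cfg = dict(
        seed=seed,
        analytes=[
            AnalyteSpec(
                "IL6R_like", causal=[("rs000005", 0.45)], covariate_frac=0.10,
                gene_chromosome="1", gene_start=40_001, gene_end=45_000,
            ),
            AnalyteSpec(
                "SPD_like", causal=[("rs000020", 0.25)], covariate_frac=0.10,
                censor_quantile=0.30,
                gene_chromosome="1", gene_start=190_001, gene_end=195_000,
            ),
            AnalyteSpec("NULL_like", causal=[], covariate_frac=0.10),
        ],
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
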