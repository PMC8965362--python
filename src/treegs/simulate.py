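"""Synthetic polycross trial generator with known ground truth.

Emulates a conifer progeny trial: maternal families sired by a pollen polymix,
offspring planted on several sites in randomized complete blocks, genotyped at
biallelic SNPs, and phenotyped for correlated additive traits.  A heritable
drought-year growth multiplier drives the tree-ring module, and a daily weather
generator produces series containing dry summers, so that every downstream
stage (relationship matrices, REML, cross-validation, drought components,
selection) can be tested against known truth.

All generators are pure functions of (config, seed); sub-streams are derived
from the dataset seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .dendro import RingSeries, bai_to_width
from .relatedness import GenotypeMatrix, Pedigree

__all__ = ["SimConfig", "TruthSet", "SimulatedDataset", "simulate_founders",
           "simulate_polycross", "drop_genotypes", "simulate_traits",
           "simulate_ring_series", "simulate_climate", "simulate_dataset"]

# fixed sub-stream offsets (one seeded generator stream per dataset)
_STREAM = {"founders": 0, "polycross": 1, "gametes": 2, "traits": 3, "rings": 4, "climate": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stream]])


def _default_corr() -> np.ndarray:
    # height, dbh, wood_density, acoustic_velocity: growth traits strongly
    # correlated, both adversely correlated with density (classic conifer
    # growth/wood-quality trade-off), density and stiffness proxy aligned.
    return np.array(
        [
            [1.0, 0.7, -0.3, -0.1],
            [0.7, 1.0, -0.3, -0.1],
            [-0.3, -0.3, 1.0, 0.4],
            [-0.1, -0.1, 0.4, 1.0],
        ]
    )


@dataclass
class SimConfig:
    """Design constants and trait architecture of the simulated trial."""

    n_mothers: int = 38
    n_fathers: int = 19
    offspring_per_family_per_site: int = 8
    offspring_range: tuple[int, int] | None = None  # unbalanced option, e.g. (6, 9)
    n_sites: int = 2
    n_blocks: int = 4
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_names: tuple[str, ...] = ("height", "dbh", "wood_density", "acoustic_velocity")
    h2_true: tuple[float, ...] = (0.46, 0.45, 0.42, 0.41)
    genetic_corr_true: np.ndarray = field(default_factory=_default_corr)
    residual_corr: np.ndarray | None = None
    pheno_means: tuple[float, ...] = (784.0, 126.3, 382.6, 3.0)
    pheno_sds: tuple[float, ...] = (158.4, 24.7, 28.9, 0.4)
    site_offset_sd_units: tuple[float, ...] = (0.0, 0.5)  # per-site mean shift, in trait SDs
    block_sd_frac: float = 0.2  # block-effect SD as a fraction of trait SD
    drought_year_per_site: tuple[int, ...] = (2010, 2012)
    drought_multiplier_mean: tuple[float, ...] = (0.94, 0.88)
    drought_multiplier_sd: float = 0.12
    drought_multiplier_h2: float = 0.25
    # genetic correlation of the drought multiplier with each trait: vigorous
    # genotypes resist severe drought better, weakly aligned with wood traits
    drought_corr_traits: tuple[float, ...] = (0.5, 0.45, 0.2, 0.05)
    # exponents applying the multiplier to post-drought years (lag effects):
    # BAI_{d+j} *= multiplier ** drought_carryover[j-1]
    drought_carryover: tuple[float, ...] = (0.4, 0.15, 0.0)
    years: tuple[int, int] = (1997, 2015)
    # lognormal SD of shared within-site year effects: large enough that
    # cross-dating has a common signal to latch onto, small enough that the
    # injected drought-year dip stays identifiable in the site chronology
    year_effect_sd: float = 0.05
    ring_noise_sd: float = 0.05  # lognormal SD of per-tree-per-year BAI noise
    tree_vigour_sd: float = 0.3  # lognormal SD of the per-tree growth level
    father_weights: tuple[float, ...] | None = None  # unequal pollen contribution option
    seed: int = 42

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_fathers < 2:
            raise ValueError("need at least 2 fathers in the polymix")
        if self.offspring_per_family_per_site < 1:
            raise ValueError("offspring counts must be >= 1")
        t = len(self.trait_names)
        for name, tup in (
            ("h2_true", self.h2_true),
            ("pheno_means", self.pheno_means),
            ("pheno_sds", self.pheno_sds),
        ):
            if len(tup) != t:
                raise ValueError(f"{name} must have one entry per trait")
        if len(self.drought_corr_traits) != t:
            raise ValueError("drought_corr_traits must have one entry per trait")
        if any(not 0.0 < h < 1.0 for h in self.h2_true):
            raise ValueError("all heritabilities must be in (0, 1)")
        if not 0.0 < self.drought_multiplier_h2 < 1.0:
            raise ValueError("drought_multiplier_h2 must be in (0, 1)")
        C = np.asarray(self.genetic_corr_true, dtype=float)
        if C.shape != (t, t) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_corr_true must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("genetic_corr_true is not positive semi-definite")
        self.genetic_corr_true = C
        if len(self.drought_year_per_site) < self.n_sites:
            raise ValueError("need a drought year per site")
        if len(self.site_offset_sd_units) < self.n_sites:
            raise ValueError("need a site offset per site")

    @property
    def site_names(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    @property
    def h2_by_trait(self) -> dict[str, float]:
        return dict(zip(self.trait_names, self.h2_true))


@dataclass
class TruthSet:
    """Ground truth of a simulated trial, for parameter-recovery checks."""

    marker_effects: pd.DataFrame  # SNP x trait (+ drought_multiplier column)
    true_bv: pd.DataFrame  # individual x trait
    true_multiplier: pd.Series  # per-individual drought-year growth multiplier
    realized_h2: dict[str, float]
    realized_genetic_corr: pd.DataFrame


def simulate_founders(config: SimConfig) -> GenotypeMatrix:
    """Founder (mothers + fathers) dosages under Hardy-Weinberg at sampled MAFs."""
    rng = _rng(config.seed, "founders")
    n = config.n_mothers + config.n_fathers
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    dos = rng.binomial(2, maf, size=(n, config.n_snps)).astype(float)
    ids = [f"M{i + 1:03d}" for i in range(config.n_mothers)] + [
        f"F{i + 1:03d}" for i in range(config.n_fathers)
    ]
    snps = [f"snp{k + 1:05d}" for k in range(config.n_snps)]
    return GenotypeMatrix(ids, snps, dos)


def simulate_polycross(config: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Polycross mating plus field layout.

    Each offspring inherits its family's mother; the father is drawn from the
    polymix (uniformly unless ``father_weights`` is set, emulating equal pollen
    volumes).  Offspring are assigned to blocks within each site.  Returns the
    full pedigree (founders first) and the offspring metadata table.
    """
    rng = _rng(config.seed, "polycross")
    mothers = [f"M{i + 1:03d}" for i in range(config.n_mothers)]
    fathers = [f"F{i + 1:03d}" for i in range(config.n_fathers)]
    w = None
    if config.father_weights is not None:
        w = np.asarray(config.father_weights, dtype=float)
        w = w / w.sum()

    rows = []
    for s, site in enumerate(config.site_names):
        for m, mother in enumerate(mothers):
            if config.offspring_range is None:
                n_off = config.offspring_per_family_per_site
            else:
                n_off = int(rng.integers(config.offspring_range[0], config.offspring_range[1] + 1))
            for k in range(n_off):
                father = fathers[rng.choice(config.n_fathers, p=w)]
                rows.append(
                    {
                        "id": f"{site}_{mother}_{k + 1:02d}",
                        "site": site,
                        "block": f"b{k % config.n_blocks + 1}",
                        "family": mother,
                        "mother": mother,
                        "father": father,
                    }
                )
    meta = pd.DataFrame(rows)
    ped = Pedigree(
        ids=mothers + fathers + list(meta["id"]),
        mothers=[""] * (len(mothers) + len(fathers)) + list(meta["mother"]),
        fathers=[""] * (len(mothers) + len(fathers)) + list(meta["father"]),
    )
    return ped, meta


def drop_genotypes(
    pedigree_meta: pd.DataFrame, founders: GenotypeMatrix, seed: int
) -> GenotypeMatrix:
    """Mendelian gamete sampling: offspring dosage = maternal + paternal allele.

    Each transmitted allele is sampled independently per locus from the
    parent's two alleles (a heterozygous parent transmits 0 or 1 with equal
    probability).
    """
    rng = _rng(seed, "gametes")
    n_snps = founders.n_snps
    out = np.empty((len(pedigree_meta), n_snps))
    for r, rec in enumerate(pedigree_meta.itertuples(index=False)):
        alleles = []
        for parent in (rec.mother, rec.father):
            try:
                pd_dos = founders.row(parent)
            except KeyError as exc:
                raise ValueError(f"parent {parent!r} has no genotype") from exc
            # dosage 0 -> transmit 0; 2 -> transmit 1; 1 -> fair coin
            het = pd_dos == 1
            allele = (pd_dos == 2).astype(float)
            allele[het] = rng.integers(0, 2, size=int(het.sum()))
            alleles.append(allele)
        out[r] = alleles[0] + alleles[1]
    return GenotypeMatrix(list(pedigree_meta["id"]), list(founders.snp_ids), out)


def simulate_traits(
    config: SimConfig, genotypes: GenotypeMatrix, meta: pd.DataFrame
) -> tuple[TruthSet, pd.DataFrame]:
    """Additive multi-trait phenotypes plus the heritable drought multiplier.

    Marker effects are drawn multivariate normal across traits with the target
    genetic correlation structure and rescaled so the realized additive
    variance matches each trait's target heritability exactly; phenotype =
    trait mean + site offset + block effect + breeding value + residual.
    """
    rng = _rng(config.seed, "traits")
    t = len(config.trait_names)
    names = list(config.trait_names) + ["drought_multiplier"]

    # joint correlation of marker effects: trait block plus the multiplier row
    C = np.eye(t + 1)
    C[:t, :t] = config.genetic_corr_true
    C[t, :t] = C[:t, t] = config.drought_corr_traits
    ev = np.linalg.eigvalsh(C)
    if ev.min() < -1e-10:
        raise ValueError(
            "joint marker-effect correlation (traits + drought multiplier) is not PSD; "
            "lower drought_corr_traits"
        )
    L = np.linalg.cholesky(C + 1e-12 * np.eye(t + 1))
    beta = rng.standard_normal((genotypes.n_snps, t + 1)) @ L.T

    Zc = genotypes.dosages - genotypes.dosages.mean(axis=0)
    raw_bv = Zc @ beta  # n x (t+1)
    # re-colour so the realized correlation of true BVs matches the target
    # exactly, then rescale so the realized additive variances hit the target
    # heritabilities exactly; beta gets the same linear map, preserving
    # true_bv == centered dosages @ marker_effects.
    std = raw_bv.std(axis=0)
    C_real = np.corrcoef(raw_bv.T)
    recolour = np.diag(1.0 / std) @ np.linalg.inv(np.linalg.cholesky(C_real)).T @ np.linalg.cholesky(C).T
    raw_bv = raw_bv @ recolour
    beta = beta @ recolour
    sd_targets = np.array(
        [np.sqrt(h) * s for h, s in zip(config.h2_true, config.pheno_sds)]
        + [np.sqrt(config.drought_multiplier_h2) * config.drought_multiplier_sd]
    )
    scale = sd_targets / raw_bv.std(axis=0)
    beta = beta * scale
    bv = raw_bv * scale  # exactly Zc @ beta

    # residuals
    if config.residual_corr is None:
        Re = np.eye(t)
    else:
        Re = np.asarray(config.residual_corr, dtype=float)
    Le = np.linalg.cholesky(Re + 1e-12 * np.eye(t))
    resid_sd = np.array(
        [np.sqrt(1.0 - h) * s for h, s in zip(config.h2_true, config.pheno_sds)]
    )
    resid = (rng.standard_normal((len(meta), t)) @ Le.T) * resid_sd

    # block effects per site x block x trait
    sites = config.site_names
    block_eff = {
        (site, f"b{b + 1}"): rng.normal(0.0, config.block_sd_frac, size=t)
        for site in sites
        for b in range(config.n_blocks)
    }

    pheno = meta.copy()
    site_of = meta["site"].to_numpy()
    site_offsets = dict(zip(sites, config.site_offset_sd_units))
    for j, trait in enumerate(config.trait_names):
        base = config.pheno_means[j] + np.array(
            [site_offsets[s] for s in site_of]
        ) * config.pheno_sds[j]
        blocks = np.array(
            [block_eff[(s, b)][j] for s, b in zip(site_of, meta["block"])]
        ) * config.pheno_sds[j]
        pheno[trait] = base + blocks + bv[:, j] + resid[:, j]

    # heritable drought multiplier, truncated to stay a positive growth factor
    mult_env = rng.normal(
        0.0, np.sqrt(1.0 - config.drought_multiplier_h2) * config.drought_multiplier_sd, len(meta)
    )
    mult_mean = np.array(
        [dict(zip(sites, config.drought_multiplier_mean))[s] for s in site_of]
    )
    mult = np.clip(mult_mean + bv[:, t] + mult_env, 0.05, 1.5)

    ids = list(meta["id"])
    bv_df = pd.DataFrame(bv, index=ids, columns=names)
    realized_h2 = {
        trait: float(bv[:, j].var() / (bv[:, j].var() + resid[:, j].var()))
        for j, trait in enumerate(config.trait_names)
    }
    corr = np.corrcoef(bv[:, :t].T)
    truth = TruthSet(
        marker_effects=pd.DataFrame(beta, index=genotypes.snp_ids, columns=names),
        true_bv=bv_df,
        true_multiplier=pd.Series(mult, index=ids, name="drought_multiplier"),
        realized_h2=realized_h2,
        realized_genetic_corr=pd.DataFrame(
            corr, index=config.trait_names, columns=config.trait_names
        ),
    )
    return truth, pheno


def simulate_ring_series(
    config: SimConfig, truth: TruthSet, meta: pd.DataFrame
) -> dict[str, list[RingSeries]]:
    """Per-tree yearly ring widths encoding the drought signal.

    Expected BAI follows a saturating juvenile trend scaled by a lognormal
    tree-vigour factor and shared lognormal year effects; in the site's drought
    year the expected BAI is multiplied by the tree's true drought multiplier.
    The BAI series is then inverted to ring widths (from the pith).
    """
    rng = _rng(config.seed, "rings")
    y0, y1 = config.years
    n_years = y1 - y0 + 1
    ages = np.arange(1, n_years + 1, dtype=float)
    # logistic juvenile BAI trend (mm^2): slow start, rapid increase, plateau
    # approaching stand closure, sized so cumulative basal area matches a
    # ~19-year-old spruce of ~140 mm DBH
    trend = 1500.0 / (1.0 + np.exp(-(ages - 8.0) / 3.0))
    drought_year = dict(zip(config.site_names, config.drought_year_per_site))

    year_effects = {
        site: np.exp(rng.normal(0.0, config.year_effect_sd, size=n_years))
        for site in config.site_names
    }
    # the drought-year deviation is carried entirely by the multiplier; the
    # shared year effect is neutral there so the injected signal is not
    # confounded with an extra random climate draw for the same year
    for site in config.site_names:
        year_effects[site][drought_year[site] - y0] = 1.0
    out: dict[str, list[RingSeries]] = {site: [] for site in config.site_names}
    for rec in meta.itertuples(index=False):
        vigour = float(np.exp(rng.normal(0.0, config.tree_vigour_sd)))
        noise = np.exp(rng.normal(0.0, config.ring_noise_sd, size=n_years))
        bai = trend * vigour * year_effects[rec.site] * noise
        d = drought_year[rec.site] - y0
        mult = float(truth.true_multiplier[rec.id])
        bai[d] *= mult
        for j, expo in enumerate(config.drought_carryover, start=1):
            if expo != 0.0 and d + j < n_years:
                bai[d + j] *= mult**expo
        series = RingSeries(rec.id, y0, bai, kind="bai")
        out[rec.site].append(bai_to_width(series))
    return out


def simulate_climate(
    years: tuple[int, int],
    drought_years: tuple[int, ...] = (),
    seed: int = 0,
    drought_precip_factor: float = 0.45,
) -> ClimateSeries:
    """Daily weather: sinusoidal seasonal temperature plus stochastic precipitation.

    In drought years, July-August precipitation is scaled by
    ``drought_precip_factor`` (a dry summer with >40% less rain in expectation).
    """
    y0, y1 = years
    if y1 < y0:
        raise ValueError(f"empty year range {years}")
    rng = _rng(seed, "climate")
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    tmean = 2.0 + 17.0 * np.sin(2.0 * np.pi * (doy - 110.0) / 365.25) + rng.normal(0, 2.0, len(dates))
    wet = rng.random(len(dates)) < 0.45
    amounts = rng.gamma(0.8, 6.0, len(dates))
    precip = np.where(wet, amounts, 0.0)
    in_drought_summer = np.isin(dates.year, list(drought_years)) & np.isin(dates.month, [7, 8])
    precip = np.where(in_drought_summer, precip * drought_precip_factor, precip)
    return ClimateSeries(
        pd.DataFrame({"date": dates, "tmean": np.round(tmean, 4), "precip": np.round(precip, 4)})
    )


@dataclass
class SimulatedDataset:
    """Everything one trial produces, bundled for the pipeline and tests."""

    config: SimConfig
    founders: GenotypeMatrix
    pedigree: Pedigree
    meta: pd.DataFrame
    genotypes: GenotypeMatrix  # offspring
    truth: TruthSet
    phenotypes: pd.DataFrame
    rings: dict[str, list[RingSeries]]
    climate: dict[str, ClimateSeries]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator chain under the dataset seed."""
    founders = simulate_founders(config)
    pedigree, meta = simulate_polycross(config)
    genotypes = drop_genotypes(meta, founders, config.seed)
    truth, pheno = simulate_traits(config, genotypes, meta)
    rings = simulate_ring_series(config, truth, meta)
    y0, y1 = config.years
    climate = {
        site: simulate_climate(
            (y0 - 2, y1), drought_years=(dy,), seed=config.seed + 1000 + i
        )
        for i, (site, dy) in enumerate(zip(config.site_names, config.drought_year_per_site))
    }
    return SimulatedDataset(
        config, founders, pedigree, meta, genotypes, truth, pheno, rings, climate
    )
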