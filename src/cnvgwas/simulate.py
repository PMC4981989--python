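"""Synthetic multi-cohort CNV study generator.

Produces intensity, genotype and phenotype data with the statistical
structure the calling/association pipeline assumes: several cohorts on
distinct "platforms" (different probe densities and noise levels, one cohort
on a summed X+Y intensity dialect), a catalogue of deletion / amplification /
multiallelic CNVRs with Hardy-Weinberg class frequencies, family structure in
one cohort, quantitative spirometry traits (FEV1, FVC, FEV1/FVC) driven by
age/sex/height with optional spiked copy-number effects, and tag SNPs at
controlled r^2.

Class-label conventions
-----------------------
``simulate_cnv_classes`` labels genotype classes by variant-allele count
(class 0 = no variant alleles).  Intensity generation and the recorded
"true" classes relabel to ascending mean intensity — the order the mixture
caller recovers — via :func:`intensity_class_order`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .calling import CNVRegion

__all__ = [
    "CNVRSpec",
    "FamilySpec",
    "TraitModel",
    "CohortSpec",
    "SimConfig",
    "CohortData",
    "SimDataset",
    "hwe_class_frequencies",
    "simulate_cnv_classes",
    "simulate_intensities",
    "simulate_phenotypes",
    "simulate_tag_snp",
    "simulate_multi_cohort_study",
    "default_config",
]


def lrr_mean(copy: float) -> float:
    """Expected Log R Ratio for a given copy number (zero copies floored)."""
    return float(np.log2(max(copy, 0.25) / 2.0))


# ----------------------------------------------------------------------
# configuration dataclasses
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CNVRSpec:
    """One catalogued copy-number-variable region to simulate."""

    region_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str            # deletion | amplification | multiallelic
    k: int                   # number of genotype classes (2..4)
    q: float                 # variant allele frequency
    tag_target_r2: Optional[float] = None  # None = no tag SNP simulated

    def __post_init__(self):
        if self.cnv_type not in ("deletion", "amplification", "multiallelic"):
            raise ValueError(f"unknown CNVR type {self.cnv_type!r}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"allele frequency q={self.q} outside (0,1)")
        if self.k < 2 or self.k > 4:
            raise ValueError(f"unsupported class count K={self.k}")
        if self.cnv_type == "multiallelic" and self.k != 4:
            raise ValueError("multiallelic CNVRs are simulated with K=4")

    @property
    def region(self) -> CNVRegion:
        return CNVRegion(self.region_id, self.chrom, self.start, self.end,
                         declared_type=self.cnv_type)


@dataclass(frozen=True)
class FamilySpec:
    """Family structure for one cohort (fraction of samples in sibships)."""

    fraction: float = 0.5
    sizes: tuple = (2, 3, 4)
    size_probs: tuple = (0.5, 0.3, 0.2)
    trait_icc: float = 0.5


@dataclass(frozen=True)
class TraitModel:
    """Linear covariate model for one spirometry trait (adult-scale units)."""

    intercept: float
    b_age: float
    b_age2: float
    b_sex: float       # effect of male sex
    b_height: float    # per metre
    b_height2: float
    residual_sd: float

    def mean(self, age, sex, height):
        return (
            self.intercept + self.b_age * age + self.b_age2 * age**2
            + self.b_sex * sex + self.b_height * height + self.b_height2 * height**2
        )


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n: int
    noise_sd: float                # per-probe intensity noise, LRR units
    probes_per_cnvr: int
    dialect: str = "LRR"           # LRR | XY
    family: Optional[FamilySpec] = None
    age_range: tuple = (25.0, 75.0)
    height_range: tuple = (1.45, 1.95)
    xy_scale: float = 1.0          # XY dialect: value = xy_offset + xy_scale * LRR
    xy_offset: float = 2.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")
        if self.dialect not in ("LRR", "XY"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


# Default trait models: plausible adult European spirometry.  FEV1 declines
# ~27 mL/yr, scales with height; FVC similar but larger; the ratio declines
# slowly with age.  Child cohorts reuse the same coefficients on their own
# age/height ranges, which keeps the traits positive and covariate-driven.
DEFAULT_TRAITS = {
    "FEV1": TraitModel(-4.2, -0.022, -5e-5, 0.25, 4.9, -0.4, 0.40),
    "FVC": TraitModel(-5.5, -0.018, -4e-5, 0.45, 6.1, -0.5, 0.50),
    "RATIO": TraitModel(0.92, -0.002, 0.0, -0.015, 0.0, 0.0, 0.07),
}


@dataclass(frozen=True)
class SimConfig:
    """Full study recipe; identical configs (incl. seed) give identical data."""

    cohorts: tuple
    cnvrs: tuple
    traits: dict = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    cnv_betas: dict = field(default_factory=dict)  # {trait: {region_id: beta per class}}
    n_background_probes: int = 150
    n_pca_snps: int = 100
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        names = [c.name for c in self.cohorts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cohort names")


@dataclass
class CohortData:
    name: str
    intensities: pd.DataFrame        # samples x probes (dialect units)
    probes: pd.DataFrame             # probe_id, chrom, pos
    phenotypes: pd.DataFrame         # traits + covariates + family_id
    true_classes: pd.DataFrame       # samples x CNVR (ascending-intensity labels)
    true_doses: pd.DataFrame         # == true_classes as float (noise-free dose)
    snp_positions: pd.DataFrame      # snp -> chrom, pos, effect/other allele
    snp_dosages: pd.DataFrame        # samples x SNPs
    dialect: str = "LRR"


@dataclass
class SimDataset:
    config: SimConfig
    regions: list
    cohorts: dict                    # name -> CohortData
    true_betas: dict                 # {trait: {region_id: beta}}


# ----------------------------------------------------------------------
# elementary generators
# ----------------------------------------------------------------------

def hwe_class_frequencies(cnv_type: str, k: int, q: float) -> np.ndarray:
    """Theoretical genotype-class frequencies (variant-allele-count order).

    Biallelic K=3: ((1-q)^2, 2q(1-q), q^2).  K=2 merges the two
    variant-free/heterozygous states into class 0, leaving the homozygous
    variant state as class 1.  Multiallelic K=4: two independent biallelic
    variants at frequency q each; class = total variant alleles truncated
    at 3.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0,1)")
    p0, p1, p2 = (1 - q) ** 2, 2 * q * (1 - q), q**2
    if k == 3:
        return np.array([p0, p1, p2])
    if k == 2:
        return np.array([p0 + p1, p2])
    if k == 4:
        g = np.array([p0, p1, p2])
        conv = np.convolve(g, g)  # allele-sum 0..4
        return np.array([conv[0], conv[1], conv[2], conv[3] + conv[4]])
    raise ValueError(f"unsupported K={k}")


def _classes_from_alleles(cnv_type: str, k: int, alleles: np.ndarray) -> np.ndarray:
    """Map per-sample variant-allele counts to genotype class labels."""
    if k == 3:
        return alleles.astype(int)
    if k == 2:
        return (alleles == 2).astype(int)
    if k == 4:
        return np.minimum(alleles, 3).astype(int)
    raise ValueError(f"unsupported K={k}")


def simulate_cnv_classes(cnv_type: str, k: int, q: float, n: int, seed=0,
                         return_alleles: bool = False):
    """Draw genotype classes under Hardy-Weinberg equilibrium.

    Returns class labels in variant-allele-count order (class 0 = no variant
    alleles); with ``return_alleles=True`` also returns the underlying
    variant-allele count per sample (0..2 biallelic, 0..4 multiallelic),
    needed for tag-SNP simulation.
    """
    if k < 2 or k > 4:
        raise ValueError(f"unsupported K={k}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_var = 2 if k == 4 else 1
    alleles = rng.binomial(2, q, size=(n, n_var)).sum(axis=1)
    classes = _classes_from_alleles(cnv_type, k, alleles)
    return (classes, alleles) if return_alleles else classes


def copy_numbers_for_classes(cnv_type: str, k: int) -> np.ndarray:
    """Copy number per genotype class (variant-allele-count order)."""
    if cnv_type == "deletion":
        return np.array([2, 0]) if k == 2 else np.array([2, 1, 0])
    if cnv_type == "amplification":
        return np.array([2, 4]) if k == 2 else np.array([2, 3, 4])
    return np.array([1, 2, 3, 4])  # multiallelic: losses and gains around diploid


def intensity_class_order(cnv_type: str, k: int) -> np.ndarray:
    """Permutation g -> ascending-intensity class label for genotype class g."""
    copies = copy_numbers_for_classes(cnv_type, k)
    order = np.argsort(copies, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel


def simulate_intensities(classes, probe_count: int, class_means=None,
                         noise_sd: float = 0.1, missing_rate: float = 0.0,
                         seed=0) -> np.ndarray:
    """Probe-level intensities: probes x samples, class mean + Gaussian noise.

    ``classes`` index into ``class_means`` (which must be strictly
    increasing); the default mean for class c is the LRR expectation for c
    copies, log2(max(c, 0.25)/2).
    """
    classes = np.asarray(classes, dtype=int)
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if class_means is None:
        class_means = np.array([lrr_mean(c) for c in range(classes.max() + 1)])
    class_means = np.asarray(class_means, dtype=float)
    if np.any(np.diff(class_means) <= 0):
        raise ValueError("class means must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = class_means[classes]  # (n,)
    mat = base[None, :] + rng.normal(scale=noise_sd, size=(probe_count, classes.size)) \
        if noise_sd > 0 else np.tile(base, (probe_count, 1))
    if missing_rate > 0:
        mask = rng.random(size=mat.shape) < missing_rate
        mat = np.where(mask, np.nan, mat)
    return mat


def assign_families(n: int, spec: FamilySpec, rng: np.random.Generator,
                    prefix: str = "F") -> np.ndarray:
    """Family id per sample; singletons get a unique id each."""
    fam_ids = np.array([f"{prefix}_S{i}" for i in range(n)], dtype=object)
    n_in_fam = int(round(spec.fraction * n))
    i = 0
    fam = 0
    while i < n_in_fam - 1:
        size = int(rng.choice(spec.sizes, p=spec.size_probs))
        size = min(size, n_in_fam - i)
        if size < 2:
            break
        fam_ids[i:i + size] = f"{prefix}{fam}"
        i += size
        fam += 1
    return fam_ids


def simulate_phenotypes(classes_or_dose, covariates: pd.DataFrame, betas: dict,
                        residual_sd: float, family_ids=None,
                        family_icc: float = 0.0, seed=0) -> pd.Series:
    """One quantitative trait: covariate terms + CNV effect + family effect + noise.

    ``betas`` holds coefficients for const/age/age2/sex/height/height2 (absent
    terms default to 0) and ``cnv`` — the effect per copy-number class.  With
    ``family_ids`` and ``family_icc`` rho > 0, members of multi-sample
    families share a N(0, rho * sd^2) effect with N(0, (1-rho) * sd^2)
    individual noise, so the residual intraclass correlation is rho.
    """
    if residual_sd <= 0:
        raise ValueError("residual SD must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(classes_or_dose, dtype=float)
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    height = covariates["height"].to_numpy(dtype=float)
    mu = (
        betas.get("const", 0.0)
        + betas.get("age", 0.0) * age + betas.get("age2", 0.0) * age**2
        + betas.get("sex", 0.0) * sex
        + betas.get("height", 0.0) * height + betas.get("height2", 0.0) * height**2
        + betas.get("cnv", 0.0) * d
    )
    n = mu.size
    if family_ids is not None and family_icc > 0:
        fam = pd.Series(family_ids)
        sizes = fam.map(fam.value_counts())
        in_family = (sizes > 1).to_numpy()
        codes, uniq = pd.factorize(fam)
        fam_eff = rng.normal(scale=np.sqrt(family_icc) * residual_sd, size=len(uniq))[codes]
        indiv_sd = np.where(in_family, np.sqrt(1 - family_icc), 1.0) * residual_sd
        noise = np.where(in_family, fam_eff, 0.0) + rng.normal(size=n) * indiv_sd
    else:
        noise = rng.normal(scale=residual_sd, size=n)
    return pd.Series(mu + noise, index=covariates.index)


def simulate_tag_snp(classes=None, target_r2: float = 0.9, seed=0,
                     allele_counts=None, q: Optional[float] = None) -> np.ndarray:
    """SNP effect-allele dosage in LD with a biallelic CNV at a target r^2.

    Each of the two SNP alleles copies the corresponding CNV variant allele
    with probability sqrt(target_r2) and is otherwise an independent
    Bernoulli(q) draw, giving genotype correlation sqrt(target_r2) and hence
    squared correlation target_r2 in expectation.  Multiallelic classes have
    no single generating allele and are rejected unless ``allele_counts``
    (0..2) is supplied explicitly.
    """
    if not 0.0 <= target_r2 <= 1.0:
        raise ValueError("target r^2 must be in [0,1]")
    if allele_counts is None:
        if classes is None:
            raise ValueError("need classes or allele_counts")
        classes = np.asarray(classes, dtype=int)
        if classes.max() > 2:
            raise ValueError(
                "multiallelic classes have no declared generating allele; "
                "pass allele_counts explicitly"
            )
        allele_counts = classes
    g = np.asarray(allele_counts, dtype=int)
    if g.max() > 2 or g.min() < 0:
        raise ValueError("allele counts must be in 0..2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if q is None:
        q = g.mean() / 2.0
        q = min(max(q, 1e-6), 1 - 1e-6)
    p_copy = np.sqrt(target_r2)
    # split genotype into two alleles: 0->(0,0), 1->(1,0), 2->(1,1)
    a1 = (g >= 1).astype(int)
    a2 = (g == 2).astype(int)
    out = np.zeros(g.size, dtype=int)
    for a in (a1, a2):
        keep = rng.random(g.size) < p_copy
        fresh = rng.binomial(1, q, size=g.size)
        out += np.where(keep, a, fresh)
    return out


# ----------------------------------------------------------------------
# whole-study generator
# ----------------------------------------------------------------------

def default_config(seed: int = 0) -> SimConfig:
    """Study-shaped default: 4 lung-function cohorts, 9 CNVRs, null effects.

    Cohort sizes mirror a 4-cohort spirometry study (three adult cohorts, one
    with family structure, plus one larger child cohort on a summed-intensity
    dialect); CNVR types cover deletions, amplifications and multiallelic
    regions in roughly the 44/34/22 percent blend seen on real arrays.
    """
    cohorts = (
        CohortSpec("ADULT_FAM", 3084, 0.10, 15, family=FamilySpec(),
                   age_range=(16.5, 97.3), height_range=(1.39, 1.97)),
        CohortSpec("ADULT_B", 2492, 0.12, 20,
                   age_range=(44.5, 46.0), height_range=(1.22, 2.02)),
        CohortSpec("ADULT_C", 1765, 0.16, 8,
                   age_range=(25.0, 85.0), height_range=(1.42, 1.97)),
        CohortSpec("CHILD_XY", 5062, 0.20, 6, dialect="XY",
                   age_range=(7.42, 10.33), height_range=(1.13, 1.59)),
    )
    cnvrs = (
        CNVRSpec("CNVR1.1", "1", 10_000_000, 10_015_000, "deletion", 3, 0.30, 0.94),
        CNVRSpec("CNVR2.1", "2", 30_000_000, 30_004_000, "deletion", 3, 0.15, 0.90),
        CNVRSpec("CNVR3.1", "3", 50_000_000, 50_001_000, "deletion", 2, 0.10, 0.85),
        CNVRSpec("CNVR4.1", "4", 70_000_000, 70_002_500, "deletion", 3, 0.40, None),
        CNVRSpec("CNVR5.1", "5", 90_000_000, 90_000_900, "amplification", 3, 0.25, 0.90),
        CNVRSpec("CNVR6.1", "6", 110_000_000, 110_003_000, "amplification", 3, 0.35, 0.80),
        CNVRSpec("CNVR7.1", "7", 130_000_000, 130_001_500, "amplification", 2, 0.20, None),
        CNVRSpec("CNVR8.1", "8", 150_000_000, 150_050_000, "multiallelic", 4, 0.30, None),
        CNVRSpec("CNVR9.1", "9", 170_000_000, 170_020_000, "multiallelic", 4, 0.20, None),
    )
    return SimConfig(cohorts=cohorts, cnvrs=cnvrs, seed=seed)


def small_study_config(seed: int = 0, spiked: bool = True) -> SimConfig:
    """Scaled-down two-cohort study for integration tests and demos.

    One family-structured reference cohort and one unrelated cohort; five
    CNVRs covering deletions, an amplification and a multiallelic region.
    When ``spiked`` is true, one deletion CNVR carries an FVC effect of
    0.5 x the residual SD per copy class; everything else is null.  Allele
    frequencies keep the rarest Hardy-Weinberg class at >= ~10 expected
    carriers at these cohort sizes, the regime in which a common CNV on a
    full-size cohort passes the minimum-class-count calling rule.
    """
    cnvrs = (
        CNVRSpec("CNVR1.1", "1", 10_000_000, 10_015_000, "deletion", 3, 0.30, 0.94),
        CNVRSpec("CNVR2.1", "2", 30_000_000, 30_004_000, "deletion", 3, 0.25, 0.90),
        CNVRSpec("CNVR5.1", "5", 90_000_000, 90_000_900, "amplification", 3, 0.25, 0.90),
        CNVRSpec("CNVR8.1", "8", 150_000_000, 150_050_000, "multiallelic", 4, 0.30, None),
        CNVRSpec("CNVR3.1", "3", 50_000_000, 50_001_000, "deletion", 2, 0.20, 0.85),
    )
    cohorts = (
        CohortSpec("A", 300, 0.10, 8, family=FamilySpec()),
        CohortSpec("B", 250, 0.14, 6),
    )
    betas = {"FVC": {"CNVR2.1": 0.25}} if spiked else {}
    return SimConfig(cohorts=cohorts, cnvrs=cnvrs, cnv_betas=betas, seed=seed)


def config_from_dict(raw: dict, seed: int = 0) -> SimConfig:
    """Build a SimConfig from plain dicts (the YAML the CLI accepts).

    Recognised keys: ``cohorts`` (list of CohortSpec fields; ``family`` may
    be true/false or a FamilySpec dict), ``cnvrs`` (list of CNVRSpec fields),
    ``cnv_betas``, ``traits`` (TraitModel fields per trait) and the scalar
    SimConfig fields.  Anything omitted falls back to the study-shaped
    defaults.
    """
    base = default_config(seed=seed)
    cohorts = base.cohorts
    if "cohorts" in raw:
        built = []
        for c in raw["cohorts"]:
            c = dict(c)
            fam = c.pop("family", None)
            if isinstance(fam, dict):
                fam = FamilySpec(**fam)
            elif fam:
                fam = FamilySpec()
            else:
                fam = None
            for key in ("age_range", "height_range"):
                if key in c:
                    c[key] = tuple(c[key])
            built.append(CohortSpec(family=fam, **c))
        cohorts = tuple(built)
    cnvrs = base.cnvrs
    if "cnvrs" in raw:
        cnvrs = tuple(CNVRSpec(**dict(c)) for c in raw["cnvrs"])
    traits = dict(base.traits)
    for name, fields in (raw.get("traits") or {}).items():
        traits[name] = TraitModel(**fields)
    return SimConfig(
        cohorts=cohorts,
        cnvrs=cnvrs,
        traits=traits,
        cnv_betas=raw.get("cnv_betas", {}),
        n_background_probes=raw.get("n_background_probes",
                                    base.n_background_probes),
        n_pca_snps=raw.get("n_pca_snps", base.n_pca_snps),
        missing_rate=raw.get("missing_rate", base.missing_rate),
        seed=raw.get("seed", seed),
    )


def _cohort_rngs(cfg: SimConfig, name: str) -> dict:
    """Deterministic per-cohort RNG streams keyed by purpose."""
    idx = [c.name for c in cfg.cohorts].index(name)
    root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
    keys = ("genotype", "intensity", "phenotype", "snp", "covariates", "family")
    children = root.spawn(len(keys))
    return {k: np.random.default_rng(s) for k, s in zip(keys, children)}


def simulate_multi_cohort_study(cfg: SimConfig) -> SimDataset:
    """Generate the full multi-cohort study bundle from a SimConfig."""
    regions = [spec.region for spec in cfg.cnvrs]
    cohorts: dict[str, CohortData] = {}
    for cspec in cfg.cohorts:
        rngs = _cohort_rngs(cfg, cspec.name)
        n = cspec.n
        sample_ids = pd.Index([f"{cspec.name}_S{i:05d}" for i in range(n)],
                              name="sample_id")

        # --- covariates and family structure
        rc = rngs["covariates"]
        age = rc.uniform(*cspec.age_range, size=n)
        sex = rc.integers(0, 2, size=n)  # 1 = male
        height = rc.uniform(*cspec.height_range, size=n)
        if cspec.family is not None:
            family_ids = assign_families(n, cspec.family, rngs["family"],
                                         prefix=cspec.name)
        else:
            family_ids = np.array([f"{cspec.name}_S{i}" for i in range(n)],
                                  dtype=object)
        covariates = pd.DataFrame(
            {"age": age, "sex": sex, "height": height}, index=sample_ids
        )

        # --- CNV genotypes and probe intensities
        probe_rows = []
        blocks = []
        true_cls = {}
        allele_store = {}
        for spec in cfg.cnvrs:
            classes, alleles = simulate_cnv_classes(
                spec.cnv_type, spec.k, spec.q, n,
                seed=rngs["genotype"], return_alleles=True,
            )
            allele_store[spec.region_id] = alleles
            relabel = intensity_class_order(spec.cnv_type, spec.k)
            intensity_classes = relabel[classes]
            copies = copy_numbers_for_classes(spec.cnv_type, spec.k)
            means = np.array([lrr_mean(c) for c in np.sort(copies)])
            block = simulate_intensities(
                intensity_classes, cspec.probes_per_cnvr, class_means=means,
                noise_sd=cspec.noise_sd, missing_rate=cfg.missing_rate,
                seed=rngs["intensity"],
            )
            blocks.append(block)
            true_cls[spec.region_id] = intensity_classes
            pos = np.linspace(spec.start, spec.end - 1, cspec.probes_per_cnvr)
            for j, p in enumerate(pos):
                probe_rows.append(
                    (f"{cspec.name}_{spec.region_id}_p{j}", spec.chrom, int(p))
                )
        # background diploid probes (support the noise metric, map outside CNVRs)
        bg = rngs["intensity"].normal(scale=cspec.noise_sd,
                                      size=(cfg.n_background_probes, n))
        blocks.append(bg)
        for j in range(cfg.n_background_probes):
            probe_rows.append((f"{cspec.name}_bg_p{j}", "22", 40_000_000 + 1000 * j))
        probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
        mat = np.vstack(blocks).T  # samples x probes
        if cspec.dialect == "XY":
            mat = cspec.xy_offset + cspec.xy_scale * mat
        intensities = pd.DataFrame(mat, index=sample_ids,
                                   columns=probes["probe_id"].tolist())

        # --- SNPs: tag SNPs per biallelic CNVR + independent PCA SNPs
        rs = rngs["snp"]
        snp_pos_rows = []
        snp_cols = {}
        for spec in cfg.cnvrs:
            if spec.tag_target_r2 is None or spec.k == 4:
                continue
            alleles = np.minimum(allele_store[spec.region_id], 2)
            dos = simulate_tag_snp(allele_counts=alleles,
                                   target_r2=spec.tag_target_r2,
                                   seed=rs, q=spec.q)
            snp_id = f"rs_{spec.region_id}"
            # dosage counts the variant allele; for deletions more variant
            # alleles mean fewer copies, so flip to keep dosages arbitrary-
            # but-consistent test material for sign alignment downstream.
            snp_pos_rows.append((snp_id, spec.chrom, spec.end + 10_000, "A", "G"))
            snp_cols[snp_id] = dos
        for j in range(cfg.n_pca_snps):
            maf = rs.uniform(0.05, 0.5)
            snp_id = f"rs_pca{j}"
            snp_pos_rows.append((snp_id, "21", 5_000_000 + 2000 * j, "A", "G"))
            snp_cols[snp_id] = rs.binomial(2, maf, size=n)
        snp_positions = pd.DataFrame(
            snp_pos_rows, columns=["snp", "chrom", "pos", "effect_allele", "other_allele"]
        ).set_index("snp")
        snp_dosages = pd.DataFrame(snp_cols, index=sample_ids, dtype=float)

        # --- phenotypes
        pheno = covariates.copy()
        pheno["family_id"] = family_ids
        icc = cspec.family.trait_icc if cspec.family is not None else 0.0
        for trait, model in cfg.traits.items():
            betas = {
                "const": model.intercept, "age": model.b_age, "age2": model.b_age2,
                "sex": model.b_sex, "height": model.b_height,
                "height2": model.b_height2, "cnv": 0.0,
            }
            y = simulate_phenotypes(
                np.zeros(n), covariates, betas, model.residual_sd,
                family_ids=family_ids, family_icc=icc, seed=rngs["phenotype"],
            )
            # spiked CNV effects act on the true ascending-intensity class
            for region_id, beta in cfg.cnv_betas.get(trait, {}).items():
                y = y + beta * true_cls[region_id]
            pheno[trait] = y

        cohorts[cspec.name] = CohortData(
            name=cspec.name,
            intensities=intensities,
            probes=probes,
            phenotypes=pheno,
            true_classes=pd.DataFrame(true_cls, index=sample_ids),
            true_doses=pd.DataFrame(true_cls, index=sample_ids, dtype=float),
            snp_positions=snp_positions,
            snp_dosages=snp_dosages,
            dialect=cspec.dialect,
        )
    return SimDataset(config=cfg, regions=regions, cohorts=cohorts,
                      true_betas=dict(cfg.cnv_betas))
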