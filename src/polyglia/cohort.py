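"""Synthetic aging-cohort generator with planted, recoverable genetics.

The analyses in this package were designed for a deeply phenotyped
autopsy cohort: elderly subjects with imputed genotypes, postmortem
pathology indices, microglial count densities across four brain regions
and morphological activation stages, annual cognitive testing, and
cortical gene co-expression module summaries.  Such data are
access-controlled, so this module generates cohorts with the same
statistical structure and *known* truth, letting every downstream step
(scoring, robust screening, driver deconstruction, concordance) be
validated against planted effects.

The genetic architecture is the central dial: an
:class:`ArchitectureSpec` either concentrates the phenotype effect in a
few *driver* variants (per-dosage effects at ``driver_indices``) or
spreads it diffusely through the weighted score (``polygenic_effect``
per SD of true score) — the two regimes the deconstruction analysis is
meant to tell apart.

All generators are pure functions of (spec, seed): the same inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import GenotypeMatrix, WeightTable, compute_grs

__all__ = [
    "ArchitectureSpec",
    "CohortTruth",
    "REGIONS",
    "STAGE_AGGREGATES",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotypes",
    "simulate_longitudinal",
    "simulate_modules",
    "weight_table",
]

REGIONS = (
    "midfrontal",
    "inferior_temporal",
    "ventral_medial_caudate",
    "posterior_putamen",
)
#: Activation-stage aggregates reported per region: stage 1 only,
#: stages 1+2+3, stages 2+3, stage 3 only.
STAGE_AGGREGATES = ("stage1", "stage123", "stage23", "stage3")

# mean density (counts/area) and spread per activation-stage component;
# chosen so the summed all-stage density sits near 190 +/- 55
_STAGE_MU = {1: 115.0, 2: 57.0, 3: 19.0}
_STAGE_SIGMA_FRAC = 0.30

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

PATHOLOGY_PHENOTYPES = ("neuritic_plaques", "diffuse_plaques", "tangles", "amyloid", "tau")

#: Modest covariate effects (per centered covariate unit, in latent-SD
#: units) so that covariate adjustment is exercised non-trivially.
DEFAULT_COVARIATE_EFFECTS = {
    "pathology": {"age": 0.02, "sex": 0.10},
    "microglia": {"age": 0.01, "sex": -0.10, "pmi": -0.01},
    "slope": {"age": -0.002, "educ": 0.002},
}


@dataclass
class ArchitectureSpec:
    """Genetic architecture of a simulated score and its target phenotype.

    Parameters
    ----------
    allele_freqs : (n_variants,) array
        Effect-allele frequencies, strictly inside (0, 1); frequencies
        outside (0.05, 0.95) draw a warning since the downstream scan
        filters on MAF > 0.1.
    weights : (n_variants,) array
        Published effect weights defining the score (ln OR scale).
    driver_indices, driver_effects
        0-based indices of variants with true per-dosage effects on the
        target phenotype, and those effects in latent-SD units.
    polygenic_effect : float
        Effect of one SD of true score on the target phenotype
        (latent-SD units) — the diffuse alternative to drivers.
    noise_sd : float
        SD of the non-genetic residual in the target phenotype latent.
    """

    n_variants: int
    allele_freqs: np.ndarray
    weights: np.ndarray
    driver_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    driver_effects: np.ndarray = field(default_factory=lambda: np.array([]))
    polygenic_effect: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.driver_indices = np.asarray(self.driver_indices, dtype=int)
        self.driver_effects = np.asarray(self.driver_effects, dtype=float)
        if self.allele_freqs.size != self.n_variants or self.weights.size != self.n_variants:
            raise ValueError("allele_freqs and weights must have length n_variants")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if np.any((self.allele_freqs < 0.05) | (self.allele_freqs > 0.95)):
            warnings.warn(
                "allele frequencies outside (0.05, 0.95); rare variants may "
                "be dropped by the MAF filter downstream",
                UserWarning,
                stacklevel=2,
            )
        if self.driver_indices.size != self.driver_effects.size:
            raise ValueError("driver_indices and driver_effects must align")
        if self.driver_indices.size and (
            self.driver_indices.min() < 0 or self.driver_indices.max() >= self.n_variants
        ):
            raise ValueError("driver_indices out of range")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    # -- convenience constructors for the two architectures under study --

    @classmethod
    def single_driver(
        cls,
        n_variants: int = 67,
        *,
        driver_effect: float = 0.4,
        driver_freq: float = 0.3,
        driver_weight: float = 0.9,
        seed: int = 0,
        **kwargs,
    ) -> "ArchitectureSpec":
        """One variant carries the whole phenotype effect (driver regime).

        The driver also carries a large published weight (default 0.9,
        roughly ln OR 2.5 against a background of ~0.1): a strongly
        weighted variant with a real effect is exactly the situation in
        which a "polygenic" association is an artifact of one locus.
        """
        rng = np.random.default_rng([11, seed])
        freqs = rng.uniform(0.1, 0.9, n_variants)
        didx = n_variants // 2
        freqs[didx] = driver_freq
        weights = np.abs(rng.normal(0.1, 0.05, n_variants))
        weights[didx] = driver_weight
        return cls(
            n_variants=n_variants,
            allele_freqs=freqs,
            weights=weights,
            driver_indices=np.array([didx]),
            driver_effects=np.array([driver_effect]),
            polygenic_effect=0.0,
            seed=seed,
            **kwargs,
        )

    @classmethod
    def diffuse(
        cls,
        n_variants: int = 67,
        *,
        total_effect: float | None = None,
        polygenic_effect: float | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "ArchitectureSpec":
        """Effect spread uniformly through the score (polygenic regime).

        ``total_effect`` sets the SD of the genetic signal so that the
        overall score-phenotype association strength matches a driver
        architecture of that signal SD; alternatively pass
        ``polygenic_effect`` directly.
        """
        rng = np.random.default_rng([11, seed])
        freqs = rng.uniform(0.1, 0.9, n_variants)
        weights = np.abs(rng.normal(0.1, 0.05, n_variants))
        if polygenic_effect is None:
            polygenic_effect = 0.26 if total_effect is None else total_effect
        return cls(
            n_variants=n_variants,
            allele_freqs=freqs,
            weights=weights,
            polygenic_effect=float(polygenic_effect),
            seed=seed,
            **kwargs,
        )


@dataclass
class CohortTruth:
    """Ground truth recorded alongside every simulated cohort."""

    seed: int
    true_scores: np.ndarray  # per-subject true per-allele score
    genetic_signal: np.ndarray  # per-subject latent genetic effect (SD units)
    true_slopes: np.ndarray  # per-subject cognitive slope (z per year)
    variant_effects: pd.DataFrame  # variant_id, weight, target phenotype effect
    subject_ids: np.ndarray = field(default=None)


def _variant_ids(n: int) -> np.ndarray:
    return np.array([f"rs{100000 + i}" for i in range(n)])


def _alleles(spec: ArchitectureSpec) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([7, spec.seed])
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), spec.n_variants)]
    eff = np.array([p[0] for p in pairs])
    oth = np.array([p[1] for p in pairs])
    return eff, oth


def weight_table(spec: ArchitectureSpec, trait_name: str = "trait") -> WeightTable:
    """The weight table defining the simulated score (consistent alleles)."""
    eff, oth = _alleles(spec)
    return WeightTable(
        trait_name,
        pd.DataFrame(
            {
                "variant_id": _variant_ids(spec.n_variants),
                "chrom": np.repeat("1", spec.n_variants),
                "pos": np.arange(1, spec.n_variants + 1) * 1000,
                "effect_allele": eff,
                "other_allele": oth,
                "weight": spec.weights,
                "effect_allele_freq": spec.allele_freqs,
            }
        ),
    )


def simulate_genotypes(
    spec: ArchitectureSpec,
    n_subjects: int,
    *,
    missing_rate: float = 0.0,
    dosage_jitter: float = 0.0,
) -> GenotypeMatrix:
    """Draw effect-allele dosages at independent Hardy-Weinberg loci.

    Hard calls are Binomial(2, f) per locus; ``dosage_jitter`` in (0, 1]
    adds symmetric Beta(2, 2) noise to emulate imputed dosages, and
    ``missing_rate`` blanks entries completely at random.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng([1, spec.seed])
    d = rng.binomial(2, spec.allele_freqs, size=(n_subjects, spec.n_variants)).astype(float)
    if dosage_jitter > 0:
        jit = dosage_jitter * (2.0 * rng.beta(2, 2, size=d.shape) - 1.0)
        d = np.clip(d + jit, 0.0, 2.0)
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    eff, oth = _alleles(spec)
    return GenotypeMatrix(
        subject_ids=np.array([f"S{i:05d}" for i in range(n_subjects)]),
        variant_ids=_variant_ids(spec.n_variants),
        dosage=d,
        counted_allele=eff,
        other_allele=oth,
        chrom=np.repeat("1", spec.n_variants),
        pos=np.arange(1, spec.n_variants + 1) * 1000,
    )


def simulate_covariates(n_subjects: int, seed: int = 0) -> pd.DataFrame:
    """Demographics resembling an elderly autopsy cohort.

    age ~ Normal(89, 6) truncated to [65, 110]; sex ~ Bernoulli(0.65)
    (1 = female); education ~ Normal(16, 3.5) years; postmortem
    interval ~ lognormal (median ~7 h, long right tail); three ancestry
    principal components ~ Normal(0, 1).
    """
    rng = np.random.default_rng([2, seed])
    age = np.clip(rng.normal(89.0, 6.0, n_subjects), 65.0, 110.0)
    sex = rng.binomial(1, 0.65, n_subjects).astype(float)
    educ = np.clip(rng.normal(16.0, 3.5, n_subjects), 5.0, 25.0)
    pmi = rng.lognormal(1.9, 0.6, n_subjects)
    pcs = rng.normal(0.0, 1.0, (n_subjects, 3))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n_subjects)],
            "age": age,
            "sex": sex,
            "educ": educ,
            "pmi": pmi,
            "pc1": pcs[:, 0],
            "pc2": pcs[:, 1],
            "pc3": pcs[:, 2],
        }
    ).set_index("subject_id")


def _genetic_signal(
    genotypes: GenotypeMatrix, spec: ArchitectureSpec
) -> tuple[np.ndarray, np.ndarray]:
    """(true per-allele score, latent genetic effect per subject)."""
    score = compute_grs(weight_table(spec), genotypes).scores.to_numpy()
    g = np.zeros(genotypes.n_subjects)
    d = genotypes.dosage
    fhat = genotypes.effect_allele_freq()
    for idx, eff in zip(spec.driver_indices, spec.driver_effects):
        col = d[:, idx].copy()
        col[~np.isfinite(col)] = 2.0 * fhat[idx]
        g += eff * col
    if spec.polygenic_effect != 0.0:
        sd = score.std()
        if sd > 0:
            g += spec.polygenic_effect * (score - score.mean()) / sd
    return score, g


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    spec: ArchitectureSpec,
    covariates: pd.DataFrame | None = None,
    *,
    targets: tuple[str, ...] = ("microglia",),
    covariate_effects: dict | None = None,
    region_cor: float = 0.5,
    outlier_rate: float = 0.02,
    slope_mean: float = -0.05,
    slope_sd: float = 0.05,
    slope_polygenic: float = 0.0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate the phenotype menu with the spec's planted genetics.

    Phenotypes
    ----------
    Pathology indices (``neuritic_plaques, diffuse_plaques, tangles,
    amyloid, tau``) on a standardized latent scale; microglial count
    densities for 4 regions x 4 activation-stage aggregates plus a
    brain-wide mean (``microglia_all``), on a counts-per-area scale
    floored at 0; and the per-subject true cognitive slope (recorded in
    the returned :class:`CohortTruth`, observable via
    :func:`simulate_longitudinal`).

    The planted genetic latent ``g`` (drivers + polygenic component)
    enters every phenotype family named in ``targets`` in latent-SD
    units.  Stage components within a region share a correlated
    subject-level latent (``region_cor`` across regions), and the
    aggregates are sums of the stage components, so ``stage123 =
    stage1 + stage23`` holds by construction.  With probability
    ``outlier_rate`` a phenotype value is displaced by 5 column SDs to
    exercise robust regression.
    """
    n = genotypes.n_subjects
    if covariates is None:
        covariates = simulate_covariates(n, seed=spec.seed)
    eff_cfg = covariate_effects if covariate_effects is not None else DEFAULT_COVARIATE_EFFECTS
    rng = np.random.default_rng([3, spec.seed])
    score, g = _genetic_signal(genotypes, spec)

    cov_c = covariates[["age", "sex", "educ", "pmi"]] - covariates[
        ["age", "sex", "educ", "pmi"]
    ].mean()

    def cov_term(family: str) -> np.ndarray:
        out = np.zeros(n)
        for name, beta in eff_cfg.get(family, {}).items():
            out += beta * cov_c[name].to_numpy()
        return out

    pheno = {}
    g_path = g if "pathology" in targets else 0.0
    for name in PATHOLOGY_PHENOTYPES:
        pheno[name] = cov_term("pathology") + g_path + spec.noise_sd * rng.normal(0, 1, n)

    g_mic = g if "microglia" in targets else 0.0
    common = rng.normal(0, 1, n)
    stage123_by_region = []
    for region in REGIONS:
        region_lat = np.sqrt(region_cor) * common + np.sqrt(1 - region_cor) * rng.normal(0, 1, n)
        comps = {}
        for s in (1, 2, 3):
            x = (
                g_mic
                + cov_term("microglia")
                + spec.noise_sd
                * (np.sqrt(0.5) * region_lat + np.sqrt(0.5) * rng.normal(0, 1, n))
            )
            mu, sig = _STAGE_MU[s], _STAGE_SIGMA_FRAC * _STAGE_MU[s]
            comps[s] = np.maximum(mu + sig * x, 0.0)
        pheno[f"microglia_{region}_stage1"] = comps[1]
        pheno[f"microglia_{region}_stage123"] = comps[1] + comps[2] + comps[3]
        pheno[f"microglia_{region}_stage23"] = comps[2] + comps[3]
        pheno[f"microglia_{region}_stage3"] = comps[3]
        stage123_by_region.append(pheno[f"microglia_{region}_stage123"])
    pheno["microglia_all"] = np.mean(stage123_by_region, axis=0)

    g_slope = g if "cognition" in targets else 0.0
    slope_score_term = 0.0
    if slope_polygenic != 0.0 and score.std() > 0:
        slope_score_term = slope_polygenic * (score - score.mean()) / score.std()
    # one latent-SD of genetic signal moves the slope by one slope-SD
    true_slopes = (
        slope_mean
        + cov_term("slope")
        + slope_sd * g_slope
        + slope_score_term
        + rng.normal(0, slope_sd, n)
    )

    df = pd.DataFrame(pheno, index=covariates.index)
    if outlier_rate > 0:
        mask = rng.random(df.shape) < outlier_rate
        sds = df.std(axis=0).to_numpy()
        shift = 5.0 * sds * rng.choice([-1.0, 1.0], size=df.shape)
        df = df.where(~mask, df + shift)
        mic = [c for c in df.columns if c.startswith("microglia")]
        df[mic] = df[mic].clip(lower=0.0)

    per_variant = np.zeros(spec.n_variants)
    per_variant[spec.driver_indices] = spec.driver_effects
    truth = CohortTruth(
        seed=spec.seed,
        true_scores=score,
        genetic_signal=np.asarray(g, dtype=float) + np.zeros(n),
        true_slopes=true_slopes,
        variant_effects=pd.DataFrame(
            {
                "variant_id": _variant_ids(spec.n_variants),
                "weight": spec.weights,
                "target_effect": per_variant,
            }
        ),
        subject_ids=genotypes.subject_ids,
    )
    return df, truth


def simulate_longitudinal(
    truth: CohortTruth,
    n_visits: int = 8,
    visit_noise_sd: float = 0.2,
    *,
    intercept_sd: float = 0.25,
    domain: str = "global",
    dropout_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annual cognitive composites: ``z_t = a_i + slope_i * t + noise``.

    Subjects keep their true slope from ``truth``; ``dropout_rate`` is a
    per-visit hazard of leaving the study (staggered follow-up), never
    truncating below 2 visits.  Returns a long table ``subject_id,
    time, domain, score``.
    """
    if n_visits < 2:
        raise ValueError("need at least 2 visits for slope estimation")
    if n_visits == 2:
        warnings.warn(
            "only 2 visits: slopes are defined but noisy", UserWarning, stacklevel=2
        )
    rng = np.random.default_rng([4, truth.seed if seed is None else seed])
    n = truth.true_slopes.size
    intercepts = rng.normal(0.0, intercept_sd, n)
    times = np.arange(n_visits, dtype=float)
    rows = []
    for i in range(n):
        last = n_visits
        if dropout_rate > 0:
            surv = rng.random(n_visits) >= dropout_rate
            surv[:2] = True
            stop = np.where(~surv)[0]
            last = stop[0] if stop.size else n_visits
        t = times[:last]
        z = intercepts[i] + truth.true_slopes[i] * t + rng.normal(0, visit_noise_sd, t.size)
        sid = truth.subject_ids[i] if truth.subject_ids is not None else f"S{i:05d}"
        rows.append(pd.DataFrame({"subject_id": sid, "time": t, "domain": domain, "score": z}))
    return pd.concat(rows, ignore_index=True)


def default_module_ids(n_modules: int = 47) -> list[str]:
    return [f"m{i:02d}" for i in range(1, n_modules + 1)]


DEFAULT_IMMUNE_MODULES = ("m05", "m13", "m21", "m34", "m42")


def simulate_modules(
    genotypes: GenotypeMatrix,
    eqtl_spec,
    *,
    n_modules: int = 47,
    immune_modules: tuple[str, ...] = DEFAULT_IMMUNE_MODULES,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Gene co-expression module summaries with planted eQTL effects.

    ``eqtl_spec`` is an iterable of ``(variant_id, module_id, beta)``:
    each mapped variant adds ``beta * dosage`` to that module's value
    (missing dosages mean-imputed); everything else is Gaussian noise.
    Returns the subject x module expression table and the list of
    module ids flagged as immune.
    """
    ids = default_module_ids(n_modules)
    idset = set(ids)
    bad = [m for m in immune_modules if m not in idset]
    if bad:
        raise ValueError(f"immune modules not among simulated modules: {bad}")
    rng = np.random.default_rng([5, seed])
    n = genotypes.n_subjects
    expr = rng.normal(0.0, noise_sd, (n, n_modules))
    df = pd.DataFrame(expr, index=pd.Index(genotypes.subject_ids, name="subject_id"), columns=ids)
    fhat = genotypes.effect_allele_freq()
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for variant_id, module_id, beta in eqtl_spec:
        if module_id not in idset:
            raise ValueError(f"eQTL maps to nonexistent module {module_id!r}")
        if variant_id not in vidx:
            raise ValueError(f"eQTL references unknown variant {variant_id!r}")
        j = vidx[variant_id]
        col = genotypes.dosage[:, j].copy()
        col[~np.isfinite(col)] = 2.0 * fhat[j]
        df[module_id] = df[module_id] + beta * col
    return df, list(immune_modules)
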