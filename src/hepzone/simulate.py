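"""Synthetic data generators with known ground truth.

Three generators emulate the three data modalities the pipeline consumes:

* :func:`generate_lobule_counts` — single-nucleus count matrices in which each
  nucleus carries a latent lobular coordinate ``u`` in [0, 1] (0 = pericentral,
  1 = periportal) and each gene's expected expression is a smooth function of
  ``u``, with negative-binomial counting noise and log-normal library sizes.
  A knockout genotype perturbs designated gene programs (flatten / ablate /
  expand), mimicking the collapse of zonation gradients seen when the
  pericentral Wnt/beta-catenin program is disrupted.
* :func:`generate_smfish_field` — smFISH-like spot fields: an inhomogeneous
  Poisson point process over tissue pixels whose rate depends on the relative
  radial coordinate ``r = d_CV / (d_CV + d_PV)`` between a central-vein and a
  portal-vein outline, optionally rendered to an image with a Gaussian PSF.
* :func:`generate_cohort` — biobank-style cohorts: Hardy–Weinberg genotypes,
  a logistic disease model with a per-allele log-odds, and Gaussian biomarkers
  with per-allele mean shifts, plus age/sex/ancestry-PC covariates.

Every generator is deterministic given its config's ``seed``; one global seed
is expanded into independent per-component substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "LobuleSimConfig",
    "SyntheticTruth",
    "SmfishSimConfig",
    "VeinOutline",
    "CohortSimConfig",
    "BiomarkerSpec",
    "generate_lobule_counts",
    "generate_smfish_field",
    "generate_cohort",
    "aggregate_cohort",
]

GENE_CLASSES = ("pericentral_monotone", "periportal_monotone", "mid_peaked", "flat")
KO_EFFECTS = ("flatten", "ablate", "expand")


# ---------------------------------------------------------------------------
# lobule count generator
# ---------------------------------------------------------------------------

@dataclass
class LobuleSimConfig:
    """Configuration for the zonated count-matrix generator.

    Defaults describe a scaled-down but realistically structured lobule:
    roughly half of the panel is zonated, gradients are two-fold end to end,
    and counting noise is moderately overdispersed.
    """

    n_nuclei_per_genotype: int = 2000
    n_pericentral: int = 150
    n_periportal: int = 150
    n_mid_peaked: int = 75
    n_flat: int = 600
    n_mito: int = 25
    gradient_fold: float = 2.0
    base_mean: float = 2.0          # mean expected counts per gene per nucleus
    ramp_steepness: float = 8.0     # logistic slope of the monotone profiles
    mid_width: float = 0.12         # SD of the mid-lobular Gaussian bump
    mito_mean: float = 0.5
    nb_dispersion: float = 0.15     # phi; Var = mu + phi * mu^2 (0 -> Poisson)
    library_size_logmean: float = 0.0
    library_size_logsd: float = 0.25
    ko_effect: Mapping[str, str] | None = None  # gene -> flatten|ablate|expand
    seed: int = 0

    def validate(self, genes: Sequence[str]) -> None:
        for name in ("n_pericentral", "n_periportal", "n_mid_peaked", "n_flat", "n_mito"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_nuclei_per_genotype <= 0:
            raise ValueError("n_nuclei_per_genotype must be positive")
        if len(genes) == 0:
            raise ValueError("gene panel is empty: all gene class counts are zero")
        if self.gradient_fold <= 1:
            raise ValueError("gradient_fold must be > 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.ko_effect:
            panel = set(genes)
            for gene, effect in self.ko_effect.items():
                if gene not in panel:
                    raise ValueError(f"ko_effect gene {gene!r} not in the gene panel")
                if effect not in KO_EFFECTS:
                    raise ValueError(f"unknown ko_effect {effect!r} for gene {gene!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for parameter-recovery tests."""

    u: np.ndarray                    # latent lobular coordinate per nucleus
    genotype: np.ndarray             # 'CON' or 'KO' per nucleus
    gene_class: pd.Series            # gene -> class label
    ko_effect: dict[str, str]        # gene -> applied KO effect
    config: LobuleSimConfig

    def expected_expression(self, gene: str, genotype: str, u: np.ndarray) -> np.ndarray:
        """Expected counts mu_g(u) (before library-size scaling)."""
        mu = _profile_fn(gene, self.gene_class[gene], self.config)(np.asarray(u, float))
        if genotype == "KO" and gene in self.ko_effect:
            mu = _apply_ko(mu, _profile_fn(gene, self.gene_class[gene], self.config),
                           self.ko_effect[gene])
        return mu


def _panel(config: LobuleSimConfig) -> tuple[list[str], pd.Series]:
    names: list[str] = []
    classes: list[str] = []
    for cls, n, prefix in (
        ("pericentral_monotone", config.n_pericentral, "PCg"),
        ("periportal_monotone", config.n_periportal, "PPg"),
        ("mid_peaked", config.n_mid_peaked, "MIDg"),
        ("flat", config.n_flat, "FLATg"),
        ("flat", config.n_mito, "mt-g"),
    ):
        for i in range(n):
            names.append(f"{prefix}{i:03d}")
            classes.append(cls)
    return names, pd.Series(classes, index=names, name="gene_class")


def _profile_fn(gene: str, cls: str, config: LobuleSimConfig) -> Callable[[np.ndarray], np.ndarray]:
    base = config.mito_mean if gene.startswith("mt-") else config.base_mean
    fold = config.gradient_fold
    lo = 2.0 * base / (1.0 + fold)
    hi = fold * lo
    s = config.ramp_steepness
    if cls == "pericentral_monotone":
        # decreasing in u: peak at the central vein (u = 0)
        return lambda u: lo + (hi - lo) / (1.0 + np.exp(s * (u - 0.5)))
    if cls == "periportal_monotone":
        return lambda u: lo + (hi - lo) / (1.0 + np.exp(-s * (u - 0.5)))
    if cls == "mid_peaked":
        w = config.mid_width
        return lambda u: lo + (hi - lo) * np.exp(-((u - 0.5) ** 2) / (2.0 * w * w))
    return lambda u: np.full_like(np.asarray(u, float), base)


def _apply_ko(mu: np.ndarray, fn: Callable, effect: str) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, 1001)
    prof = fn(grid)
    if effect == "flatten":
        return np.full_like(mu, np.trapezoid(prof, grid))
    if effect == "ablate":
        return np.full_like(mu, 0.02 * np.trapezoid(prof, grid))
    if effect == "expand":
        return np.full_like(mu, prof.max())
    raise ValueError(effect)


def default_ko_effect(config: LobuleSimConfig) -> dict[str, str]:
    """A knockout resembling loss of the pericentral program: the pericentral
    genes lose zonation (a few are ablated outright), a few periportal genes
    become ubiquitous, and the rest of the periportal program flattens."""
    genes, classes = _panel(config)
    out: dict[str, str] = {}
    pc = [g for g in genes if classes[g] == "pericentral_monotone"]
    pp = [g for g in genes if classes[g] == "periportal_monotone"]
    n_abl = max(1, len(pc) // 15)
    n_exp = max(1, len(pp) // 15)
    for g in pc[:n_abl]:
        out[g] = "ablate"
    for g in pc[n_abl:]:
        out[g] = "flatten"
    for g in pp[:n_exp]:
        out[g] = "expand"
    for g in pp[n_exp:]:
        out[g] = "flatten"
    return out


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma–Poisson draw with Var = mu + phi*mu^2; phi = 0 is Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def generate_lobule_counts(config: LobuleSimConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Simulate a gene-by-nucleus count matrix for a CON and a KO genotype.

    Returns an :class:`anndata.AnnData` (nuclei x genes) with integer counts,
    ``obs['genotype']``, ``obs['true_u']`` and ``var['mito']``, together with
    the :class:`SyntheticTruth` record.
    """
    genes, classes = _panel(config)
    config.validate(genes)
    if config.ko_effect is None:
        ko_effect = default_ko_effect(config)
    else:
        ko_effect = dict(config.ko_effect)

    ss = np.random.SeedSequence(config.seed)
    rng_u, rng_lib, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    n = config.n_nuclei_per_genotype
    u = rng_u.uniform(0.0, 1.0, size=2 * n)
    genotype = np.array(["CON"] * n + ["KO"] * n)
    lib = np.exp(rng_lib.normal(config.library_size_logmean,
                                config.library_size_logsd, size=2 * n))

    mu = np.empty((2 * n, len(genes)))
    ko_mask = genotype == "KO"
    for j, g in enumerate(genes):
        fn = _profile_fn(g, classes[g], config)
        mu[:, j] = fn(u)
        if g in ko_effect:
            mu[ko_mask, j] = _apply_ko(mu[ko_mask, j], fn, ko_effect[g])
    mu *= lib[:, None]

    counts = _nb_counts(rng_counts, mu, config.nb_dispersion)

    obs = pd.DataFrame(
        {"genotype": pd.Categorical(genotype, categories=["CON", "KO"]),
         "true_u": u},
        index=[f"nucleus{i:05d}" for i in range(2 * n)],
    )
    var = pd.DataFrame(
        {"mito": [g.startswith("mt-") for g in genes],
         "gene_class": classes.values},
        index=genes,
    )
    adata = ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
    truth = SyntheticTruth(u=u, genotype=genotype, gene_class=classes,
                           ko_effect=ko_effect, config=config)
    return adata, truth


# ---------------------------------------------------------------------------
# smFISH field generator
# ---------------------------------------------------------------------------

@dataclass
class VeinOutline:
    """A central or portal vein outline (simple closed polygon, pixel units)."""

    polygon: Polygon
    kind: str  # 'central' | 'portal'

    def __post_init__(self) -> None:
        if self.kind not in ("central", "portal"):
            raise ValueError("kind must be 'central' or 'portal'")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("vein outline must be a valid non-empty polygon")


@dataclass
class SmfishSimConfig:
    """Configuration for the smFISH spot-field generator.

    ``lam_intercept``/``lam_slope`` parameterize a linear transcript density
    lambda(r) = intercept + slope * r in spots per pixel, where r is the
    relative distance from the central vein. The default is pericentrally
    skewed, like glutamine synthetase (Glul) expression.
    """

    width: int = 512
    height: int = 512
    cv_center: tuple[float, float] = (130.0, 256.0)
    cv_radius: float = 40.0
    pv_center: tuple[float, float] = (420.0, 256.0)
    pv_radius: float = 28.0
    lam_intercept: float = 0.004
    lam_slope: float = -0.003
    gene: str = "Glul"
    psf_sigma: float = 1.5
    background: float = 0.02
    amplitude: float = 1.0
    n_images: int = 3
    n_mice: int = 3
    seed: int = 0

    def veins(self) -> tuple[VeinOutline, VeinOutline]:
        cv = VeinOutline(Point(*self.cv_center).buffer(self.cv_radius, quad_segs=64),
                         "central")
        pv = VeinOutline(Point(*self.pv_center).buffer(self.pv_radius, quad_segs=64),
                         "portal")
        return cv, pv

    def intensity(self, r: np.ndarray) -> np.ndarray:
        return self.lam_intercept + self.lam_slope * np.asarray(r, float)

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        cv, pv = self.veins()
        if cv.polygon.intersects(pv.polygon):
            raise ValueError("central and portal vein polygons overlap")
        frame = shapely.box(0, 0, self.width, self.height)
        if not (frame.contains(cv.polygon) and frame.contains(pv.polygon)):
            raise ValueError("vein polygons must lie inside the image")
        r = np.linspace(0, 1, 101)
        if np.any(self.intensity(r) < 0):
            raise ValueError("lambda(r) must be non-negative on [0, 1]")


def relative_radial_coordinate(x: np.ndarray, y: np.ndarray,
                               cv: VeinOutline, pv: VeinOutline) -> np.ndarray:
    """r = d_CV / (d_CV + d_PV) with distances to the polygon boundaries."""
    pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
    d_cv = shapely.distance(pts, cv.polygon.exterior)
    d_pv = shapely.distance(pts, pv.polygon.exterior)
    denom = d_cv + d_pv
    if np.any(denom == 0):
        raise ValueError("a point is simultaneously on both vein boundaries")
    return d_cv / denom


def _render(spots: pd.DataFrame, config: SmfishSimConfig,
            rng: np.random.Generator) -> np.ndarray:
    img = rng.normal(0.0, config.background, size=(config.height, config.width))
    sig = config.psf_sigma
    half = int(np.ceil(4 * sig))
    for x, y in zip(spots["x"], spots["y"]):
        j0, i0 = int(np.floor(x)), int(np.floor(y))
        jj = np.arange(max(0, j0 - half), min(config.width, j0 + half + 1))
        ii = np.arange(max(0, i0 - half), min(config.height, i0 + half + 1))
        if len(jj) == 0 or len(ii) == 0:
            continue
        gx = np.exp(-((jj - x) ** 2) / (2 * sig * sig))
        gy = np.exp(-((ii - y) ** 2) / (2 * sig * sig))
        img[np.ix_(ii, jj)] += config.amplitude * np.outer(gy, gx)
    return img


def generate_smfish_field(
    config: SmfishSimConfig, render: bool = False
) -> tuple[pd.DataFrame, tuple[VeinOutline, VeinOutline], list[np.ndarray] | None, Callable]:
    """Simulate smFISH spot fields for ``n_mice`` mice x ``n_images`` images.

    Spots follow an inhomogeneous Poisson process with rate lambda(r) over
    tissue pixels (vein interiors excluded), generated by thinning. Returns
    the spot table (x, y, gene, image, mouse), the vein outlines, optional
    rendered images, and the true intensity function.
    """
    config.validate()
    cv, pv = config.veins()
    lam_max = float(np.max(config.intensity(np.linspace(0, 1, 201))))
    if lam_max <= 0:
        raise ValueError("lambda(r) is identically zero")

    ss = np.random.SeedSequence(config.seed)
    rows: list[pd.DataFrame] = []
    images: list[np.ndarray] | None = [] if render else None
    image_id = 0
    for mouse in range(config.n_mice):
        for _ in range(config.n_images):
            rng = np.random.default_rng(ss.spawn(1)[0])
            n_cand = rng.poisson(lam_max * config.width * config.height)
            x = rng.uniform(0, config.width, size=n_cand)
            y = rng.uniform(0, config.height, size=n_cand)
            pts = shapely.points(x, y)
            in_vein = shapely.contains(cv.polygon, pts) | shapely.contains(pv.polygon, pts)
            x, y = x[~in_vein], y[~in_vein]
            r = relative_radial_coordinate(x, y, cv, pv)
            keep = rng.uniform(0, 1, size=len(x)) < config.intensity(r) / lam_max
            spots = pd.DataFrame({
                "x": x[keep], "y": y[keep],
                "gene": config.gene,
                "image": f"img{image_id:03d}",
                "mouse": f"mouse{mouse:02d}",
            })
            rows.append(spots)
            if render:
                images.append(_render(spots, config, rng))
            image_id += 1
    table = pd.concat(rows, ignore_index=True)
    return table, (cv, pv), images, config.intensity


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSpec:
    """A Gaussian biomarker with a per-T-allele mean shift."""

    mean: float
    per_allele: float
    sd: float
    age_slope: float = 0.0
    male_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("biomarker residual SD must be > 0")


def _default_biomarkers() -> dict[str, BiomarkerSpec]:
    # Glucose rises and glutamine falls with T-allele dosage, on roughly the
    # scales reported for NMR biomarker panels (mmol/l and umol/l).
    return {
        "glucose": BiomarkerSpec(mean=5.0, per_allele=0.055, sd=0.8),
        "glutamine": BiomarkerSpec(mean=560.0, per_allele=-2.0, sd=60.0),
    }


@dataclass
class CohortSimConfig:
    """Hardy–Weinberg cohort with a logistic disease model and biomarkers."""

    n_individuals: int = 50_000
    q: float = 0.29                  # T-allele frequency
    disease_intercept: float = -3.3
    per_allele_log_odds: float = 0.30
    age_mean: float = 56.6
    age_sd: float = 8.0
    p_male: float = 0.46
    n_pcs: int = 10
    age_log_odds: float = 0.04       # per year, age centered
    male_log_odds: float = 0.25
    pc_log_odds: float = 0.0
    biomarkers: dict[str, BiomarkerSpec] = field(default_factory=_default_biomarkers)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("allele frequency q must be in [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be > 0")
        for spec in self.biomarkers.values():
            if spec.sd <= 0:
                raise ValueError("biomarker residual SD must be > 0")


def generate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an individual-level cohort and its genotype-by-case aggregate.

    Genotypes are Hardy–Weinberg at frequency ``q``; disease status follows a
    logistic model in dosage, centered age, sex and ancestry PCs; biomarkers
    are Gaussian with per-allele shifts. Returns ``(individuals, counts)``
    where ``counts`` has one row per dosage with columns n and cases.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_dis, rng_bio = (np.random.default_rng(s) for s in ss.spawn(4))

    n = config.n_individuals
    dosage = rng_geno.binomial(2, config.q, size=n)
    age = rng_cov.normal(config.age_mean, config.age_sd, size=n)
    male = rng_cov.binomial(1, config.p_male, size=n)
    pcs = rng_cov.normal(0.0, 1.0, size=(n, config.n_pcs))

    eta = (config.disease_intercept
           + config.per_allele_log_odds * dosage
           + config.age_log_odds * (age - config.age_mean)
           + config.male_log_odds * male
           + config.pc_log_odds * pcs.sum(axis=1))
    case = rng_dis.binomial(1, 1.0 / (1.0 + np.exp(-eta)))

    data = {"dosage": dosage, "case": case, "age": age, "male": male}
    for j in range(config.n_pcs):
        data[f"pc{j + 1}"] = pcs[:, j]
    for name, spec in config.biomarkers.items():
        data[name] = (spec.mean
                      + spec.per_allele * dosage
                      + spec.age_slope * (age - config.age_mean)
                      + spec.male_shift * male
                      + rng_bio.normal(0.0, spec.sd, size=n))
    individuals = pd.DataFrame(data)
    counts = aggregate_cohort(individuals)
    return individuals, counts


def aggregate_cohort(individuals: pd.DataFrame) -> pd.DataFrame:
    """Collapse an individual-level table to genotype-by-case counts."""
    rows = []
    for d in (0, 1, 2):
        sub = individuals[individuals["dosage"] == d]
        rows.append({"dosage": d, "n": len(sub), "cases": int(sub["case"].sum())})
    return pd.DataFrame(rows)
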