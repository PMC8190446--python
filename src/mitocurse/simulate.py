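"""Synthetic mitonuclear panel generator.

Phenotypes are drawn from an additive fixed-effects structure with
sex-specific mitochondrial and mitonuclear-interaction effects:

    y = mu + s * delta + alpha_nuc + beta_(mito, sex) + gamma_(nuc, mito, sex) + eps

where ``s`` is a female indicator (females carry the dimorphism term),
``alpha`` is a nuclear main effect shared between sexes, and ``beta`` /
``gamma`` are drawn per label *per sex* from a bivariate normal with a
configurable cross-sex correlation.  Effects are drawn once per label and
reused across replicate individuals, so line means are meaningful — each
genotype is a clonal line, not a fresh draw per fly.

The male-biased mitochondrial variance signal ("mother's curse") is encoded
as ``sigma_mito_m > sigma_mito_f``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import PanelDesign, drosophila_panel

#: canonical sex codes used throughout the package
FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

PHENOTYPE_COLUMNS = ["individual_id", "nuc", "mito", "sex", "replicate", "trait"]

#: individuals measured per vial in the synthetic replicate labelling
_VIAL_SIZE = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Variance-component configuration for :func:`simulate_panel`.

    Defaults emulate a wing-size-like trait (units: mm): strong female-larger
    sexual dimorphism, nuclear main effects explaining about half the
    within-sex variance, substantial mitonuclear epistasis, small mitochondrial
    main effects that are larger in males than in females, and residual noise
    from measurement plus within-line environmental variation.
    """

    design: PanelDesign = field(default_factory=drosophila_panel)
    n_per_cell: int = 15
    grand_mean: float = 2.50
    sex_effect: float = 0.25
    sigma_nuc: float = 0.055
    sigma_mito_f: float = 0.0075
    sigma_mito_m: float = 0.012
    sigma_epi_f: float = 0.026
    sigma_epi_m: float = 0.031
    sigma_resid: float = 0.045
    cross_sex_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        sds = {
            "sigma_nuc": self.sigma_nuc,
            "sigma_mito_f": self.sigma_mito_f,
            "sigma_mito_m": self.sigma_mito_m,
            "sigma_epi_f": self.sigma_epi_f,
            "sigma_epi_m": self.sigma_epi_m,
            "sigma_resid": self.sigma_resid,
        }
        for name, value in sds.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not -1.0 <= self.cross_sex_corr <= 1.0:
            raise ValueError(
                f"cross_sex_corr must lie in [-1, 1], got {self.cross_sex_corr}"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def curse_scenario(seed: int = 0, ratio: float = 2.0) -> SimulationConfig:
    """Benchmark condition with a strong, detectable curse signal.

    Male mitochondrial effect SD is ``ratio`` times the female one, and the
    mitochondrial component dominates the across-haplotype line-mean variance
    (small epistasis and shot noise).  With the default 2x ratio the
    per-nucleus male/female variance ratio of line means is ~3.7, which an
    F(8,8)-ratio argument puts at ~0.96 probability of a positive CV
    difference per nucleus — high enough that >= 8 of 9 nuclei come out
    positive in most replicate panels.
    """
    return SimulationConfig(
        n_per_cell=15, seed=seed,
        sigma_nuc=0.05, sigma_mito_f=0.025, sigma_mito_m=0.025 * ratio,
        sigma_epi_f=0.005, sigma_epi_m=0.005, sigma_resid=0.025,
    )


def curse_free_scenario(seed: int = 0) -> SimulationConfig:
    """Benchmark condition with no sex asymmetry whatsoever.

    Two deliberate choices make this an honest null for the CV sign test:
    ``sex_effect`` is zero (the CV divides by the group mean, so equal
    absolute spreads over unequal sex means would mechanically inflate the
    smaller sex's CV), and the mitochondrial SD is small relative to the
    epistatic SD (mitochondrial effects are shared across nuclei, so a
    mito-dominated spread would correlate the nine per-nucleus signs and the
    nominally independent sign test would over-reject).
    """
    return SimulationConfig(
        n_per_cell=15, seed=seed, sex_effect=0.0,
        sigma_nuc=0.05, sigma_mito_f=0.01, sigma_mito_m=0.01,
        sigma_epi_f=0.03, sigma_epi_m=0.03, sigma_resid=0.025,
    )


def _paired_effects(
    rng: np.random.Generator, n: int, sd_f: float, sd_m: float, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """n draws of (female, male) effects with cross-sex correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    eff_f = sd_f * z1
    eff_m = sd_m * (rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
    return eff_f, eff_m


def simulate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Simulate one measured panel.

    Returns
    -------
    pandas.DataFrame
        Long-format phenotype table with columns
        ``individual_id, nuc, mito, sex, replicate, trait`` — one row per
        individual; incompatible design cells emit no rows.
    """
    d = config.design
    rng = np.random.default_rng(config.seed)

    alpha = dict(zip(d.nuc_labels, config.sigma_nuc * rng.standard_normal(len(d.nuc_labels))))
    bf, bm = _paired_effects(
        rng, len(d.mito_labels), config.sigma_mito_f, config.sigma_mito_m,
        config.cross_sex_corr,
    )
    beta = {FEMALE: dict(zip(d.mito_labels, bf)), MALE: dict(zip(d.mito_labels, bm))}

    cells = d.cells()
    gf, gm = _paired_effects(
        rng, len(cells), config.sigma_epi_f, config.sigma_epi_m, config.cross_sex_corr
    )
    gamma = {FEMALE: dict(zip(cells, gf)), MALE: dict(zip(cells, gm))}

    n = config.n_per_cell
    groups = [(nuc, mito, sex) for nuc, mito in cells for sex in SEXES]
    base = np.array(
        [
            config.grand_mean
            + (config.sex_effect if sex == FEMALE else 0.0)
            + alpha[nuc]
            + beta[sex][mito]
            + gamma[sex][(nuc, mito)]
            for nuc, mito, sex in groups
        ]
    )
    n_groups = len(groups)
    trait = np.repeat(base, n) + config.sigma_resid * rng.standard_normal(n_groups * n)

    nuc_col = pd.Series(np.repeat([g[0] for g in groups], n), dtype="str")
    mito_col = pd.Series(np.repeat([g[1] for g in groups], n), dtype="str")
    sex_col = pd.Series(np.repeat([g[2] for g in groups], n), dtype="str")
    k = np.tile(np.arange(n), n_groups)
    out = pd.DataFrame(
        {
            "individual_id": nuc_col.str.cat(
                [mito_col, sex_col.str[0] + pd.Series(k + 1).astype(str)], sep="-"
            ),
            "nuc": nuc_col,
            "mito": mito_col,
            "sex": sex_col,
            "replicate": pd.Series(k // _VIAL_SIZE + 1).map("v{}".format),
            "trait": trait,
        }
    )
    return out


def simulate_distance_matrix(
    design: PanelDesign, mean_snps: float, seed: int = 0, dispersion: float = 10.0
):
    """Simulate a pairwise SNP-count matrix over the design's haplotypes.

    Off-diagonal entries are independent negative-binomial counts with mean
    ``mean_snps`` (overdispersed relative to Poisson, as real between-strain
    SNP counts are); the matrix is symmetric with a zero diagonal.

    Returns a :class:`skbio.DistanceMatrix` keyed by the mito labels.
    """
    from skbio import DistanceMatrix

    labels = design.mito_labels
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two haplotypes to have pairwise distances")
    if mean_snps <= 0:
        raise ValueError("mean_snps must be > 0")
    rng = np.random.default_rng(seed)
    p = dispersion / (dispersion + mean_snps)
    mat = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    mat[iu] = rng.negative_binomial(dispersion, p, size=len(iu[0])).astype(float)
    mat = mat + mat.T
    return DistanceMatrix(mat, ids=list(labels))
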