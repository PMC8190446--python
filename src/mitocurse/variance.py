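"""Line means, coefficients of variation, bootstrap, and the sign test.

The mother's curse prediction is tested by comparing, within each nuclear
background, the dispersion of mitochondrial line means between the sexes.
Dispersion is measured as the coefficient of variation (CV = sample SD of
the across-haplotype line means divided by their mean); a male-biased
mitochondrial mutation load predicts male CV > female CV for most nuclear
backgrounds, assessed with an exact two-sided sign test.

The bootstrap resamples the vector of line means with replacement (the line
mean — one genotype x sex cell — is the sampling unit, not the individual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import PanelDesign
from .simulate import FEMALE, MALE, SEXES


class AnalysisError(ValueError):
    """Raised when an analysis step receives data it cannot operate on."""


def line_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean trait value and count per (nuc, sex, mito) cell.

    Returns a DataFrame indexed by ``(nuc, sex, mito)`` with columns
    ``mean`` and ``n``.
    """
    if table.empty:
        raise AnalysisError("empty phenotype table")
    grouped = table.groupby(["nuc", "sex", "mito"], sort=True)["trait"]
    out = grouped.agg(mean="mean", n="size")
    out["n"] = out["n"].astype(int)
    return out


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each trait value by its (nuc, sex) group mean.

    After standardization every (nuc, sex) group has mean 1, which puts
    mitochondrial variation in all backgrounds and both sexes on a common
    relative scale for visual comparison.  CVs are unaffected (they are
    scale-free within each group).
    """
    group_means = table.groupby(["nuc", "sex"])["trait"].transform("mean")
    bad = table.loc[group_means == 0, ["nuc", "sex"]]
    if not bad.empty:
        nuc, sex = bad.iloc[0]
        raise AnalysisError(
            f"group (nuc={nuc!r}, sex={sex!r}) has zero mean trait; "
            "cannot standardize by division"
        )
    out = table.copy()
    out["trait"] = table["trait"] / group_means
    return out


def _cv(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1) / np.mean(values))


def _bootstrap_cvs(means: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    k = means.size
    idx = rng.integers(0, k, size=(n_boot, k))
    samples = means[idx]
    sd = samples.std(axis=1, ddof=1)
    return sd / samples.mean(axis=1)


@dataclass(frozen=True)
class CVEstimate:
    """Coefficient of variation of a vector of line means, with bootstrap.

    ``cv_point`` uses the n-1 sample SD; ``raw_variance``/``raw_sd`` are the
    sample variance and SD of the line means on the trait scale; the CI is
    the 2.5/97.5 percentile interval of the bootstrap CVs.
    """

    nuc: str
    sex: str
    cv_point: float
    raw_variance: float
    raw_sd: float
    n_lines: int
    bootstrap_cvs: np.ndarray = field(repr=False)
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {
            "nuc": self.nuc,
            "sex": self.sex,
            "cv": self.cv_point,
            "variance": self.raw_variance,
            "sd": self.raw_sd,
            "n_lines": self.n_lines,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _cv_estimate_from_means(
    means: np.ndarray, nuc: str, sex: str, n_boot: int, rng: np.random.Generator
) -> CVEstimate:
    if means.size < 2:
        raise AnalysisError(
            f"group (nuc={nuc!r}, sex={sex!r}) has {means.size} haplotype mean(s); "
            "need >= 2 for a CV"
        )
    if means.mean() <= 0:
        raise AnalysisError(
            f"group (nuc={nuc!r}, sex={sex!r}) has non-positive mean of line means; "
            "CV is undefined for this trait convention"
        )
    boots = _bootstrap_cvs(means, n_boot, rng)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CVEstimate(
        nuc=nuc,
        sex=sex,
        cv_point=_cv(means),
        raw_variance=float(np.var(means, ddof=1)),
        raw_sd=float(np.std(means, ddof=1)),
        n_lines=int(means.size),
        bootstrap_cvs=boots,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def mito_cv(
    table: pd.DataFrame, nuc: str, sex: str, n_boot: int = 1000, seed: int = 0
) -> CVEstimate:
    """Mitochondrial CV for one (nucleus, sex) group on untransformed data.

    The line means of all haplotypes observed in the group form the vector
    whose CV is taken; the bootstrap resamples that vector with replacement
    ``n_boot`` times.
    """
    means = line_means(table)
    try:
        group = means.loc[(nuc, sex)]
    except KeyError:
        raise AnalysisError(f"no rows for (nuc={nuc!r}, sex={sex!r})") from None
    rng = np.random.default_rng(seed)
    return _cv_estimate_from_means(
        group["mean"].to_numpy(), nuc, sex, n_boot, rng
    )


def sign_test_pvalue(n_positive: int, n_informative: int) -> float:
    """Exact two-sided binomial sign test at p = 1/2.

    ``p = min(1, 2 * min(P(X <= k), P(X >= k)))`` for ``X ~ Bin(n, 1/2)``.
    """
    if not 0 <= n_positive <= n_informative:
        raise ValueError("need 0 <= n_positive <= n_informative")
    if n_informative == 0:
        raise AnalysisError("sign test needs at least one informative pair")
    lower = stats.binom.cdf(n_positive, n_informative, 0.5)
    upper = stats.binom.sf(n_positive - 1, n_informative, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class SignTestResult:
    """Cross-nucleus sign test of male vs female mitochondrial CV.

    ``difference_summary`` maps nucleus -> (male CV - female CV) point
    difference; ``mean_diff_ci`` is the percentile interval of the
    across-nuclei mean difference over paired bootstrap replicates.
    """

    n_informative: int
    n_positive: int
    p_value: float
    difference_summary: dict[str, float]
    mean_diff: float
    mean_diff_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "n_informative": self.n_informative,
            "n_positive": self.n_positive,
            "p_value": self.p_value,
            "differences": dict(self.difference_summary),
            "mean_difference": self.mean_diff,
            "mean_difference_ci": list(self.mean_diff_ci),
        }


def curse_sign_test(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> SignTestResult:
    """Test for male-biased mitochondrial CV across nuclear backgrounds.

    For every nucleus with both sexes observed, the point CV difference
    (male - female) is computed on untransformed data; zero differences are
    dropped and the remaining signs go into an exact two-sided sign test.
    Paired bootstrap replicates of the CVs give a percentile CI for the mean
    of the differences across nuclei.
    """
    means = line_means(table)
    nuclei = sorted(means.index.get_level_values("nuc").unique())
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(nuclei))

    diffs: dict[str, float] = {}
    boot_diffs = []
    for nuc, stream in zip(nuclei, streams):
        sexes = means.loc[nuc].index.get_level_values("sex").unique()
        if not all(s in sexes for s in SEXES):
            raise AnalysisError(f"nucleus {nuc!r} lacks one sex; both are required")
        rng = np.random.default_rng(stream)
        est = {
            s: _cv_estimate_from_means(
                means.loc[(nuc, s)]["mean"].to_numpy(), nuc, s, n_boot, rng
            )
            for s in SEXES
        }
        diffs[nuc] = est[MALE].cv_point - est[FEMALE].cv_point
        boot_diffs.append(est[MALE].bootstrap_cvs - est[FEMALE].bootstrap_cvs)

    informative = {n: d for n, d in diffs.items() if d != 0.0}
    if not informative:
        raise AnalysisError("no informative nuclei (all CV differences are zero)")
    n_pos = sum(d > 0 for d in informative.values())
    n_inf = len(informative)

    mean_diff_boot = np.mean(boot_diffs, axis=0)
    lo, hi = np.percentile(mean_diff_boot, [2.5, 97.5])
    return SignTestResult(
        n_informative=n_inf,
        n_positive=n_pos,
        p_value=sign_test_pvalue(n_pos, n_inf),
        difference_summary=diffs,
        mean_diff=float(np.mean(list(diffs.values()))),
        mean_diff_ci=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class NuclearCVComparison:
    """Nuclear CVs over coevolved-line means, per sex, with a sex contrast.

    The contrast is a one-way F test between the male and female bootstrap CV
    distributions.  ``caveat`` is always set: bootstrap replicates are not
    independent observations, so the F test's nominal p-value overstates
    certainty and is reported for descriptive comparison only.
    """

    female: CVEstimate
    male: CVEstimate
    f_stat: float
    p_value: float
    degenerate: bool
    caveat: str = (
        "F test computed on bootstrap replicate distributions; replicates are "
        "resamples, not independent observations"
    )

    def as_dict(self) -> dict:
        return {
            "female": self.female.as_dict(),
            "male": self.male.as_dict(),
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "caveat": self.caveat,
        }


def nuclear_cv(
    table: pd.DataFrame,
    design: PanelDesign,
    n_boot: int = 1000,
    seed: int = 0,
) -> NuclearCVComparison:
    """Male-variability control: CV across nuclear backgrounds per sex.

    Only the coevolved lines (each nucleus with its native haplotype) enter,
    so the across-nuclei dispersion reflects nuclear genetic variance
    uncontaminated by mitonuclear disruption.  If males were intrinsically
    more variable (e.g. through X hemizygosity) the male nuclear CV would
    exceed the female one, which would confound the mitochondrial comparison.
    """
    means = line_means(table)
    nuclei = sorted(means.index.get_level_values("nuc").unique())
    missing = [n for n in nuclei if n not in design.coevolved]
    if missing:
        raise AnalysisError(
            f"coevolved map lacks nuclei present in the data: {missing}"
        )
    root = np.random.SeedSequence(seed)
    estimates = {}
    for sex, stream in zip(SEXES, root.spawn(len(SEXES))):
        vals = []
        for nuc in nuclei:
            key = (nuc, sex, design.coevolved[nuc])
            if key in means.index:
                vals.append(means.loc[key, "mean"])
        if len(vals) < 2:
            raise AnalysisError(
                f"fewer than 2 coevolved line means observed for sex {sex!r}"
            )
        rng = np.random.default_rng(stream)
        estimates[sex] = _cv_estimate_from_means(
            np.asarray(vals, dtype=float), "coevolved", sex, n_boot, rng
        )

    bf = estimates[FEMALE].bootstrap_cvs
    bm = estimates[MALE].bootstrap_cvs
    degenerate = bool(np.ptp(bf) == 0 and np.ptp(bm) == 0)
    if degenerate:
        f_stat, p = float("nan"), float("nan")
    else:
        f_stat, p = (float(v) for v in stats.f_oneway(bm, bf))
    return NuclearCVComparison(
        female=estimates[FEMALE],
        male=estimates[MALE],
        f_stat=f_stat,
        p_value=p,
        degenerate=degenerate,
    )
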