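"""Intersex genetic correlations of genotype line means.

The correlation between male and female line means over genotypes (r_mf)
measures how concordant the two sexes' genetic effects are: a high positive
value means a genotype that enlarges the trait in one sex does so in the
other too.  Computed overall (all genotypes) or within a single nuclear
background (across its haplotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .simulate import FEMALE, MALE
from .variance import AnalysisError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of paired male/female genotype means."""

    scope: str
    r: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {"scope": self.scope, "r": self.r, "p_value": self.p_value, "n": self.n}


def intersex_correlation(means: pd.DataFrame, scope: str = "overall") -> CorrelationResult:
    """Pearson r between male and female line means.

    Parameters
    ----------
    means : DataFrame indexed by (nuc, sex, mito) with a ``mean`` column
        Output of :func:`mitocurse.variance.line_means` (raw, unstandardized
        means by default convention).
    scope : "overall" or a nuclear-background label
        "overall" pairs every genotype; a nucleus label restricts to its
        haplotypes.

    Genotypes with a mean for only one sex are excluded with a warning;
    the two-sided p-value comes from the t distribution on n - 2 df.
    """
    wide = means["mean"].unstack("sex")
    if scope != "overall":
        nuclei = wide.index.get_level_values("nuc").unique()
        if scope not in nuclei:
            raise AnalysisError(
                f"unknown scope {scope!r}; expected 'overall' or one of {list(nuclei)}"
            )
        wide = wide.loc[[scope]]
    for col in (FEMALE, MALE):
        if col not in wide.columns:
            raise AnalysisError(f"no {col} line means in scope {scope!r}")
    unpaired = wide[wide.isna().any(axis=1)]
    if not unpaired.empty:
        logger.warning(
            "excluding %d genotype(s) without both sexes: %s",
            len(unpaired),
            list(unpaired.index),
        )
        wide = wide.dropna()
    n = len(wide)
    if n < 3:
        raise AnalysisError(f"scope {scope!r} has {n} paired genotypes; need >= 3")
    r, p = stats.pearsonr(wide[MALE].to_numpy(), wide[FEMALE].to_numpy())
    return CorrelationResult(scope=scope, r=float(r), p_value=float(p), n=n)


def intersex_correlations_by_nucleus(means: pd.DataFrame) -> list[CorrelationResult]:
    """One per-nucleus intersex correlation for every nuclear background."""
    nuclei = sorted(means.index.get_level_values("nuc").unique())
    return [intersex_correlation(means, scope=n) for n in nuclei]
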