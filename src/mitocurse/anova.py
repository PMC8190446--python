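"""Factorial fixed-effects ANOVA with sequential (type-I) sums of squares.

The decomposition is computed by incremental least-squares projection: the
design matrix is grown one term block at a time (each block holding the full
set of indicator columns for that factor or interaction), and each term's sum
of squares is the drop in residual sum of squares when its block enters.
Degrees of freedom are the rank increase of the design matrix, so designs
with missing (inviable) cells are handled naturally: only estimable
interaction contrasts are counted, and interaction df shrink accordingly.

Because every block spans the full indicator space of its term, the fitted
subspaces — hence the sums of squares — do not depend on how factor levels
are ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import FEMALE, MALE, SEXES


class ModelSpecError(ValueError):
    """Raised when a phenotype table cannot support the requested model."""


#: fixed term order of the full three-factor model
FULL_MODEL_TERMS: tuple[tuple[str, ...], ...] = (
    ("sex",),
    ("mito",),
    ("nuc",),
    ("sex", "mito"),
    ("sex", "nuc"),
    ("mito", "nuc"),
    ("sex", "mito", "nuc"),
)

#: term order of the single-sex model
SEX_MODEL_TERMS: tuple[tuple[str, ...], ...] = (("mito",), ("nuc",), ("mito", "nuc"))


@dataclass(frozen=True)
class AnovaTable:
    """Sequential ANOVA decomposition.

    ``table`` has one row per model term plus a final ``residual`` row, with
    columns ``term, df, ss, ms, f, p`` (``f``/``p`` are NaN on the residual
    row).  ``total_ss`` is the total corrected sum of squares.
    """

    table: pd.DataFrame
    total_ss: float
    n_obs: int

    @property
    def terms(self) -> list[str]:
        return [t for t in self.table["term"] if t != "residual"]

    def __getitem__(self, term: str) -> pd.Series:
        rows = self.table[self.table["term"] == term]
        if rows.empty:
            raise KeyError(term)
        return rows.iloc[0]

    @property
    def residual(self) -> pd.Series:
        return self["residual"]

    def variance_proportions(self) -> pd.Series:
        """Proportion of total (corrected) sum of squares per term, residual
        included.  Proportions sum to one."""
        if self.total_ss <= 0:
            raise ModelSpecError(
                "total sum of squares is zero (constant trait); proportions undefined"
            )
        props = self.table.set_index("term")["ss"] / self.total_ss
        props.name = "proportion"
        return props

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        with pd.option_context("display.float_format", "{:.6g}".format):
            return self.table.to_string(index=False)


def term_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _indicator_block(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Full one-hot indicator matrix (no reference level dropped)."""
    block = np.zeros((codes.size, n_levels))
    block[np.arange(codes.size), codes] = 1.0
    return block


def _term_block(factors: dict[str, np.ndarray], term: tuple[str, ...]) -> np.ndarray:
    """Indicator block for a term: one column per observed level combination."""
    if len(term) == 1:
        codes, levels = factors[term[0]]
        return _indicator_block(codes, len(levels))
    key = np.stack([factors[f][0] for f in term], axis=1)
    _, combo = np.unique(key, axis=0, return_inverse=True)
    return _indicator_block(combo, combo.max() + 1)


def sequential_anova(
    y: np.ndarray, factors: dict[str, tuple], terms: tuple[tuple[str, ...], ...]
) -> AnovaTable:
    """Sequential SS over ``terms`` (in order) for response ``y``.

    ``factors`` maps factor name to ``(codes, levels)`` where ``codes`` is an
    integer array aligned with ``y``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    blocks = [np.ones((n, 1))]
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        raise ModelSpecError("constant trait: no variance to decompose")

    rows = []
    prev_rank = 1
    prev_rss = ss_total
    for term in terms:
        blocks.append(_term_block(factors, term))
        x = np.hstack(blocks)
        beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(np.sum((y - x @ beta) ** 2))
        df = int(rank) - prev_rank
        ss = max(prev_rss - rss, 0.0)
        rows.append([term_name(term), df, ss])
        prev_rank, prev_rss = int(rank), rss

    df_resid = n - prev_rank
    if df_resid <= 0:
        raise ModelSpecError(
            "zero residual degrees of freedom: the design has no replication "
            f"(n = {n}, model rank = {prev_rank}); at least one cell needs >= 2 "
            "observations"
        )
    dropped = [r[0] for r in rows if r[1] == 0]
    if dropped:
        raise ModelSpecError(
            f"terms {dropped} are completely aliased (zero estimable contrasts); "
            "check for single-level factors or fully confounded cells"
        )
    ms_resid = prev_rss / df_resid

    out = []
    for name, df, ss in rows:
        ms = ss / df
        f = ms / ms_resid
        p = float(stats.f.sf(f, df, df_resid))
        out.append((name, df, ss, ms, f, p))
    out.append(("residual", df_resid, prev_rss, ms_resid, np.nan, np.nan))
    table = pd.DataFrame(out, columns=["term", "df", "ss", "ms", "f", "p"])
    return AnovaTable(table=table, total_ss=ss_total, n_obs=n)


def _factor_codes(table: pd.DataFrame, columns: list[str]) -> dict[str, tuple]:
    """First-appearance-ordered integer coding of each factor column."""
    factors = {}
    for col in columns:
        levels = list(pd.unique(table[col]))
        if len(levels) < 2:
            raise ModelSpecError(
                f"factor {col!r} has a single level ({levels[0]!r}); "
                "at least two are required"
            )
        lookup = {lev: i for i, lev in enumerate(levels)}
        codes = table[col].map(lookup).to_numpy()
        factors[col] = (codes, levels)
    return factors


def fit_full_model(table: pd.DataFrame) -> AnovaTable:
    """Three-factor fixed-effects model of the trait.

    Terms enter in the order sex, mito, nuc, sex:mito, sex:nuc, mito:nuc,
    sex:mito:nuc.  Missing (inviable) cells are handled by fitting on observed
    cells only, with interaction df reduced to the estimable contrasts.
    """
    factors = _factor_codes(table, ["sex", "mito", "nuc"])
    return sequential_anova(table["trait"].to_numpy(), factors, FULL_MODEL_TERMS)


def fit_sex_model(table: pd.DataFrame, sex: str) -> AnovaTable:
    """Two-factor (mito, nuc, mito:nuc) model on a single-sex subset."""
    if sex not in SEXES:
        raise ModelSpecError(f"unknown sex label {sex!r}; valid labels: {SEXES}")
    subset = table[table["sex"] == sex]
    if subset.empty:
        raise ModelSpecError(
            f"no rows for sex {sex!r}; sexes present: {sorted(table['sex'].unique())}"
        )
    factors = _factor_codes(subset, ["mito", "nuc"])
    return sequential_anova(subset["trait"].to_numpy(), factors, SEX_MODEL_TERMS)


def variance_proportions(anova: AnovaTable) -> pd.Series:
    """Proportion of total SS attributed to each term (residual included)."""
    return anova.variance_proportions()
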