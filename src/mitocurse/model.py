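"""Model/Results facade over the full mitonuclear panel analysis.

`MitonuclearPanelModel` is constructed from a long-format phenotype table
(plus the panel design and, optionally, a mitochondrial genetic-distance
matrix); `fit()` runs the complete inference sequence and returns a
`MitonuclearPanelResults` carrying every stage's output:

1. full three-factor ANOVA (sex x mito x nuc) and its variance proportions;
2. per-sex two-factor ANOVAs and variance proportions;
3. per-(nucleus, sex) mitochondrial CVs with bootstrap CIs;
4. the cross-nucleus sign test for male-biased mitochondrial variance;
5. the nuclear-CV (coevolved lines) male-variability control;
6. intersex genetic correlations, overall and per nucleus;
7. per-(nucleus, sex) Mantel tests of genetic vs phenotypic divergence,
   when a genetic distance matrix is supplied.

One root seed deterministically derives an independent substream per stage,
so any stage can be rerun in isolation with identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anova as _anova
from . import correlation as _correlation
from . import mantel as _mantel
from . import variance as _variance
from .design import PanelDesign
from .simulate import FEMALE, MALE, SEXES

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _anova_records(table: "_anova.AnovaTable") -> list[dict]:
    """ANOVA rows as JSON-safe records (NaN on the residual row -> None)."""
    frame = table.to_frame().astype(object)
    return frame.where(pd.notna(frame), None).to_dict(orient="records")

_STAGES = ("anova", "cv", "sign_test", "nuclear_cv", "correlation", "mantel")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % (2**31))


class MitonuclearPanelModel:
    """Full-factorial mitonuclear panel analysis.

    Parameters
    ----------
    data : DataFrame
        Long-format phenotypes with columns
        ``individual_id, nuc, mito, sex, replicate, trait``.
    design : PanelDesign, optional
        Panel structure (coevolved pairs, incompatible cells).  When omitted,
        a design is inferred from the data with the identity coevolved map,
        which is only correct when haplotype and background labels coincide.
    genetic_distance : skbio.DistanceMatrix, optional
        Pairwise mitochondrial distances (e.g. SNP counts); enables the
        Mantel stage.
    """

    def __init__(self, data: pd.DataFrame, design: "PanelDesign | None" = None,
                 genetic_distance=None):
        required = {"nuc", "mito", "sex", "trait"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required column(s) {sorted(missing)}")
        bad_sex = set(data["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(
                f"unknown sex label(s) {sorted(bad_sex)}; expected {SEXES}"
            )
        if design is None:
            design = self._infer_design(data)
        self._check_against_design(data, design)
        self.data = data.reset_index(drop=True)
        self.design = design
        self.genetic_distance = genetic_distance

    @staticmethod
    def _infer_design(data: pd.DataFrame) -> PanelDesign:
        mito = sorted(data["mito"].unique())
        nuc = sorted(data["nuc"].unique())
        observed = set(map(tuple, data[["nuc", "mito"]].drop_duplicates().to_numpy()))
        missing = {(n, m) for n in nuc for m in mito} - observed
        coevolved = {n: n for n in nuc if n in mito if (n, n) not in missing}
        return PanelDesign(
            mito_labels=tuple(mito), nuc_labels=tuple(nuc),
            coevolved=coevolved, incompatible=frozenset(missing),
        )

    @staticmethod
    def _check_against_design(data: pd.DataFrame, design: PanelDesign) -> None:
        observed = set(map(tuple, data[["nuc", "mito"]].drop_duplicates().to_numpy()))
        allowed = set(design.cells())
        stray = observed - allowed
        if stray:
            raise ValueError(
                f"data contains cells outside the design (or marked "
                f"incompatible): {sorted(stray)[:5]}"
            )

    @classmethod
    def from_dataframe(cls, data, design=None, genetic_distance=None):
        return cls(data, design=design, genetic_distance=genetic_distance)

    @classmethod
    def from_csv(cls, path, design=None, genetic_distance=None):
        from .io import read_phenotypes

        return cls(read_phenotypes(path), design=design,
                   genetic_distance=genetic_distance)

    def fit(self, bootstrap: int = 1000, n_perm: int = 10000,
            seed: int = 0) -> "MitonuclearPanelResults":
        """Run the full analysis sequence; returns the results object."""
        data, design = self.data, self.design
        logger.info("fitting panel model: %d rows, %d x %d design, seed %d",
                    len(data), len(design.nuc_labels), len(design.mito_labels), seed)

        anova_full = _anova.fit_full_model(data)
        anova_by_sex = {s: _anova.fit_sex_model(data, s) for s in SEXES}

        means = _variance.line_means(data)

        cv_seed = stage_seed(seed, "cv")
        nuclei = sorted(data["nuc"].unique())
        cv_estimates = []
        for i, nuc in enumerate(nuclei):
            for j, sex in enumerate(SEXES):
                cv_estimates.append(
                    _variance.mito_cv(
                        data, nuc, sex, n_boot=bootstrap,
                        seed=cv_seed + 2 * i + j,
                    )
                )

        sign = _variance.curse_sign_test(
            data, n_boot=bootstrap, seed=stage_seed(seed, "sign_test")
        )
        nuclear = _variance.nuclear_cv(
            data, design, n_boot=bootstrap, seed=stage_seed(seed, "nuclear_cv")
        )

        overall_r = _correlation.intersex_correlation(means, "overall")
        per_nucleus_r = _correlation.intersex_correlations_by_nucleus(means)

        mantel_results: dict[tuple[str, str], _mantel.MantelResult] = {}
        if self.genetic_distance is not None:
            m_seed = stage_seed(seed, "mantel")
            for i, nuc in enumerate(nuclei):
                for j, sex in enumerate(SEXES):
                    pheno = _mantel.phenotypic_divergence_matrix(means, nuc, sex)
                    mantel_results[(nuc, sex)] = _mantel.mantel_test(
                        self.genetic_distance, pheno, n_perm=n_perm,
                        seed=m_seed + 2 * i + j,
                    )

        return MitonuclearPanelResults(
            model=self,
            anova_full=anova_full,
            anova_by_sex=anova_by_sex,
            line_means=means,
            cv_estimates=cv_estimates,
            sign_test=sign,
            nuclear_cv=nuclear,
            intersex_overall=overall_r,
            intersex_by_nucleus=per_nucleus_r,
            mantel_results=mantel_results,
            bootstrap=bootstrap,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class MitonuclearPanelResults:
    """Results container for a fitted mitonuclear panel analysis."""

    model: MitonuclearPanelModel
    anova_full: _anova.AnovaTable
    anova_by_sex: dict[str, _anova.AnovaTable]
    line_means: pd.DataFrame
    cv_estimates: list[_variance.CVEstimate]
    sign_test: _variance.SignTestResult
    nuclear_cv: _variance.NuclearCVComparison
    intersex_overall: _correlation.CorrelationResult
    intersex_by_nucleus: list[_correlation.CorrelationResult]
    mantel_results: dict = field(default_factory=dict)
    bootstrap: int = 1000
    n_perm: int = 10000
    seed: int = 0

    # -- tabular views -----------------------------------------------------

    def cv_table(self) -> pd.DataFrame:
        """Per-(nucleus, sex) CV, raw variance, SD and bootstrap CI."""
        return pd.DataFrame([e.as_dict() for e in self.cv_estimates])

    def variance_proportions(self, scope: str = "full") -> pd.Series:
        """Variance proportions of the full model or a per-sex model."""
        if scope == "full":
            return self.anova_full.variance_proportions()
        return self.anova_by_sex[scope].variance_proportions()

    def mantel_table(self) -> pd.DataFrame:
        rows = [
            {"nuc": nuc, "sex": sex, **res.as_dict()}
            for (nuc, sex), res in self.mantel_results.items()
        ]
        return pd.DataFrame(rows)

    # -- report ------------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serializable report of every stage (full precision)."""
        d = self.model.design
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": self.seed,
            "bootstrap": self.bootstrap,
            "n_perm": self.n_perm,
            "design": {
                "n_mito": len(d.mito_labels),
                "n_nuc": len(d.nuc_labels),
                "n_genotypes": d.n_genotypes,
                "n_coevolved": d.n_coevolved,
                "n_incompatible": len(d.incompatible),
            },
            "n_individuals": int(len(self.model.data)),
            "anova_full": _anova_records(self.anova_full),
            "anova_by_sex": {
                s: _anova_records(t) for s, t in self.anova_by_sex.items()
            },
            "variance_proportions": {
                "full": self.variance_proportions("full").to_dict(),
                FEMALE: self.variance_proportions(FEMALE).to_dict(),
                MALE: self.variance_proportions(MALE).to_dict(),
            },
            "cv": [e.as_dict() for e in self.cv_estimates],
            "sign_test": self.sign_test.as_dict(),
            "nuclear_cv": self.nuclear_cv.as_dict(),
            "intersex_correlation": {
                "overall": self.intersex_overall.as_dict(),
                "by_nucleus": [c.as_dict() for c in self.intersex_by_nucleus],
            },
        }
        if self.mantel_results:
            report["mantel"] = [
                {"nuc": nuc, "sex": sex, **res.as_dict()}
                for (nuc, sex), res in self.mantel_results.items()
            ]
        return report

    def save(self, outdir) -> None:
        """Write report.json plus TSV side files to ``outdir``."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_report(), fh, indent=2, sort_keys=True)
        self.anova_full.to_tsv(out / "anova_full.tsv")
        for sex, table in self.anova_by_sex.items():
            table.to_tsv(out / f"anova_{sex}.tsv")
        self.cv_table().to_csv(out / "cv_estimates.tsv", sep="\t", index=False)
        self.line_means.reset_index().to_csv(
            out / "line_means.tsv", sep="\t", index=False
        )
        if self.mantel_results:
            self.mantel_table().to_csv(out / "mantel.tsv", sep="\t", index=False)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable multi-section summary (display rounding only)."""
        lines = []
        add = lines.append
        d = self.model.design
        add("Mitonuclear panel analysis")
        add("=" * 60)
        add(f"design: {len(d.nuc_labels)} nuclear x {len(d.mito_labels)} mito, "
            f"{d.n_genotypes} genotypes ({len(d.incompatible)} missing), "
            f"{len(self.model.data)} individuals")
        add("")
        add("Full model (sequential SS)")
        add(self.anova_full.to_frame().to_string(
            index=False, float_format=lambda v: f"{v:.6g}"))
        add("")
        for sex in SEXES:
            props = self.variance_proportions(sex)
            add(f"{sex} model variance proportions: "
                + ", ".join(f"{t}={v:.1%}" for t, v in props.items()))
        add("")
        st = self.sign_test
        add("Mother's curse sign test (male CV - female CV across nuclei):")
        add(f"  positive differences: {st.n_positive}/{st.n_informative}, "
            f"two-sided P = {st.p_value:.5g}")
        add(f"  mean difference {st.mean_diff:.5g} "
            f"[{st.mean_diff_ci[0]:.4g}, {st.mean_diff_ci[1]:.4g}]")
        add("")
        ncv = self.nuclear_cv
        add("Nuclear-CV control (coevolved lines): "
            f"female CV {ncv.female.cv_point:.4g}, male CV {ncv.male.cv_point:.4g}, "
            f"F = {ncv.f_stat:.4g}, P = {ncv.p_value:.4g} (caveat: {ncv.caveat})")
        add("")
        r = self.intersex_overall
        add(f"Intersex correlation r_mf = {r.r:.3f} (P = {r.p_value:.3g}, "
            f"n = {r.n} genotypes)")
        if self.mantel_results:
            add("")
            add("Mantel tests (genetic vs phenotypic divergence):")
            for (nuc, sex), res in sorted(self.mantel_results.items()):
                flag = " *" if res.p_value < 0.05 else ""
                add(f"  {nuc}/{sex}: r = {res.r_obs:.3f}, "
                    f"P = {res.p_value:.4g}{flag}")
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """Boxplot of bootstrap mitochondrial CV distributions per nucleus
        and sex (the standard visual for the curse signal)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        nuclei = sorted({e.nuc for e in self.cv_estimates})
        width = 0.35
        colors = {FEMALE: "#d95f02", MALE: "#1b9e77"}
        for j, sex in enumerate(SEXES):
            data = [
                next(e.bootstrap_cvs for e in self.cv_estimates
                     if e.nuc == n and e.sex == sex)
                for n in nuclei
            ]
            pos = [i + (j - 0.5) * width for i in range(len(nuclei))]
            bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                            patch_artist=True, showfliers=False)
            for box in bp["boxes"]:
                box.set_facecolor(colors[sex])
        ax.set_xticks(range(len(nuclei)))
        ax.set_xticklabels(nuclei)
        ax.set_xlabel("nuclear background")
        ax.set_ylabel("bootstrap mitochondrial CV")
        return ax
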