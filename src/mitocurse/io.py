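"""Readers, writers, and run configuration.

Phenotype tables travel as delimited text with the header
``individual_id,nuc,mito,sex,replicate,trait``; distance matrices as square
CSV/TSV with a header row and a first column of labels; hypervariable-region
masks as BED intervals (zero-based, half-open); run configuration as
YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from .simulate import PHENOTYPE_COLUMNS, SEXES


class DataFormatError(ValueError):
    """Raised for malformed input files, with file locations where possible."""


_SEX_ALIASES = {
    "female": "female", "f": "female", "fem": "female",
    "male": "male", "m": "male",
}


def _sniff_sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_phenotypes(path, sep: "str | None" = None) -> pd.DataFrame:
    """Read and validate a long-format phenotype table.

    Sex labels are normalized case-insensitively onto {female, male}.
    Malformed rows are reported with their file line number (header = line 1).
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataFormatError(f"{path}: cannot parse: {exc}") from exc

    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {PHENOTYPE_COLUMNS}"
        )
    df = df[PHENOTYPE_COLUMNS].copy()

    # file line = dataframe position + 2 (header is line 1)
    empty = df.apply(lambda col: col.str.strip() == "").any(axis=1)
    if empty.any():
        line = int(np.flatnonzero(empty)[0]) + 2
        raise DataFormatError(f"{path}: line {line}: missing value (blank field)")

    trait = pd.to_numeric(df["trait"], errors="coerce")
    bad = ~np.isfinite(trait)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise DataFormatError(
            f"{path}: line {line}: trait {df['trait'].iloc[line - 2]!r} "
            "is not a finite number"
        )
    df["trait"] = trait.astype(float)

    sex = df["sex"].str.strip().str.lower().map(_SEX_ALIASES)
    bad = sex.isna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise DataFormatError(
            f"{path}: line {line}: unknown sex label {df['sex'].iloc[line - 2]!r}; "
            f"accepted (case-insensitive): {sorted(_SEX_ALIASES)}"
        )
    df["sex"] = sex
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_distance_matrix(path, sep: "str | None" = None) -> DistanceMatrix:
    """Square labelled distance matrix from CSV/TSV (first column = labels)."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index) != list(df.columns):
        raise DataFormatError(
            f"{path}: row labels and column labels differ; a square labelled "
            "matrix is required"
        )
    try:
        return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
    except Exception as exc:
        raise DataFormatError(f"{path}: not a valid distance matrix: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path, sep: str = ",") -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep=sep)


def read_mask_bed(path) -> list[tuple[int, int]]:
    """BED intervals (chrom ignored — single-molecule coordinates assumed)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno}: BED needs >= 3 tab-separated fields"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise DataFormatError(
                    f"{path}: line {lineno}: non-integer BED coordinates"
                ) from None
            if start < 0 or end < start:
                raise DataFormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            intervals.append((start, end))
    return intervals


def read_coevolved_map(path) -> dict[str, str]:
    """Coevolved-pair map: YAML/JSON mapping nuclear label -> native mito label,
    or a two-column CSV/TSV (nuc, mito) with header."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise DataFormatError(f"{path}: expected a mapping nuc -> mito")
        return {str(k): str(v) for k, v in data.items()}
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (nuc, mito)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration.

    ``B`` is the bootstrap replicate count (default 1000) and ``n_perm`` the
    Mantel permutation count (default 10,000) — the procedural constants of
    the standard analysis.
    """

    phenotypes: str
    coevolved: "str | dict[str, str]"
    output_dir: str = "mitocurse_out"
    distance_matrix: "str | None" = None
    alignment: "str | None" = None
    mask: "str | list | None" = None
    B: int = 1000
    n_perm: int = 10000
    seed: int = 0
    incompatible: list = field(default_factory=list)

    def validate(self) -> None:
        if self.B < 100:
            raise DataFormatError(f"B must be >= 100 (got {self.B})")
        if self.n_perm < 99:
            raise DataFormatError(f"n_perm must be >= 99 (got {self.n_perm})")
        if self.distance_matrix and self.alignment:
            raise DataFormatError(
                "give either distance_matrix or alignment, not both"
            )
        for attr in ("phenotypes", "distance_matrix", "alignment"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise DataFormatError(f"{attr} path does not exist: {p}")
        if isinstance(self.coevolved, str) and not Path(self.coevolved).exists():
            raise DataFormatError(f"coevolved path does not exist: {self.coevolved}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = (
                json.load(fh)
                if str(path).endswith(".json")
                else yaml.safe_load(fh)
            )
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataFormatError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)
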