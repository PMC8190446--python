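"""End-to-end pipeline: config in, JSON report plus TSV side files out."""

from __future__ import annotations

import logging

from .design import PanelDesign
from .io import (
    AnalysisConfig,
    read_coevolved_map,
    read_distance_matrix,
    read_mask_bed,
    read_phenotypes,
)
from .mantel import snp_distance_matrix
from .model import MitonuclearPanelModel

logger = logging.getLogger(__name__)


def design_from_data(table, coevolved: dict[str, str],
                     incompatible=()) -> PanelDesign:
    """Panel design over the labels present in the data.

    Cells absent from the data but implied by the factorial are recorded as
    incompatible, in addition to any explicitly listed ones.
    """
    mito = tuple(sorted(table["mito"].unique()))
    nuc = tuple(sorted(table["nuc"].unique()))
    observed = set(map(tuple, table[["nuc", "mito"]].drop_duplicates().to_numpy()))
    implied_missing = {(n, m) for n in nuc for m in mito} - observed
    return PanelDesign(
        mito_labels=mito,
        nuc_labels=nuc,
        coevolved={n: m for n, m in coevolved.items() if n in nuc},
        incompatible=frozenset(implied_missing) | {tuple(c) for c in incompatible},
    )


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis described by ``config``; returns the report dict
    and writes ``report.json`` + TSVs under ``config.output_dir``."""
    config.validate()
    logger.info("pipeline start: %s", config.phenotypes)
    table = read_phenotypes(config.phenotypes)
    logger.info("read %d individuals", len(table))

    coevolved = (
        read_coevolved_map(config.coevolved)
        if isinstance(config.coevolved, str)
        else dict(config.coevolved)
    )
    design = design_from_data(table, coevolved, config.incompatible)
    logger.info(
        "design: %d nuc x %d mito, %d genotypes, %d missing cell(s)",
        len(design.nuc_labels), len(design.mito_labels),
        design.n_genotypes, len(design.incompatible),
    )

    genetic = None
    if config.distance_matrix:
        genetic = read_distance_matrix(config.distance_matrix)
    elif config.alignment:
        mask = (
            read_mask_bed(config.mask)
            if isinstance(config.mask, str)
            else [tuple(iv) for iv in (config.mask or [])]
        )
        genetic = snp_distance_matrix(config.alignment, mask=mask)

    model = MitonuclearPanelModel(table, design=design, genetic_distance=genetic)
    results = model.fit(bootstrap=config.B, n_perm=config.n_perm, seed=config.seed)
    results.save(config.output_dir)
    logger.info("report written to %s", config.output_dir)
    return results.to_report()
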