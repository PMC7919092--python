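"""End-to-end pipeline runner: quantify -> diversity -> diffabund -> accessory.

A run is a pure function of (input files, config, seed): outputs carry a
provenance header with the tool version, seed, and a hash of the resolved
config, and a manifest records the same so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .accessory import screen_all_modules
from .diff_abundance import degenerate_treatment_cells, diff_abundance_pipeline
from .diversity import bray_curtis, order_covariates, pcoa, permanova, shannon
from .io import (
    read_counts,
    read_gene_info,
    read_metadata,
    validate_consistency,
    write_table,
    ValidationError,
)
from .quantify import msp_abundance, tpm_normalize

logger = logging.getLogger("mspscreen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters; defaults are the study's."""

    counts_path: str
    gene_info_path: str
    metadata_path: str
    outdir: str
    seed: int = 0
    n_representatives: int = 30
    min_prev: float = 0.20
    rescue_fdr: float = 0.05
    n_perm: int = 1000
    min_group_detected: int = 20
    formula_terms: list[str] = field(default_factory=lambda: ["age", "sex", "cohort", "treatment"])
    permanova_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "cohort", "treatment"]
    )
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the analysis parameters; where results land does not alter it."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload.pop("log_level")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def provenance(self) -> str:
        return f"mspscreen v{__version__} seed={self.seed} config={self.config_hash()}"


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()

    logger.info("loading inputs")
    counts = read_counts(config.counts_path)
    gene_info = read_gene_info(config.gene_info_path)
    metadata = read_metadata(config.metadata_path)
    report = validate_consistency(counts, gene_info, metadata)
    if not report.ok:
        raise ValidationError(f"inconsistent inputs: {dataclasses.asdict(report)}")

    logger.info("stage quantify")
    tpm = tpm_normalize(counts, gene_info)
    msp_table = msp_abundance(tpm, gene_info, config.n_representatives)
    write_table(tpm.tpm, outdir / "tpm.tsv", prov)
    write_table(msp_table.abundance, outdir / "msp_abundance.tsv", prov)
    write_table(msp_table.rel_abundance, outdir / "msp_rel_abundance.tsv", prov)

    logger.info("stage diversity")
    alpha = msp_table.rel_abundance.apply(lambda col: shannon(col.to_numpy()), axis=0)
    write_table(alpha.rename("shannon").to_frame(), outdir / "alpha.tsv", prov)
    dm = bray_curtis(msp_table.rel_abundance)
    write_table(
        pd.DataFrame(dm.d, index=dm.sample_ids, columns=dm.sample_ids),
        outdir / "bray_curtis.tsv",
        prov,
    )
    coords, _ = pcoa(dm, k=2)
    write_table(coords, outdir / "pcoa.tsv", prov)
    ordered, r2_table = order_covariates(dm, metadata, config.permanova_covariates)
    perm = permanova(dm, metadata, ordered, n_perm=config.n_perm, seed=config.seed)
    perm_out = perm.terms.join(r2_table, how="left")
    write_table(perm_out, outdir / "permanova.tsv", prov)

    logger.info("stage diffabund")
    diff = diff_abundance_pipeline(
        msp_table.rel_abundance,
        metadata,
        min_prev=config.min_prev,
        rescue_fdr=config.rescue_fdr,
        terms=config.formula_terms,
    )
    write_table(diff.set_index("feature_id"), outdir / "diffabund.tsv", prov)
    degen = degenerate_treatment_cells(metadata)
    if len(degen):
        logger.warning("treatment categories confined to one cohort:\n%s", degen)
        write_table(degen, outdir / "degenerate_treatments.tsv", prov)

    logger.info("stage accessory")
    screen = screen_all_modules(
        counts,
        gene_info,
        metadata,
        min_group_detected=config.min_group_detected,
        n_representatives=config.n_representatives,
    )
    write_table(screen.set_index(["msp_id", "module_id"]), outdir / "enrichment.tsv", prov)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("run complete: %s", outdir)
    return outdir
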