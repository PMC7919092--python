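"""Gene-catalog quantification: TPM, MSP abundances, taxa, gene-set signals.

MSP abundance follows the median-of-representative-core-genes convention:
the abundance of a metagenomic species pan-genome in a sample is the
median TPM of its 30 top-ranked core genes. Zeros count toward the
median, so an MSP below the detection limit scores 0 rather than being
propped up by its few detected genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneCatalogCounts, GeneInfo, TpmMatrix, ValidationError

__all__ = [
    "MspAbundanceTable",
    "GeneSetSignal",
    "tpm_normalize",
    "msp_abundance",
    "aggregate_taxa",
    "gene_set_signal",
]

TAXA_LEVELS = ("species", "genus", "phylum")


@dataclass
class MspAbundanceTable:
    """Per-sample MSP abundances (median core TPM) and relative abundances."""

    abundance: pd.DataFrame  # MSP x sample, median-core-TPM
    rel_abundance: pd.DataFrame  # MSP x sample, columns sum to 1 where any MSP nonzero

    @property
    def msp_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.columns


@dataclass
class GeneSetSignal:
    """Summed counts and TPM over a named gene set (e.g. a locus' homologs)."""

    set_id: str
    gene_ids: list[str]
    counts: pd.Series  # per-sample summed read counts
    tpm: pd.Series  # per-sample summed TPM


def tpm_normalize(counts: GeneCatalogCounts, gene_info: GeneInfo) -> TpmMatrix:
    """Length-normalize counts to transcripts-per-million.

    tpm_gs = (x_gs / len_g) / sum_g'(x_g's / len_g') * 1e6. Samples with no
    mapped reads stay all-zero.
    """
    missing = counts.gene_ids.difference(gene_info.gene_ids)
    if len(missing):
        raise ValidationError(f"genes missing from gene info: {missing.tolist()[:5]}")
    lengths = gene_info.frame.loc[counts.gene_ids, "length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = counts.counts.to_numpy(dtype=float) / lengths[:, None]
    col_sums = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(col_sums > 0, rate / col_sums * 1e6, 0.0)
    return TpmMatrix(pd.DataFrame(tpm, index=counts.gene_ids.copy(), columns=counts.sample_ids.copy()))


def msp_abundance(
    tpm: TpmMatrix, gene_info: GeneInfo, n_representatives: int = 30
) -> MspAbundanceTable:
    """MSP abundance = median TPM over the top-ranked representative core genes.

    MSPs with fewer than ``n_representatives`` core genes use all of their
    core genes. Undetected representatives contribute zeros to the median.
    Relative abundance renormalizes the medians to sum 1 per sample.
    """
    gf = gene_info.frame
    core = gf[gf["gene_class"] == "core"]
    msp_ids = gf["msp_id"].dropna().unique()
    no_core = [m for m in msp_ids if (core["msp_id"] == m).sum() == 0]
    if no_core:
        raise ValidationError(f"MSPs with no core genes: {sorted(no_core)}")
    rows = []
    for msp_id in msp_ids:
        sel = core[core["msp_id"] == msp_id]
        reps = sel[sel["core_rank"] <= n_representatives].index
        if len(reps) == 0:  # unranked core genes: fall back to all
            reps = sel.index
        rows.append(np.median(tpm.tpm.loc[reps].to_numpy(dtype=float), axis=0))
    abundance = pd.DataFrame(
        rows, index=pd.Index(msp_ids, name="msp_id"), columns=tpm.sample_ids.copy()
    )
    totals = abundance.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = abundance.div(totals.where(totals > 0, 1.0), axis=1)
    return MspAbundanceTable(abundance=abundance, rel_abundance=rel)


def aggregate_taxa(
    msp_table: MspAbundanceTable, gene_info: GeneInfo, level: str
) -> pd.DataFrame:
    """Sum member-MSP relative abundances per taxon at the requested level.

    MSPs without an annotation at that level pool under "unclassified", so
    column sums are conserved.
    """
    if level not in TAXA_LEVELS:
        raise ValidationError(f"unknown taxonomic level {level!r}; choose from {TAXA_LEVELS}")
    gf = gene_info.frame
    tax = (
        gf.dropna(subset=["msp_id"])
        .groupby("msp_id", observed=True)[level]
        .first()
        .reindex(msp_table.msp_ids)
    )
    labels = tax.fillna("unclassified").astype(str)
    out = msp_table.rel_abundance.groupby(labels.to_numpy()).sum()
    out.index.name = level
    return out


def gene_set_signal(
    counts: GeneCatalogCounts, tpm: TpmMatrix, gene_ids, set_id: str
) -> GeneSetSignal:
    """Aggregate a named gene set (e.g. the cgr locus homologs) per sample.

    Returns the summed read count — the presence/absence signal used by the
    carriage analysis — and the summed TPM, the combined relative-abundance
    signal used for homolog sets such as HypD.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValidationError(f"gene set {set_id!r} is empty")
    unknown = [g for g in gene_ids if g not in counts.gene_ids]
    if unknown:
        raise ValidationError(f"gene set {set_id!r} has genes absent from the catalog: {unknown[:5]}")
    return GeneSetSignal(
        set_id=set_id,
        gene_ids=gene_ids,
        counts=counts.counts.loc[gene_ids].sum(axis=0),
        tpm=tpm.tpm.loc[gene_ids].sum(axis=0),
    )
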