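"""Strain-level accessory-module carriage analysis.

Whether a sample's strain population carries an accessory module (e.g. the
cgr locus of E. lenta) is decided from read counts, but absence of reads
is only evidence of absence when the species itself is well covered. The
detection model exploits the proportionality between a module's read
count and the read count of the MSP's top-30 representative core genes in
carrier samples: beta = accessory reads per core read, so a carrier needs
at least m* = ceil(1/beta) core reads before one accessory read is
expected. Samples below m* core reads are undetermined and never enter
contingency tables; determined samples are positive with >= 1 accessory
read, negative with 0.

Enrichment of carriage in a disease cohort vs controls uses Fisher's
exact test — one-sided for a targeted hypothesis, two-sided with BH
correction for the microbiome-wide screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diff_abundance import bh_adjust
from .io import GeneCatalogCounts, GeneInfo, SampleMetadata, ValidationError
from .quantify import MspAbundanceTable

__all__ = [
    "DetectionModel",
    "CarriageCallSet",
    "EnrichmentResult",
    "module_counts",
    "fit_detection_model",
    "call_carriage",
    "targeted_enrichment",
    "screen_all_modules",
    "carrier_abundance_test",
]


def _min_core_reads(beta: float) -> int:
    """Smallest positive integer m with beta * m >= 1."""
    m = max(1, int(math.ceil(1.0 / beta)))
    while beta * m < 1.0:
        m += 1
    while m > 1 and beta * (m - 1) >= 1.0:
        m -= 1
    return m


@dataclass
class DetectionModel:
    """Accessory/core proportionality and the derived detection threshold."""

    msp_id: str
    module_id: str
    beta: float  # expected accessory reads per core read in carriers
    m_star: int  # minimal core reads for reliable presence/absence calls
    n_fit: int  # carrier samples the fit used

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValidationError("beta must be positive")
        if self.n_fit < 1:
            raise ValidationError("detection model needs >= 1 carrier sample")
        if self.m_star != _min_core_reads(self.beta):
            raise ValidationError("m_star inconsistent with beta")


@dataclass
class CarriageCallSet:
    """Per-sample carriage calls for one accessory module of one MSP."""

    msp_id: str
    module_id: str
    model: DetectionModel
    #: index sample_id; columns core_reads, accessory_reads, call
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        undet = f["core_reads"] < self.model.m_star
        pos = ~undet & (f["accessory_reads"] >= 1)
        expected = np.where(undet, "undetermined", np.where(pos, "positive", "negative"))
        if not (f["call"].to_numpy() == expected).all():
            raise ValidationError("carriage calls inconsistent with the detection model")

    def determined(self) -> pd.DataFrame:
        return self.frame[self.frame["call"] != "undetermined"]


@dataclass
class EnrichmentResult:
    """Fisher 2x2 carriage contrast of one disease cohort vs controls."""

    msp_id: str
    module_id: str
    contrast: str
    disease_pos: int
    disease_neg: int
    control_pos: int
    control_neg: int
    odds_ratio: float
    log2_odds_ratio: float
    sidedness: str
    p: float
    q: float | None = None


def module_counts(
    counts: GeneCatalogCounts,
    gene_info: GeneInfo,
    msp_id: str,
    module_id: str | None = None,
    gene_ids=None,
    n_representatives: int = 30,
) -> pd.DataFrame:
    """Per-sample core and accessory read sums for one MSP module.

    Core reads sum over the MSP's top-ranked representative core genes;
    accessory reads sum over the module's genes, or over an explicit
    homolog gene list (which may not contain core genes).
    """
    if (module_id is None) == (gene_ids is None):
        raise ValidationError("provide exactly one of module_id or gene_ids")
    core_genes = gene_info.core_genes(msp_id, n_representatives)
    if gene_ids is not None:
        gene_ids = list(gene_ids)
        if not gene_ids:
            raise ValidationError("explicit accessory gene list is empty")
        unknown = [g for g in gene_ids if g not in counts.gene_ids]
        if unknown:
            raise ValidationError(f"genes absent from the catalog: {unknown[:5]}")
        classes = gene_info.frame.reindex(gene_ids)["gene_class"]
        if (classes == "core").any():
            bad = classes.index[classes == "core"].tolist()
            raise ValidationError(f"core genes not allowed in an accessory set: {bad[:5]}")
        acc_genes = pd.Index(gene_ids)
    else:
        acc_genes = gene_info.module_genes(msp_id, module_id)
    return pd.DataFrame(
        {
            "core_reads": counts.counts.loc[counts.gene_ids.intersection(core_genes)].sum(axis=0),
            "accessory_reads": counts.counts.loc[counts.gene_ids.intersection(acc_genes)].sum(axis=0),
        }
    )


def fit_detection_model(
    mod_counts: pd.DataFrame, msp_id: str = "", module_id: str = ""
) -> DetectionModel:
    """Estimate beta and the minimal core-read threshold from putative carriers.

    Carriers are samples with >= 1 accessory and >= 1 core read; beta is the
    median of their per-sample accessory/core ratios — robust to a few
    spurious-read contaminants. m* = ceil(1/beta).
    """
    carriers = mod_counts[(mod_counts["accessory_reads"] >= 1) & (mod_counts["core_reads"] >= 1)]
    if carriers.empty:
        raise ValidationError(
            f"module {module_id!r} of MSP {msp_id!r} never observed; threshold undefined"
        )
    ratios = carriers["accessory_reads"].to_numpy(dtype=float) / carriers["core_reads"].to_numpy(
        dtype=float
    )
    beta = float(np.median(ratios))
    return DetectionModel(
        msp_id=msp_id,
        module_id=module_id,
        beta=beta,
        m_star=_min_core_reads(beta),
        n_fit=len(carriers),
    )


def call_carriage(mod_counts: pd.DataFrame, model: DetectionModel) -> CarriageCallSet:
    """Positive/negative/undetermined per sample under the detection model.

    A sample below m* core reads is undetermined even when it has accessory
    reads: low-coverage samples are discarded unconditionally.
    """
    frame = mod_counts[["core_reads", "accessory_reads"]].copy()
    undet = frame["core_reads"] < model.m_star
    pos = ~undet & (frame["accessory_reads"] >= 1)
    frame["call"] = np.where(undet, "undetermined", np.where(pos, "positive", "negative"))
    return CarriageCallSet(
        msp_id=model.msp_id, module_id=model.module_id, model=model, frame=frame
    )


def _fisher_cells(
    calls: CarriageCallSet, metadata: SampleMetadata, disease_cohort: str
) -> tuple[int, int, int, int]:
    det = calls.determined()
    cohorts = metadata.frame.loc[det.index, "cohort"]
    pos = det["call"] == "positive"
    d = cohorts == disease_cohort
    c = cohorts == "control"
    if not d.any() or not c.any():
        raise ValidationError(
            f"no determined samples in {'control' if not c.any() else disease_cohort}"
        )
    return int((pos & d).sum()), int((~pos & d).sum()), int((pos & c).sum()), int((~pos & c).sum())


def _odds_ratio(dp: int, dn: int, cp: int, cn: int) -> tuple[float, float]:
    """Sample odds ratio and its log2; Haldane-Anscombe +0.5 only when a cell is 0."""
    if min(dp, dn, cp, cn) == 0:
        log2_or = math.log2(((dp + 0.5) * (cn + 0.5)) / ((dn + 0.5) * (cp + 0.5)))
        if dn * cp == 0:
            or_ = math.inf if dp * cn > 0 else math.nan
        else:
            or_ = (dp * cn) / (dn * cp)
    else:
        or_ = (dp * cn) / (dn * cp)
        log2_or = math.log2(or_)
    return or_, log2_or


def targeted_enrichment(
    calls: CarriageCallSet,
    metadata: SampleMetadata,
    disease_cohort: str,
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher test of carriage enrichment in a disease cohort.

    The default alternative "greater" tests the targeted hypothesis that
    carriage is more frequent in disease than in controls.
    """
    dp, dn, cp, cn = _fisher_cells(calls, metadata, disease_cohort)
    _, p = stats.fisher_exact([[dp, dn], [cp, cn]], alternative=alternative)
    or_, log2_or = _odds_ratio(dp, dn, cp, cn)
    return EnrichmentResult(
        msp_id=calls.msp_id,
        module_id=calls.module_id,
        contrast=f"{disease_cohort} vs control",
        disease_pos=dp,
        disease_neg=dn,
        control_pos=cp,
        control_neg=cn,
        odds_ratio=or_,
        log2_odds_ratio=log2_or,
        sidedness=alternative,
        p=float(p),
    )


def screen_all_modules(
    counts: GeneCatalogCounts,
    gene_info: GeneInfo,
    metadata: SampleMetadata,
    min_group_detected: int = 20,
    n_representatives: int = 30,
    disease_cohorts: list[str] | None = None,
) -> pd.DataFrame:
    """Microbiome-wide two-sided carriage screen over all MSP x module pairs.

    Each module gets its own detection model and carriage calls. A module
    enters the screen only when the number of determined samples exceeds
    ``min_group_detected`` in every cohort present in the metadata. Fisher
    tests are two-sided, one per disease-vs-control contrast, BH-corrected
    across all tested modules within each contrast. Modules never observed
    in any sample are skipped. The result may be empty.
    """
    meta = metadata.frame
    groups = [c for c in pd.unique(meta["cohort"])]
    if disease_cohorts is None:
        disease_cohorts = [c for c in groups if c != "control"]
    gf = gene_info.frame
    pairs = (
        gf[gf["gene_class"] == "accessory"][["msp_id", "module_id"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    rows = []
    for msp_id, module_id in pairs:
        mc = module_counts(counts, gene_info, msp_id, module_id, n_representatives=n_representatives)
        try:
            model = fit_detection_model(mc, msp_id, module_id)
        except ValidationError:
            continue  # never observed anywhere
        calls = call_carriage(mc, model)
        det_cohorts = meta.loc[calls.determined().index, "cohort"]
        n_det = det_cohorts.value_counts()
        if any(n_det.get(g, 0) <= min_group_detected for g in groups):
            continue
        for disease in disease_cohorts:
            dp, dn, cp, cn = _fisher_cells(calls, metadata, disease)
            _, p = stats.fisher_exact([[dp, dn], [cp, cn]], alternative="two-sided")
            or_, log2_or = _odds_ratio(dp, dn, cp, cn)
            rows.append(
                {
                    "msp_id": msp_id,
                    "module_id": module_id,
                    "contrast": f"{disease} vs control",
                    "beta": model.beta,
                    "m_star": model.m_star,
                    "disease_pos": dp,
                    "disease_neg": dn,
                    "control_pos": cp,
                    "control_neg": cn,
                    "odds_ratio": or_,
                    "log2_odds_ratio": log2_or,
                    "p": float(p),
                }
            )
    result = pd.DataFrame(
        rows,
        columns=[
            "msp_id",
            "module_id",
            "contrast",
            "beta",
            "m_star",
            "disease_pos",
            "disease_neg",
            "control_pos",
            "control_neg",
            "odds_ratio",
            "log2_odds_ratio",
            "p",
        ],
    )
    result["q"] = np.nan
    for contrast, idx in result.groupby("contrast").groups.items():
        result.loc[idx, "q"] = bh_adjust(result.loc[idx, "p"].to_numpy())
    return result


def carrier_abundance_test(
    calls: CarriageCallSet,
    msp_table: MspAbundanceTable,
    metadata: SampleMetadata,
    group: str,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum: MSP abundance in carrier vs non-carrier samples.

    Restricted to determined samples of one cohort. Returns the rank-sum
    (Mann-Whitney U) statistic and its p-value; the exact null distribution
    is used for small tie-free samples, midranks otherwise.
    """
    det = calls.determined()
    in_group = metadata.frame.loc[det.index, "cohort"] == group
    det = det[in_group.to_numpy()]
    abund = msp_table.abundance.loc[calls.msp_id, det.index]
    x = abund[(det["call"] == "positive").to_numpy()].to_numpy(dtype=float)
    y = abund[(det["call"] == "negative").to_numpy()].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError(f"need >= 1 carrier and >= 1 non-carrier in {group!r}")
    stat, p = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(stat), float(p)
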