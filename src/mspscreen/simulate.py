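"""Synthetic shotgun-metagenome generator with known ground truth.

Emulates the post-mapping gene-catalog count matrix of an MSP-style
analysis: each metagenomic species pan-genome (MSP) has ranked core genes
and strain-variable accessory modules; samples carry a module with a
cohort-dependent probability; reads land on present genes proportionally
to gene length at a sample's sequencing depth and the MSP's relative
abundance. The generator exists so every downstream stage can be tested
against a known truth — it is test scaffolding, not a model of any real
community (no taxonomic realism, no sequencing-error model, no read-level
output).

Counts are Poisson by default; a gamma over-dispersion switch is provided
to stress robustness of downstream detection rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    COHORTS,
    IGG4_ACTIVITY,
    SSC_SUBGROUPS,
    TREATMENTS,
    GeneCatalogCounts,
    GeneInfo,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "ModuleSpec",
    "MspSpec",
    "CommunitySpec",
    "GroundTruth",
    "generate_metadata",
    "generate_community",
    "simulate_counts",
    "simple_community",
]

# cohort composition frequencies mirroring the study design defaults
_DEFAULT_SEX_FREQ = {"male": 0.3, "female": 0.7}
_DEFAULT_TREATMENT_FREQ = {
    "none": 0.25,
    "RTX": 0.20,
    "prednisone": 0.20,
    "other": 0.15,
    "RTX+prednisone": 0.10,
    "prednisone+other": 0.10,
}
_SSC_SUBGROUP_FREQ = {"lcSSc": 39 / 90, "dcSSc": 39 / 90, "ssSSc": 7 / 90, "osSSc": 5 / 90}
_IGG4_ACTIVE_FREQ = {"active": 13 / 58, "inactive": 45 / 58}


@dataclass
class ModuleSpec:
    """One accessory module: a co-abundant strain-variable gene set."""

    module_id: str
    n_genes: int
    #: per-cohort carriage probability, e.g. {"control": 0.5, "IgG4-RD": 0.75}
    carriage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError(f"module {self.module_id!r} must have >= 1 gene")
        for cohort, p in self.carriage.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(
                    f"carriage probability for {self.module_id!r}/{cohort} not in [0,1]: {p}"
                )

    def prob(self, cohort: str) -> float:
        return self.carriage.get(cohort, self.carriage.get("default", 0.5))


@dataclass
class MspSpec:
    """One metagenomic species pan-genome in the simulated community."""

    msp_id: str
    n_core_genes: int = 30
    modules: list[ModuleSpec] = field(default_factory=list)
    #: log10 fold-change on abundance per cohort (control baseline = 0)
    log10_effect: dict[str, float] = field(default_factory=dict)
    #: log10 effects of covariates: keys 'age' (per year, centered at 57),
    #: 'sex:female', 'treatment:<category>'
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    #: resolved base log10 abundance; drawn from Normal(base_mu, base_sigma) if None
    base_log10: float | None = None
    taxonomy: tuple[str | None, str | None, str | None] = (None, None, None)

    def __post_init__(self) -> None:
        if self.n_core_genes < 1:
            raise ValidationError(f"MSP {self.msp_id!r} must have >= 1 core gene")
        for v in self.log10_effect.values():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite cohort effect for MSP {self.msp_id!r}")


@dataclass
class CommunitySpec:
    """Community-level generative parameters.

    Gene lengths are log-uniform over ``length_range`` bp; base MSP
    log10-abundances are Normal(base_mu, base_sigma); per-sample biological
    noise adds Normal(0, sample_sigma) on the log10 scale before softmax
    normalization to relative abundances.
    """

    msps: list[MspSpec]
    length_range: tuple[int, int] = (300, 3000)
    base_mu: float = 0.0
    base_sigma: float = 1.0
    sample_sigma: float = 0.25
    depth_sigma: float = 0.3
    #: gamma over-dispersion of per-gene rates; None = pure Poisson
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if not self.msps:
            raise ValidationError("community must contain at least one MSP")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValidationError(f"invalid gene length range: {self.length_range}")


@dataclass
class GroundTruth:
    """True per-sample quantities recorded alongside a simulated matrix."""

    rel_abundance: pd.DataFrame  # MSP x sample, columns sum to 1
    carriage: pd.DataFrame  # (msp_id, module_id) x sample, 0/1
    effects: pd.DataFrame  # MSP x cohort log10 effects
    depths: pd.Series  # per-sample expected read depth


def generate_metadata(
    n_control: int,
    n_igg4rd: int,
    n_ssc: int,
    seed: int,
    sex_freq: dict[str, float] | None = None,
    treatment_freq: dict[str, float] | None = None,
) -> SampleMetadata:
    """Draw a sample-metadata table with the study's cohort structure.

    Defaults mirror the cohorts: ages ~ Normal(57, 10) clipped to [18, 90];
    controls are always untreated; SSc subgroups and IgG4-RD activity are
    drawn at the study's observed frequencies.
    """
    sizes = {"control": n_control, "IgG4-RD": n_igg4rd, "SSc": n_ssc}
    if any(n < 0 for n in sizes.values()):
        raise ValidationError("cohort sizes must be non-negative")
    n_total = sum(sizes.values())
    if n_total == 0:
        raise ValidationError("at least one cohort must be non-empty")
    sex_freq = sex_freq or _DEFAULT_SEX_FREQ
    treatment_freq = treatment_freq or _DEFAULT_TREATMENT_FREQ

    rng = np.random.default_rng(seed)
    cohort = np.repeat(list(sizes), list(sizes.values()))
    ages = np.clip(rng.normal(57.0, 10.0, n_total), 18.0, 90.0).round(1)
    sexes = rng.choice(list(sex_freq), p=_norm(list(sex_freq.values())), size=n_total)
    treatment = rng.choice(
        list(treatment_freq), p=_norm(list(treatment_freq.values())), size=n_total
    ).astype(object)
    treatment[cohort == "control"] = "none"
    subgroup = np.full(n_total, None, dtype=object)
    is_ssc = cohort == "SSc"
    subgroup[is_ssc] = rng.choice(
        list(_SSC_SUBGROUP_FREQ), p=_norm(list(_SSC_SUBGROUP_FREQ.values())), size=is_ssc.sum()
    )
    activity = np.full(n_total, None, dtype=object)
    is_igg4 = cohort == "IgG4-RD"
    activity[is_igg4] = rng.choice(
        list(_IGG4_ACTIVE_FREQ), p=_norm(list(_IGG4_ACTIVE_FREQ.values())), size=is_igg4.sum()
    )
    frame = pd.DataFrame(
        {
            "cohort": cohort,
            "subgroup": pd.array(subgroup, dtype="string"),
            "activity": pd.array(activity, dtype="string"),
            "age": ages,
            "sex": pd.array(sexes, dtype="string"),
            "treatment": pd.array(treatment, dtype="string"),
        },
        index=pd.Index([f"S{i:04d}" for i in range(1, n_total + 1)], name="sample_id"),
    )
    frame["cohort"] = frame["cohort"].astype("string")
    return SampleMetadata(frame)


def _norm(w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def generate_community(spec: CommunitySpec, seed: int) -> tuple[GeneInfo, CommunitySpec]:
    """Materialize a gene catalog for a community spec.

    Returns the gene-info table (ids, lengths, MSP/core/accessory labels,
    core ranks) and a resolved copy of the spec in which every MSP has a
    concrete base log10 abundance.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.length_range
    rows = []
    resolved_msps = []
    for msp in spec.msps:
        base = msp.base_log10
        if base is None:
            base = float(rng.normal(spec.base_mu, spec.base_sigma))
        resolved_msps.append(replace(msp, base_log10=base))
        species, genus, phylum = msp.taxonomy
        for rank in range(1, msp.n_core_genes + 1):
            rows.append(
                (
                    f"{msp.msp_id}_core_{rank:04d}",
                    _draw_length(rng, lo, hi),
                    msp.msp_id,
                    "core",
                    rank,
                    None,
                    None,
                    species,
                    genus,
                    phylum,
                )
            )
        for module in msp.modules:
            for g in range(1, module.n_genes + 1):
                rows.append(
                    (
                        f"{msp.msp_id}_{module.module_id}_{g:03d}",
                        _draw_length(rng, lo, hi),
                        msp.msp_id,
                        "accessory",
                        None,
                        module.module_id,
                        None,
                        species,
                        genus,
                        phylum,
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "length_bp",
            "msp_id",
            "gene_class",
            "core_rank",
            "module_id",
            "ko_id",
            "species",
            "genus",
            "phylum",
        ],
    ).set_index("gene_id")
    frame = frame.astype({"length_bp": "Int64", "core_rank": "Int64"})
    for col in ("msp_id", "gene_class", "module_id", "ko_id", "species", "genus", "phylum"):
        frame[col] = frame[col].astype("string")
    return GeneInfo(frame), replace(spec, msps=resolved_msps)


def _draw_length(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def simulate_counts(
    gene_info: GeneInfo,
    metadata: SampleMetadata,
    spec: CommunitySpec,
    depth_mean: float,
    seed: int,
) -> tuple[GeneCatalogCounts, GroundTruth]:
    """Draw a gene-catalog count matrix and its ground truth.

    For sample s with depth D_s ~ LogNormal(ln depth_mean, depth_sigma):
    MSP log10-abundances are base + cohort effect + covariate effects +
    Normal(0, sample_sigma) noise, softmax-normalized to relative
    abundances a_m(s). Each accessory module is carried with its cohort's
    probability; gene g of MSP m draws X_gs ~ Poisson(D_s a_m(s) w_g) where
    w_g is the gene's length share among the genes present in that sample's
    strain (absent modules contribute no genes).
    """
    if depth_mean < 0:
        raise ValidationError("depth_mean must be non-negative")
    for msp in spec.msps:
        if msp.base_log10 is None:
            raise ValidationError(
                f"MSP {msp.msp_id!r} has no resolved base abundance; "
                "pass the spec returned by generate_community"
            )
    rng = np.random.default_rng(seed)
    meta = metadata.frame
    samples = meta.index
    n_samples = len(samples)
    cohorts = meta["cohort"].to_numpy()

    if depth_mean == 0:
        depths = np.zeros(n_samples)
    else:
        depths = rng.lognormal(math.log(depth_mean), spec.depth_sigma, n_samples)

    # per-sample log10 abundance for every MSP
    msp_ids = [m.msp_id for m in spec.msps]
    log_ab = np.empty((len(spec.msps), n_samples))
    age_c = meta["age"].to_numpy(dtype=float) - 57.0
    is_female = (meta["sex"] == "female").to_numpy()
    for i, msp in enumerate(spec.msps):
        row = np.full(n_samples, msp.base_log10, dtype=float)
        for cohort, eff in msp.log10_effect.items():
            row[cohorts == cohort] += eff
        coefs = msp.covariate_coefs
        if "age" in coefs:
            row += coefs["age"] * age_c
        if "sex:female" in coefs:
            row += coefs["sex:female"] * is_female
        for key, val in coefs.items():
            if key.startswith("treatment:"):
                row[(meta["treatment"] == key.split(":", 1)[1]).to_numpy()] += val
        row += rng.normal(0.0, spec.sample_sigma, n_samples)
        log_ab[i] = row
    # softmax on the natural-log scale defines compositionality
    log_ab -= log_ab.max(axis=0, keepdims=True)
    rel = np.power(10.0, log_ab)
    rel /= rel.sum(axis=0, keepdims=True)

    # carriage indicators per (msp, module)
    carriage_rows = []
    carriage_index = []
    for msp in spec.msps:
        for module in msp.modules:
            p = np.array([module.prob(c) for c in cohorts])
            carriage_rows.append((rng.random(n_samples) < p).astype(np.int8))
            carriage_index.append((msp.msp_id, module.module_id))

    gf = gene_info.frame
    lengths = gf["length_bp"].to_numpy(dtype=float)
    counts = np.zeros((len(gf), n_samples), dtype=np.int64)
    carriage_lookup = dict(zip(carriage_index, carriage_rows))
    gene_pos = {g: i for i, g in enumerate(gf.index)}

    for i, msp in enumerate(spec.msps):
        in_msp = gf["msp_id"].eq(msp.msp_id).fillna(False).to_numpy(dtype=bool)
        core_mask = in_msp & gf["gene_class"].eq("core").to_numpy(dtype=bool)
        core_len = lengths[core_mask].sum()
        # per-sample total present length in this MSP's strain
        total_len = np.full(n_samples, core_len)
        module_masks = {}
        for module in msp.modules:
            m_mask = in_msp & gf["module_id"].eq(module.module_id).fillna(False).to_numpy(dtype=bool)
            module_masks[module.module_id] = m_mask
            carried = carriage_lookup[(msp.msp_id, module.module_id)]
            total_len += lengths[m_mask].sum() * carried
        scale = np.where(total_len > 0, depths * rel[i] / np.where(total_len > 0, total_len, 1), 0.0)
        lam = np.outer(lengths[core_mask], scale)
        counts[np.flatnonzero(core_mask)] = _draw_counts(rng, lam, spec.dispersion)
        for module in msp.modules:
            m_mask = module_masks[module.module_id]
            carried = carriage_lookup[(msp.msp_id, module.module_id)]
            lam = np.outer(lengths[m_mask], scale * carried)
            counts[np.flatnonzero(m_mask)] = _draw_counts(rng, lam, spec.dispersion)

    counts_df = pd.DataFrame(counts, index=gf.index.copy(), columns=samples.copy())
    truth = GroundTruth(
        rel_abundance=pd.DataFrame(rel, index=pd.Index(msp_ids, name="msp_id"), columns=samples),
        carriage=pd.DataFrame(
            np.array(carriage_rows) if carriage_rows else np.zeros((0, n_samples), dtype=np.int8),
            index=pd.MultiIndex.from_tuples(
                carriage_index or [], names=["msp_id", "module_id"]
            ),
            columns=samples,
        ),
        effects=pd.DataFrame(
            {c: [m.log10_effect.get(c, 0.0) for m in spec.msps] for c in COHORTS},
            index=pd.Index(msp_ids, name="msp_id"),
        ),
        depths=pd.Series(depths, index=samples, name="depth"),
    )
    return GeneCatalogCounts(counts_df), truth


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, dispersion: float | None
) -> np.ndarray:
    if dispersion:
        lam = lam * rng.gamma(1.0 / dispersion, dispersion, size=lam.shape)
    return rng.poisson(lam)


def simple_community(
    n_msps: int = 20,
    n_core_genes: int = 30,
    modules_per_msp: int = 1,
    module_n_genes: int = 5,
    carriage: dict[str, float] | None = None,
    log10_effects: dict[str, dict[str, float]] | None = None,
    **spec_kwargs,
) -> CommunitySpec:
    """Convenience builder for a homogeneous community spec.

    ``log10_effects`` maps msp_id -> cohort -> log10 fold-change for spiked
    MSPs; all other MSPs have no cohort effect.
    """
    carriage = carriage if carriage is not None else {"default": 0.5}
    log10_effects = log10_effects or {}
    msps = []
    for i in range(1, n_msps + 1):
        msp_id = f"msp_{i:03d}"
        modules = [
            ModuleSpec(f"mod_{i:03d}_{j:02d}", module_n_genes, dict(carriage))
            for j in range(1, modules_per_msp + 1)
        ]
        msps.append(
            MspSpec(
                msp_id,
                n_core_genes=n_core_genes,
                modules=modules,
                log10_effect=dict(log10_effects.get(msp_id, {})),
            )
        )
    return CommunitySpec(msps, **spec_kwargs)
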