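"""Shared data model, controlled vocabularies, and TSV readers/writers.

All tabular inputs and outputs are UTF-8, tab-separated, '.' decimal
separator, no quoting; missing optional fields are empty strings. Output
files carry a single '#'-prefixed provenance line; readers skip '#' lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "COHORTS",
    "SSC_SUBGROUPS",
    "IGG4_ACTIVITY",
    "TREATMENTS",
    "GENE_CLASSES",
    "CALL_STATES",
    "GeneCatalogCounts",
    "GeneInfo",
    "SampleMetadata",
    "TpmMatrix",
    "ConsistencyReport",
    "read_counts",
    "write_counts",
    "read_gene_info",
    "write_gene_info",
    "read_metadata",
    "write_metadata",
    "write_table",
    "validate_consistency",
]


class FormatError(ValueError):
    """A file does not parse as the declared tabular format."""


class ValidationError(ValueError):
    """Parsed data violate a declared invariant or controlled vocabulary."""


COHORTS = ("control", "IgG4-RD", "SSc")
SSC_SUBGROUPS = ("lcSSc", "dcSSc", "ssSSc", "osSSc")
IGG4_ACTIVITY = ("active", "inactive")
#: six treatment categories; controls are non-medicated by design
TREATMENTS = ("none", "RTX", "prednisone", "other", "RTX+prednisone", "prednisone+other")
GENE_CLASSES = ("core", "accessory", "unassigned")
CALL_STATES = ("positive", "negative", "undetermined")

GENE_INFO_COLUMNS = (
    "length_bp",
    "msp_id",
    "gene_class",
    "core_rank",
    "module_id",
    "ko_id",
    "species",
    "genus",
    "phylum",
)
METADATA_COLUMNS = ("cohort", "subgroup", "activity", "age", "sex", "treatment")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups}")


@dataclass
class GeneCatalogCounts:
    """Read counts per catalog gene (rows) per sample (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        _check_unique(c.index, "gene")
        _check_unique(c.columns, "sample")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # locate the first offending cell for the error message
            for j, col in enumerate(c.columns):
                vals = c[col].to_numpy()
                frac = vals != np.floor(vals)
                if frac.any():
                    i = int(np.argmax(frac))
                    raise FormatError(
                        f"non-integer count at gene {c.index[i]!r}, sample {col!r}: {vals[i]!r}"
                    )
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {c.index[i]!r}, sample {c.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class GeneInfo:
    """Per-gene catalog annotations: length, MSP membership, core/accessory labels.

    The frame is indexed by gene_id with columns ``length_bp, msp_id,
    gene_class, core_rank, module_id, ko_id, species, genus, phylum``.
    Optional fields are NA.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(f.index, "gene")
        missing = [c for c in GENE_INFO_COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"gene-info table missing columns: {missing}")
        if (f["length_bp"] <= 0).any() or f["length_bp"].isna().any():
            bad = f.index[(f["length_bp"].isna()) | (f["length_bp"] <= 0)].tolist()
            raise ValidationError(f"non-positive or missing length_bp for genes: {bad[:5]}")
        unknown = set(f["gene_class"].unique()) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene_class values: {sorted(unknown)}")
        is_core = f["gene_class"] == "core"
        is_acc = f["gene_class"] == "accessory"
        if f["core_rank"].notna().to_numpy()[~is_core.to_numpy()].any():
            bad = f.index[f["core_rank"].notna() & ~is_core].tolist()
            raise ValidationError(f"core_rank set on non-core genes: {bad[:5]}")
        if (is_core & f["core_rank"].notna() & (f["core_rank"] <= 0)).any():
            raise ValidationError("core_rank must be a positive integer")
        if (is_acc & f["module_id"].isna()).any():
            bad = f.index[is_acc & f["module_id"].isna()].tolist()
            raise ValidationError(f"accessory genes lacking module_id: {bad[:5]}")
        if (~is_acc & f["module_id"].notna()).any():
            bad = f.index[~is_acc & f["module_id"].notna()].tolist()
            raise ValidationError(f"module_id set on non-accessory genes: {bad[:5]}")
        mod_msp = f.loc[is_acc, ["module_id", "msp_id"]].drop_duplicates()
        counts = mod_msp.groupby("module_id", observed=True)["msp_id"].nunique()
        if (counts > 1).any():
            raise ValidationError(
                f"modules assigned to multiple MSPs: {counts.index[counts > 1].tolist()}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    def core_genes(self, msp_id: str, n_representatives: int | None = None) -> pd.Index:
        """Core genes of one MSP; optionally only the top-ranked representatives."""
        f = self.frame
        sel = f[f["msp_id"].eq(msp_id).fillna(False) & f["gene_class"].eq("core")]
        if sel.empty:
            raise ValidationError(f"MSP {msp_id!r} has no core genes")
        if n_representatives is not None:
            sel = sel[sel["core_rank"] <= n_representatives]
        return sel.index

    def module_genes(self, msp_id: str, module_id: str) -> pd.Index:
        f = self.frame
        sel = f[f["msp_id"].eq(msp_id).fillna(False) & f["module_id"].eq(module_id).fillna(False)]
        if sel.empty:
            raise ValidationError(f"unknown module {module_id!r} for MSP {msp_id!r}")
        return sel.index


@dataclass
class SampleMetadata:
    """Per-sample clinical covariates, indexed by sample_id."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        _check_unique(f.index, "sample")
        missing = [c for c in METADATA_COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"metadata table missing columns: {missing}")
        for col, vocab in [
            ("cohort", COHORTS),
            ("sex", ("male", "female")),
            ("treatment", TREATMENTS),
        ]:
            unknown = set(f[col].dropna().unique()) - set(vocab)
            if unknown:
                raise ValidationError(f"unknown {col} values: {sorted(unknown)}")
        unknown = set(f["subgroup"].dropna().unique()) - set(SSC_SUBGROUPS)
        if unknown:
            raise ValidationError(f"unknown subgroup values: {sorted(unknown)}")
        unknown = set(f["activity"].dropna().unique()) - set(IGG4_ACTIVITY)
        if unknown:
            raise ValidationError(f"unknown activity values: {sorted(unknown)}")
        if (f["subgroup"].notna() & (f["cohort"] != "SSc")).any():
            bad = f.index[f["subgroup"].notna() & (f["cohort"] != "SSc")].tolist()
            raise ValidationError(f"subgroup set outside the SSc cohort: {bad[:5]}")
        if (f["activity"].notna() & (f["cohort"] != "IgG4-RD")).any():
            bad = f.index[f["activity"].notna() & (f["cohort"] != "IgG4-RD")].tolist()
            raise ValidationError(f"activity set outside the IgG4-RD cohort: {bad[:5]}")
        # healthy controls are recruited non-medicated
        bad_ctl = f.index[(f["cohort"] == "control") & (f["treatment"] != "none")]
        if len(bad_ctl):
            raise ValidationError(f"control samples with treatment != none: {bad_ctl.tolist()[:5]}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class TpmMatrix:
    """Length-normalized abundances; nonzero sample columns sum to 1e6."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.tpm.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("TPM matrix has negative entries")
        sums = arr.sum(axis=0)
        nonzero = sums > 0
        if nonzero.any() and not np.allclose(sums[nonzero], 1e6, rtol=1e-9):
            raise ValidationError("nonzero TPM columns must sum to 1e6")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, index_name: str) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")
                break
        if header is None:
            raise FormatError(f"{path}: empty file")
        if len(header) != len(set(header)):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise FormatError(f"{path}: duplicated header fields {dups}")
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    frame.index = frame.index.astype(str)
    frame.index.name = index_name
    return frame


def read_counts(path) -> GeneCatalogCounts:
    """Read a genes × samples integer count matrix."""
    frame = _read_tsv(path, "gene_id")
    frame.columns.name = "sample_id"
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            raise FormatError(
                f"{path}: non-numeric count at gene {bad.index[0]!r}, sample {col!r}: {bad.iloc[0]!r}"
            )
    return GeneCatalogCounts(frame)


def write_counts(counts: GeneCatalogCounts, path, provenance: str | None = None) -> None:
    write_table(counts.counts, path, provenance)


def read_gene_info(path) -> GeneInfo:
    frame = _read_tsv(path, "gene_id")
    missing = [c for c in GENE_INFO_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: gene-info table missing columns {missing}")
    frame = frame.astype({"length_bp": "Int64", "core_rank": "Int64"}, errors="ignore")
    for col in ("msp_id", "gene_class", "module_id", "ko_id", "species", "genus", "phylum"):
        frame[col] = frame[col].astype("string")
    return GeneInfo(frame)


def write_gene_info(gene_info: GeneInfo, path, provenance: str | None = None) -> None:
    write_table(gene_info.frame, path, provenance)


def read_metadata(path) -> SampleMetadata:
    frame = _read_tsv(path, "sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: metadata table missing columns {missing}")
    for col in ("cohort", "subgroup", "activity", "sex", "treatment"):
        frame[col] = frame[col].astype("string")
    frame["age"] = pd.to_numeric(frame["age"])
    return SampleMetadata(frame)


def write_metadata(metadata: SampleMetadata, path, provenance: str | None = None) -> None:
    write_table(metadata.frame, path, provenance)


def write_table(frame: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write any result table as TSV with an optional '#' provenance line."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t", na_rep="")


@dataclass
class ConsistencyReport:
    """Cross-table id reconciliation. Empty lists mean the tables agree."""

    genes_without_info: list = field(default_factory=list)
    info_without_counts: list = field(default_factory=list)
    samples_without_metadata: list = field(default_factory=list)
    metadata_without_counts: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.genes_without_info
            or self.info_without_counts
            or self.samples_without_metadata
            or self.metadata_without_counts
        )


def validate_consistency(
    counts: GeneCatalogCounts, gene_info: GeneInfo, metadata: SampleMetadata
) -> ConsistencyReport:
    """Reconcile gene and sample id sets across the three input tables."""
    genes_c = set(counts.gene_ids)
    genes_i = set(gene_info.gene_ids)
    samp_c = set(counts.sample_ids)
    samp_m = set(metadata.sample_ids)
    return ConsistencyReport(
        genes_without_info=sorted(genes_c - genes_i),
        info_without_counts=sorted(genes_i - genes_c),
        samples_without_metadata=sorted(samp_c - samp_m),
        metadata_without_counts=sorted(samp_m - samp_c),
    )
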