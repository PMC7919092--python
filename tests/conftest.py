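import numpy as np
import pandas as pd
import pytest

from mspscreen.io import GeneCatalogCounts, GeneInfo, SampleMetadata
from mspscreen.simulate import (
    generate_community,
    generate_metadata,
    simple_community,
    simulate_counts,
)


def make_gene_info(rows):
    """rows: (gene_id, length_bp, msp_id, gene_class, core_rank, module_id)."""
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "length_bp", "msp_id", "gene_class", "core_rank", "module_id"],
    ).set_index("gene_id")
    frame["ko_id"] = pd.NA
    frame["species"] = pd.NA
    frame["genus"] = pd.NA
    frame["phylum"] = pd.NA
    frame = frame.astype({"length_bp": "Int64", "core_rank": "Int64"})
    for col in ("msp_id", "gene_class", "module_id", "ko_id", "species", "genus", "phylum"):
        frame[col] = frame[col].astype("string")
    return GeneInfo(frame)


def make_metadata(cohorts, ages=None, sexes=None, treatments=None):
    n = len(cohorts)
    frame = pd.DataFrame(
        {
            "cohort": pd.array(cohorts, dtype="string"),
            "subgroup": pd.array([None] * n, dtype="string"),
            "activity": pd.array([None] * n, dtype="string"),
            "age": ages if ages is not None else np.linspace(30, 70, n),
            "sex": pd.array(sexes if sexes is not None else ["female", "male"] * (n // 2 + 1), dtype="string")[:n],
            "treatment": pd.array(
                treatments
                if treatments is not None
                else ["none" if c == "control" else "RTX" for c in cohorts],
                dtype="string",
            ),
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id"),
    )
    return SampleMetadata(frame)


def make_counts(matrix, gene_ids, sample_ids):
    return GeneCatalogCounts(
        pd.DataFrame(
            np.asarray(matrix, dtype=np.int64),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """3-cohort synthetic dataset exercised by several modules."""
    metadata = generate_metadata(40, 20, 20, seed=11)
    spec = simple_community(n_msps=5, modules_per_msp=1, carriage={"default": 0.5})
    gene_info, resolved = generate_community(spec, seed=12)
    counts, truth = simulate_counts(gene_info, metadata, resolved, depth_mean=2e5, seed=13)
    return {
        "metadata": metadata,
        "gene_info": gene_info,
        "spec": resolved,
        "counts": counts,
        "truth": truth,
    }
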