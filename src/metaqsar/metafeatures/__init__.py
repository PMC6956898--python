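"""Meta-feature extraction: dataset properties and protein-target properties.

`collection_metafeatures` assembles the per-target feature table consumed by
the meta-learners: dataset meta-features (``ds_`` scalars and ``fp_agg_``
aggregated fingerprint bits), target meta-features (``tg_``), and the
categorical grouping columns (``class_L1`` ... ``class_L6``,
``preferred_name``) that are one-hot encoded inside the estimators.
"""

from __future__ import annotations

import pandas as pd

from ..data import Collection
from .dataset import (
    aggregated_fingerprint,
    dataset_metafeatures,
    entropy,
    equal_frequency_bins,
    mutual_information,
    normalized_entropy,
    response_moments,
    total_correlation,
)
from .target import (
    aliphatic_index,
    boman_index,
    dipeptide_composition,
    hydrophobicity_profile,
    instability_index,
    is_stable,
    isoelectric_point,
    molecular_weight,
    net_charge,
    target_metafeatures,
)

GROUPING_COLUMNS = tuple(f"class_L{i}" for i in range(1, 7)) + ("preferred_name",)


def feature_group(column: str) -> str:
    """Map a meta-feature column to its reporting group."""
    if column.startswith("fp_agg_"):
        return "aggregated-fingerprint"
    if column.startswith("ds_"):
        return "information-theory"
    if column.startswith("tg_"):
        return "target-property"
    if column in GROUPING_COLUMNS or column.startswith(("class_", "preferred_name")):
        return "target-grouping"
    raise ValueError(f"column {column!r} belongs to no meta-feature group")


def collection_metafeatures(collection: Collection, seed: int = 0) -> pd.DataFrame:
    """Per-target meta-feature table for a whole collection.

    One row per target: dataset meta-features computed on the fingerprint
    table (nominal features), the all-descriptor table (feature moments)
    and the response; target meta-features from the protein sequence; and
    the class-path / preferred-name grouping labels as raw categoricals.
    """
    rows = {}
    for tid in collection.target_ids:
        tables = collection.tables[tid]
        ds = dataset_metafeatures(
            tables["fp"], tables["all"], collection.activities[tid], seed=seed
        )
        tg = target_metafeatures(collection.targets[tid]["sequence"])
        groups = pd.Series(
            {
                **{
                    f"class_L{level + 1}": label
                    for level, label in enumerate(collection.hierarchy.path_of(tid))
                },
                "preferred_name": collection.targets[tid]["preferred_name"],
            }
        )
        rows[tid] = pd.concat([ds, tg, groups])
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "target_id"
    return table


def write_metafeatures(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="target_id")


def read_metafeatures(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="target_id")
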