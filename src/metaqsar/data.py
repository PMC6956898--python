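"""QSAR dataset model, preprocessing, and collection I/O.

One QSAR problem is one protein target with a table of tested compounds.
Each target is materialised as three dataset representations:

=====================  ==========================================  =========
representation          features                                    kind
=====================  ==========================================  =========
``basicmolprop.miss``   basic/constitutional descriptors, imputed   continuous
``allmolprop.miss``     all 2D descriptors, imputed                 continuous
``fpFCFP4``             circular-fingerprint bits, complete         binary
=====================  ==========================================  =========

Descriptor tables may carry missing cells (descriptor software failing on a
structure); these are median-imputed per feature. Fingerprint tables are
complete by construction. The unimputed descriptor variants can be built for
inspection but are excluded from benchmarking.

Bioactivities are potency endpoints on a log scale (pIC50-like). When a
compound-target pair has several reported activities, the consensus value is
the median of the activities falling in the modal unit-width log bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Benchmarked representations, in canonical order.
REPRESENTATIONS = ("basicmolprop.miss", "allmolprop.miss", "fpFCFP4")
#: Constructed-but-not-benchmarked raw descriptor variants.
UNIMPUTED_REPRESENTATIONS = ("basicmolprop", "allmolprop")

FINGERPRINT_REPRESENTATION = "fpFCFP4"


@dataclass
class QSARDataset:
    """One target x one representation: feature matrix plus bioactivities.

    Attributes
    ----------
    target_id : str
    representation : str
        One of :data:`REPRESENTATIONS` (or an unimputed variant).
    X : pandas.DataFrame
        Compounds x features. Binary 0/1 for fingerprints, floats otherwise.
    y : pandas.Series
        Log-activity per compound, aligned with ``X``.
    feature_kind : str
        ``"binary"`` or ``"continuous"``.
    """

    target_id: str
    representation: str
    X: pd.DataFrame
    y: pd.Series
    feature_kind: str

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError(
                f"{self.target_id}/{self.representation}: X rows and y are misaligned"
            )
        if self.feature_kind not in ("binary", "continuous"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.feature_kind == "binary":
            vals = self.X.to_numpy()
            if np.isnan(vals).any():
                raise ValueError("fingerprint representation must be complete")
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("fingerprint entries must be 0/1")
        elif self.representation.endswith(".miss"):
            if self.X.isna().any().any():
                raise ValueError(
                    f"{self.representation} must be complete after imputation"
                )

    @property
    def n_compounds(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class ActivityRecord:
    """One reported log-activity for a compound-target pair."""

    compound_id: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"{self.compound_id}: activity must be finite")


def consensus_activity(values: Iterable[float | ActivityRecord]) -> float:
    """Consensus log-activity for one compound-target pair.

    Activities are binned into unit-width log bins anchored at integers,
    ``[k, k+1)``; the consensus is the median of the values in the most
    populated (modal) bin. If two bins tie for the mode, the bin containing
    the global median is preferred, then the lower bin.

    Parameters
    ----------
    values : iterable of float or ActivityRecord
        Reported log-activities, at least one, all finite.
    """
    vals = np.asarray(
        [v.value if isinstance(v, ActivityRecord) else v for v in values],
        dtype=float,
    )
    if vals.size == 0:
        raise ValueError("consensus_activity needs at least one record")
    if not np.isfinite(vals).all():
        raise ValueError("activities must be finite")
    bins: dict[int, list[float]] = {}
    for v in vals:
        bins.setdefault(math.floor(v), []).append(v)
    top = max(len(members) for members in bins.values())
    modal = sorted(k for k, members in bins.items() if len(members) == top)
    if len(modal) > 1:
        global_median_bin = math.floor(float(np.median(vals)))
        if global_median_bin in modal:
            chosen = global_median_bin
        else:
            chosen = modal[0]
    else:
        chosen = modal[0]
    return float(np.median(bins[chosen]))


def impute_median(X: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the per-column median of observed values.

    Observed cells are untouched, so the operation is idempotent. A column
    with no observed value cannot be imputed and raises.
    """
    all_missing = X.columns[X.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            "cannot impute all-missing column(s): " + ", ".join(map(str, all_missing))
        )
    return X.fillna(X.median(axis=0))


def n_datasets(n_targets: int, include_unimputed: bool = False) -> int:
    """Number of dataset representations produced for ``n_targets`` targets."""
    per_target = len(REPRESENTATIONS)
    if include_unimputed:
        per_target += len(UNIMPUTED_REPRESENTATIONS)
    return per_target * n_targets


def build_representations(
    target_id: str,
    fp: pd.DataFrame,
    basic: pd.DataFrame,
    all_desc: pd.DataFrame,
    y: pd.Series,
    include_unimputed: bool = False,
) -> dict[str, QSARDataset]:
    """Build the per-target dataset representations from raw tables.

    All tables must share the compound index of ``y``. Descriptor tables are
    median-imputed; the fingerprint table is used as-is. Raw (unimputed)
    descriptor variants are built only on request and are not benchmarked.
    """
    for name, table in (("fp", fp), ("basic", basic), ("all", all_desc)):
        if not table.index.equals(y.index):
            raise ValueError(f"{target_id}: {name} table compound ids misaligned with y")
    out = {
        "basicmolprop.miss": QSARDataset(
            target_id, "basicmolprop.miss", impute_median(basic), y, "continuous"
        ),
        "allmolprop.miss": QSARDataset(
            target_id, "allmolprop.miss", impute_median(all_desc), y, "continuous"
        ),
        "fpFCFP4": QSARDataset(target_id, "fpFCFP4", fp, y, "binary"),
    }
    if include_unimputed:
        out["basicmolprop"] = QSARDataset(
            target_id, "basicmolprop", basic, y, "continuous"
        )
        out["allmolprop"] = QSARDataset(
            target_id, "allmolprop", all_desc, y, "continuous"
        )
    return out


# ---------------------------------------------------------------------------
# Collection I/O
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="compound_id")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="compound_id")


def write_activity(y: pd.Series, path) -> None:
    y.rename("activity").to_csv(path, index_label="compound_id")


def read_activity(path) -> pd.Series:
    return pd.read_csv(path, index_col="compound_id")["activity"]


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=t, description="") for t, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class Collection:
    """An in-memory QSAR problem collection.

    Attributes
    ----------
    targets : dict
        ``target_id`` -> metadata dict with at least ``sequence``,
        ``preferred_name`` (``mechanism`` is present for synthetic targets).
    tables : dict
        ``target_id`` -> dict of raw tables ``{"fp", "basic", "all"}``.
    activities : dict
        ``target_id`` -> log-activity Series.
    hierarchy : ClassHierarchy
    config : dict or None
        Provenance (the generating configuration, if synthetic).
    """

    targets: dict[str, dict]
    tables: dict[str, dict[str, pd.DataFrame]]
    activities: dict[str, pd.Series]
    hierarchy: "ClassHierarchy"
    config: dict | None = None

    @property
    def target_ids(self) -> list[str]:
        return list(self.targets)

    def datasets(
        self, target_id: str, include_unimputed: bool = False
    ) -> dict[str, QSARDataset]:
        t = self.tables[target_id]
        return build_representations(
            target_id,
            t["fp"],
            t["basic"],
            t["all"],
            self.activities[target_id],
            include_unimputed=include_unimputed,
        )

    def write(self, directory) -> None:
        import yaml

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for tid in self.target_ids:
            write_activity(self.activities[tid], directory / f"{tid}.activity.csv")
            write_table(self.tables[tid]["fp"], directory / f"{tid}.fp.csv")
            write_table(self.tables[tid]["basic"], directory / f"{tid}.basic.csv")
            write_table(self.tables[tid]["all"], directory / f"{tid}.all.csv")
        write_fasta(
            {t: meta["sequence"] for t, meta in self.targets.items()},
            directory / "targets.fasta",
        )
        self.hierarchy.to_json(directory / "hierarchy.json")
        meta = {
            "config": self.config,
            "targets": {
                t: {k: v for k, v in m.items() if k != "sequence"}
                for t, m in self.targets.items()
            },
        }
        with open(directory / "collection.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def read(cls, directory) -> "Collection":
        import yaml

        from .hierarchy import ClassHierarchy

        directory = Path(directory)
        with open(directory / "collection.yaml") as fh:
            meta = yaml.safe_load(fh)
        sequences = read_fasta(directory / "targets.fasta")
        hierarchy = ClassHierarchy.from_json(directory / "hierarchy.json")
        targets, tables, activities = {}, {}, {}
        for tid, tmeta in meta["targets"].items():
            targets[tid] = dict(tmeta, sequence=sequences[tid])
            tables[tid] = {
                "fp": read_table(directory / f"{tid}.fp.csv"),
                "basic": read_table(directory / f"{tid}.basic.csv"),
                "all": read_table(directory / f"{tid}.all.csv"),
            }
            activities[tid] = read_activity(directory / f"{tid}.activity.csv")
        return cls(targets, tables, activities, hierarchy, config=meta.get("config"))
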