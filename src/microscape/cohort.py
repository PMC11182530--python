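"""Cohort tables and the sample-selection rules of the study design.

The pipeline starts from a genus-level taxonomic abundance table (samples x
genera) and a per-sample metadata table carrying the participant identifier,
the within-participant collection order (``visit_index``) and a disease-class
label (by default CD / UC / nonIBD).  Three selection rules shape the cohort:

* :func:`select_time_series` keeps each participant's first ``k`` successive
  samples and drops participants with fewer than ``k``;
* :func:`first_samples` keeps only the earliest sample per participant (the
  subset used to fit the assemblage model, avoiding within-participant
  pseudo-replication);
* :func:`balanced_subset` draws the same number of participants per class so
  the per-class maximum-entropy fits see equally sized inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CLASS_LABELS",
    "TaxonProfileTable",
    "read_profile_table",
    "read_metadata",
    "validate_metadata",
    "select_time_series",
    "first_samples",
    "balanced_subset",
]

DEFAULT_CLASS_LABELS = ("CD", "UC", "nonIBD")

METADATA_COLUMNS = ["sample_id", "participant_id", "visit_index", "class_label"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class TaxonProfileTable:
    """A samples x genera abundance matrix with labelled axes.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per genus.  Entries are
        non-negative counts or relative abundances.
    is_counts
        True when every entry is a non-negative integer.
    """

    data: pd.DataFrame
    is_counts: bool = field(default=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate genus names: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("profile table contains non-numeric values")
        if np.isnan(values).any():
            raise ValidationError("profile table contains missing values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {df.index[r]!r}, genus {df.columns[c]!r}"
            )
        if self.is_counts and not np.allclose(values, np.round(values)):
            raise ValidationError("is_counts=True but entries are not integers")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def genus_names(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genera(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, sample_ids) -> "TaxonProfileTable":
        """Return a new table restricted to ``sample_ids`` (in that order)."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"sample ids not in table: {missing[:5]}")
        return TaxonProfileTable(self.data.loc[list(sample_ids)], is_counts=self.is_counts)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def read_profile_table(path, orientation: str = "samples-as-rows") -> TaxonProfileTable:
    """Read a TSV abundance table into the canonical samples x genera layout.

    ``orientation`` is ``"samples-as-rows"`` or ``"taxa-as-rows"``; the latter
    is transposed on read.  Counts are detected automatically (all entries
    integral).
    """
    if orientation not in ("samples-as-rows", "taxa-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dup = pd.Index(header)
    if dup.has_duplicates:  # read_csv silently mangles duplicate headers
        kind = "sample ids" if orientation == "taxa-as-rows" else "genus names"
        raise ValidationError(
            f"duplicate {kind} in header: {dup[dup.duplicated()].unique().tolist()}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() and not df[col].isna().any():
            row = df.index[bad.isna().to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = bad
    if orientation == "taxa-as-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    values = df.to_numpy(dtype=float)
    is_counts = bool(values.size) and bool(np.allclose(values, np.round(values)))
    if is_counts:
        df = df.astype(np.int64)
    return TaxonProfileTable(df, is_counts=is_counts)


def read_metadata(path, class_labels=DEFAULT_CLASS_LABELS) -> pd.DataFrame:
    """Read and validate the sample metadata TSV.

    Expected columns: ``sample_id``, ``participant_id``, ``visit_index``,
    ``class_label``.  ``class_labels`` configures the allowed label set.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    return validate_metadata(df, class_labels=class_labels)


def validate_metadata(df: pd.DataFrame, class_labels=DEFAULT_CLASS_LABELS) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    df = df[METADATA_COLUMNS].copy()
    df["visit_index"] = pd.to_numeric(df["visit_index"], errors="raise").astype(int)
    if (df["visit_index"] < 1).any():
        raise ValidationError("visit_index must be a positive integer")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
    pv = df[["participant_id", "visit_index"]]
    if pv.duplicated().any():
        dup = pv[pv.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate (participant, visit) pair: ({dup.participant_id!r}, {dup.visit_index})"
        )
    unknown = sorted(set(df["class_label"]) - set(class_labels))
    if unknown:
        raise ValidationError(
            f"unknown class labels {unknown}; allowed labels are {sorted(class_labels)}"
        )
    per_participant = df.groupby("participant_id")["class_label"].nunique()
    mixed = per_participant[per_participant > 1].index.tolist()
    if mixed:
        raise ValidationError(f"class_label varies within participants: {mixed[:5]}")
    return df.reset_index(drop=True)


def _align(table: TaxonProfileTable, metadata: pd.DataFrame) -> None:
    table_ids = set(table.sample_ids)
    meta_ids = set(metadata["sample_id"])
    if table_ids != meta_ids:
        only_t = sorted(table_ids - meta_ids)[:5]
        only_m = sorted(meta_ids - table_ids)[:5]
        raise ValidationError(
            f"table/metadata sample mismatch (table-only: {only_t}, metadata-only: {only_m})"
        )


def select_time_series(table: TaxonProfileTable, metadata: pd.DataFrame, k: int = 10):
    """Keep each participant's first ``k`` samples; drop shorter participants.

    "First" means the ``k`` smallest ``visit_index`` values.  Output is ordered
    by participant then visit.  Returns ``(table, metadata)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _align(table, metadata)
    md = metadata.sort_values(["participant_id", "visit_index"], kind="mergesort")
    counts = md.groupby("participant_id")["sample_id"].transform("size")
    md = md[counts >= k]
    md = md.groupby("participant_id", group_keys=False, sort=True).head(k)
    md = md.reset_index(drop=True)
    if md.empty:
        warnings.warn(f"no participant has {k} or more samples; selection is empty")
    return table.subset(md["sample_id"]), md


def first_samples(table: TaxonProfileTable, metadata: pd.DataFrame):
    """Keep exactly one sample per participant: the minimum ``visit_index``."""
    _align(table, metadata)
    md = metadata.sort_values(["participant_id", "visit_index"], kind="mergesort")
    md = md.groupby("participant_id", group_keys=False, sort=True).head(1)
    md = md.reset_index(drop=True)
    return table.subset(md["sample_id"]), md


def balanced_subset(
    table: TaxonProfileTable,
    metadata: pd.DataFrame,
    per_class: int = 26,
    seed: int = 0,
):
    """Draw ``per_class`` participants per class without replacement (seeded).

    All retained samples of a chosen participant are included, so with ``k``
    samples per participant each class contributes ``per_class * k`` samples.
    """
    _align(table, metadata)
    rng = np.random.default_rng(seed)
    kept = []
    for label, grp in metadata.groupby("class_label", sort=True):
        participants = np.array(sorted(grp["participant_id"].unique()))
        if len(participants) < per_class:
            raise ValidationError(
                f"class {label!r} has only {len(participants)} participants, "
                f"need {per_class}"
            )
        chosen = rng.choice(participants, size=per_class, replace=False)
        kept.append(grp[grp["participant_id"].isin(set(chosen))])
    md = pd.concat(kept)
    md = md.sort_values(["class_label", "participant_id", "visit_index"], kind="mergesort")
    md = md.reset_index(drop=True)
    md.attrs["subset_seed"] = seed
    return table.subset(md["sample_id"]), md
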