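"""Shared in-memory containers for multi-omic cohort data.

A :class:`FeatureTable` wraps a samples x features :class:`pandas.DataFrame`
together with a feature-class tag (``taxon``, ``metabolite`` or ``clinical``);
a :class:`SampleMetadata` wraps the per-sample design (role, timepoint,
responder status, donor linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FEATURE_CLASSES = ("taxon", "metabolite", "clinical")

ROLE_DONOR = "donor"
ROLE_PATIENT = "patient"
TIME_BASELINE = "baseline"
TIME_POST = "post"

#: metadata CSV column order used on disk
METADATA_COLUMNS = ["sample_id", "subject_id", "role", "timepoint", "responder", "donor_id"]


@dataclass
class FeatureTable:
    """Samples x features matrix with a feature-class tag.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per feature. Taxon tables
        hold relative abundances (rows sum to 1); metabolite tables hold
        absolute concentrations; clinical tables hold marker values.
    feature_class
        One of ``taxon``, ``metabolite``, ``clinical``.
    """

    values: pd.DataFrame
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if (self.values.values < 0).any():
            raise ValueError("feature table contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(sample_ids)], self.feature_class)

    def to_tsv(self, path) -> None:
        """Write features x samples TSV (header row of sample ids)."""
        self.values.T.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path, feature_class: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.T, feature_class)


@dataclass
class SampleMetadata:
    """Per-sample design table.

    Columns: ``sample_id`` (index), ``subject_id``, ``role`` (donor/patient),
    ``timepoint`` (baseline/post; donors carry ``baseline``), ``responder``
    (R/NR/NA) and ``donor_id`` (the fixed donor linked to a patient).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(METADATA_COLUMNS[1:]) - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def _ids(self, mask) -> list[str]:
        return list(self.table.index[mask])

    def donor_samples(self) -> list[str]:
        return self._ids(self.table["role"] == ROLE_DONOR)

    def baseline_samples(self) -> list[str]:
        return self._ids(
            (self.table["role"] == ROLE_PATIENT) & (self.table["timepoint"] == TIME_BASELINE)
        )

    def post_samples(self, responder: str | None = None) -> list[str]:
        mask = (self.table["role"] == ROLE_PATIENT) & (self.table["timepoint"] == TIME_POST)
        if responder is not None:
            mask &= self.table["responder"] == responder
        return self._ids(mask)

    def responder_ids(self) -> set[str]:
        mask = (self.table["role"] == ROLE_PATIENT) & (self.table["responder"] == "R")
        return set(self.table.loc[mask, "subject_id"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, index_col="sample_id"))
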