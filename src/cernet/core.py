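"""Core domain containers and errors shared by every pipeline stage.

The pipeline operates on four in-memory objects: an :class:`ExpressionMatrix`
(features x samples with RNA-class and group metadata), a :class:`TargetTable`
of predicted miRNA->target interactions, :class:`AnnotationIntervals` with
genomic coordinates for cis-target assignment, and a :class:`GeneSetAnnotation`
carrying user-supplied gene->term maps for over-representation analysis.

All containers validate their invariants on construction; I/O code in
:mod:`cernet.io` converts external files into these objects and back, so the
analysis modules never touch raw files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
LONG_RNA_CLASSES = ("mRNA", "lncRNA", "circRNA")
CERNA_CLASSES = ("lncRNA", "circRNA")
GROUPS = ("groupA", "groupB")
BIOTYPES = ("protein_coding", "lncRNA", "other")
STRANDS = ("+", "-", ".")

#: abundance unit carried by each RNA class (long RNAs are FPKM-quantified,
#: small RNAs TPM-normalised)
UNIT_OF_CLASS = {
    "mRNA": "FPKM",
    "lncRNA": "FPKM",
    "circRNA": "FPKM",
    "miRNA": "TPM",
}


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


class LoadError(ValidationError):
    """A file could not be parsed into a valid container.

    Messages name the file, the line and the offending token wherever the
    parse context allows it.
    """


class UndefinedCorrelationError(ValueError):
    """Correlation requested for a constant (zero-variance) vector."""


def _require_unique(values, what: str) -> None:
    s = pd.Series(values)
    dup = s[s.duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dup[:5]))}")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with class and group metadata.

    Parameters
    ----------
    values
        Non-negative abundances, index = feature ids, columns = sample ids.
        Long RNAs (mRNA/lncRNA/circRNA) are FPKM, miRNAs TPM.
    feature_class
        Series mapping each feature id to one of ``RNA_CLASSES``.
    group_of_sample
        Series mapping each sample id to ``groupA`` or ``groupB`` (the
        small-yellow-follicle vs large-yellow-follicle roles of the two-group
        design).
    """

    values: pd.DataFrame
    feature_class: pd.Series
    group_of_sample: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        _require_unique(self.values.index, "feature id")
        _require_unique(self.values.columns, "sample id")

        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self.values.stack()[~np.isfinite(arr).ravel()]
            raise ValidationError(f"non-finite expression value at {bad.index[0]}")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value {arr[r, c]!r} at feature "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

        missing = self.values.index.difference(self.feature_class.index)
        if len(missing):
            raise ValidationError(f"features without class label: {list(missing[:5])}")
        self.feature_class = self.feature_class.reindex(self.values.index)
        unknown = set(self.feature_class.unique()) - set(RNA_CLASSES)
        if unknown:
            raise ValidationError(f"unknown RNA class: {sorted(unknown)}")

        missing = self.values.columns.difference(self.group_of_sample.index)
        if len(missing):
            raise ValidationError(f"samples without group label: {list(missing[:5])}")
        self.group_of_sample = self.group_of_sample.reindex(self.values.columns)
        unknown = set(self.group_of_sample.unique()) - set(GROUPS)
        if unknown:
            raise ValidationError(f"unknown sample group: {sorted(unknown)}")
        for g in GROUPS:
            if (self.group_of_sample == g).sum() < 2:
                raise ValidationError(f"group {g} has fewer than 2 samples")

    # ------------------------------------------------------------------ views
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return list(self.group_of_sample.index[self.group_of_sample == group])

    def features_of_class(self, rna_class: str) -> list[str]:
        if rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {rna_class!r}")
        return list(self.feature_class.index[self.feature_class == rna_class])

    def unit_of(self, feature_id: str) -> str:
        return UNIT_OF_CLASS[self.feature_class[feature_id]]

    def row(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id].to_numpy(dtype=float)


TARGET_COLUMNS = ["mirna_id", "target_id", "target_class", "site_count"]


@dataclass
class TargetTable:
    """Predicted miRNA->target interactions (the pre-correlation edge set).

    Duplicate (mirna_id, target_id) rows from upstream predictors are
    collapsed with their site counts summed; ``n_collapsed`` records how many
    input rows were merged away.
    """

    records: pd.DataFrame
    n_collapsed: int = 0

    def __post_init__(self) -> None:
        missing = set(TARGET_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"target table missing columns: {sorted(missing)}")
        self.records = self.records[TARGET_COLUMNS].reset_index(drop=True)
        bad = set(self.records["target_class"].unique()) - set(LONG_RNA_CLASSES)
        if bad:
            raise ValidationError(
                f"unsupported target_class {sorted(bad)}: miRNA-miRNA edges are not modelled"
            )
        _require_unique(
            list(zip(self.records["mirna_id"], self.records["target_id"])),
            "(mirna_id, target_id) pair",
        )
        if (self.records["site_count"].to_numpy() <= 0).any():
            raise ValidationError("site_count must be a positive integer")

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "TargetTable":
        """Build a table from possibly duplicated predictor output."""
        df = df.copy()
        if "site_count" not in df.columns:
            df["site_count"] = 1
        df["site_count"] = df["site_count"].fillna(1).astype(int)
        n_in = len(df)
        collapsed = (
            df.groupby(["mirna_id", "target_id", "target_class"], as_index=False, sort=True)[
                "site_count"
            ]
            .sum()
        )
        return cls(records=collapsed, n_collapsed=n_in - len(collapsed))

    def __len__(self) -> int:
        return len(self.records)


INTERVAL_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "biotype"]


@dataclass
class AnnotationIntervals:
    """Genomic intervals, stored 0-based half-open regardless of source dialect."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(INTERVAL_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValidationError(f"interval table missing columns: {sorted(missing)}")
        self.records = self.records[INTERVAL_COLUMNS].reset_index(drop=True)
        _require_unique(self.records["feature_id"], "interval feature_id")
        starts = self.records["start"].to_numpy()
        ends = self.records["end"].to_numpy()
        if (starts >= ends).any():
            i = int(np.argwhere(starts >= ends)[0][0])
            raise ValidationError(
                f"empty interval for {self.records['feature_id'][i]!r}: "
                f"start {starts[i]} >= end {ends[i]}"
            )
        bad = set(self.records["strand"].unique()) - set(STRANDS)
        if bad:
            raise ValidationError(f"unknown strand: {sorted(bad)}")
        bad = set(self.records["biotype"].unique()) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotype: {sorted(bad)}")

    def of_biotype(self, biotype: str) -> "AnnotationIntervals":
        return AnnotationIntervals(
            self.records[self.records["biotype"] == biotype].reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSetAnnotation:
    """User-supplied gene->term annotation for over-representation analysis."""

    terms: pd.DataFrame  # term_id, term_name
    members: dict = field(default_factory=dict)  # term_id -> frozenset of gene ids

    def __post_init__(self) -> None:
        _require_unique(self.terms["term_id"], "term_id")
        for term_id in self.terms["term_id"]:
            if not self.members.get(term_id):
                raise ValidationError(f"term {term_id!r} has no member genes")

    def __len__(self) -> int:
        return len(self.terms)
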