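"""Shared data model: expression matrix, sample/probeset annotation and the
global expression thresholds.

The pipeline operates on a single log2-scale intensity matrix (probesets x
samples, post-normalization) together with two annotation tables:

* a sample annotation assigning every array to a *group* (a tissue, a
  germ-cell/testis compartment, or a cancer subtype) and every cancer group
  to its matched normal tissue of origin;
* a probeset annotation mapping array probesets to gene symbols (several
  probesets may interrogate the same gene; unmapped probesets are allowed).

All detection decisions downstream are made against three global cutoffs
derived from the pooled intensity distribution of the matrix: the background
expression cutoff (BEC, the overall median) and the 25th/75th percentiles
bounding the "low" and "highly expressed" tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferentialIntegrityError, ValidationError

TARGET = "TARGET"
NORMAL = "NORMAL"
CANCER = "CANCER"
CATEGORIES = (TARGET, NORMAL, CANCER)


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Validated log2 intensity matrix.

    ``data`` is a float DataFrame with probeset IDs as index and sample IDs
    as columns. Values must be finite; missing values are rejected rather
    than imputed (the screening protocol has no imputation step).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "probeset IDs")
        _check_unique(df.columns, "sample IDs")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"matrix must have at least 2 probesets and 2 samples, got {df.shape}"
            )
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in expression matrix: {exc}") from exc
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite value at probeset "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        self.data = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))

    @property
    def probeset_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleAnnotation:
    """Sample -> group and group -> category/matched-normal structure.

    ``samples``: DataFrame indexed by sample_id with column ``group_id``.
    ``groups``: DataFrame indexed by group_id with columns ``category``
    (one of TARGET/NORMAL/CANCER), ``matched_normal`` (empty string unless
    category is CANCER) and a free-text ``label``.
    """

    samples: pd.DataFrame
    groups: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.samples.index, "sample IDs")
        _check_unique(self.groups.index, "group IDs")
        self.samples = self.samples.copy()
        self.groups = self.groups.copy()
        self.samples.index = self.samples.index.astype(str)
        self.groups.index = self.groups.index.astype(str)
        if "label" not in self.groups.columns:
            self.groups["label"] = ""
        self.groups["matched_normal"] = self.groups["matched_normal"].fillna("").astype(str)

        bad_cat = set(self.groups["category"]) - set(CATEGORIES)
        if bad_cat:
            raise ValidationError(f"unknown category token(s): {sorted(bad_cat)}")
        missing_groups = set(self.samples["group_id"]) - set(self.groups.index)
        if missing_groups:
            raise ReferentialIntegrityError(
                f"samples reference unknown group(s): {sorted(missing_groups)[:5]}"
            )
        for gid, row in self.groups.iterrows():
            if row["category"] == CANCER:
                mn = row["matched_normal"]
                if not mn:
                    raise ReferentialIntegrityError(f"cancer group {gid!r} has no matched_normal")
                if mn not in self.groups.index:
                    raise ReferentialIntegrityError(
                        f"cancer group {gid!r} matched to unknown group {mn!r}"
                    )
                if self.groups.loc[mn, "category"] != NORMAL:
                    raise ReferentialIntegrityError(
                        f"cancer group {gid!r} matched to non-NORMAL group {mn!r}"
                    )
            elif row["matched_normal"]:
                raise ValidationError(
                    f"non-cancer group {gid!r} must have empty matched_normal"
                )
        if not self.groups_of(TARGET):
            raise ValidationError("at least one TARGET group is required")
        if not self.groups_of(NORMAL):
            raise ValidationError("at least one NORMAL group is required")
        counts = self.samples["group_id"].value_counts()
        empty = [g for g in self.groups.index if counts.get(g, 0) == 0]
        if empty:
            raise ValidationError(f"group(s) with zero samples: {empty[:5]}")

    def groups_of(self, category: str) -> list[str]:
        return self.groups.index[self.groups["category"] == category].tolist()

    def samples_in_group(self, group_id: str) -> list[str]:
        return self.samples.index[self.samples["group_id"] == group_id].tolist()

    def samples_in_category(self, category: str) -> list[str]:
        gids = set(self.groups_of(category))
        return self.samples.index[self.samples["group_id"].isin(gids)].tolist()

    def matched_normal(self, cancer_group: str) -> str:
        return str(self.groups.loc[cancer_group, "matched_normal"])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Require an exact 1:1 correspondence with the matrix samples."""
        annot = set(self.samples.index)
        mat = set(matrix.sample_ids)
        if annot != mat:
            missing = sorted(mat - annot)[:5]
            extra = sorted(annot - mat)[:5]
            raise ReferentialIntegrityError(
                f"sample annotation does not match matrix samples; "
                f"missing from annotation: {missing}, not in matrix: {extra}"
            )


@dataclass
class ProbesetAnnotation:
    """Probeset -> gene symbol map; empty symbol marks an unmapped probeset."""

    mapping: pd.Series  # index probeset_id, values gene_symbol (str, '' = unmapped)

    def __post_init__(self) -> None:
        _check_unique(self.mapping.index, "probeset IDs")
        s = self.mapping.fillna("").astype(str)
        s.index = s.index.astype(str)
        s.name = "gene_symbol"
        self.mapping = s

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        unknown = set(self.mapping.index) - set(matrix.probeset_ids)
        if unknown:
            raise ReferentialIntegrityError(
                f"probeset annotation references probesets absent from the matrix: "
                f"{sorted(unknown)[:5]}"
            )

    def gene_for(self, probesets) -> pd.Series:
        """Gene symbol per probeset ('' for unmapped/unannotated)."""
        return self.mapping.reindex(pd.Index(probesets).astype(str)).fillna("")


@dataclass(frozen=True)
class GlobalThresholds:
    """Global detection/expression cutoffs, all in log2 units.

    bec: background expression cutoff (overall matrix median); q_low/q_high:
    25th/75th percentiles of the pooled intensity distribution. Values at or
    above q_high count as highly expressed; values below bec as undetected.
    """

    bec: float
    q_low: float
    q_high: float
    convention: str = field(default="linear", compare=False)

    def __post_init__(self) -> None:
        if not (self.q_low <= self.bec <= self.q_high):
            raise ValidationError(
                f"thresholds must satisfy q_low <= bec <= q_high, got "
                f"({self.q_low}, {self.bec}, {self.q_high})"
            )


def compute_global_thresholds(matrix: ExpressionMatrix) -> GlobalThresholds:
    """Pool every cell of the matrix and take the median and quartiles.

    Percentiles use linear interpolation between closest ranks (numpy's
    default), recorded in the ``convention`` field for reproducibility.
    """
    pooled = matrix.values.ravel()
    q_low, bec, q_high = np.percentile(pooled, [25.0, 50.0, 75.0], method="linear")
    return GlobalThresholds(bec=float(bec), q_low=float(q_low), q_high=float(q_high))


def group_summaries(matrix: ExpressionMatrix, annot: SampleAnnotation) -> pd.DataFrame:
    """Per-(probeset, group) summary signal: the median over the group's
    replicate samples.

    The median is robust to the heterogeneous biopsy composition of real
    tissue groups; a group's summary with a single sample is that sample.
    Returns a DataFrame probesets x groups (group order follows the
    annotation's group table).
    """
    annot.validate_against(matrix)
    cols = {}
    for gid in annot.groups.index:
        cols[gid] = matrix.data[annot.samples_in_group(gid)].median(axis=1)
    return pd.DataFrame(cols, index=matrix.probeset_ids)
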