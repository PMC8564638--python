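"""Tissue-specificity classification of probesets.

Each probeset is assigned exactly one of seven classes from its group
summaries, the global thresholds and the target-vs-somatic contrast:

* SET / SEHET — specifically expressed in the target compartment (testis /
  germ cells): detected there (signal > BEC), at least twofold above every
  normal somatic tissue, none of which is itself detected, and significant
  (q <= 0.01). The HE variant additionally has target signal in the upper
  quartile of the pooled matrix.
* PET / PEHET — as above but up to three somatic tissues may violate the
  detection or fold-change criteria (a single shared exception budget).
* IE — intermediate expression: detected in 4-10 somatic tissues.
* UE — ubiquitous: detected in every normal somatic tissue.
* OTHER — any remaining profile (e.g. detected in 11+ but not all somatic
  tissues, or target-detected without statistical support).

A somatic group counts as one exception if its summary exceeds the BEC
*or* lies within twofold (1.0 log2 unit) of the target signal; the target
signal is the maximum over TARGET group summaries, so expression confined
to a single germ-cell compartment still counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, CTScreenError
from .model import GlobalThresholds, SampleAnnotation, NORMAL, TARGET
from .stats import ContrastResult

CLASS_LABELS = ("SET", "SEHET", "PET", "PEHET", "IE", "UE", "OTHER")
SE_CLASSES = frozenset({"SET", "SEHET"})
TESTIS_CLASSES = frozenset({"SET", "SEHET", "PET", "PEHET"})


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable thresholds of both classifiers (defaults = protocol values)."""

    fold_change: float = 1.0   # log2 units; 1.0 = twofold
    q_cutoff: float = 0.01
    exception_budget: int = 3
    ie_min: int = 4
    ie_max: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.q_cutoff <= 1):
            raise CTScreenError("q_cutoff must be in (0, 1]")
        if self.exception_budget < 0:
            raise CTScreenError("exception_budget must be >= 0")
        if self.fold_change < 0:
            raise CTScreenError("fold_change must be >= 0")
        if not (0 <= self.ie_min <= self.ie_max):
            raise CTScreenError("need 0 <= ie_min <= ie_max")


def classify_tissue(
    summaries: pd.DataFrame,
    annot: SampleAnnotation,
    thresholds: GlobalThresholds,
    contrast: ContrastResult,
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Assign one tissue-specificity class per probeset.

    ``summaries`` is the probesets x groups median table; ``contrast`` the
    target-vs-pooled-somatic moderated test (one q per probeset). Returns a
    DataFrame indexed by probeset with columns class_label, target_signal,
    n_somatic_detected, n_exceptions, q.
    """
    target_groups = annot.groups_of(TARGET)
    normal_groups = annot.groups_of(NORMAL)
    missing = summaries.index.difference(contrast.table.index)
    if len(missing):
        raise ConsistencyError(
            f"contrast is missing {len(missing)} probeset(s), e.g. {list(missing[:3])}"
        )
    q = contrast.table["q"].reindex(summaries.index)

    target_signal = summaries[target_groups].max(axis=1)
    som = summaries[normal_groups]
    detected = som.gt(thresholds.bec)
    within_fold = som.gt(target_signal - params.fold_change, axis=0)
    exception = detected | within_fold
    n_det = detected.sum(axis=1).astype(int)
    n_exc = exception.sum(axis=1).astype(int)

    significant = (q <= params.q_cutoff) & (target_signal > thresholds.bec)
    se = significant & (n_exc == 0)
    pe = significant & (n_exc >= 1) & (n_exc <= params.exception_budget)
    high = target_signal >= thresholds.q_high
    ue = n_det == len(normal_groups)
    ie = (n_det >= params.ie_min) & (n_det <= params.ie_max)

    # SE/PE take precedence; UE before IE (they can overlap when there are
    # few somatic groups).
    label = np.select(
        [se & high, se & ~high, pe & high, pe & ~high, ue, ie],
        ["SEHET", "SET", "PEHET", "PET", "UE", "IE"],
        default="OTHER",
    )
    return pd.DataFrame(
        {
            "class_label": label,
            "target_signal": target_signal,
            "n_somatic_detected": n_det,
            "n_exceptions": n_exc,
            "q": q,
        },
        index=summaries.index.rename("probeset_id"),
    )


def summarize_class_distribution(records: pd.DataFrame, subset=None) -> pd.DataFrame:
    """Class -> (count, rounded percentage, raw fraction) over ``subset``
    (a probeset list) or over all classified probesets."""
    if subset is not None:
        subset = pd.Index(subset).astype(str)
        unknown = subset.difference(records.index)
        if len(unknown):
            raise ConsistencyError(
                f"subset contains unclassified probeset(s): {list(unknown[:3])}"
            )
        records = records.loc[subset]
    if len(records) == 0:
        raise CTScreenError("cannot summarize an empty probeset subset")
    counts = records["class_label"].value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "count": [int(counts.get(c, 0)) for c in CLASS_LABELS],
            "fraction": [counts.get(c, 0) / total for c in CLASS_LABELS],
        },
        index=pd.Index(CLASS_LABELS, name="class_label"),
    )
    out["percentage"] = (100.0 * out["fraction"]).round().astype(int)
    return out[["count", "percentage", "fraction"]]
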