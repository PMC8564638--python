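"""Cancer-upregulation classification, per probeset and per cancer subtype.

Four nested flags are assigned against each subtype's matched normal tissue
of origin:

* UC — upregulated in the cancer subtype: subtype signal above the BEC, at
  least twofold (1.0 log2 unit) above the matched normal tissue, and
  significant (q <= 0.01) in the subtype-vs-matched-normal contrast;
* UHEC — UC with subtype signal in the upper quartile (>= q_high);
* UCNDH — UC with the matched normal tissue below the BEC (not detected in
  healthy tissue);
* UHECNDH — UHEC and UCNDH together.

Flags use the per-subtype median summaries; the significance q comes from
the per-sample moderated test. Comparisons are fixed package-wide:
detection strictly > BEC, high expression >= q_high, not-detected strictly
< BEC, fold change >= the log2 threshold.
"""

from __future__ import annotations

import pandas as pd

from .errors import ConsistencyError
from .model import GlobalThresholds, SampleAnnotation, CANCER
from .stats import ContrastResult
from .tissue import ClassifierParams

CANCER_FLAG_COLUMNS = ["uc", "uhec", "ucndh", "uhecndh"]


def classify_cancer(
    summaries: pd.DataFrame,
    annot: SampleAnnotation,
    thresholds: GlobalThresholds,
    contrasts: dict[str, ContrastResult],
    params: ClassifierParams = ClassifierParams(),
) -> pd.DataFrame:
    """Flag every (probeset, cancer subtype) pair.

    ``contrasts`` maps each CANCER group to its cancer-vs-matched-normal
    contrast. Returns a long DataFrame with columns probeset_id,
    cancer_group, uc, uhec, ucndh, uhecndh, cancer_signal, normal_signal,
    log2fc, q.
    """
    frames = []
    for cg in annot.groups_of(CANCER):
        if cg not in contrasts:
            raise ConsistencyError(f"no contrast provided for cancer group {cg!r}")
        contrast = contrasts[cg]
        missing = summaries.index.difference(contrast.table.index)
        if len(missing):
            raise ConsistencyError(
                f"contrast for {cg!r} is missing {len(missing)} probeset(s)"
            )
        q = contrast.table["q"].reindex(summaries.index)
        cancer_signal = summaries[cg]
        normal_signal = summaries[annot.matched_normal(cg)]
        log2fc = cancer_signal - normal_signal
        uc = (
            (cancer_signal > thresholds.bec)
            & (log2fc >= params.fold_change)
            & (q <= params.q_cutoff)
        )
        uhec = uc & (cancer_signal >= thresholds.q_high)
        ucndh = uc & (normal_signal < thresholds.bec)
        frames.append(
            pd.DataFrame(
                {
                    "probeset_id": summaries.index,
                    "cancer_group": cg,
                    "uc": uc.to_numpy(),
                    "uhec": uhec.to_numpy(),
                    "ucndh": ucndh.to_numpy(),
                    "uhecndh": (uhec & ucndh).to_numpy(),
                    "cancer_signal": cancer_signal.to_numpy(),
                    "normal_signal": normal_signal.to_numpy(),
                    "log2fc": log2fc.to_numpy(),
                    "q": q.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def aggregate_cancer_flags(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse subtype flags to one row per probeset.

    Returns counts of subtypes with each flag plus ``any_ucndh``, the
    entry criterion of the CT caller (upregulated in at least one subtype
    with no detectable expression in that subtype's healthy tissue).
    """
    g = records.groupby("probeset_id", sort=False)
    out = pd.DataFrame(
        {
            "n_subtypes_uc": g["uc"].sum().astype(int),
            "n_subtypes_uhec": g["uhec"].sum().astype(int),
            "n_subtypes_ucndh": g["ucndh"].sum().astype(int),
            "n_subtypes_uhecndh": g["uhecndh"].sum().astype(int),
        }
    )
    out["any_ucndh"] = out["n_subtypes_ucndh"] > 0
    return out


def write_cancer_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    for c in CANCER_FLAG_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
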