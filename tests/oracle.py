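"""Independent brute-force evaluators of the screening criteria.

Deliberately written as literal per-probeset Python loops, sharing no code
with the vectorized classifiers: every detection, fold-change, significance
and precedence rule is spelled out one comparison at a time.
"""

from __future__ import annotations


def brute_force_tissue_class(
    target_summaries: dict,
    somatic_summaries: dict,
    q: float,
    bec: float,
    q_high: float,
    fold_change: float = 1.0,
    q_cutoff: float = 0.01,
    exception_budget: int = 3,
    ie_min: int = 4,
    ie_max: int = 10,
) -> str:
    """Tissue class of a single probeset, evaluated criterion by criterion."""
    target_signal = max(target_summaries.values())

    n_detected = 0
    n_exceptions = 0
    for tissue in somatic_summaries:
        s = somatic_summaries[tissue]
        detected = s > bec
        fold_violation = (target_signal - s) < fold_change
        if detected:
            n_detected += 1
        if detected or fold_violation:
            n_exceptions += 1

    target_detected = target_signal > bec
    significant = q <= q_cutoff
    highly_expressed = target_signal >= q_high

    if target_detected and significant and n_exceptions == 0:
        return "SEHET" if highly_expressed else "SET"
    if target_detected and significant and 1 <= n_exceptions <= exception_budget:
        return "PEHET" if highly_expressed else "PET"
    if n_detected == len(somatic_summaries):
        return "UE"
    if ie_min <= n_detected <= ie_max:
        return "IE"
    return "OTHER"


def brute_force_cancer_flags(
    cancer_signal: float,
    normal_signal: float,
    q: float,
    bec: float,
    q_high: float,
    fold_change: float = 1.0,
    q_cutoff: float = 0.01,
) -> dict:
    """UC/UHEC/UCNDH/UHECNDH flags for one (probeset, subtype) pair."""
    uc = (
        cancer_signal > bec
        and (cancer_signal - normal_signal) >= fold_change
        and q <= q_cutoff
    )
    uhec = uc and cancer_signal >= q_high
    ucndh = uc and normal_signal < bec
    return {"uc": uc, "uhec": uhec, "ucndh": ucndh, "uhecndh": uhec and ucndh}


def step_up_bh(pvalues):
    """BH adjusted p-values by the literal step-up formula."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    q = [None] * n
    best = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        best = min(best, pvalues[i] * n / rank)
        q[i] = best
    return q
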