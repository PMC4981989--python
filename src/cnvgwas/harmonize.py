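"""Cross-cohort harmonization of copy-number calls.

Cohorts are clustered independently, so the same CNVR can come out with
different class counts and frequencies on different genotyping platforms.
Harmonization anchors every cohort to a designated best-performing reference
cohort: cohorts whose freely selected class count disagrees are re-clustered
with K fixed to the reference value, and a Pearson chi-square test on the
2 x K table of MAP-class counts decides whether the class frequencies are
compatible.  Only compatible cohorts contribute a CNVR to meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompatibilityResult",
    "class_frequency_compatibility",
    "reclustering_worklist",
    "harmonize_cohorts",
    "classify_cnvr",
]

DEFAULT_ALPHA = 0.05
MIN_EXPECTED = 1.0


@dataclass
class CompatibilityResult:
    region_id: str
    cohort_pair: tuple
    chi2: Optional[float]
    dof: Optional[int]
    pvalue: Optional[float]
    compatible: bool
    reason: str = ""


def _pool_sparse_classes(table: np.ndarray, min_expected: float) -> np.ndarray:
    """Merge adjacent classes until every expected cell is >= min_expected.

    Classes are ordered (ascending intensity), so pooling is only ever with a
    neighbour.  Returns the pooled 2 x K' table (K' >= 1).
    """
    table = table.astype(float).copy()
    while table.shape[1] > 1:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        bad = np.where((expected < min_expected).any(axis=0))[0]
        if bad.size == 0:
            break
        j = bad[0]
        # merge into whichever neighbour exists (prefer the left one)
        tgt = j - 1 if j > 0 else j + 1
        table[:, tgt] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def class_frequency_compatibility(
    counts_ref,
    counts_test,
    alpha: float = DEFAULT_ALPHA,
    region_id: str = "?",
    cohort_pair: tuple = ("ref", "test"),
    min_expected: float = MIN_EXPECTED,
) -> CompatibilityResult:
    """Pearson chi-square compatibility of MAP-class counts between cohorts.

    A class-count mismatch is incompatible by construction (it triggers
    fixed-K re-clustering upstream, not a test).  Sparse classes with expected
    count < ``min_expected`` are pooled with the adjacent class first.
    Compatible iff P >= alpha.
    """
    a = np.asarray(counts_ref, dtype=float)
    b = np.asarray(counts_test, dtype=float)
    if a.shape != b.shape:
        return CompatibilityResult(
            region_id, cohort_pair, None, None, None, False, "class-count mismatch"
        )
    table = _pool_sparse_classes(np.vstack([a, b]), min_expected)
    if table.shape[1] < 2:
        # everything pooled into one class: no frequency information to test
        return CompatibilityResult(
            region_id, cohort_pair, 0.0, 0, 1.0, True, "single pooled class"
        )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return CompatibilityResult(
        region_id, cohort_pair, float(chi2), int(dof), float(p), bool(p >= alpha)
    )


def reclustering_worklist(free_k: pd.DataFrame, reference: str) -> list[tuple]:
    """(cohort, region) pairs whose free class count differs from the reference.

    ``free_k`` is a regions x cohorts table of freely selected K (NaN where a
    CNVR was not callable in a cohort).
    """
    if reference not in free_k.columns:
        raise ValueError(f"reference cohort {reference!r} not in table")
    work = []
    for region, row in free_k.iterrows():
        k_ref = row[reference]
        if pd.isna(k_ref):
            continue
        for cohort in free_k.columns:
            if cohort == reference or pd.isna(row[cohort]):
                continue
            if int(row[cohort]) != int(k_ref):
                work.append((cohort, region))
    return work


def harmonize_cohorts(
    counts: dict,
    reference: str,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, dict]:
    """Admit, per CNVR, the cohorts compatible with the reference.

    Parameters
    ----------
    counts : {cohort: {region_id: MAP-class count vector}}
        Post-reclustering class counts (all cohorts already forced to the
        reference K where they disagreed; absent entries mean uncallable).
    reference : reference cohort id
    alpha : compatibility significance level

    Returns
    -------
    report : DataFrame with one row per (region, cohort) giving K, counts,
        chi-square, P and the admission flag.
    admitted : {region_id: [cohort, ...]} — cohorts contributing the CNVR to
        meta-analysis (the reference always included where it called the
        region; reference-only CNVRs are admitted with cohort count 1).
    """
    if reference not in counts:
        raise ValueError(f"reference cohort {reference!r} missing from counts")
    rows = []
    admitted: dict[str, list] = {}
    ref_calls = counts[reference]
    for region, c_ref in ref_calls.items():
        admitted[region] = [reference]
        rows.append(
            {
                "region_id": region,
                "cohort": reference,
                "k": len(c_ref),
                "counts": ",".join(str(int(v)) for v in c_ref),
                "chi2": np.nan,
                "pvalue": np.nan,
                "compatible": True,
                "reason": "reference",
            }
        )
        for cohort, calls in counts.items():
            if cohort == reference or region not in calls:
                continue
            res = class_frequency_compatibility(
                c_ref, calls[region], alpha=alpha,
                region_id=region, cohort_pair=(reference, cohort),
            )
            rows.append(
                {
                    "region_id": region,
                    "cohort": cohort,
                    "k": len(calls[region]),
                    "counts": ",".join(str(int(v)) for v in calls[region]),
                    "chi2": res.chi2,
                    "pvalue": res.pvalue,
                    "compatible": res.compatible,
                    "reason": res.reason,
                }
            )
            if res.compatible:
                admitted[region].append(cohort)
    report = pd.DataFrame(rows)
    return report, admitted


def classify_cnvr(results) -> str:
    """Type a CNVR as deletion / amplification / multiallelic.

    The modal class (largest weight) anchors the diploid state; classes with
    lower mean intensity are losses, higher are gains.  Losses only ->
    deletion; gains only -> amplification; both sides occupied or K > 3 ->
    multiallelic; K = 1 -> non-polymorphic.
    """
    k = results.k
    if k <= 1:
        return "non-polymorphic"
    if k > 3:
        return "multiallelic"
    modal = int(np.argmax(results.weights))
    losses = modal > 0
    gains = modal < k - 1
    if losses and gains:
        return "multiallelic"
    return "deletion" if losses else "amplification"
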