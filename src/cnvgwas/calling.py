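"""Per-CNVR copy-number genotype calling.

Workflow per copy-number-variable region (CNVR): collapse the in-region probe
intensities to a single value per sample, cluster those values with a Gaussian
mixture (:mod:`cnvgwas.mixture`), and emit MAP classes, posterior class
probabilities and the continuous copy-number dose.

Coordinates are 0-based half-open (BED convention): a probe at position ``p``
is inside a region iff ``start <= p < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mixture import IntensityMixture, IntensityMixtureResults

__all__ = [
    "CNVRegion",
    "IntensitySummary",
    "CopyNumberCalls",
    "summarize_cnvr",
    "fit_mixture",
    "select_classes",
    "call_with_fixed_k",
    "posterior_doses",
]

AUTOSOMES = {str(i) for i in range(1, 23)}


def _normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class CNVRegion:
    """A catalogued copy-number-variable interval (0-based half-open)."""

    region_id: str
    chrom: str
    start: int
    end: int
    declared_type: Optional[str] = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"{self.region_id}: start must be < end ({self.start} >= {self.end})"
            )

    @property
    def is_autosomal(self) -> bool:
        return _normalize_chrom(self.chrom) in AUTOSOMES

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos) -> np.ndarray:
        pos = np.asarray(pos)
        return (pos >= self.start) & (pos < self.end)


@dataclass
class IntensitySummary:
    """One intensity value per sample for one CNVR.

    ``values`` covers only samples with complete (non-missing) in-region probe
    data; everyone else is listed in ``excluded`` with the reason.  A region
    with no mapped probe is ``callable_region=False`` rather than an error.
    """

    region_id: str
    values: pd.Series
    probe_ids: list = field(default_factory=list)
    excluded: dict = field(default_factory=dict)
    callable_region: bool = True

    @property
    def nobs(self) -> int:
        return len(self.values)


@dataclass
class CopyNumberCalls:
    """Per-sample calls for one CNVR: MAP class, posterior vector, dose."""

    region_id: str
    k: int
    table: pd.DataFrame  # sample_id index; map_class, dose, confidence, post_0..post_{k-1}

    @property
    def doses(self) -> pd.Series:
        return self.table["dose"]

    @property
    def map_classes(self) -> pd.Series:
        return self.table["map_class"]


def summarize_cnvr(
    intensities: pd.DataFrame,
    probes: pd.DataFrame,
    region: CNVRegion,
) -> IntensitySummary:
    """Mean in-region probe intensity per sample.

    Parameters
    ----------
    intensities : DataFrame, samples x probes (LRR units, NaN = missing)
    probes : DataFrame with columns ``probe_id``, ``chrom``, ``pos``
    region : CNVRegion

    Samples with any missing in-region probe are excluded (only complete
    profiles are clustered).
    """
    chroms = probes["chrom"].map(_normalize_chrom)
    in_region = (chroms == _normalize_chrom(region.chrom)) & region.contains(
        probes["pos"].to_numpy()
    )
    probe_ids = [p for p in probes.loc[in_region, "probe_id"] if p in intensities.columns]
    if not probe_ids:
        return IntensitySummary(
            region_id=region.region_id,
            values=pd.Series(dtype=float),
            probe_ids=[],
            callable_region=False,
        )
    sub = intensities[probe_ids]
    complete = sub.notna().all(axis=1)
    excluded = {s: "missing in-region probe" for s in sub.index[~complete]}
    return IntensitySummary(
        region_id=region.region_id,
        values=sub.loc[complete].mean(axis=1),
        probe_ids=probe_ids,
        excluded=excluded,
    )


def fit_mixture(values, k: int, seed: int = 0, **kwargs) -> IntensityMixtureResults:
    """EM Gaussian mixture with K components on the 1-D summary values."""
    return IntensityMixture(values).fit(k, seed=seed, **kwargs)


def select_classes(values, k_max: int = 6, seed: int = 0, **kwargs):
    """Pick the number of classes by minimum BIC; returns (best_k, results)."""
    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError(f"need >= 30 samples for class selection, got {values.size}")
    res = IntensityMixture(values).select(k_max=k_max, seed=seed, **kwargs)
    return res.k, res


def call_with_fixed_k(
    values, k_ref: int, seed: int = 0, min_expected: float = 3.0, **kwargs
) -> Optional[IntensityMixtureResults]:
    """Re-cluster with the class count anchored to the reference cohort.

    Returns ``None`` (uncallable) when there are fewer than ``5 * k_ref``
    samples.  The fit is flagged ``low_quality`` when any class expects fewer
    than ``min_expected`` samples.
    """
    if k_ref < 2:
        raise ValueError(f"k_ref must be >= 2, got {k_ref}")
    values = np.asarray(values, dtype=float)
    if values.size < 5 * k_ref:
        return None
    res = IntensityMixture(values).fit(k_ref, seed=seed, **kwargs)
    if np.any(res.expected_counts() < min_expected):
        res.low_quality = True
    return res


def posterior_doses(
    results: IntensityMixtureResults,
    region_id: str,
    sample_ids=None,
) -> CopyNumberCalls:
    """Turn a fitted mixture into per-sample calls with continuous dose."""
    n = results.nobs
    if sample_ids is None:
        sample_ids = pd.RangeIndex(n)
    table = pd.DataFrame(
        {
            "map_class": results.map_classes,
            "dose": results.doses,
            "confidence": results.confidences,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for j in range(results.k):
        table[f"post_{j}"] = results.posteriors[:, j]
    return CopyNumberCalls(region_id=region_id, k=results.k, table=table)
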