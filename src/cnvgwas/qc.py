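"""Sample-level quality control before copy-number calling.

Three filters, applied in order: declared-replicate removal, intensity-noise
filtering (per-sample SD of autosomal Log R Ratio values against a threshold),
and ancestry principal-component outlier exclusion (any of the first PCs
further than a given number of SDs from the mean).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "intensity_noise_metric",
    "noise_filter",
    "drop_replicates",
    "pca_ancestry_scores",
    "pc_outlier_filter",
    "sample_qc",
]

MIN_NOISE_PROBES = 100
DEFAULT_NOISE_THRESHOLD = 0.30  # LRR units
DEFAULT_PC_SD = 6.0
DEFAULT_N_PCS = 4


def intensity_noise_metric(lrr, sample_id: str = "?", min_probes: int = MIN_NOISE_PROBES) -> float:
    """Per-sample noise metric: population SD of autosomal LRR values.

    Missing (NaN) probes are ignored; fewer than ``min_probes`` non-missing
    values is an error naming the sample.
    """
    x = np.asarray(lrr, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_probes:
        raise ValueError(
            f"sample {sample_id}: only {x.size} non-missing probes "
            f"(need >= {min_probes}) for the noise metric"
        )
    return float(x.std(ddof=0))


def noise_filter(metrics: pd.Series, threshold: float = DEFAULT_NOISE_THRESHOLD) -> pd.Index:
    """Sample ids whose noise metric is <= threshold."""
    if threshold <= 0:
        raise ValueError("noise threshold must be > 0")
    return metrics.index[metrics <= threshold]


def drop_replicates(sample_ids) -> pd.Index:
    """Keep the first occurrence of each declared sample id."""
    idx = pd.Index(sample_ids)
    return idx[~idx.duplicated(keep="first")]


def pca_ancestry_scores(dosages: pd.DataFrame, n_components: int = DEFAULT_N_PCS) -> pd.DataFrame:
    """Ancestry-informative principal components from SNP dosages.

    Dosages are per-sample counts of the effect allele in [0, 2]
    (samples x SNPs).  Monomorphic SNPs (allele frequency 0 or 1) are dropped;
    each remaining SNP is centred at 2p and scaled by sqrt(2p(1-p)), the
    variance of a binomial(2, p) genotype, before the eigendecomposition.
    """
    X = dosages.to_numpy(dtype=float)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    X = X[:, poly]
    p = p[poly]
    if X.shape[1] < n_components:
        raise ValueError(
            f"{X.shape[1]} polymorphic SNPs < {n_components} requested components"
        )
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z -= Z.mean(axis=0)  # sample-centred so scores are exactly zero-mean
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=dosages.index, columns=cols)


def pc_outlier_filter(
    scores: pd.DataFrame,
    sd_threshold: float = DEFAULT_PC_SD,
    n_components: int = DEFAULT_N_PCS,
    iterative: bool = False,
) -> pd.Index:
    """Samples whose first PCs all lie within ``sd_threshold`` SDs of the mean.

    Strictly-greater deviations are removed; a sample exactly at the threshold
    is retained.  The default is a single pass with all-sample mean/SD;
    ``iterative=True`` recomputes mean/SD after each removal round until no
    further sample is excluded.
    """
    use = scores.iloc[:, :n_components]
    keep = pd.Series(True, index=scores.index)
    while True:
        sub = use[keep]
        z = (sub - sub.mean()).abs() / sub.std(ddof=0)
        out = (z > sd_threshold).any(axis=1)
        if not out.any():
            break
        keep[out.index[out]] = False
        if not iterative:
            break
    return scores.index[keep]


def sample_qc(
    intensities: pd.DataFrame,
    dosages: pd.DataFrame | None = None,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    pc_sd: float = DEFAULT_PC_SD,
    n_components: int = DEFAULT_N_PCS,
    noise_columns=None,
) -> pd.DataFrame:
    """Full sample QC report: one row per input sample.

    Columns: ``noise`` (metric), ``PC1..PCn`` (NaN when no genotypes given),
    boolean flags ``replicate``, ``noise_fail``, ``pc_outlier`` and
    ``retained`` (true iff no flag set).  ``noise_columns`` restricts the
    noise metric to a probe subset (e.g. probes outside catalogued CNVRs, so
    genuinely variable regions do not inflate the metric on sparse arrays).
    """
    idx = pd.Index(intensities.index, name="sample_id")
    report = pd.DataFrame(index=idx)
    report["replicate"] = idx.duplicated(keep="first")

    noise_mat = intensities if noise_columns is None else intensities[list(noise_columns)]
    noise = pd.Series(
        [intensity_noise_metric(row, sample_id=str(s)) for s, row in noise_mat.iterrows()],
        index=idx,
    )
    report["noise"] = noise
    report["noise_fail"] = noise > noise_threshold

    report["pc_outlier"] = False
    if dosages is not None:
        shared = report.index[~report.index.duplicated()].intersection(dosages.index)
        scores = pca_ancestry_scores(dosages.loc[shared], n_components=n_components)
        for c in scores.columns:
            report[c] = scores[c].reindex(report.index)
        kept = pc_outlier_filter(scores, sd_threshold=pc_sd, n_components=n_components)
        report.loc[shared.difference(kept), "pc_outlier"] = True

    report["retained"] = ~(report["replicate"] | report["noise_fail"] | report["pc_outlier"])
    return report
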