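"""Meta-analysis, significance thresholds, tag-SNP LD and replication.

Cohort-level CNVR association results are combined by fixed-effect
inverse-variance weighting (IVW) when all studies share a trait scale, and by
sample-size-weighted Stouffer Z-score meta-analysis when they do not (for
this pipeline: FVC replication, where one study analysed untransformed FVC).
Replication of suggestive signals goes through tag SNPs — SNPs within 1 Mb of
a CNVR whose dosage correlates with the copy-number genotype at r^2 > 0.7 —
looked up in external GWAS summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CNVRegion

__all__ = [
    "MetaResult",
    "TagSNPResult",
    "ivw_meta",
    "stouffer_meta",
    "bonferroni_threshold",
    "select_suggestive",
    "tag_r2",
    "replicate",
]

TAG_WINDOW = 1_000_000
TAG_R2_THRESHOLD = 0.7
SUGGESTIVE_P = 1e-3


@dataclass
class MetaResult:
    method: str                     # 'IVW' or 'Z'
    beta: Optional[float]           # IVW only
    se: Optional[float]             # IVW only
    z: float
    pvalue: float
    direction: str                  # one char per contributing study
    n_studies: int

    def summary(self) -> str:
        if self.method == "IVW":
            return (
                f"IVW meta ({self.n_studies} studies): beta={self.beta:.6g} "
                f"SE={self.se:.6g} Z={self.z:.4f} P={self.pvalue:.4g} [{self.direction}]"
            )
        return (
            f"Z-score meta ({self.n_studies} studies): Z={self.z:.4f} "
            f"P={self.pvalue:.4g} [{self.direction}]"
        )


@dataclass
class TagSNPResult:
    region_id: str
    snp: Optional[str]
    r2: Optional[float]
    align_sign: Optional[int]  # +1: SNP effect allele tracks increased copy number
    tagged: bool
    reason: str = ""


def ivw_meta(studies: Sequence[tuple]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    ``studies`` is a sequence of (beta, se) pairs; studies with SE <= 0 or
    non-finite inputs are rejected.  Combined beta = sum(b/se^2)/sum(1/se^2),
    SE = 1/sqrt(sum(1/se^2)), two-sided P from the normal Z = beta/SE.
    """
    use = []
    for b, se in studies:
        if not (np.isfinite(b) and np.isfinite(se)) or se <= 0:
            raise ValueError(f"study with invalid (beta, SE) = ({b}, {se}) rejected")
        use.append((float(b), float(se)))
    if not use:
        raise ValueError("no usable studies")
    b = np.array([u[0] for u in use])
    w = np.array([1.0 / u[1] ** 2 for u in use])
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    direction = "".join("+" if x >= 0 else "-" for x in b)
    return MetaResult("IVW", beta, se, float(z), p, direction, len(use))


def stouffer_meta(studies: Sequence[tuple]) -> MetaResult:
    """Sample-size-weighted Stouffer Z-score meta-analysis.

    ``studies`` is a sequence of (pvalue, sign, n) with two-sided P in (0,1),
    sign '+'/'-' (or +-1), and study sample size n.  Each study contributes a
    signed z_i = sign * Phi^-1(1 - P/2) with weight w_i = sqrt(n_i);
    Z = sum(w_i z_i) / sqrt(sum(w_i^2)).
    """
    zs, ws, signs = [], [], []
    for p, sign, n in studies:
        if not (0.0 < p < 1.0):
            raise ValueError(f"study P={p} outside (0,1) rejected")
        if n < 1:
            raise ValueError(f"study N={n} < 1 rejected")
        s = {"+": 1, "-": -1, 1: 1, -1: -1}.get(sign)
        if s is None:
            raise ValueError(f"invalid sign {sign!r}")
        zs.append(s * stats.norm.isf(p / 2.0))
        ws.append(np.sqrt(n))
        signs.append("+" if s > 0 else "-")
    if not zs:
        raise ValueError("no usable studies")
    zs, ws = np.array(zs), np.array(ws)
    z = float((ws * zs).sum() / np.sqrt((ws**2).sum()))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult("Z", None, None, z, p, "".join(signs), len(zs))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha / m for m independent tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def select_suggestive(table: pd.DataFrame, p_col: str = "pvalue",
                      threshold: float = SUGGESTIVE_P) -> pd.DataFrame:
    """Rows with P strictly below the suggestive threshold."""
    if p_col not in table.columns:
        raise ValueError(f"column {p_col!r} not in table")
    return table[table[p_col] < threshold].copy()


def tag_r2(
    dose: pd.Series,
    snp_positions: pd.DataFrame,
    snp_dosages: pd.DataFrame,
    region: CNVRegion,
    window: int = TAG_WINDOW,
    r2_threshold: float = TAG_R2_THRESHOLD,
) -> TagSNPResult:
    """Best tag SNP for a CNVR: highest squared Pearson correlation.

    Parameters
    ----------
    dose : per-sample copy-number dose (or MAP class), sample-id index
    snp_positions : DataFrame indexed by SNP id with columns chrom, pos
    snp_dosages : samples x SNPs effect-allele dosage table
    region : the CNVR; candidate SNPs lie within ``window`` bp of its
        start/end on the same chromosome.

    The alignment sign records whether the SNP effect allele is positively
    (+1) or negatively (-1) correlated with increasing copy number.  Ties on
    r^2 go to the lowest genomic position.  ``tagged`` requires r^2 strictly
    greater than ``r2_threshold``.
    """
    chrom = str(region.chrom)
    pos = snp_positions["pos"]
    cand = snp_positions[
        (snp_positions["chrom"].astype(str) == chrom)
        & (pos >= region.start - window)
        & (pos <= region.end + window)
    ]
    cand = cand[cand.index.isin(snp_dosages.columns)]
    if cand.empty:
        return TagSNPResult(region.region_id, None, None, None, False, "no tag available")
    shared = dose.index.intersection(snp_dosages.index)
    d = dose.loc[shared].to_numpy(dtype=float)
    best = None  # (r2, pos, snp, sign)
    for snp, row in cand.iterrows():
        g = snp_dosages.loc[shared, snp].to_numpy(dtype=float)
        ok = np.isfinite(d) & np.isfinite(g)
        if ok.sum() < 2 or np.var(g[ok]) == 0 or np.var(d[ok]) == 0:
            continue
        r = np.corrcoef(d[ok], g[ok])[0, 1]
        key = (r * r, -row["pos"])
        if best is None or key > (best[0], -best[1]):
            best = (r * r, row["pos"], snp, 1 if r >= 0 else -1)
    if best is None:
        return TagSNPResult(region.region_id, None, None, None, False, "no variable SNP")
    r2, _, snp, sign = best
    return TagSNPResult(region.region_id, snp, float(r2), sign, bool(r2 > r2_threshold))


def _aligned_study_effect(entry: pd.Series, tag: TagSNPResult,
                          tag_effect_allele: Optional[str]) -> tuple:
    """Sign-align one study's (beta, se, p, n) to the copy-increasing allele."""
    beta = float(entry["beta"])
    flip = 1
    if tag_effect_allele is not None and "effect_allele" in entry.index:
        if str(entry["effect_allele"]) != str(tag_effect_allele):
            flip = -1  # study reported the other allele
    beta *= flip * tag.align_sign
    return beta, float(entry["se"]), float(entry["pvalue"]), int(entry["n"])


def replicate(
    suggestive: pd.DataFrame,
    tags: dict,
    studies: dict,
    trait_methods: dict,
    alpha: float = 0.05,
    tag_effect_alleles: Optional[dict] = None,
) -> pd.DataFrame:
    """Tag-SNP replication of suggestive CNVR-trait associations.

    Parameters
    ----------
    suggestive : DataFrame with columns region_id, trait (one row per
        CNVR-trait combination that passed the suggestive screen and has a
        tag SNP).
    tags : {region_id: TagSNPResult}
    studies : {study_name: DataFrame indexed by SNP with columns beta, se,
        pvalue, n and optionally effect_allele}; study order fixes the
        direction-string order.
    trait_methods : {trait: 'IVW' | 'Z'}
    alpha : familywise level; the per-test threshold is alpha divided by the
        number of tagged CNVR-trait tests.
    tag_effect_alleles : optional {region_id: allele} — the allele the tag
        r^2 computation counted, for cross-study sign alignment.

    Study effects are sign-aligned to the allele positively correlated with
    increased copy number before meta-analysis.  A study without the SNP is
    dropped and shows as '.' in the direction string.
    """
    m = len(suggestive)
    threshold = bonferroni_threshold(alpha, max(m, 1))
    study_names = list(studies)
    rows = []
    for _, srow in suggestive.iterrows():
        region_id, trait = srow["region_id"], srow["trait"]
        tag = tags.get(region_id)
        if tag is None or not tag.tagged:
            continue
        ea = (tag_effect_alleles or {}).get(region_id)
        aligned, direction = [], []
        for name in study_names:
            tab = studies[name]
            if tag.snp not in tab.index:
                direction.append(".")
                continue
            b, se, p, n = _aligned_study_effect(tab.loc[tag.snp], tag, ea)
            aligned.append((b, se, p, n))
            direction.append("+" if b >= 0 else "-")
        if not aligned:
            continue
        method = trait_methods.get(trait, "IVW")
        if method == "IVW":
            res = ivw_meta([(b, se) for b, se, _, _ in aligned])
        else:
            res = stouffer_meta([(p, "+" if b >= 0 else "-", n) for b, _, p, n in aligned])
        rows.append(
            {
                "region_id": region_id,
                "trait": trait,
                "snp": tag.snp,
                "r2": tag.r2,
                "method": method,
                "beta": res.beta,
                "se": res.se,
                "z": res.z,
                "pvalue": res.pvalue,
                "direction": "".join(direction),
                "threshold": threshold,
                "replicated": res.pvalue < threshold,
            }
        )
    return pd.DataFrame(rows)
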