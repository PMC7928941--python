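"""Allelic-imbalance testing on haplotype-resolved read counts.

At a heterozygous site, reads carrying each haplotype should split ~50/50
under the null of no allele-specific chromatin state. The exact two-sided
binomial test (minimum-likelihood two-sided definition, as in
``scipy.stats.binomtest``) compares the observed haplotype-1 proportion
with the expected 0.5; counts can be pooled over variants in LD, over
timepoints, and across donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

COUNT_COLUMNS = ["VARIANT", "DONOR", "ASSAY", "TIMEPOINT", "HAP1", "HAP2"]


@dataclass
class ImbalanceResult:
    """Haplotype-1 over haplotype-2 fold with its binomial p-value."""

    fold: float               # hap1/hap2 on pooled counts; inf if hap2 == 0
    p: float
    n_reads: int
    n_variants: int = 1
    fold_infinite: bool = False


def binomial_imbalance(k1: int, k2: int, p0: float = 0.5,
                       two_sided: str = "minlike") -> ImbalanceResult:
    """Exact binomial test of k1 hap-1 reads out of k1+k2 against p0.

    ``two_sided`` selects the two-sided definition: "minlike" sums the
    probabilities of all outcomes no more likely than the observed one
    (the default of the exact binomial test); "double" doubles the smaller
    one-sided tail (capped at 1).
    """
    k1, k2 = int(k1), int(k2)
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    n = k1 + k2
    if n == 0:
        raise ValueError("k1 + k2 must be >= 1")
    if two_sided == "minlike":
        p = sps.binomtest(k1, n, p0).pvalue
    elif two_sided == "double":
        lower = sps.binom.cdf(k1, n, p0)
        upper = sps.binom.sf(k1 - 1, n, p0)
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown two-sided method {two_sided!r}")
    fold = k1 / k2 if k2 > 0 else inf
    return ImbalanceResult(fold, float(p), n, 1, k2 == 0)


def pool_region(table: pd.DataFrame, variants=None, donor=None, assay=None,
                timepoints=None, p0: float = 0.5) -> ImbalanceResult:
    """Sum haplotype counts over the selected rows, then test the pool.

    Any of ``variants`` (iterable of ids), ``donor``, ``assay`` and
    ``timepoints`` restricts the selection; omitted filters keep all rows.
    Pooling matches how replicate reads over an LD region are combined
    before a single imbalance test.
    """
    sel = pd.Series(True, index=table.index)
    if variants is not None:
        sel &= table["VARIANT"].isin(list(variants))
    if donor is not None:
        sel &= table["DONOR"] == donor
    if assay is not None:
        sel &= table["ASSAY"] == assay
    if timepoints is not None:
        sel &= table["TIMEPOINT"].isin(list(timepoints))
    sub = table[sel]
    if sub.empty:
        raise ValueError("empty selection")
    k1 = int(sub["HAP1"].sum())
    k2 = int(sub["HAP2"].sum())
    res = binomial_imbalance(k1, k2, p0)
    res.n_variants = sub["VARIANT"].nunique()
    return res


def combine_donors(per_donor: dict[str, tuple[int, int]],
                   method: str = "pooled") -> ImbalanceResult:
    """Combine per-donor (hap1, hap2) counts into one imbalance call.

    "pooled" sums counts across donors and tests the pool; "stouffer"
    combines per-donor signed z-scores (sign from the fold direction,
    magnitude from the two-sided p) weighted by sqrt(reads). The fold is
    the pooled ratio in both modes.
    """
    if len(per_donor) < 2:
        raise ValueError("need >= 2 donors to combine")
    k1 = sum(k for k, _ in per_donor.values())
    k2 = sum(k for _, k in per_donor.values())
    pooled = binomial_imbalance(k1, k2)
    pooled.n_variants = len(per_donor)
    if method == "pooled":
        return pooled
    if method != "stouffer":
        raise ValueError(f"unknown method {method!r}")
    zs, ws = [], []
    for d1, d2 in per_donor.values():
        r = binomial_imbalance(d1, d2)
        z = sps.norm.isf(min(r.p, 1 - 1e-16) / 2)
        sign = 1.0 if d1 >= d2 else -1.0
        zs.append(sign * z)
        ws.append(sqrt(d1 + d2))
    z_comb = float(np.dot(ws, zs) / np.linalg.norm(ws))
    p_comb = float(2 * sps.norm.sf(abs(z_comb)))
    return ImbalanceResult(pooled.fold, min(p_comb, 1.0), pooled.n_reads,
                           len(per_donor), pooled.fold_infinite)


def imbalance_table(table: pd.DataFrame, group_by=("DONOR", "ASSAY"),
                    p0: float = 0.5) -> pd.DataFrame:
    """Per-group pooled imbalance: FOLD P N_READS N_VARIANTS columns."""
    rows = []
    for key, sub in table.groupby(list(group_by)):
        res = binomial_imbalance(int(sub["HAP1"].sum()),
                                 int(sub["HAP2"].sum()), p0)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(dict(zip(group_by, key),
                         FOLD=res.fold, P=res.p, N_READS=res.n_reads,
                         N_VARIANTS=sub["VARIANT"].nunique()))
    return pd.DataFrame(rows)
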