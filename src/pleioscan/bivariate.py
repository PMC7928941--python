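"""Bivariate GWAS summary-statistic combination and pleiotropy filtering.

Two GWAS scans over (partly) shared samples yield per-SNP z-scores whose
null correlation reflects the sample overlap. Three cross-phenotype
statistics are provided:

* ``shom`` — omnibus test assuming homogeneous effects: a weighted z-sum
  referenced to chi-square with 1 df, the highest-power test when effects
  agree across traits.
* ``shet`` — heterogeneity-tolerant truncated statistic: ``shom`` restricted
  to the traits whose |z| clears a threshold, maximized over a threshold
  grid; its genome-wide null is summarized by a maximum-likelihood gamma fit
  from which per-SNP p-values are read.
* ``dlc`` — parametric linear combination z' R^-1 z referenced to chi-square
  with 2 df.

Pleiotropic SNP selection applies three criteria: bivariate P <= 5e-6,
bivariate/univariate p ratio < 0.05, and univariate P <= 0.05 for both
phenotypes; passing SNPs are clumped into loci around lead SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

SUMMARY_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "MAF"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _is_ambiguous(a1: str, a2: str) -> bool:
    return a2 == a1.translate(_COMPLEMENT)


@dataclass
class PairedSummaryStats:
    """Allele-harmonized per-SNP records from two GWAS.

    ``table`` has one row per shared SNP with signed z-scores on a common
    effect allele; ``R`` is the 2x2 trait correlation matrix; ``n_dropped``
    counts SNPs lost to strand ambiguity or irreconcilable alleles.
    """

    table: pd.DataFrame          # SNP CHR BP A1 A2 Z_A Z_B N_A N_B P_A P_B
    R: np.ndarray
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0


def harmonize(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> PairedSummaryStats:
    """Intersect two summary tables by SNP id and align effect alleles.

    If study B reports the same alleles swapped (or strand-complemented and
    swapped), its z-score sign is flipped; strand-ambiguous (A/T, C/G) SNPs
    are dropped, as are SNPs whose allele sets cannot be reconciled. The
    trait correlation matrix starts at identity — estimate it afterwards
    with :func:`estimate_null_correlation`.
    """
    if stats_a.empty or stats_b.empty:
        raise ValueError("both summary tables must be non-empty")
    a = stats_a.set_index("SNP")
    b = stats_b.set_index("SNP")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no SNPs shared between the two studies")

    a = a.loc[shared]
    b = b.loc[shared]
    a1a = a["A1"].str.upper().to_numpy()
    a2a = a["A2"].str.upper().to_numpy()
    a1b = b["A1"].str.upper().to_numpy()
    a2b = b["A2"].str.upper().to_numpy()

    ambiguous = np.array([_is_ambiguous(x, y) for x, y in zip(a1a, a2a)])
    same = (a1b == a1a) & (a2b == a2a)
    swapped = (a1b == a2a) & (a2b == a1a)
    comp1a = np.array([x.translate(_COMPLEMENT) for x in a1a])
    comp2a = np.array([x.translate(_COMPLEMENT) for x in a2a])
    comp_same = (a1b == comp1a) & (a2b == comp2a)
    comp_swapped = (a1b == comp2a) & (a2b == comp1a)

    keep = ~ambiguous & (same | swapped | comp_same | comp_swapped)
    flip = (swapped | comp_swapped) & keep
    n_ambig = int(ambiguous.sum())
    n_mismatch = int((~keep & ~ambiguous).sum())

    z_a = (a["BETA"] / a["SE"]).to_numpy()
    z_b = (b["BETA"] / b["SE"]).to_numpy()
    z_b = np.where(flip, -z_b, z_b)

    table = pd.DataFrame({
        "SNP": shared,
        "CHR": a["CHR"].to_numpy(),
        "BP": a["BP"].to_numpy(),
        "A1": a1a,
        "A2": a2a,
        "Z_A": z_a,
        "Z_B": z_b,
        "N_A": a["N"].to_numpy(),
        "N_B": b["N"].to_numpy(),
        "P_A": a["P"].to_numpy(),
        "P_B": b["P"].to_numpy(),
    })[keep].reset_index(drop=True)
    if table.empty:
        raise ValueError("no harmonizable SNPs remain")
    return PairedSummaryStats(table, np.eye(2), n_ambig, n_mismatch)


def _box_truncated_corr(rho: float, c: float, n_nodes: int = 64) -> float:
    """Corr(X, Y) of a standard bivariate normal truncated to the box
    |X| < c, |Y| < c, by Gauss-Legendre quadrature."""
    x, wx = np.polynomial.legendre.leggauss(n_nodes)
    x = x * c
    wx = wx * c
    xx, yy = np.meshgrid(x, x)
    ww = np.outer(wx, wx)
    det = 1.0 - rho * rho
    dens = np.exp(-(xx ** 2 - 2 * rho * xx * yy + yy ** 2) / (2 * det))
    dens /= 2 * np.pi * np.sqrt(det)
    mass = float((ww * dens).sum())
    exy = float((ww * dens * xx * yy).sum()) / mass
    exx = float((ww * dens * xx * xx).sum()) / mass
    return exy / exx  # E[Y^2] = E[X^2] by symmetry


def estimate_null_correlation(paired: PairedSummaryStats,
                              z_cut: float = 1.96,
                              truncation_correction: bool = True,
                              ) -> np.ndarray:
    """Trait correlation from SNPs null in both scans (|z| < z_cut).

    The Pearson correlation of (z_a, z_b) over null SNPs estimates the
    sample-overlap-induced correlation. Restricting to the |z| < z_cut box
    attenuates correlation (e.g. a true 0.3 appears as ~0.24 at z_cut
    1.96), so by default the estimate inverts the bivariate-normal
    box-truncation map to recover the untruncated value. The result is
    clamped to (-0.999, 0.999) and written back onto ``paired.R``.
    """
    from scipy.optimize import brentq

    t = paired.table
    mask = (t["Z_A"].abs() < z_cut) & (t["Z_B"].abs() < z_cut)
    if mask.sum() < 100:
        raise ValueError(f"only {int(mask.sum())} null SNPs; need >= 100")
    r_obs = float(np.corrcoef(t.loc[mask, "Z_A"], t.loc[mask, "Z_B"])[0, 1])
    if truncation_correction and abs(r_obs) < _box_truncated_corr(0.999, z_cut):
        r = float(brentq(lambda q: _box_truncated_corr(q, z_cut) - r_obs,
                         -0.999, 0.999, xtol=1e-6))
    else:
        r = r_obs
    r = float(np.clip(r, -0.999, 0.999))
    R = np.array([[1.0, r], [r, 1.0]])
    paired.R = R
    return R


def shom(z: np.ndarray, R: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Homogeneous-effect omnibus statistic (w'z)^2 / (w'Rw), chi2 1 df."""
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    denom = float(w @ R @ w)
    if denom <= 0:
        raise ValueError("w'Rw must be positive (R not positive definite?)")
    s = float(w @ z) ** 2 / denom
    return s, float(sps.chi2.sf(s, df=1))


DEFAULT_SHET_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def shet(z: np.ndarray, R: np.ndarray, w: np.ndarray,
         threshold_grid=DEFAULT_SHET_GRID) -> float:
    """Truncated omnibus statistic maximized over a |z| threshold grid.

    For each threshold t only the traits with |z| >= t enter ``shom`` (with
    R and w subset accordingly); an empty surviving set scores 0. The
    returned statistic has no parametric null — fit one genome-wide with
    :func:`fit_gamma_null`.
    """
    grid = list(threshold_grid)
    if not grid:
        raise ValueError("threshold_grid must be non-empty")
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    best = 0.0
    for t in grid:
        idx = np.flatnonzero(np.abs(z) >= t)
        if idx.size == 0:
            continue
        s, _ = shom(z[idx], R[np.ix_(idx, idx)], w[idx])
        best = max(best, s)
    return best


def shet_vector(z_a: np.ndarray, z_b: np.ndarray, R: np.ndarray,
                w: np.ndarray, threshold_grid=DEFAULT_SHET_GRID) -> np.ndarray:
    """Vectorized two-trait ``shet`` over SNP arrays (same definition)."""
    z_a = np.asarray(z_a, float)
    z_b = np.asarray(z_b, float)
    w = np.asarray(w, float)
    denom_full = float(w @ R @ w)
    if denom_full <= 0:
        raise ValueError("w'Rw must be positive")
    s_full = (w[0] * z_a + w[1] * z_b) ** 2 / denom_full
    s_a = z_a ** 2           # single-trait shom reduces to z^2
    s_b = z_b ** 2
    best = np.zeros_like(z_a)
    for t in threshold_grid:
        surv_a = np.abs(z_a) >= t
        surv_b = np.abs(z_b) >= t
        s_t = np.where(surv_a & surv_b, s_full,
                       np.where(surv_a, s_a, np.where(surv_b, s_b, 0.0)))
        best = np.maximum(best, s_t)
    return best


def fit_gamma_null(shet_values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Genome-wide maximum-likelihood gamma fit of SHet; upper-tail p-values.

    Zeros are replaced by half the smallest positive observed value before
    the MLE (the gamma support excludes 0). Returns (shape, scale, p).
    """
    v = np.asarray(shet_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1000:
        raise ValueError("need >= 1000 finite SHet values for the null fit")
    if np.allclose(v, v[0]):
        raise ValueError("degenerate (constant) SHet values")
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("all SHet values are zero")
    fit_v = np.where(v > 0, v, pos.min() / 2.0)
    shape, _, scale = sps.gamma.fit(fit_v, floc=0.0)
    p = sps.gamma.sf(np.asarray(shet_values, float), shape, scale=scale)
    return float(shape), float(scale), np.clip(p, np.finfo(float).tiny, 1.0)


def dlc(z: np.ndarray, R: np.ndarray) -> tuple[float, float]:
    """Linear-combination statistic z' R^-1 z against chi-square, 2 df."""
    z = np.asarray(z, dtype=float)
    if np.linalg.cond(R) > 1e6:
        raise ValueError("R near-singular (condition number > 1e6)")
    s = float(z @ np.linalg.solve(R, z))
    return s, float(sps.chi2.sf(s, df=len(z)))


@dataclass
class PleiotropicCall:
    """Outcome of the three-criterion pleiotropy filter for one SNP."""

    snp_id: str
    passes: bool
    criterion_flags: tuple[bool, bool, bool]
    locus_id: int | None = None
    lead: bool = False


def select_pleiotropic(p_bivar: float, p_uni_a: float, p_uni_b: float,
                       snp_id: str = "", *, bivar_threshold: float = 5e-6,
                       ratio_threshold: float = 0.05,
                       uni_threshold: float = 0.05,
                       ratio_any: bool = True) -> PleiotropicCall:
    """Apply the three pleiotropic-SNP selection criteria.

    1. bivariate P <= 5e-6 (suggestive genome-wide significance);
    2. bivariate p / univariate p < 0.05 — satisfied against at least one
       univariate p by default (several published lead SNPs fail the
       stricter both-traits reading, e.g. a bivariate 1.83e-7 against a
       glycemic 2.26e-6 gives ratio 0.08); ``ratio_any=False`` demands it
       for both;
    3. univariate P <= 0.05 for both phenotypes.
    """
    for p in (p_bivar, p_uni_a, p_uni_b):
        if not 0 < p <= 1:
            raise ValueError("p-values must lie in (0, 1]")
    c1 = p_bivar <= bivar_threshold
    ratios_ok = (p_bivar / p_uni_a < ratio_threshold,
                 p_bivar / p_uni_b < ratio_threshold)
    c2 = any(ratios_ok) if ratio_any else all(ratios_ok)
    c3 = p_uni_a <= uni_threshold and p_uni_b <= uni_threshold
    return PleiotropicCall(snp_id, c1 and c2 and c3, (c1, c2, c3))


def clump_loci(calls: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy clumping of passing SNPs into loci around lead SNPs.

    Repeatedly takes the unassigned passing SNP with the smallest bivariate
    p (ties broken by (CHR, BP)) as lead and assigns all passing SNPs within
    +/- window_bp on the same chromosome to its locus. Expects columns
    SNP CHR BP P_BIVAR PASS; adds LOCUS (int, -1 for non-passing) and LEAD.
    """
    out = calls.copy()
    out["LOCUS"] = -1
    out["LEAD"] = False
    passing = out.index[out["PASS"]].to_numpy()
    order = out.loc[passing].sort_values(
        ["P_BIVAR", "CHR", "BP"], kind="mergesort").index.to_numpy()
    assigned = set()
    locus = 0
    for lead_idx in order:
        if lead_idx in assigned:
            continue
        chrom = out.at[lead_idx, "CHR"]
        pos = out.at[lead_idx, "BP"]
        members = [i for i in passing
                   if i not in assigned and out.at[i, "CHR"] == chrom
                   and abs(out.at[i, "BP"] - pos) <= window_bp]
        for i in members:
            out.at[i, "LOCUS"] = locus
            assigned.add(i)
        out.at[lead_idx, "LEAD"] = True
        locus += 1
    return out


def bivariate_scan(paired: PairedSummaryStats, method: str = "shom",
                   w: np.ndarray | None = None,
                   threshold_grid=DEFAULT_SHET_GRID,
                   clump_window_bp: int = 1_000_000) -> pd.DataFrame:
    """Full per-SNP scan: statistics, p-values, pleiotropy filter, clumping.

    Weights default to sqrt(N) per trait. ``method`` picks which bivariate
    p-value feeds the pleiotropy filter ("shom", "shet" or "dlc"); all three
    statistics are reported.
    """
    t = paired.table
    R = paired.R
    z_a = t["Z_A"].to_numpy()
    z_b = t["Z_B"].to_numpy()
    if w is None:
        w = np.sqrt([float(t["N_A"].median()), float(t["N_B"].median())])
    w = np.asarray(w, float)

    denom = float(w @ R @ w)
    s_hom = (w[0] * z_a + w[1] * z_b) ** 2 / denom
    p_hom = sps.chi2.sf(s_hom, df=1)

    s_het = shet_vector(z_a, z_b, R, w, threshold_grid)
    shape, scale, p_het = fit_gamma_null(s_het)

    Rinv = np.linalg.inv(R)
    s_dlc = (Rinv[0, 0] * z_a ** 2 + 2 * Rinv[0, 1] * z_a * z_b
             + Rinv[1, 1] * z_b ** 2)
    p_dlc = sps.chi2.sf(s_dlc, df=2)

    p_bivar = {"shom": p_hom, "shet": p_het, "dlc": p_dlc}[method]
    out = t[["SNP", "CHR", "BP"]].copy()
    out["S_HOM"], out["P_HOM"] = s_hom, p_hom
    out["S_HET"], out["P_HET"] = s_het, p_het
    out["S_DLC"], out["P_DLC"] = s_dlc, p_dlc
    out["P_BIVAR"] = p_bivar
    out["GAMMA_SHAPE"], out["GAMMA_SCALE"] = shape, scale
    flags = [select_pleiotropic(pb, pa, pvb).passes
             for pb, pa, pvb in zip(np.clip(p_bivar, np.finfo(float).tiny, 1),
                                    t["P_A"], t["P_B"])]
    out["PASS"] = flags
    return clump_loci(out, clump_window_bp)
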