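"""Additive linear-model association engine and SNP quality control.

The workhorse is ordinary least squares of a quantitative trait on
(intercept, minor-allele dosage, age, sex), with the two-sided P value of
the dosage slope from the t distribution on n - 4 degrees of freedom —
the standard age- and sex-adjusted additive genetic model.  Missing
genotypes and missing trait values are handled by complete-case analysis
per (SNP, trait) pair, so n varies across results.

``scan`` evaluates every (SNP, trait) pair.  For speed it accumulates the
normal equations once per SNP on all subjects and subtracts the
contribution of each trait's missing rows, which is algebraically exact
and independent of any chunking of the work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import GenotypeSet

__all__ = [
    "AssociationResult",
    "snp_qc",
    "hwe_chisq_p",
    "fit_additive_model",
    "scan",
    "scan_matrix",
    "spearman_assoc_test",
]

#: Smallest positive normal double: P values are clamped here rather than
#: underflowing to zero (ratio scans can reach the 1e-94 scale).
P_FLOOR = float(np.finfo(float).tiny)

_N_PARAMS = 4  # intercept, dosage, age, sex


@dataclass
class AssociationResult:
    """One SNP x trait test."""

    snp: str
    trait: str
    n: int
    beta: float
    se: float
    stat: float
    p: float
    testable: bool = True


# --------------------------------------------------------------------------
# SNP quality control
# --------------------------------------------------------------------------

def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """Hardy-Weinberg equilibrium P by a 1-df chi-square goodness of fit.

    ``n0/n1/n2`` count genotypes with 0/1/2 copies of the minor allele.
    """
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    q = (2 * n2 + n1) / (2 * n)  # minor-allele frequency
    p = 1.0 - q
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n0, n1, n2], dtype=float)
    nz = exp > 0
    chi2 = float(((obs[nz] - exp[nz]) ** 2 / exp[nz]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    genotypes: GenotypeSet,
    call_rate_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
) -> tuple[pd.DataFrame, GenotypeSet]:
    """Filter SNPs on call rate, MAF and Hardy-Weinberg equilibrium.

    Each criterion is a strict inequality (call rate > min, MAF > min,
    HWE P > min); a monomorphic SNP fails the MAF criterion.  Returns the
    per-SNP report and the filtered GenotypeSet.
    """
    for thr in (call_rate_min, maf_min, hwe_p_min):
        if not (0.0 <= thr <= 1.0):
            raise ValueError("QC thresholds must lie in [0, 1]")
    d = genotypes.dosage
    n_subj = d.shape[0]
    rows = []
    for j, snp_id in enumerate(genotypes.snps["id"]):
        col = d[:, j]
        obs = col[np.isfinite(col)]
        call_rate = obs.size / n_subj if n_subj else 0.0
        maf = float(obs.mean() / 2.0) if obs.size else 0.0
        maf = min(maf, 1.0 - maf)
        n2 = int((obs == 2).sum())
        n1 = int((obs == 1).sum())
        n0 = int((obs == 0).sum())
        hwe_p = hwe_chisq_p(n0, n1, n2)
        reasons = []
        if not call_rate > call_rate_min:
            reasons.append("call_rate")
        if not maf > maf_min:
            reasons.append("maf")
        if not hwe_p > hwe_p_min:
            reasons.append("hwe")
        rows.append(dict(id=snp_id, call_rate=call_rate, maf=maf, hwe_p=hwe_p,
                         passed=not reasons, fail_reason=";".join(reasons)))
    report = pd.DataFrame(rows, columns=["id", "call_rate", "maf", "hwe_p",
                                         "passed", "fail_reason"])
    return report, genotypes.subset(report["passed"].to_numpy())


# --------------------------------------------------------------------------
# single-model fit
# --------------------------------------------------------------------------

def _p_from_t(tstat: np.ndarray, df: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return np.clip(p, P_FLOOR, 1.0)


def fit_additive_model(
    trait: np.ndarray,
    dosage: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    snp: str = "snp",
    trait_id: str = "trait",
) -> AssociationResult:
    """OLS of trait on (1, dosage, age, sex); beta/SE/P for the dosage term.

    Complete-case restriction first; requires n > 4 and non-constant trait
    and dosage, otherwise a flagged not-testable result is returned.
    """
    trait = np.asarray(trait, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    keep = (np.isfinite(trait) & np.isfinite(dosage)
            & np.isfinite(age) & np.isfinite(sex))
    y = trait[keep]
    n = y.size
    bad = AssociationResult(snp=snp, trait=trait_id, n=n, beta=np.nan,
                            se=np.nan, stat=np.nan, p=np.nan, testable=False)
    if n <= _N_PARAMS:
        return bad
    d = dosage[keep]
    if np.ptp(d) == 0 or np.ptp(y) == 0:
        return bad
    X = np.column_stack([np.ones(n), d, age[keep], sex[keep]])
    G = X.T @ X
    Xy = X.T @ y
    try:
        beta = np.linalg.solve(G, Xy)
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return bad
    rss = max(float(y @ y - beta @ Xy), 0.0)
    df = n - _N_PARAMS
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * Ginv[1, 1]))
    if se > 0:
        tstat = float(beta[1] / se)
        p = float(_p_from_t(np.array(tstat), df))
    else:  # perfect fit: slope exact, P clamps at the smallest positive normal
        tstat = np.inf if beta[1] > 0 else (-np.inf if beta[1] < 0 else 0.0)
        p = P_FLOOR if beta[1] != 0 else 1.0
    return AssociationResult(snp=snp, trait=trait_id, n=n, beta=float(beta[1]),
                             se=se, stat=tstat, p=p)


# --------------------------------------------------------------------------
# vectorized scan
# --------------------------------------------------------------------------

def _scan_one_snp(X: np.ndarray, Y: np.ndarray):
    """All-trait OLS against one design matrix, complete-case per trait.

    X is (n, 4) with finite entries; Y is (n, T) with NaN for missing.
    Returns arrays (beta, se, stat, p, n_used, testable), each length T.
    """
    n, p = X.shape
    miss = ~np.isfinite(Y)
    Y0 = np.where(miss, 0.0, Y)
    T = Y.shape[1]

    G = X.T @ X                                   # (p, p) full-data
    outer = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    corr = miss.T.astype(float) @ outer           # (T, p*p) missing-row part
    Gt = G.reshape(1, p, p) - corr.reshape(T, p, p)
    Xy = (X.T @ Y0).T                             # (T, p)
    yy = np.einsum("nt,nt->t", Y0, Y0)
    n_used = n - miss.sum(axis=0)

    # variance screens on the complete-case subset, via the same corrections
    colsum = X.sum(axis=0) - miss.T.astype(float) @ X   # (T, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_d = Gt[:, 1, 1] - colsum[:, 1] ** 2 / np.maximum(n_used, 1)
        var_y = yy - Xy[:, 0] ** 2 / np.maximum(n_used, 1)
    # relative floors: cancellation error in the sums scales with the raw
    # second moments, so an absolute epsilon would misclassify constants
    testable = ((n_used > p)
                & (var_d > 1e-9 * np.maximum(Gt[:, 1, 1], 1.0))
                & (var_y > 1e-10 * np.maximum(yy, 1.0)))
    return _finish_batch(Gt, Xy, yy, n_used, testable)


def _finish_batch(Gt, Xy, yy, n_used, testable):
    """Solve the per-trait normal equations and derive beta/SE/t/P."""
    T, p = Xy.shape
    beta = np.full(T, np.nan)
    se = np.full(T, np.nan)
    stat = np.full(T, np.nan)
    pvals = np.full(T, np.nan)
    idx = np.flatnonzero(testable)
    if idx.size:
        Gs = Gt[idx]
        try:
            coef = np.linalg.solve(Gs, Xy[idx][:, :, None])[:, :, 0]
            Ginv = np.linalg.inv(Gs)
        except np.linalg.LinAlgError:
            coef = np.full((idx.size, p), np.nan)
            Ginv = np.full((idx.size, p, p), np.nan)
            for k, t in enumerate(idx):
                try:
                    coef[k] = np.linalg.solve(Gt[t], Xy[t])
                    Ginv[k] = np.linalg.inv(Gt[t])
                except np.linalg.LinAlgError:
                    pass
        rss = np.maximum(yy[idx] - np.einsum("tp,tp->t", coef, Xy[idx]), 0.0)
        df = n_used[idx] - p
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = rss / df
            se_i = np.sqrt(sigma2 * Ginv[:, 1, 1])
            t_i = coef[:, 1] / se_i
        p_i = np.where(
            se_i > 0,
            _p_from_t(np.where(np.isfinite(t_i), t_i, 0.0), df),
            np.where(coef[:, 1] != 0, P_FLOOR, 1.0),
        )
        t_i = np.where(se_i > 0, t_i,
                       np.where(coef[:, 1] > 0, np.inf,
                                np.where(coef[:, 1] < 0, -np.inf, 0.0)))
        ok = np.isfinite(coef[:, 1]) & np.isfinite(se_i)
        beta[idx] = np.where(ok, coef[:, 1], np.nan)
        se[idx] = np.where(ok, se_i, np.nan)
        stat[idx] = np.where(ok, t_i, np.nan)
        pvals[idx] = np.where(ok, p_i, np.nan)
        testable = testable.copy()
        testable[idx] &= ok
    return beta, se, stat, pvals, n_used, testable


def scan_matrix(
    traits: np.ndarray,
    trait_labels: list[str],
    genotypes: GenotypeSet,
    covariates: pd.DataFrame,
):
    """Scan every SNP against every trait column; array-valued output.

    Returns a dict of (n_traits, n_snps) arrays: beta, se, stat, p, n,
    testable.  Rows of ``covariates`` must align with genotype subjects
    (columns 'age' and 'sex').

    Subjects with missing covariates are excluded throughout (every model
    adjusts for age and sex).  For a SNP with complete dosages the
    per-trait normal equations are assembled from full-sample moments
    minus the (sparse) contribution of each trait's missing rows, which
    is exact and avoids re-reducing the whole matrix per SNP; SNPs with
    missing dosages take a general per-SNP path.
    """
    from scipy import sparse

    traits = np.atleast_2d(np.asarray(traits, dtype=float))
    if traits.shape[0] != genotypes.n_subjects:
        raise ValueError("trait matrix rows must match genotype subjects")
    age_all = covariates["age"].to_numpy(dtype=float)
    sex_all = covariates["sex"].to_numpy(dtype=float)
    cov_ok = np.isfinite(age_all) & np.isfinite(sex_all)
    T = traits.shape[1]
    M = genotypes.n_snps
    out = {k: np.full((T, M), np.nan) for k in ("beta", "se", "stat", "p")}
    out["n"] = np.zeros((T, M), dtype=int)
    out["testable"] = np.zeros((T, M), dtype=bool)

    Y = traits[cov_ok]
    age = age_all[cov_ok]
    sex = sex_all[cov_ok]
    n = Y.shape[0]
    miss = ~np.isfinite(Y)
    Y0 = np.where(miss, 0.0, Y)
    Mt = sparse.csr_matrix(miss.T)          # (T, n) missing indicators
    n_t = n - miss.sum(axis=0)
    yy = np.einsum("nt,nt->t", Y0, Y0)
    U = np.column_stack([np.ones(n), age, sex])
    SYu = U.T @ Y0                          # (3, T): exact complete-case sums
    uu_full = U.T @ U
    # X layout: [1, dosage, age, sex]; U column -> X index
    umap = (0, 2, 3)
    ucorr = {}
    for a in range(3):
        for b in range(a, 3):
            ucorr[(a, b)] = Mt @ (U[:, a] * U[:, b])

    for j in range(M):
        d_all = genotypes.dosage[:, j]
        d = d_all[cov_ok]
        finite_d = np.isfinite(d)
        if not finite_d.all():
            rows = cov_ok & np.isfinite(d_all)
            nr = int(rows.sum())
            if nr <= _N_PARAMS:
                continue
            X = np.column_stack([np.ones(nr), d_all[rows],
                                 age_all[rows], sex_all[rows]])
            b_, s_, t_, p_, n_used, ok = _scan_one_snp(X, traits[rows])
        else:
            Gt = np.empty((T, _N_PARAMS, _N_PARAMS))
            for a in range(3):
                for b in range(a, 3):
                    val = uu_full[a, b] - ucorr[(a, b)]
                    Gt[:, umap[a], umap[b]] = val
                    Gt[:, umap[b], umap[a]] = val
            dmoms = np.column_stack([d, d * d, d * age, d * sex])
            full = dmoms.sum(axis=0)
            corr = Mt @ dmoms                 # (T, 4)
            for col, xi in zip(range(4), (0, 1, 2, 3)):
                Gt[:, 1, xi] = full[col] - corr[:, col]
                Gt[:, xi, 1] = Gt[:, 1, xi]
            Xy = np.column_stack([SYu[0], d @ Y0, SYu[1], SYu[2]])
            with np.errstate(invalid="ignore", divide="ignore"):
                var_d = Gt[:, 1, 1] - Gt[:, 0, 1] ** 2 / np.maximum(n_t, 1)
                var_y = yy - SYu[0] ** 2 / np.maximum(n_t, 1)
            testable = ((n_t > _N_PARAMS)
                        & (var_d > 1e-9 * np.maximum(Gt[:, 1, 1], 1.0))
                        & (var_y > 1e-10 * np.maximum(yy, 1.0)))
            b_, s_, t_, p_, n_used, ok = _finish_batch(Gt, Xy, yy, n_t, testable)
        out["beta"][:, j] = b_
        out["se"][:, j] = s_
        out["stat"][:, j] = t_
        out["p"][:, j] = p_
        out["n"][:, j] = n_used
        out["testable"][:, j] = ok
    out["trait_labels"] = list(trait_labels)
    return out


def scan(
    traits: np.ndarray,
    trait_labels: list[str],
    genotypes: GenotypeSet,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy (SNP x trait) association table in deterministic order.

    Output is trait-major, then SNPs by (chrom, pos); columns follow the
    fixed downstream contract: SNP, CHR, POS, A, B, MAF, TRAIT, N, BETA,
    SE, STAT, P plus a TESTABLE flag.
    """
    res = scan_matrix(traits, trait_labels, genotypes, covariates)
    snps = genotypes.snps
    chrom_key = pd.to_numeric(snps["chrom"], errors="coerce").fillna(10**9).to_numpy()
    snp_order = np.lexsort((snps["pos"].to_numpy(), chrom_key))
    T, M = res["p"].shape
    t_idx = np.repeat(np.arange(T), M)
    s_idx = np.tile(snp_order, T)
    df = pd.DataFrame({
        "SNP": snps["id"].to_numpy()[s_idx],
        "CHR": snps["chrom"].to_numpy()[s_idx],
        "POS": snps["pos"].to_numpy()[s_idx],
        "A": snps["allele_a"].to_numpy()[s_idx],
        "B": snps["allele_b"].to_numpy()[s_idx],
        "MAF": snps["maf"].to_numpy()[s_idx],
        "TRAIT": np.asarray(res["trait_labels"], dtype=object)[t_idx],
        "N": res["n"][t_idx, s_idx],
        "BETA": res["beta"][t_idx, s_idx],
        "SE": res["se"][t_idx, s_idx],
        "STAT": res["stat"][t_idx, s_idx],
        "P": res["p"][t_idx, s_idx],
        "TESTABLE": res["testable"][t_idx, s_idx],
    })
    return df


# --------------------------------------------------------------------------
# non-parametric check
# --------------------------------------------------------------------------

def spearman_assoc_test(trait: np.ndarray, dosage: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation of a trait with dosage, t-approximation P.

    Ties receive average ranks.  Returns (rho, p); (nan, nan) for constant
    input.  Requires at least 5 complete cases.
    """
    trait = np.asarray(trait, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    keep = np.isfinite(trait) & np.isfinite(dosage)
    x, y = trait[keep], dosage[keep]
    if x.size < 5:
        raise ValueError("spearman_assoc_test requires >= 5 complete cases")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(np.clip(p, P_FLOOR, 1.0))
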