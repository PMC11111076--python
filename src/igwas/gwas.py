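"""Linear-mixed-model association engine.

A desk-scale, exact analog of the infinitesimal-model LMM used by
large-cohort GWAS tools: the phenotype is modeled as

    y = X b + g + e,    g ~ N(0, sigma_g^2 K),    e ~ N(0, sigma_e^2 I)

with K the genetic relationship matrix from standardized dosages.
Variance components are estimated by REML via one eigendecomposition of
K and a bounded 1-D search over the variance ratio; per-SNP effects are
generalized-least-squares Wald tests under the fitted covariance, with
the leave-one-chromosome-out (LOCO) GRM by default so a tested SNP
never contributes to its own covariance structure. Covariates (age,
sex, top ancestral principal components) are projected out under the
V-inverse metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import GenotypePanel

__all__ = [
    "Kinship", "compute_grm", "compute_pcs", "reml_fit_null",
    "assoc_scan", "run_endophenotype_gwas", "genomic_inflation",
    "LmmWorkspace", "CHI2_NULL_MEDIAN",
]

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))   # 0.4549364... (1-df median)
P_FLOOR = 1e-300


@dataclass
class Kinship:
    """n x n genetic relationship matrix with its eigendecomposition cache."""

    values: np.ndarray
    n_snps: int
    _eig: tuple | None = None

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            lam, U = np.linalg.eigh(self.values)
            if lam.min() < -1e-6 * max(lam.max(), 1.0):
                raise ValueError("kinship matrix is not PSD within tolerance")
            self._eig = (np.maximum(lam, 0.0), U)
        return self._eig


def standardized_dosages(panel: GenotypePanel, maf_filter: float = 0.01
                         ) -> tuple[np.ndarray, np.ndarray]:
    """GCTA-style standardization: (d - 2p)/sqrt(2p(1-p)), p = sample ALT
    frequency; missing dosages (-1) are mean-imputed. Returns (Z, kept
    SNP index)."""
    D = panel.dosages.astype(float)
    miss = D < 0
    if miss.any():
        col_mean = np.where(miss, np.nan, D)
        col_mean = np.nanmean(col_mean, axis=0)
        D = np.where(miss, col_mean[None, :], D)
    p = D.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    # a SNP must both pass the MAF filter and actually vary (an
    # all-heterozygote column has MAF 0.5 but zero variance)
    keep = np.flatnonzero((maf >= max(maf_filter, 1e-12)) & (D.std(axis=0) > 0))
    if len(keep) == 0:
        raise ValueError("no polymorphic SNPs pass the MAF filter")
    Z = (D[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    return Z, keep


def compute_grm(panel: GenotypePanel, maf_filter: float = 0.01) -> Kinship:
    """K = Z Z^T / M over the M MAF-filtered, standardized SNPs."""
    Z, keep = standardized_dosages(panel, maf_filter)
    if len(keep) < 1:
        raise ValueError("need at least one SNP for the GRM")
    return Kinship(values=Z @ Z.T / len(keep), n_snps=len(keep))


def compute_pcs(K: Kinship | np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k eigenvectors of the GRM; each column sign-fixed so its
    largest-magnitude loading is positive."""
    values = K.values if isinstance(K, Kinship) else np.asarray(K)
    n = values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    lam, U = (K.eig() if isinstance(K, Kinship) else np.linalg.eigh(values))
    top = U[:, np.argsort(lam)[::-1][:k]]
    for j in range(k):
        i = np.argmax(np.abs(top[:, j]))
        if top[i, j] < 0:
            top[:, j] = -top[:, j]
    return top


def _reml_neg_loglik(log_ratio: float, lam, ty, tX) -> float:
    r = np.exp(log_ratio)
    D = r * lam + 1.0
    W = 1.0 / D
    XtWX = tX.T @ (tX * W[:, None])
    XtWy = tX.T @ (ty * W)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = ty - tX @ beta
    n, p = len(ty), tX.shape[1]
    S = float(resid @ (resid * W))
    sigma_e2 = S / (n - p)
    _, logdet_xwx = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(sigma_e2) + np.sum(np.log(D)) + logdet_xwx)
    return -ll


def reml_fit_null(y: np.ndarray, X: np.ndarray, K: Kinship
                  ) -> tuple[float, float, float]:
    """REML variance components (sigma_g2, sigma_e2, restricted loglik).

    One eigendecomposition of K plus a bounded scalar search over
    log(sigma_g2/sigma_e2) in [-10, 10]; the exact OLS boundary
    (sigma_g2 = 0) is also evaluated and kept if better.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank-deficient")
    if n < X.shape[1] + 2:
        raise ValueError("too few subjects for REML")
    lam, U = K.eig()
    ty, tX = U.T @ y, U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), args=(lam, ty, tX),
        method="bounded", options={"xatol": 1e-8},
    )
    candidates = [(res.fun, float(np.exp(res.x)))]
    nll0 = _reml_neg_loglik(-np.inf, lam, ty, tX)
    candidates.append((nll0, 0.0))
    nll, ratio = min(candidates, key=lambda t: t[0])

    D = ratio * lam + 1.0
    W = 1.0 / D
    beta = np.linalg.solve(tX.T @ (tX * W[:, None]), tX.T @ (ty * W))
    resid = ty - tX @ beta
    sigma_e2 = float(resid @ (resid * W)) / (n - X.shape[1])
    sigma_g2 = ratio * sigma_e2
    return sigma_g2, sigma_e2, -nll


@dataclass
class LmmWorkspace:
    """Shared per-panel state for scanning many traits.

    Holds the standardized dosages, the global GRM, and (with LOCO) one
    eigendecomposition of the leave-each-chromosome-out GRM, reused
    across traits and eyes.
    """

    panel: GenotypePanel
    Z: np.ndarray
    keep: np.ndarray
    K: Kinship
    loco: bool
    loco_eigs: dict

    @classmethod
    def build(cls, panel: GenotypePanel, maf_filter: float = 0.01,
              loco: bool = True) -> "LmmWorkspace":
        Z, keep = standardized_dosages(panel, maf_filter)
        M = len(keep)
        K = Kinship(values=Z @ Z.T / M, n_snps=M)
        loco_eigs = {}
        if loco:
            chroms = np.asarray(panel.chrom)[keep]
            KZ = Z @ Z.T
            for c in dict.fromkeys(chroms):
                mask = chroms == c
                Mc = int(mask.sum())
                if M - Mc < 1:
                    loco_eigs[c] = Kinship(values=K.values, n_snps=M)
                    continue
                Zc = Z[:, mask]
                Kc = (KZ - Zc @ Zc.T) / (M - Mc)
                loco_eigs[c] = Kinship(values=Kc, n_snps=M - Mc)
        return cls(panel=panel, Z=Z, keep=keep, K=K, loco=loco,
                   loco_eigs=loco_eigs)

    def kinship_for(self, chrom: str) -> Kinship:
        if self.loco and chrom in self.loco_eigs:
            return self.loco_eigs[chrom]
        return self.K


def _gls_scan_block(y, X, G, kin: Kinship, sigma_g2, sigma_e2):
    """Vectorized GLS Wald statistics for a block of SNP columns G."""
    lam, U = kin.eig()
    W = 1.0 / (sigma_g2 * lam + sigma_e2)
    ty, tX, tG = U.T @ y, U.T @ X, U.T @ G
    XtWX = tX.T @ (tX * W[:, None])
    coefy = np.linalg.solve(XtWX, tX.T @ (ty * W))
    y_res = ty - tX @ coefy
    coefG = np.linalg.solve(XtWX, tX.T @ (tG * W[:, None]))
    G_res = tG - tX @ coefG
    gWg = np.einsum("ij,ij->j", G_res, G_res * W[:, None])
    gWy = G_res.T @ (y_res * W)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gWy / gWg
        se = np.sqrt(1.0 / gWg)
    chi2 = np.where(gWg > 0, beta * beta * gWg, 0.0)
    return beta, se, chi2


def assoc_scan(y, X, workspace: LmmWorkspace, trait: str = "trait",
               eye: str = "left") -> pd.DataFrame:
    """Scan every SNP of the panel for one trait.

    REML variance components are fitted per LOCO kinship; monomorphic
    or MAF-filtered SNPs are emitted with beta 0, p 1 and a flag so the
    SNP universe stays complete.
    """
    panel = workspace.panel
    y = np.asarray(y, dtype=float)
    m = panel.n_snps
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    chi2 = np.zeros(m)
    pval = np.ones(m)
    flag = np.array(["low_maf"] * m, dtype=object)

    kept_set = workspace.keep
    chroms = np.asarray(panel.chrom)
    D = panel.dosages.astype(float)

    for c in dict.fromkeys(chroms[kept_set]):
        idx = kept_set[chroms[kept_set] == c]
        kin = workspace.kinship_for(c)
        sg2, se2, _ = reml_fit_null(y, X, kin)
        b, s, x2 = _gls_scan_block(y, X, D[:, idx], kin, sg2, se2)
        beta[idx], se[idx], chi2[idx] = b, s, x2
        pval[idx] = np.maximum(stats.chi2.sf(x2, df=1), P_FLOOR)
        flag[idx] = "ok"

    sample_p = D.mean(axis=0) / 2.0
    mono = D.std(axis=0) == 0
    flag[mono] = "monomorphic"

    return pd.DataFrame({
        "snp_id": panel.snp_ids, "chrom": chroms, "pos": panel.pos,
        "ref": panel.ref, "alt": panel.alt, "altfreq": sample_p,
        "trait": trait, "eye": eye,
        "beta": beta, "se": se, "chi2": chi2, "pvalue": pval, "flag": flag,
    })


def build_covariates(covars: pd.DataFrame, pcs: np.ndarray | None) -> np.ndarray:
    """Design matrix [1, age, sex, PCs]."""
    cols = [np.ones(len(covars)), covars["age"].to_numpy(float),
            covars["sex"].to_numpy(float)]
    X = np.column_stack(cols)
    if pcs is not None:
        X = np.column_stack([X, pcs])
    return X


def run_endophenotype_gwas(phenos_left: pd.DataFrame, phenos_right: pd.DataFrame,
                           covars: pd.DataFrame, panel: GenotypePanel,
                           maf_filter: float = 0.01, n_pcs: int = 10,
                           loco: bool = True, log=None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One LMM scan per trait per eye; the two eyes are never meta-analyzed.

    Phenotype frames are indexed by subject id with one column per
    trait, in the panel's subject order.
    """
    ids = list(panel.subject_ids)
    for name, frame in (("left", phenos_left), ("right", phenos_right),
                        ("covariates", covars)):
        frame_ids = list(frame.index if name != "covariates" else frame["id"])
        if frame_ids != ids:
            offenders = sorted(set(frame_ids).symmetric_difference(ids))[:10]
            raise ValueError(
                f"subject mismatch between {name} table and genotypes; "
                f"first offenders: {offenders}"
            )
    if list(phenos_left.columns) != list(phenos_right.columns):
        raise ValueError("trait columns differ between eyes")

    workspace = LmmWorkspace.build(panel, maf_filter=maf_filter, loco=loco)
    n_pcs = min(n_pcs, panel.n_subjects - 1)
    pcs = compute_pcs(workspace.K, k=n_pcs) if n_pcs > 0 else None
    X = build_covariates(covars, pcs)

    tables = []
    for eye, phenos in (("left", phenos_left), ("right", phenos_right)):
        rows = []
        for trait in phenos.columns:
            if log is not None:
                log(f"scan eye={eye} trait={trait}")
            rows.append(assoc_scan(phenos[trait].to_numpy(float), X,
                                   workspace, trait=str(trait), eye=eye))
        tables.append(pd.concat(rows, ignore_index=True))
    return tables[0], tables[1]


def genomic_inflation(pvalues) -> float:
    """lambda_GC: median observed chi-square over the null median 0.4549364."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)
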