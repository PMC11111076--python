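"""Post-GWAS analysis.

Dual-eye intersection replication (a variant counts only if its best
p-value passes the genome-wide threshold in both eyes independently),
merging of significant variants into independent loci by LD (r^2 > 0.2)
or physical distance (250 kb) with single-link transitive closure,
windowed LD scores, a simplified univariate/bivariate LD-score
regression for heritability and genetic correlation, descriptive
statistics of the endophenotypes, and range queries against a local
association catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .synthetic import GenotypePanel

__all__ = [
    "SelectedVariant", "Locus", "LdscResult",
    "intersect_eyes", "pairwise_hits", "ld_r2_matrix", "clump_loci",
    "compute_ld_scores", "ldsc_h2", "ldsc_rg",
    "endophenotype_descriptives", "write_descriptives", "catalog_range_query",
]

GENOME_WIDE_P = 5e-8


@dataclass
class SelectedVariant:
    snp_id: str
    chrom: str
    pos: int
    min_p_left: float
    min_p_right: float
    best_trait_left: str
    best_trait_right: str

    @property
    def reported_p(self) -> float:
        return min(self.min_p_left, self.min_p_right)


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    members: list = field(default_factory=list)      # snp ids
    lead_snp: str = ""
    min_p: float = 1.0


@dataclass
class LdscResult:
    estimate: float          # h2 or rg
    intercept: float
    se: float
    intercept_se: float
    kind: str = "h2"


# --------------------------------------------------------------------------
# dual-eye selection
# --------------------------------------------------------------------------

def _check_universe(left: pd.DataFrame, right: pd.DataFrame) -> None:
    lu, ru = set(left["snp_id"]), set(right["snp_id"])
    if lu != ru:
        diff = sorted(lu.symmetric_difference(ru))[:10]
        raise ValueError(f"SNP universes differ between eyes; e.g. {diff}")


def intersect_eyes(left: pd.DataFrame, right: pd.DataFrame,
                   threshold: float = GENOME_WIDE_P) -> list[SelectedVariant]:
    """Variants whose per-eye minimum p-value (over traits) passes the
    threshold in BOTH eyes; the smaller of the two minima is reported."""
    _check_universe(left, right)

    def best(table):
        i = table.groupby("snp_id")["pvalue"].idxmin()
        b = table.loc[i, ["snp_id", "chrom", "pos", "pvalue", "trait"]]
        return b.set_index("snp_id")

    bl, br = best(left), best(right)
    out = []
    for snp in bl.index:
        pl, pr = float(bl.loc[snp, "pvalue"]), float(br.loc[snp, "pvalue"])
        if pl < threshold and pr < threshold:
            out.append(SelectedVariant(
                snp_id=str(snp), chrom=str(bl.loc[snp, "chrom"]),
                pos=int(bl.loc[snp, "pos"]),
                min_p_left=pl, min_p_right=pr,
                best_trait_left=str(bl.loc[snp, "trait"]),
                best_trait_right=str(br.loc[snp, "trait"]),
            ))
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def pairwise_hits(left: pd.DataFrame, right: pd.DataFrame,
                  threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """(snp, trait) pairs significant in both eyes for the same trait."""
    _check_universe(left, right)
    keyed_l = left.set_index(["snp_id", "trait"])["pvalue"]
    keyed_r = right.set_index(["snp_id", "trait"])["pvalue"]
    joined = pd.concat({"p_left": keyed_l, "p_right": keyed_r}, axis=1)
    hits = joined[(joined.p_left < threshold) & (joined.p_right < threshold)]
    return hits.reset_index()


# --------------------------------------------------------------------------
# LD and clumping
# --------------------------------------------------------------------------

def ld_r2_matrix(panel: GenotypePanel, snp_subset) -> np.ndarray:
    """Squared Pearson correlation between dosage columns of the subset."""
    idx = np.asarray(snp_subset)
    if len(idx) == 0:
        raise ValueError("empty SNP subset")
    D = panel.dosages[:, idx].astype(float)
    sd = D.std(axis=0)
    bad = sd == 0
    if bad.any():
        warnings.warn("monomorphic SNP(s) in LD computation; r^2 set to 0")
    Dc = D - D.mean(axis=0)
    denom = np.outer(sd, sd) * D.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Dc.T @ Dc) / denom
    r[np.ix_(bad, bad)] = 0.0
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    r2 = r * r
    np.fill_diagonal(r2, 1.0)
    return r2


def clump_loci(variants: list[SelectedVariant], panel: GenotypePanel,
               r2_threshold: float = 0.2, dist_threshold: int = 250_000
               ) -> list[Locus]:
    """Merge significant variants into loci by single-link closure.

    Same-chromosome variants are linked when r^2 > r2_threshold OR
    |delta pos| <= dist_threshold; loci are the connected components
    (union-find), the lead SNP has the smallest reported p (position
    breaks ties). The result is independent of input order.
    """
    if not variants:
        return []
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.snp_id))
    snp_index = {str(s): j for j, s in enumerate(panel.snp_ids)}
    idx = [snp_index[v.snp_id] for v in variants]
    r2 = ld_r2_matrix(panel, idx)

    parent = list(range(len(variants)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i in range(len(variants)):
        for j in range(i + 1, len(variants)):
            if variants[i].chrom != variants[j].chrom:
                continue
            close = abs(variants[i].pos - variants[j].pos) <= dist_threshold
            linked = r2[i, j] > r2_threshold
            if close or linked:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(variants)):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for members in groups.values():
        vs = [variants[i] for i in members]
        lead = min(vs, key=lambda v: (v.reported_p, v.pos))
        loci.append(Locus(
            chrom=vs[0].chrom,
            start=min(v.pos for v in vs), end=max(v.pos for v in vs),
            members=[v.snp_id for v in vs],
            lead_snp=lead.snp_id, min_p=lead.reported_p,
        ))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def compute_ld_scores(panel: GenotypePanel, window_bp: int = 1_000_000
                      ) -> np.ndarray:
    """l_j = sum of r^2 with SNPs within window_bp on the same chromosome
    (self term included, so independent SNPs have l_j ~ 1)."""
    m = panel.n_snps
    l = np.zeros(m)
    chroms = np.asarray(panel.chrom)
    pos = np.asarray(panel.pos)
    for c in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == c)
        r2 = ld_r2_matrix(panel, idx)
        dist = np.abs(pos[idx][:, None] - pos[idx][None, :])
        r2[dist > window_bp] = 0.0
        l[idx] = r2.sum(axis=1)
    return l


# --------------------------------------------------------------------------
# LD score regression
# --------------------------------------------------------------------------

def _jackknife_slope_intercept(x: np.ndarray, y: np.ndarray,
                               n_blocks: int = 20):
    """OLS slope/intercept with block-jackknife standard errors."""
    def fit(xx, yy):
        A = np.column_stack([xx, np.ones_like(xx)])
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        return coef  # (slope, intercept)

    full = fit(x, y)
    m = len(x)
    n_blocks = min(n_blocks, m)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    deletions = []
    for b in range(n_blocks):
        mask = np.ones(m, dtype=bool)
        mask[edges[b]:edges[b + 1]] = False
        deletions.append(fit(x[mask], y[mask]))
    deletions = np.array(deletions)
    pseudo = n_blocks * full - (n_blocks - 1) * deletions
    se = pseudo.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return full, se


def ldsc_h2(chi2: np.ndarray, l: np.ndarray, N: float, M: float,
            n_blocks: int = 20) -> LdscResult:
    """Heritability by regression of chi^2 on LD scores.

    Model: E[chi^2_j] = 1 + N h^2 l_j / M with a free intercept;
    h^2 = slope * M / N. Unit regression weights; standard errors by
    block jackknife.
    """
    chi2 = np.asarray(chi2, dtype=float)
    l = np.asarray(l, dtype=float)
    if N <= 0 or M <= 0:
        raise ValueError("N and M must be positive")
    if len(chi2) != len(l):
        raise ValueError("chi2 and LD scores not aligned")
    if np.allclose(l, l[0]):
        raise ValueError("LD scores are constant; slope undefined")
    (slope, intercept), (slope_se, int_se) = _jackknife_slope_intercept(
        l, chi2, n_blocks)
    return LdscResult(
        estimate=float(slope * M / N), intercept=float(intercept),
        se=float(slope_se * M / N), intercept_se=float(int_se), kind="h2",
    )


def ldsc_rg(z1: np.ndarray, z2: np.ndarray, l: np.ndarray,
            N1: float, N2: float, M: float, h2_1: float, h2_2: float,
            n_blocks: int = 20) -> LdscResult:
    """Genetic correlation from the cross-trait z-score product.

    Model: E[z1 z2] = sqrt(N1 N2) rho_g l / M + intercept;
    rg = rho_g / sqrt(h2_1 h2_2), clipped to [-1.25, 1.25] with warning.
    """
    if h2_1 <= 0 or h2_2 <= 0:
        raise ValueError("rg undefined for non-positive heritabilities")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(l, dtype=float)
    if not (len(z1) == len(z2) == len(l)):
        raise ValueError("z-scores and LD scores not aligned")
    if np.allclose(l, l[0]):
        raise ValueError("LD scores are constant; slope undefined")
    (slope, intercept), (slope_se, int_se) = _jackknife_slope_intercept(
        l, z1 * z2, n_blocks)
    rho_g = slope * M / np.sqrt(N1 * N2)
    rg = rho_g / np.sqrt(h2_1 * h2_2)
    rg_se = slope_se * M / np.sqrt(N1 * N2) / np.sqrt(h2_1 * h2_2)
    if abs(rg) > 1.25:
        warnings.warn(f"genetic correlation {rg:.3f} outside [-1.25, 1.25]; clipped")
        rg = float(np.clip(rg, -1.25, 1.25))
    return LdscResult(estimate=float(rg), intercept=float(intercept),
                      se=float(rg_se), intercept_se=float(int_se), kind="rg")


# --------------------------------------------------------------------------
# descriptives and catalog
# --------------------------------------------------------------------------

def endophenotype_descriptives(values: np.ndarray, trait_names=None,
                               n_hist_bins: int = 40) -> dict:
    """Univariate histograms and the clustered absolute-correlation matrix.

    Returns a dict with the |r| matrix (unit diagonal), the
    average-linkage leaf order, and per-trait histograms.
    """
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    if d < 2:
        raise ValueError("need at least 2 traits")
    if trait_names is None:
        trait_names = [f"e{j}" for j in range(d)]

    sd = values.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn("constant trait(s); correlations set to 0")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    acorr = np.abs(corr)
    np.fill_diagonal(acorr, 1.0)

    dist = squareform(1.0 - acorr, checks=False)
    order = leaves_list(average(dist)) if d > 2 else np.arange(d)

    hists = {}
    for j, name in enumerate(trait_names):
        counts, edges = np.histogram(values[:, j], bins=n_hist_bins)
        hists[name] = (counts, edges)
    return {"abs_corr": acorr, "order": np.asarray(order),
            "trait_names": list(trait_names), "histograms": hists}


def write_descriptives(report: dict, out_prefix) -> None:
    """Persist a descriptives report as TSV plus a clustered heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = report["trait_names"]
    order = report["order"]
    ordered = [names[i] for i in order]
    frame = pd.DataFrame(report["abs_corr"][np.ix_(order, order)],
                         index=ordered, columns=ordered)
    frame.to_csv(f"{out_prefix}_abs_corr.tsv", sep="\t", float_format="%.6g")

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(frame.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_title("absolute endophenotype correlations (clustered)")
    fig.colorbar(im, ax=ax, label="|r|")
    fig.savefig(f"{out_prefix}_abs_corr.png", dpi=120)
    plt.close(fig)


def catalog_range_query(loci: list[Locus], catalog: pd.DataFrame,
                        flank: int = 250_000) -> pd.DataFrame:
    """Catalog entries within [start - flank, end + flank] (closed) of each
    locus, on the same chromosome.

    The catalog is a TSV-like frame with columns chrom, pos, trait (and
    optionally pmid), in the same genome build as the loci.
    """
    if "build_mismatch" in catalog.attrs and catalog.attrs["build_mismatch"]:
        raise ValueError("catalog genome build differs from loci; "
                         "coordinate conversion is out of scope")
    rows = []
    cat_chrom = catalog["chrom"].astype(str)
    for k, locus in enumerate(loci):
        lo, hi = locus.start - flank, locus.end + flank
        sel = catalog[(cat_chrom == str(locus.chrom))
                      & (catalog["pos"] >= lo) & (catalog["pos"] <= hi)]
        for _, entry in sel.iterrows():
            rows.append((k, locus.lead_snp, str(locus.chrom),
                         int(entry["pos"]), str(entry["trait"]),
                         entry.get("pmid", "")))
    return pd.DataFrame(rows, columns=["locus", "lead_snp", "chrom",
                                       "catalog_pos", "catalog_trait", "pmid"])
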