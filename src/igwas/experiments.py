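"""Self-contained evaluation experiments on fully synthetic cohorts.

Each function simulates its own data with known ground truth, runs the
relevant slice of the pipeline, and returns the measured quantities.
They are used by the test suite and by ``scripts/acceptance.py``; the
cohort settings (sample sizes, five causal pigmentation SNPs at 5%
variance explained each, one per chromosome) are the package's standard
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .colors import color_table
from .config import ArcFaceConfig, QualityConfig, SimConfig, substream
from .gwas import LmmWorkspace, assoc_scan, genomic_inflation, \
    run_endophenotype_gwas
from .phenotyper import embed_images, pair_similarity_stats, train_phenotyper
from .postprocess import clump_loci, intersect_eyes, ldsc_h2
from .quality import classification_metrics, score_quality, train_quality_scorer
from .synthetic import make_quality_corpus, render_fundus_pair, \
    simulate_genotypes, simulate_subjects

__all__ = [
    "null_calibration", "make_causal_cohort", "color_gwas_recovery",
    "endo_gwas_recovery", "contrastive_separation", "quality_benchmark",
    "ldsc_recovery",
]

# desk-scale learning rate for the small convolutional encoder
DESK_LR = 3e-3
GENOME_WIDE_P = 5e-8


def null_calibration(seed: int, n_subjects: int = 500, n_snps: int = 2000
                     ) -> dict:
    """Global-null LMM scan: genomic inflation and type-I error at 0.05.

    Genotypes are independent SNPs; the phenotype is pure noise,
    independent of the genotypes.
    """
    cfg = SimConfig(n_subjects=n_subjects, n_snps=n_snps, ld_block_size=1,
                    within_block_r=0.0, seed=seed, n_chromosomes=2)
    panel = simulate_genotypes(cfg)
    rng = substream(seed, "null_pheno")
    y = rng.standard_normal(n_subjects)
    X = np.column_stack([np.ones(n_subjects), rng.standard_normal(n_subjects)])
    ws = LmmWorkspace.build(panel, loco=True)
    tab = assoc_scan(y, X, ws)
    ok = tab.flag == "ok"
    pvals = tab.pvalue[ok]
    return {
        "lambda_gc": genomic_inflation(pvals),
        "type1_at_0.05": float((pvals < 0.05).mean()),
        "n_tests": int(ok.sum()),
    }


def make_causal_cohort(seed: int, n_subjects: int = 1000, n_snps: int = 500,
                       n_causal: int = 5, variance_explained: float = 0.05):
    """Cohort with ``n_causal`` pigmentation SNPs, one per chromosome.

    Returns (panel, subjects, images, causal_indices).
    """
    per_chrom = n_snps // n_causal
    causal_idx = [c * per_chrom + per_chrom // 2 for c in range(n_causal)]
    cfg = SimConfig(
        n_subjects=n_subjects, n_snps=n_snps, ld_block_size=10,
        within_block_r=0.8, seed=seed, n_chromosomes=n_causal,
        pos_stride=10_000,
        causal_map=[(i, "pigment", variance_explained) for i in causal_idx],
    )
    panel = simulate_genotypes(cfg)
    subjects = simulate_subjects(panel, cfg)
    images = []
    for s in subjects:
        left, right = render_fundus_pair(s, cfg, seed=seed)
        images.extend([left, right])
    return panel, subjects, images, causal_idx


def _recovered_loci(loci, panel, causal_idx, flank: int = 250_000) -> int:
    hits = 0
    for i in causal_idx:
        c, p = str(panel.chrom[i]), int(panel.pos[i])
        if any(l.chrom == c and l.start - flank <= p <= l.end + flank
               for l in loci):
            hits += 1
    return hits


def _pheno_frames(values_by_eye, ids):
    frames = {}
    for eye, frame in values_by_eye.items():
        frames[eye] = frame.loc[ids]
    return frames


def _covar_frame(panel, subjects) -> pd.DataFrame:
    return pd.DataFrame({
        "id": [str(s) for s in panel.subject_ids],
        "age": [s.age for s in subjects],
        "sex": [s.sex for s in subjects],
    })


def color_gwas_recovery(seed: int, n_subjects: int = 1000) -> dict:
    """Retina-color GWAS + dual-eye intersection + clumping vs ground truth."""
    panel, subjects, images, causal_idx = make_causal_cohort(
        seed, n_subjects=n_subjects)
    ids = [str(s) for s in panel.subject_ids]
    ct = color_table(images)
    cols = ["mean_red", "mean_green", "mean_blue"]
    phenos = {
        eye: ct[ct.eye == eye].set_index(
            ct[ct.eye == eye].subject_id.astype(str))[cols]
        for eye in ("left", "right")
    }
    phenos = _pheno_frames(phenos, ids)
    left, right = run_endophenotype_gwas(
        phenos["left"], phenos["right"], _covar_frame(panel, subjects), panel)
    selected = intersect_eyes(left, right, threshold=GENOME_WIDE_P)
    loci = clump_loci(selected, panel)
    return {
        "n_causal": len(causal_idx),
        "n_recovered": _recovered_loci(loci, panel, causal_idx),
        "n_loci": len(loci),
        "n_selected_snps": len(selected),
    }


def endo_gwas_recovery(seed: int, n_subjects: int = 1000, d: int = 8,
                       epochs: int = 20, n_train_subjects: int = 150) -> dict:
    """Endophenotype GWAS recovery with a per-seed trained phenotyper.

    The encoder is trained on a subset of subjects, then embeds the full
    cohort; its coordinates are the GWAS traits.
    """
    panel, subjects, images, causal_idx = make_causal_cohort(
        seed, n_subjects=n_subjects)
    ids = [str(s) for s in panel.subject_ids]
    train_imgs = images[: 2 * n_train_subjects]
    acfg = ArcFaceConfig(d=d, epochs=epochs, seed=seed, lr=DESK_LR)
    model, _ = train_phenotyper(train_imgs, cfg=acfg)
    emb = embed_images(model, images)
    phenos = {}
    for eye in ("left", "right"):
        m = emb.for_eye(eye)
        phenos[eye] = pd.DataFrame(
            m.values, index=[str(s) for s in m.subject_ids],
            columns=[f"e{j + 1}" for j in range(m.d)])
    phenos = _pheno_frames(phenos, ids)
    left, right = run_endophenotype_gwas(
        phenos["left"], phenos["right"], _covar_frame(panel, subjects), panel)
    selected = intersect_eyes(left, right, threshold=GENOME_WIDE_P)
    loci = clump_loci(selected, panel)
    return {
        "n_causal": len(causal_idx),
        "n_recovered": _recovered_loci(loci, panel, causal_idx),
        "n_loci": len(loci),
        "n_selected_snps": len(selected),
    }


def contrastive_separation(seed: int, n_subjects: int = 200, d: int = 16,
                           epochs: int = 30) -> dict:
    """Matched/random cosine-similarity separation, trained vs untrained."""
    cfg = SimConfig(n_subjects=n_subjects, n_snps=40, seed=seed,
                    causal_map=[(3, "pigment", 0.3), (23, "vessel", 0.3)])
    panel = simulate_genotypes(cfg)
    subjects = simulate_subjects(panel, cfg)
    images = []
    for s in subjects:
        left, right = render_fundus_pair(s, cfg, seed=seed)
        images.extend([left, right])
    grades = {s.id: s.dr_grade for s in subjects}

    out = {}
    for label, n_epochs in (("trained", epochs), ("untrained", 0)):
        acfg = ArcFaceConfig(d=d, epochs=n_epochs, seed=seed, lr=DESK_LR)
        model, _ = train_phenotyper(images, dr_grades=grades, cfg=acfg)
        emb = embed_images(model, images)
        st = pair_similarity_stats(emb, n_random_pairs=1000, seed=seed)
        out[label] = {
            "js_distance": st.js_distance,
            "jaccard_index": st.jaccard_index,
            "matched_median": float(np.median(st.matched)),
            "random_median": float(np.median(st.random)),
            "random_mean": st.mean_random,
        }
    return out


def quality_benchmark(seed: int, n_good: int = 200, n_bad: int = 200) -> dict:
    """Train the quality scorer and evaluate on a fresh labeled corpus."""
    cfg = SimConfig(n_subjects=4, seed=seed)
    train_corpus = make_quality_corpus(n_good, n_bad, cfg, seed=seed)
    model = train_quality_scorer(
        train_corpus, cfg=QualityConfig(epochs=15, seed=seed))
    eval_cfg = SimConfig(n_subjects=4, seed=seed + 1)
    eval_corpus = make_quality_corpus(n_good // 2, n_bad // 2, eval_cfg,
                                      seed=seed + 10_001)
    scores = score_quality(model, eval_corpus)
    labels = np.array([c.quality_label == "good" for c in eval_corpus])
    rep = classification_metrics(scores, labels, threshold=0.5)
    return {"auroc": rep.auroc, "ppv": rep.ppv, "npv": rep.npv,
            "sensitivity": rep.sensitivity, "specificity": rep.specificity}


def ldsc_recovery(seed: int, h2: float = 0.3, N: int = 1000, M: int = 2000,
                  reps: int = 50) -> dict:
    """Mean LDSC heritability estimate over model-simulated chi-squares."""
    rng = substream(seed, "ldsc_sim")
    l = rng.uniform(1.0, 8.0, M)
    ests = []
    for _ in range(reps):
        chi2 = (rng.standard_normal(M) ** 2) * (1 + N * h2 * l / M)
        ests.append(ldsc_h2(chi2, l, N, M).estimate)
    exact = ldsc_h2(1 + N * h2 * l / M, l, N, M).estimate
    return {"h2_true": h2, "h2_mean_estimate": float(np.mean(ests)),
            "h2_exact_input_estimate": float(exact), "reps": reps}
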