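"""End-to-end pipeline: simulate -> QC -> train -> embed -> colors ->
GWAS (both eyes) -> intersect -> clump -> LDSC -> report.

Every stage writes its artifacts as TSV (floats rounded to 6 significant
digits for checksum stability) under the run directory; a stage that is
toggled off reuses the artifacts already on disk and fails with the name
of the missing stage otherwise. A manifest with sha256 checksums of all
tabular outputs is written at the end; two runs from the same config and
master seed produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datio
from .colors import color_table
from .config import RunConfig
from .gwas import genomic_inflation, run_endophenotype_gwas
from .phenotyper import EmbeddingMatrix, embed_images, pair_similarity_stats, \
    train_phenotyper
from .postprocess import SelectedVariant, clump_loci, compute_ld_scores, \
    intersect_eyes, ldsc_h2
from .quality import score_quality, select_top_quality, train_quality_scorer
from .synthetic import make_quality_corpus, render_fundus_pair, \
    simulate_genotypes, simulate_subjects

__all__ = ["run_pipeline"]

STAGES = ["simulate", "quality", "phenotyper", "embed", "colors", "gwas",
          "intersect", "clump", "ldsc"]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; enable stage {stage!r}"
        )
    return path


def _emb_frame(emb: EmbeddingMatrix) -> pd.DataFrame:
    cols = {f"e{j + 1}": emb.values[:, j] for j in range(emb.d)}
    return pd.DataFrame({"subject_id": emb.subject_ids, "eye": emb.eyes, **cols})


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    sim = config.sim
    sim.seed = config.seed
    timings: dict[str, float] = {}
    manifest: dict = {"stages": {}, "seed": config.seed}

    def stage_on(name):
        return config.stages.get(name, True)

    def tick(name, t0):
        timings[name] = round(time.time() - t0, 3)
        log(f"[igwas] stage {name} done in {timings[name]:.1f}s (seed {config.seed})")

    # ---- simulate -------------------------------------------------------
    data_dir = out / "data"
    t0 = time.time()
    if stage_on("simulate"):
        panel = simulate_genotypes(sim)
        subjects = simulate_subjects(panel, sim)
        images = []
        for s in subjects:
            left, right = render_fundus_pair(s, sim, seed=config.seed)
            images.extend([left, right])
        datio.write_dataset(panel, subjects, images, data_dir)
        tick("simulate", t0)
    else:
        _require(data_dir / "genotypes.vcf", "simulate")
        panel, covars_df, images = datio.read_dataset(data_dir)
        subjects = None
    covars = pd.read_csv(data_dir / "covariates.tsv", sep="\t")

    # ---- quality --------------------------------------------------------
    scores_path = out / "quality_scores.tsv"
    t0 = time.time()
    if stage_on("quality"):
        corpus = make_quality_corpus(config.n_good_quality,
                                     config.n_bad_quality, sim,
                                     seed=config.seed)
        qcfg = config.quality
        qcfg.seed = config.seed
        model = train_quality_scorer(corpus, cfg=qcfg)
        scores = score_quality(model, images)
        _write_tsv(pd.DataFrame({
            "image_path": [f"images/{im.subject_id}_{im.eye}.png" for im in images],
            "subject_id": [im.subject_id for im in images],
            "eye": [im.eye for im in images],
            "score": scores,
        }), scores_path)
        tick("quality", t0)
    else:
        _require(scores_path, "quality")
        scores = pd.read_csv(scores_path, sep="\t")["score"].to_numpy()

    # ---- phenotyper -----------------------------------------------------
    t0 = time.time()
    emb_paths = {eye: out / f"embeddings_{eye}.tsv" for eye in ("left", "right")}
    if stage_on("phenotyper") or stage_on("embed"):
        keep = select_top_quality(images, scores,
                                  score_floor=config.quality_keep_threshold)
        grades = dict(zip(covars["id"].astype(str), covars["dr_grade"]))
        acfg = config.arcface
        acfg.seed = config.seed
        model, bank = train_phenotyper(keep, dr_grades=grades, cfg=acfg)
        tick("phenotyper", t0)

        t0 = time.time()
        emb = embed_images(model, images)
        for eye in ("left", "right"):
            _write_tsv(_emb_frame(emb.for_eye(eye)), emb_paths[eye])
        stats = pair_similarity_stats(emb, n_random_pairs=min(
            2000, len(images) * (len(images) - 1) // 4), seed=config.seed)
        manifest["pair_stats"] = {
            "js_distance": stats.js_distance,
            "jaccard_index": stats.jaccard_index,
            "mean_random_similarity": stats.mean_random,
        }
        tick("embed", t0)
    else:
        for eye in ("left", "right"):
            _require(emb_paths[eye], "embed")

    emb_frames = {eye: pd.read_csv(emb_paths[eye], sep="\t")
                  for eye in ("left", "right")}

    # ---- colors ---------------------------------------------------------
    t0 = time.time()
    color_paths = {eye: out / f"colors_{eye}.tsv" for eye in ("left", "right")}
    if stage_on("colors"):
        ct = color_table(images)
        for eye in ("left", "right"):
            _write_tsv(ct[ct.eye == eye], color_paths[eye])
        tick("colors", t0)
    else:
        for eye in ("left", "right"):
            _require(color_paths[eye], "colors")
    color_frames = {eye: pd.read_csv(color_paths[eye], sep="\t")
                    for eye in ("left", "right")}

    # ---- gwas -----------------------------------------------------------
    t0 = time.time()
    gwas_paths = {
        ("endo", eye): out / f"gwas_endo_{eye}.tsv" for eye in ("left", "right")
    } | {
        ("color", eye): out / f"gwas_color_{eye}.tsv" for eye in ("left", "right")
    }
    if stage_on("gwas"):
        ids = [str(s) for s in panel.subject_ids]

        def pheno_frame(frame, value_cols):
            f = frame.set_index(frame["subject_id"].astype(str))[value_cols]
            return f.loc[ids]

        import re

        e_cols = [c for c in emb_frames["left"].columns
                  if re.fullmatch(r"e\d+", c)]
        c_cols = ["mean_red", "mean_green", "mean_blue"]
        covars_aligned = covars.set_index(covars["id"].astype(str)).loc[ids]

        endo_l, endo_r = run_endophenotype_gwas(
            pheno_frame(emb_frames["left"], e_cols),
            pheno_frame(emb_frames["right"], e_cols),
            covars_aligned, panel, maf_filter=config.maf_filter,
            n_pcs=config.n_pcs)
        col_l, col_r = run_endophenotype_gwas(
            pheno_frame(color_frames["left"], c_cols),
            pheno_frame(color_frames["right"], c_cols),
            covars_aligned, panel, maf_filter=config.maf_filter,
            n_pcs=config.n_pcs)
        for key, table in {("endo", "left"): endo_l, ("endo", "right"): endo_r,
                           ("color", "left"): col_l, ("color", "right"): col_r}.items():
            _write_tsv(table, gwas_paths[key])
        tick("gwas", t0)
    else:
        for key, path in gwas_paths.items():
            _require(path, "gwas")
    tables = {key: pd.read_csv(path, sep="\t", dtype={"chrom": str})
              for key, path in gwas_paths.items()}

    lam = {f"lambda_gc_{kind}_{eye}": genomic_inflation(
        tables[(kind, eye)].query("flag == 'ok'")["pvalue"])
        for kind in ("endo", "color") for eye in ("left", "right")}
    manifest["genomic_inflation"] = lam

    # ---- intersect ------------------------------------------------------
    t0 = time.time()
    sel_paths = {kind: out / f"selected_{kind}.tsv" for kind in ("endo", "color")}
    selected = {}
    if stage_on("intersect"):
        for kind in ("endo", "color"):
            sel = intersect_eyes(tables[(kind, "left")], tables[(kind, "right")],
                                 threshold=config.gwas_threshold)
            selected[kind] = sel
            _write_tsv(pd.DataFrame([{
                "snp_id": v.snp_id, "chrom": v.chrom, "pos": v.pos,
                "min_p_left": v.min_p_left, "min_p_right": v.min_p_right,
                "reported_p": v.reported_p,
                "best_trait_left": v.best_trait_left,
                "best_trait_right": v.best_trait_right,
            } for v in sel]), sel_paths[kind])
        tick("intersect", t0)
    else:
        for kind in ("endo", "color"):
            _require(sel_paths[kind], "intersect")
            df = pd.read_csv(sel_paths[kind], sep="\t", dtype={"chrom": str})
            selected[kind] = [SelectedVariant(
                snp_id=r.snp_id, chrom=str(r.chrom), pos=int(r.pos),
                min_p_left=r.min_p_left, min_p_right=r.min_p_right,
                best_trait_left=str(r.best_trait_left),
                best_trait_right=str(r.best_trait_right)) for r in df.itertuples()]

    # ---- clump ----------------------------------------------------------
    t0 = time.time()
    loci_paths = {kind: out / f"loci_{kind}.tsv" for kind in ("endo", "color")}
    if stage_on("clump"):
        altfreq = dict(zip(panel.snp_ids, tables[("endo", "left")]["altfreq"]))
        color_best = {v.snp_id: v.reported_p for v in selected["color"]}
        for kind in ("endo", "color"):
            loci = clump_loci(selected[kind], panel,
                              r2_threshold=config.clump_r2,
                              dist_threshold=config.clump_dist_bp)
            ref = dict(zip(panel.snp_ids, panel.ref))
            alt = dict(zip(panel.snp_ids, panel.alt))
            _write_tsv(pd.DataFrame([{
                "SNP": lo.lead_snp, "CHR": lo.chrom,
                "BP": next(v.pos for v in selected[kind] if v.snp_id == lo.lead_snp),
                "REF/ALT": f"{ref[lo.lead_snp]}/{alt[lo.lead_snp]}",
                "ALTFREQ": altfreq.get(lo.lead_snp, np.nan),
                "raw_PVAL": lo.min_p,
                "color_PVAL": color_best.get(lo.lead_snp, ""),
                "GENE": "",
                "start": lo.start, "end": lo.end,
                "n_members": len(lo.members),
            } for lo in loci]), loci_paths[kind])
            manifest["stages"][f"n_loci_{kind}"] = len(loci)
        tick("clump", t0)
    else:
        for kind in ("endo", "color"):
            _require(loci_paths[kind], "clump")

    # ---- ldsc -----------------------------------------------------------
    t0 = time.time()
    ldsc_path = out / "ldsc_h2.tsv"
    if stage_on("ldsc"):
        l = compute_ld_scores(panel)
        n_subj = panel.n_subjects
        snp_row = {s: i for i, s in enumerate(panel.snp_ids)}
        rows = []
        for eye in ("left", "right"):
            table = tables[("endo", eye)]
            ok = table.flag == "ok"
            for trait, grp in table[ok].groupby("trait"):
                lj = l[grp["snp_id"].map(snp_row).to_numpy()]
                try:
                    res = ldsc_h2(grp["chi2"].to_numpy(), lj, N=n_subj,
                                  M=len(lj))
                    rows.append((trait, eye, res.estimate, res.se, res.intercept))
                except ValueError:
                    continue
        h2_frame = pd.DataFrame(
            rows, columns=["trait", "eye", "h2", "h2_se", "intercept"])
        _write_tsv(h2_frame, ldsc_path)
        if len(h2_frame):
            manifest["h2_mean"] = float(h2_frame.h2.mean())
            manifest["h2_sd"] = float(h2_frame.h2.std(ddof=1)) \
                if len(h2_frame) > 1 else 0.0
        tick("ldsc", t0)
    else:
        _require(ldsc_path, "ldsc")

    # ---- manifest -------------------------------------------------------
    artifacts = sorted(p for p in out.glob("*.tsv"))
    manifest["artifacts"] = {p.name: _sha256(p) for p in artifacts}
    manifest["timings_s"] = timings
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
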