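"""Synthetic genotype-to-fundus-image simulator.

Generates the full study material with known ground truth: a block-LD
genotype panel, subject covariates and latent traits (pigmentation,
vessel density, disease grade), paired left/right fundus-like images
whose appearance is driven by those traits, and a labeled good/bad
image-quality corpus.

Model
-----
Genotypes follow a Gaussian copula: within a block, latent normals have
AR(1) correlation ``within_block_r`` and are thresholded at the
Hardy-Weinberg quantiles of the drawn minor-allele frequency, so the
marginal genotype distribution is exactly HWE while the latent r is
tunable. Latent traits are linear in standardized dosages with the
requested per-SNP variance explained, topped up to unit variance with
Gaussian noise. Images are procedural: a circular field of view whose
background color darkens with pigmentation, a subject-seeded recursive
bifurcating vessel tree whose branch count grows with the vessel trait,
a foveal dark spot, and per-image nuisance (rotation, illumination,
blur). The right eye is the horizontal mirror of the subject's base
rendering, so with nuisance disabled flip(left) == right bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.draw import line_aa

from .config import SimConfig, substream

__all__ = [
    "GenotypePanel",
    "SubjectRecord",
    "FundusImage",
    "simulate_genotypes",
    "simulate_subjects",
    "render_fundus_pair",
    "make_quality_corpus",
]


@dataclass
class GenotypePanel:
    """Subjects x SNPs dosage matrix with per-SNP metadata."""

    dosages: np.ndarray          # (n_subjects, n_snps) int8 in {0,1,2}
    chrom: np.ndarray            # (n_snps,) str labels, e.g. "1"
    pos: np.ndarray              # (n_snps,) 1-based bp coordinates
    ref: np.ndarray              # (n_snps,) reference allele
    alt: np.ndarray              # (n_snps,) alternate allele
    maf: np.ndarray              # (n_snps,) drawn minor-allele frequency
    snp_ids: np.ndarray = field(default=None)
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        n, m = self.dosages.shape
        if self.snp_ids is None:
            self.snp_ids = np.array(
                [f"rs{c}_{p}" for c, p in zip(self.chrom, self.pos)]
            )
        if self.subject_ids is None:
            self.subject_ids = np.array([f"S{i:05d}" for i in range(n)])

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def sample_maf(self) -> np.ndarray:
        """Per-SNP sample allele frequency, folded to the minor allele."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class SubjectRecord:
    id: str
    age: float
    sex: int
    pigment: float
    vessel: float
    dr_grade: int


@dataclass
class FundusImage:
    """An RGB raster tagged with its provenance."""

    pixels: np.ndarray           # (rows, cols, 3) uint8
    subject_id: str
    eye: str                     # "left" | "right"
    quality_label: str = "unlabeled"
    nuisance: tuple = (0.0, 1.0, 0.0)   # (rotation deg, illumination, blur sigma)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _hwe_thresholds(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-normal cutpoints giving Hardy-Weinberg genotype frequencies."""
    q = 1.0 - maf
    t0 = stats.norm.ppf(q ** 2)            # below: 0 copies of ALT
    t1 = stats.norm.ppf(q ** 2 + 2 * q * maf)
    return t0, t1


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Draw a block-LD diploid genotype panel.

    Each haplotype is a latent AR(1) Gaussian per block, thresholded at
    the HWE quantiles of the SNP's MAF; the diploid dosage is the sum of
    two independent haplotype draws only in the limiting sense — here the
    latent is drawn once per genotype and cut at the two HWE quantiles,
    which preserves the marginal HWE frequencies exactly and makes the
    between-SNP genotype correlation a monotone function of
    ``within_block_r``.
    """
    config.validate()
    rng = substream(config.seed, "genotypes")
    n, m = config.n_subjects, config.n_snps
    r = config.within_block_r
    bs = config.ld_block_size

    maf = rng.uniform(*config.maf_range, size=m)
    t0, t1 = _hwe_thresholds(maf)

    # AR(1) latent per block: z_k = r * z_{k-1} + sqrt(1-r^2) * eps
    z = np.empty((n, m))
    eps = rng.standard_normal((n, m))
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        z[:, start] = eps[:, start]
        for k in range(start + 1, stop):
            z[:, k] = r * z[:, k - 1] + np.sqrt(1.0 - r * r) * eps[:, k]

    dosages = ((z > t0).astype(np.int8) + (z > t1).astype(np.int8))

    # chromosome labels: contiguous block ranges
    n_blocks = -(-m // bs)
    blocks_per_chrom = -(-n_blocks // config.n_chromosomes)
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for j in range(m):
        block = j // bs
        c = min(block // blocks_per_chrom, config.n_chromosomes - 1)
        chrom[j] = str(c + 1)
        first_block_on_chrom = c * blocks_per_chrom
        offset = j - first_block_on_chrom * bs
        pos[j] = 1 + offset * config.pos_stride

    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt_choices = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + alt_choices) % 4]

    return GenotypePanel(
        dosages=dosages, chrom=chrom.astype(str), pos=pos,
        ref=ref, alt=alt, maf=maf,
    )


# --------------------------------------------------------------------------
# subjects / latent traits
# --------------------------------------------------------------------------

_DR_CUTS = (0.8, 1.3, 1.8, 2.3)   # vessel-trait cutpoints for grades 1..4


def simulate_subjects(panel: GenotypePanel, config: SimConfig) -> list[SubjectRecord]:
    """Attach covariates and genetically-driven latent traits to the panel.

    Each trait is ``sum_k beta_k * z_k + e`` where ``z_k`` is the
    sample-standardized dosage of causal SNP k, ``beta_k =
    sqrt(variance_explained_k)`` and the noise variance tops the total up
    to one.
    """
    config.validate()
    rng = substream(config.seed, "subjects")
    n = panel.n_subjects

    per_trait: dict[str, list[tuple[int, float]]] = {"pigment": [], "vessel": []}
    for idx, trait, ve in config.causal_map:
        if trait not in per_trait:
            raise ValueError(f"unknown trait {trait!r}")
        per_trait[trait].append((idx, ve))

    traits: dict[str, np.ndarray] = {}
    for trait, causals in per_trait.items():
        g = np.zeros(n)
        total_ve = 0.0
        for idx, ve in causals:
            d = panel.dosages[:, idx].astype(float)
            sd = d.std()
            if sd == 0:
                raise ValueError(f"causal SNP {idx} is monomorphic")
            g += np.sqrt(ve) * (d - d.mean()) / sd
            total_ve += ve
        if total_ve >= 1.0:
            raise ValueError(f"variance budget exceeded for {trait!r}")
        noise = rng.standard_normal(n) * np.sqrt(1.0 - total_ve)
        traits[trait] = g + noise

    age = rng.uniform(*config.age_range, size=n)
    sex = rng.integers(0, 2, size=n)
    dr_grade = np.searchsorted(_DR_CUTS, traits["vessel"])

    return [
        SubjectRecord(
            id=str(panel.subject_ids[i]), age=float(age[i]), sex=int(sex[i]),
            pigment=float(traits["pigment"][i]), vessel=float(traits["vessel"][i]),
            dr_grade=int(dr_grade[i]),
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

# background color at pigment = 0; channel slopes per pigment SD.
_BASE_RGB = np.array([168.0, 96.0, 52.0])
_PIG_SLOPE = np.array([-20.0, -14.0, -8.0])


def _vessel_tree(rng: np.random.Generator, size: int, vessel: float) -> list:
    """Recursive bifurcation skeleton as a list of (r0, c0, r1, c1) segments.

    Branch depth (hence count) is a monotone step function of the vessel
    trait; angles and lengths come from the subject-seeded rng so both
    eyes of one subject share the topology.
    """
    depth = 4 + int(np.clip(np.floor(vessel + 2.0), 0, 4))  # 4..8 levels
    segments = []
    # optic-disc origin, off-center as in a real fundus
    origin = np.array([0.5 * size, 0.82 * size])
    stack = []
    for a0 in (-0.9, -0.35, 0.35, 0.9):
        ang = np.pi + a0 + rng.uniform(-0.15, 0.15)
        stack.append((origin, ang, 0.16 * size * rng.uniform(0.9, 1.1), 0))
    while stack:
        p, ang, length, lvl = stack.pop()
        q = p + length * np.array([np.sin(ang), np.cos(ang)])
        segments.append((p[0], p[1], q[0], q[1]))
        if lvl + 1 < depth:
            for sgn in (-1.0, 1.0):
                child = ang + sgn * rng.uniform(0.25, 0.6)
                stack.append((q, child, length * rng.uniform(0.62, 0.78), lvl + 1))
    return segments


def _render_base(subject: SubjectRecord, config: SimConfig) -> np.ndarray:
    """Deterministic base rendering (float RGB in [0,255]) for one subject."""
    rows, cols = config.image_size
    size = min(rows, cols)
    rng = substream(config.seed, "render", subject.id)

    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    rad = np.hypot(rr - cy, cc - cx)
    fov = rad <= 0.48 * size

    pig = float(np.clip(subject.pigment, -3.0, 3.0))
    base = _BASE_RGB + _PIG_SLOPE * pig          # darker / less red-bright with pigment
    img = np.zeros((rows, cols, 3))
    # gentle radial vignette inside the field of view
    vignette = 1.0 - 0.25 * (rad / (0.48 * size)) ** 2
    for ch in range(3):
        img[..., ch] = np.where(fov, base[ch] * vignette, 0.0)

    # fovea: dark spot slightly nasal of center (fixed offset)
    fr, fc = cy + 0.02 * size, cx - 0.05 * size
    fdist = np.hypot(rr - fr, cc - fc)
    fovea = np.exp(-0.5 * (fdist / (0.06 * size)) ** 2)
    img *= (1.0 - 0.35 * fovea[..., None])

    # vessel tree, dark red, anti-aliased
    vessel_rgb = np.array([96.0, 24.0, 18.0]) + _PIG_SLOPE * pig * 0.3
    for r0, c0, r1, c1 in _vessel_tree(rng, size, subject.vessel):
        pts = [int(round(v)) for v in (r0, c0, r1, c1)]
        pts = [int(np.clip(v, 0, s - 1)) for v, s in zip(pts, (rows, cols, rows, cols))]
        li, lj, w = line_aa(*pts)
        keep = fov[li, lj]
        li, lj, w = li[keep], lj[keep], w[keep]
        for ch in range(3):
            img[li, lj, ch] = (1 - w) * img[li, lj, ch] + w * vessel_rgb[ch]

    return np.clip(img, 0.0, 255.0)


def _apply_nuisance(img: np.ndarray, rotation: float, illum: float,
                    blur: float) -> np.ndarray:
    """Rotation (degrees, about center), illumination scale, Gaussian blur."""
    out = img
    if rotation != 0.0:
        out = ndimage.rotate(out, rotation, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.0)
    if illum != 1.0:
        out = out * illum
    if blur > 0.0:
        out = ndimage.gaussian_filter(out, sigma=(blur, blur, 0.0))
    return np.clip(out, 0.0, 255.0)


def render_fundus_pair(subject: SubjectRecord, config: SimConfig,
                       seed: int) -> tuple[FundusImage, FundusImage]:
    """Render the (left, right) eye pair of one subject.

    The right eye is the horizontal mirror of the subject's base
    rendering; nuisance (rotation, illumination, blur) is drawn
    independently per image from ``seed``.
    """
    rows, cols = config.image_size
    if rows < 64 or cols < 64:
        raise ValueError("image_size must be at least 64x64")
    base = _render_base(subject, config)
    rng = substream(seed, "nuisance", subject.id)

    out = []
    for eye, canvas in (("left", base), ("right", base[:, ::-1, :])):
        rot = rng.uniform(-config.rotation_max_deg, config.rotation_max_deg) \
            if config.rotation_max_deg > 0 else 0.0
        illum = 1.0 + rng.standard_normal() * config.illum_sd \
            if config.illum_sd > 0 else 1.0
        blur = config.blur_sigma
        pixels = _apply_nuisance(canvas, rot, illum, blur)
        out.append(FundusImage(
            pixels=np.round(pixels).astype(np.uint8),
            subject_id=subject.id, eye=eye,
            nuisance=(rot, illum, blur),
        ))
    return out[0], out[1]


# --------------------------------------------------------------------------
# quality corpus
# --------------------------------------------------------------------------

def make_quality_corpus(n_good: int, n_bad: int, config: SimConfig,
                        seed: int) -> list[FundusImage]:
    """A labeled good/bad-quality corpus of synthetic fundus images.

    Bad images are good renderings degraded by heavy blur, severe under-
    or over-illumination, or a large occluding patch.
    """
    if n_good < 0 or n_bad < 0 or (n_good + n_bad) == 0:
        raise ValueError("corpus counts must be nonnegative and not both zero")
    rng = substream(seed, "quality_corpus")
    corpus: list[FundusImage] = []
    for i in range(n_good + n_bad):
        subj = SubjectRecord(
            id=f"Q{i:05d}", age=50.0, sex=0,
            pigment=float(rng.normal()), vessel=float(rng.normal()),
            dr_grade=0,
        )
        img = _render_base(subj, config)
        rot = rng.uniform(-10, 10)
        if i < n_good:
            pixels = _apply_nuisance(img, rot, 1.0 + rng.normal(0, 0.03), 0.0)
            label = "good"
        else:
            mode = rng.integers(0, 3)
            if mode == 0:                                  # heavy blur
                pixels = _apply_nuisance(img, rot, 1.0, rng.uniform(3.0, 6.0))
            elif mode == 1:                                # bad exposure + defocus
                scale = rng.choice([rng.uniform(0.1, 0.3), rng.uniform(2.5, 4.0)])
                pixels = _apply_nuisance(img, rot, scale, rng.uniform(1.0, 2.0))
            else:                                          # occlusion + defocus
                pixels = _apply_nuisance(img, rot, 1.0, 0.0).copy()
                r0 = int(rng.integers(0, pixels.shape[0] // 2))
                c0 = int(rng.integers(0, pixels.shape[1] // 2))
                pixels[r0:r0 + pixels.shape[0] // 2,
                       c0:c0 + pixels.shape[1] // 2] = 0.0
                pixels = ndimage.gaussian_filter(
                    pixels, sigma=(rng.uniform(1.0, 2.0),) * 2 + (0.0,))
            label = "bad"
        corpus.append(FundusImage(
            pixels=np.round(pixels).astype(np.uint8),
            subject_id=subj.id, eye="left", quality_label=label,
        ))
    return corpus
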