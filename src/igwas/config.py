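"""Configuration objects for the simulation and training stages.

All randomness in the package flows from a single master seed through
named substreams (see :func:`substream`), so every stage is a pure
function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "ArcFaceConfig",
    "QualityConfig",
    "RunConfig",
    "substream",
]


def substream(seed: int, *names) -> np.random.Generator:
    """Derive an independent, reproducible random stream from a master seed.

    Parameters
    ----------
    seed
        Master seed.
    names
        Any hashable labels (strings, ints) identifying the substream.
    """
    import zlib

    # zlib.crc32 is stable across processes (str hash() is salted)
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=tuple(
        zlib.crc32(repr(n).encode()) for n in names
    ))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Parameters of the genotype-to-image simulator.

    Attributes
    ----------
    n_subjects, n_snps
        Cohort and panel sizes.
    ld_block_size
        SNPs per LD block; blocks are mutually independent.
    within_block_r
        Latent (Gaussian-copula) correlation between adjacent SNPs inside
        a block, AR(1) decay with distance in SNPs. In [0, 1).
    maf_range
        Minor allele frequencies are drawn uniformly from this interval,
        a sub-interval of (0, 0.5].
    causal_map
        List of ``(snp_index, trait_name, variance_explained)`` triples;
        trait_name is ``"pigment"`` or ``"vessel"``.
    image_size
        (rows, cols) of rendered images. 128x128 by default: full-scale
        fundus photographs are 1536x2048 but the renderer and encoder run
        at desk scale; windows defined on the full-scale grid are mapped
        fractionally.
    n_chromosomes
        Blocks are assigned contiguously to this many autosome labels.
    pos_stride
        Base-pair spacing between consecutive SNPs (1-based positions
        restart on each chromosome) so distance-based locus merging is
        exercised.
    rotation_max_deg, illum_sd, blur_sigma
        Per-image nuisance: rotation is uniform in +/-rotation_max_deg,
        illumination is a multiplicative scale ~ N(1, illum_sd^2), blur
        is a Gaussian with this sigma (0 disables). Setting all three to
        zero makes the right image exactly the mirrored left image.
    """

    n_subjects: int = 200
    n_snps: int = 200
    ld_block_size: int = 10
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    causal_map: Sequence[tuple[int, str, float]] = field(default_factory=list)
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0
    n_chromosomes: int = 2
    pos_stride: int = 5_000
    age_range: tuple[float, float] = (40.0, 70.0)
    rotation_max_deg: float = 15.0
    illum_sd: float = 0.01
    blur_sigma: float = 0.0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0 or self.ld_block_size <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be inside (0, 0.5]")
        budget: dict[str, float] = {}
        for idx, trait, ve in self.causal_map:
            if not (0 <= idx < self.n_snps):
                raise ValueError(f"causal index {idx} out of range")
            if not (0.0 <= ve < 1.0):
                raise ValueError("variance_explained must lie in [0, 1)")
            budget[trait] = budget.get(trait, 0.0) + ve
        for trait, tot in budget.items():
            if tot >= 1.0:
                raise ValueError(
                    f"variance budget for trait {trait!r} is {tot} >= 1"
                )
        if self.n_chromosomes <= 0:
            raise ValueError("n_chromosomes must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["causal_map"] = [list(t) for t in self.causal_map]
        return d


@dataclass
class ArcFaceConfig:
    """Hyperparameters of the additive-angular-margin contrastive phenotyper.

    ``s`` is the inverse-temperature scale on cosine logits and ``m`` the
    angular margin (radians) added to the target angle. The auxiliary
    disease-grade head is weighted 1:``aux_weight_ratio`` relative to the
    contrastive loss.
    """

    d: int = 128
    s: float = 30.0
    m: float = 0.5
    aux_weight_ratio: float = 10.0
    lr: float = 1e-4
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    input_hw: int = 32  # images are block-averaged to this square size
    hidden: int = 64
    val_fraction: float = 0.2
    rotation_max_deg: float = 15.0

    def validate(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if not (0.0 <= self.m < np.pi):
            raise ValueError("margin m must lie in [0, pi)")


@dataclass
class QualityConfig:
    """Hyperparameters of the image-quality scorer."""

    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    input_hw: int = 32
    hidden: int = 32
    patience: int = 5
    val_fraction: float = 0.2


@dataclass
class RunConfig:
    """Nested configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    arcface: ArcFaceConfig = field(default_factory=ArcFaceConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    seed: int = 0
    out_dir: str = "igwas_run"
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "simulate": True,
        "quality": True,
        "phenotyper": True,
        "embed": True,
        "colors": True,
        "gwas": True,
        "intersect": True,
        "clump": True,
        "ldsc": True,
    })
    # analysis constants, surfaced with their customary defaults
    quality_keep_threshold: float = 0.5
    quality_top_floor: float = 0.95
    gwas_threshold: float = 5e-8
    clump_r2: float = 0.2
    clump_dist_bp: int = 250_000
    maf_filter: float = 0.01
    n_pcs: int = 10
    n_good_quality: int = 100
    n_bad_quality: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, klass in (("sim", SimConfig), ("arcface", ArcFaceConfig),
                               ("quality", QualityConfig)):
            if section in raw:
                setattr(cfg, section, klass(**raw.pop(section)))
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "arcface": asdict(self.arcface),
            "quality": asdict(self.quality),
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "stages": dict(self.stages),
            "quality_keep_threshold": self.quality_keep_threshold,
            "quality_top_floor": self.quality_top_floor,
            "gwas_threshold": self.gwas_threshold,
            "clump_r2": self.clump_r2,
            "clump_dist_bp": self.clump_dist_bp,
            "maf_filter": self.maf_filter,
            "n_pcs": self.n_pcs,
            "n_good_quality": self.n_good_quality,
            "n_bad_quality": self.n_bad_quality,
        }
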