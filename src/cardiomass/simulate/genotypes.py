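"""Synthetic genotype panels with controllable allele frequency, LD and effects.

Dosages are sums of two haplotypes. Inside a declared LD block every
haplotype copies a latent founder allele with probability sqrt(r), otherwise
draws fresh at the block's allele frequency; this makes every pairwise
dosage correlation in the block equal r in expectation while preserving the
marginal frequency. Variants outside blocks are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class LDBlock:
    start: int
    size: int
    r: float


@dataclass(frozen=True)
class GenoSimSpec:
    """Generative settings for a dosage panel."""

    n_subjects: int = 5000
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: tuple[LDBlock, ...] = ()
    causal_betas: dict[int, float] = field(default_factory=dict)
    pos_step: int = 100_000
    chrom: int = 1
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0.01 <= lo <= hi <= 0.5")
        for b in self.ld_blocks:
            if not 0.0 <= b.r < 1.0:
                raise ConfigurationError(f"LD r target must be in [0, 1), got {b.r}")
            if b.start < 0 or b.start + b.size > self.n_variants:
                raise ConfigurationError("LD block exceeds the variant range")
        for idx in self.causal_betas:
            if not 0 <= idx < self.n_variants:
                raise ConfigurationError(f"causal index {idx} out of range")


@dataclass
class GenotypePanel:
    """Subjects x variants dosage matrix plus variant metadata.

    ``variants`` columns: variant_id, chr, pos (1-based), ref, alt, maf, info.
    ``truth_betas`` carries the generative per-allele effects (zeros when a
    variant is non-causal); None for panels read from disk.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    truth_betas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ConfigurationError("dosage / metadata variant counts differ")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            dosages=self.dosages[:, keep],
            variants=self.variants.iloc[keep].reset_index(drop=True),
            truth_betas=None if self.truth_betas is None else self.truth_betas[keep],
        )


def generate_genotypes(spec: GenoSimSpec) -> GenotypePanel:
    """Simulate a dosage panel per the spec; deterministic under its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.n_variants

    maf = rng.uniform(*spec.maf_range, m)
    in_block = np.full(m, -1)
    for bi, b in enumerate(spec.ld_blocks):
        sl = slice(b.start, b.start + b.size)
        if (in_block[sl] != -1).any():
            raise ConfigurationError("overlapping LD blocks")
        in_block[sl] = bi
        maf[sl] = maf[b.start]  # the copy model needs a shared block frequency

    haps = np.empty((2, n, m), dtype=np.int8)
    for h in range(2):
        fresh = (rng.random((n, m)) < maf).astype(np.int8)
        haps[h] = fresh
        for b in spec.ld_blocks:
            sl = slice(b.start, b.start + b.size)
            founder = (rng.random(n) < maf[b.start]).astype(np.int8)
            copy = rng.random((n, b.size)) < np.sqrt(b.r)
            haps[h, :, sl] = np.where(copy, founder[:, None], fresh[:, sl])
    dosages = (haps[0] + haps[1]).astype(float)

    ref_i = rng.integers(0, 4, m)
    alt_i = (ref_i + rng.integers(1, 4, m)) % 4
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{spec.chrom}_{i:06d}" for i in range(m)],
            "chr": spec.chrom,
            "pos": np.arange(1, m + 1, dtype=np.int64) * spec.pos_step,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "maf": maf,
            "info": np.ones(m),
        }
    )
    betas = np.zeros(m)
    for idx, beta in spec.causal_betas.items():
        betas[idx] = beta
    return GenotypePanel(dosages=dosages, variants=variants, truth_betas=betas)


def simulate_quantitative_phenotype(
    panel: GenotypePanel, noise_sd: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Phenotype = dosages @ truth betas + Gaussian noise."""
    if panel.truth_betas is None:
        raise ConfigurationError("panel carries no truth betas")
    rng = np.random.default_rng(seed)
    return panel.dosages @ panel.truth_betas + rng.normal(0.0, noise_sd, panel.n_subjects)


# ---------------------------------------------------------------------------
# Text serialisation (TSV): variant_id, chr, pos, ref, alt, maf, info,
# then one dosage column per subject.


def write_genotypes_tsv(panel: GenotypePanel, path, subject_ids=None) -> None:
    subject_ids = subject_ids or [f"S{i:06d}" for i in range(panel.n_subjects)]
    df = panel.variants.copy()
    dos = pd.DataFrame(panel.dosages.T, columns=list(subject_ids))
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_genotypes_tsv(path) -> tuple[GenotypePanel, list[str]]:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chr", "pos", "ref", "alt", "maf", "info"]
    subject_ids = [c for c in df.columns if c not in meta_cols]
    panel = GenotypePanel(
        dosages=df[subject_ids].to_numpy(dtype=float).T,
        variants=df[meta_cols].copy(),
    )
    return panel, subject_ids
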