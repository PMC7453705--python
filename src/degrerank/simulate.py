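"""Synthetic log2-expression cohorts with known ground truth.

The generator emulates the statistical shape of a normalized microarray
cohort for a rare-outcome study: per-gene Gaussian log2 expression
around a common baseline, a minority positive class (default 28 of 199
samples), and informative gene *blocks* — one latent factor per block
produces strong within-block correlation, and every gene of a block
carries the same class mean shift, mimicking tightly co-expressed
differential clusters.  Background genes carry no signal and are
mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, PhenotypeLabels

__all__ = ["SyntheticConfig", "simulate_expression", "permute_labels"]

POSITIVE_LABEL = "non_survivor"
NEGATIVE_LABEL = "survivor"


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-scale defaults mirror a 199-sample study with 28 events and
    a 10k-gene transcriptome.  effect_size is the class mean shift in
    within-class SD units on the log2 scale; within_block_correlation is
    the target pairwise Pearson correlation of genes sharing a block;
    direction_mix is the fraction of informative blocks that are
    down-regulated in the positive class."""

    n_samples: int = 199
    n_positive: int = 28
    n_genes: int = 10_000
    n_blocks: int = 5
    block_size: int = 5
    effect_size: float = 2.0
    within_block_correlation: float = 0.9
    baseline_mean: float = 6.0
    noise_sd: float = 1.0
    direction_mix: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_positive < self.n_samples:
            raise ValueError("need 0 < n_positive < n_samples")
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("informative blocks exceed the number of genes")
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if not 0 <= self.direction_mix <= 1:
            raise ValueError("direction_mix must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_expression(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, PhenotypeLabels, pd.DataFrame]:
    """Draw one cohort; fully deterministic given cfg.seed.

    Returns the expression matrix (genes x samples), the phenotype
    labels (positive class = the minority event group) and a ground
    truth table with columns gene_id, block, causal, direction, effect.
    Block genes are x = sqrt(rho) * z_block + sqrt(1 - rho) * e, scaled
    to noise_sd, so every within-block pair has correlation rho; the
    first gene of each block is flagged causal (the block's
    representative), though all genes of a block are genuinely
    differential with the same shift.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_genes
    gene_ids = tuple(f"G{i + 1:05d}" for i in range(p))
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n))

    pos_idx = rng.choice(n, size=cfg.n_positive, replace=False)
    is_pos = np.zeros(n, dtype=bool)
    is_pos[pos_idx] = True
    labels = tuple(POSITIVE_LABEL if flag else NEGATIVE_LABEL for flag in is_pos)

    values = cfg.baseline_mean + cfg.noise_sd * rng.standard_normal((p, n))

    rho = cfg.within_block_correlation
    n_down = int(round(cfg.direction_mix * cfg.n_blocks))
    block_col = np.full(p, -1)
    causal = np.zeros(p, dtype=bool)
    direction = np.zeros(p, dtype=int)
    effect = np.zeros(p)
    shift = cfg.effect_size * cfg.noise_sd
    for b in range(cfg.n_blocks):
        rows = np.arange(b * cfg.block_size, (b + 1) * cfg.block_size)
        z = rng.standard_normal(n)
        eps = rng.standard_normal((len(rows), n))
        latent = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
        sign = -1 if b < n_down else 1
        values[rows] = cfg.baseline_mean + cfg.noise_sd * latent
        values[rows[:, None], np.where(is_pos)[0][None, :]] += sign * shift
        block_col[rows] = b
        causal[rows[0]] = True
        direction[rows] = sign
        effect[rows] = cfg.effect_size

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "block": block_col,
            "causal": causal,
            "direction": direction,
            "effect": effect,
        }
    )
    m = ExpressionMatrix(gene_ids, sample_ids, values)
    y = PhenotypeLabels(sample_ids, labels, POSITIVE_LABEL)
    return m, y, truth


def permute_labels(y: PhenotypeLabels, seed: int) -> PhenotypeLabels:
    """Uniformly random relabeling of the samples; class counts are
    preserved (the null-model fixture)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y.labels))
    return PhenotypeLabels(
        y.sample_ids, tuple(y.labels[i] for i in perm), y.positive_class
    )
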