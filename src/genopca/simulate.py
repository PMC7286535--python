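"""Structured genotype simulation under a divergence (drift) model.

A single ancestral population splits into q subpopulations. For SNP j the
ancestral allele frequency is f_j0 ~ Uniform(0.05, 0.95); each subpopulation
drifts independently,

    f_jl ~ Normal(f_j0, f_j0 (1 - f_j0) Fst),   clipped to {0, 1} outside [0, 1],

and a diploid individual in population l draws its genotype at SNP j from
Binomial(2, f_jl). SNPs are unlinked, so Fst fully parameterizes the strength
of structure; the top q-1 PCs of such a panel separate the populations once
n * Fst is large enough relative to the Marchenko-Pastur noise level.

One seeded generator drives everything in a fixed documented order
(ancestral frequencies, then the m x q drifted frequency matrix, then the
genotype blocks population by population), so fixtures are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationSpec",
    "simulate_genotypes",
    "plant_rank_k_matrix",
    "simulate_to_plink",
]

_CHUNK_SNPS = 4096  # genotype draws are chunked to cap temporary memory


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated panel."""

    m: int  # SNP count
    n: int  # sample count
    q: int  # subpopulation count
    fst: float  # drift parameter in [0, 1)
    seed: int = 0
    sample_assignment: np.ndarray | None = None  # length-n population labels

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.q < 1:
            raise ParameterError("m, n, q must all be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ParameterError(f"fst must lie in [0, 1), got {self.fst}")
        if self.sample_assignment is not None:
            labels = np.asarray(self.sample_assignment)
            if labels.shape != (self.n,):
                raise ParameterError("sample_assignment must have length n")
            if labels.max() >= self.q or labels.min() < 0:
                raise ParameterError("sample_assignment labels must lie in [0, q)")

    def labels(self) -> np.ndarray:
        """Population label per sample; default equal-size contiguous blocks
        with the remainder going to the last population."""
        if self.sample_assignment is not None:
            return np.asarray(self.sample_assignment, dtype=np.intp)
        block = self.n // self.q
        labels = np.minimum(np.arange(self.n) // max(block, 1), self.q - 1)
        return labels.astype(np.intp)


def drift_frequencies(spec: SimulationSpec, rng: np.random.Generator) -> tuple:
    """Draw ancestral and per-population allele frequencies."""
    f0 = rng.uniform(0.05, 0.95, size=spec.m)
    sd = np.sqrt(f0 * (1.0 - f0) * spec.fst)
    freqs = f0[:, None] + sd[:, None] * rng.standard_normal((spec.m, spec.q))
    np.clip(freqs, 0.0, 1.0, out=freqs)
    return f0, freqs


def simulate_genotypes(
    spec: SimulationSpec,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Simulate a panel; returns (genotypes, population labels, true freqs).

    The returned matrix may contain SNPs that are monomorphic across the whole
    sample (clipping and finite sampling allow it); remove them with
    :func:`genopca.genotypes.drop_monomorphic` before PCA.
    """
    rng = np.random.default_rng(spec.seed)
    _, freqs = drift_frequencies(spec, rng)
    labels = spec.labels()
    values = np.empty((spec.m, spec.n), dtype=np.int8)
    pop_cols = [np.flatnonzero(labels == l) for l in range(spec.q)]
    for start in range(0, spec.m, _CHUNK_SNPS):
        stop = min(start + _CHUNK_SNPS, spec.m)
        for l, cols in enumerate(pop_cols):
            if cols.size == 0:
                continue
            block = rng.binomial(
                2, freqs[start:stop, l][:, None], size=(stop - start, cols.size)
            )
            values[start:stop, cols] = block.astype(np.int8)
    return GenotypeMatrix(values), labels, freqs


def plant_rank_k_matrix(
    m: int, n: int, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact rank-k matrix Y0 = C0 X0 with known orthonormal column space.

    Noiseless oracle for EM convergence tests: returns (Y0, C0) where C0 is an
    m x k orthonormal basis of Y0's column span.
    """
    if k > min(m, n):
        raise ParameterError(f"k={k} exceeds min(m, n)={min(m, n)}")
    rng = np.random.default_rng(seed)
    c0 = np.linalg.qr(rng.standard_normal((m, k)))[0]
    # distinct singular values keep the top-k subspace unambiguous
    sv = np.linspace(2.0, 1.0, k)
    x0 = sv[:, None] * rng.standard_normal((k, n))
    return c0 @ x0, c0


def simulate_to_plink(spec: SimulationSpec, prefix) -> tuple:
    """Write a simulated panel as PLINK .bed/.bim/.fam plus a .pop label file.

    The synthetic map places every SNP on chromosome "1" at 1 kb spacing.
    """
    from pathlib import Path

    from .genotypes import snp_metadata
    from .plink import write_plink

    geno, labels, freqs = simulate_genotypes(spec)
    meta = snp_metadata(
        geno,
        chrom=["1"] * spec.m,
        ids=[f"snp{j}" for j in range(spec.m)],
        pos=np.arange(spec.m, dtype=np.int64) * 1000 + 1,
    )
    sample_ids = [f"sample{i}" for i in range(spec.n)]
    write_plink(prefix, geno, meta, sample_ids)
    pop_path = Path(str(prefix) + ".pop")
    pop_path.write_text("\n".join(f"pop{l}" for l in labels) + "\n")
    return geno, labels, freqs
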