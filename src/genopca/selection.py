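"""PC-based selection scan: per-PC differentiation statistics and diagnostics.

Under the probabilistic PCA model a neutral SNP's standardized genotype
vector is a low-rank combination of the PCs plus isotropic noise, so the part
of it not explained by the PC scores, projected onto a score direction, is
Gaussian with a variance shared across SNPs. A SNP under selection is
differentiated along some axis of ancestry beyond what drift predicts, which
inflates that projection. For SNP j and PC k the statistic is

    d_jk^2 / sigma_k^2  ~  chi^2_1  under neutrality,

with sigma_k^2 the genome-wide sample variance of column k of d. Summing the
K per-PC statistics gives a combined chi^2_K statistic.

Projection convention: a least-squares residual against *all* K score
directions is orthogonal to every one of them, which would make d identically
zero; the operational statistic therefore residualizes each PC against the
other K-1 score directions only (leave-one-direction-out) and projects onto
the unit-normalized k-th score vector. When the score vectors are mutually
orthogonal — always true when they come from an SVD — this reduces to the
plain projection d_jk = y_j . x_hat_k, the classic PC differentiation
statistic. The literal all-directions residual is kept behind
``projection="full"`` for inspection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    DegenerateScanError,
    ParameterError,
)
from .genotypes import GenotypeMatrix, StandardizationParams, standardized_matrix

__all__ = [
    "residual_projections",
    "selection_statistics",
    "combined_statistic",
    "genomic_inflation",
    "significance_threshold",
    "cluster_loci",
    "region_freq_test",
    "SelectionScan",
    "SelectionScanResults",
]

_LN10 = np.log(10.0)


def _unit_scores(scores: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(scores, axis=1)
    if (norms == 0).any():
        raise ParameterError("a score vector is identically zero")
    return scores / norms[:, None]


def residual_projections(
    geno_scan: GenotypeMatrix,
    params_scan: StandardizationParams,
    scores: np.ndarray,
    projection: str = "loo",
    chunk: int = 4096,
) -> np.ndarray:
    """Project PC-unexplained SNP residuals onto each score direction.

    Parameters
    ----------
    geno_scan, params_scan
        The scan panel (possibly different from the PCA panel) and its own
        standardization; samples must match the score columns in order.
    scores : ndarray (K, n)
        PC score vectors (rows), e.g. ``PCAResults.scores``.
    projection : {"loo", "full"}
        "loo" residualizes PC k against the other K-1 directions (the
        operational statistic); "full" uses the all-directions residual,
        which is identically zero for orthogonal scores.

    Returns
    -------
    d : ndarray (m_scan, K)
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    kdim, n = scores.shape
    if n != geno_scan.n:
        raise AlignmentError(
            f"scan panel has {geno_scan.n} samples but scores cover {n}"
        )
    if projection not in ("loo", "full"):
        raise ParameterError(f"unknown projection {projection!r}")
    xhat = _unit_scores(scores)
    gram = xhat @ xhat.T

    d = np.empty((geno_scan.m, kdim), dtype=np.float64)
    for start in range(0, geno_scan.m, chunk):
        stop = min(start + chunk, geno_scan.m)
        sub = geno_scan.take_snps(np.arange(start, stop)) if stop - start < geno_scan.m else geno_scan
        y = standardized_matrix(sub, _slice_params(params_scan, start, stop))
        proj = y @ xhat.T  # (chunk, K) plain projections
        if projection == "full":
            # residual after regressing on all K directions, then onto x_hat_k
            beta = np.linalg.solve(gram, proj.T).T
            d[start:stop] = proj - beta @ gram
        else:
            for k in range(kdim):
                others = [t for t in range(kdim) if t != k]
                if not others:
                    d[start:stop, k] = proj[:, k]
                    continue
                g_oo = gram[np.ix_(others, others)]
                g_ok = gram[others, k]
                coef = np.linalg.solve(g_oo, g_ok)
                d[start:stop, k] = proj[:, k] - proj[:, others] @ coef
    return d


def _slice_params(params: StandardizationParams, start: int, stop: int):
    return StandardizationParams(
        mean=params.mean[start:stop],
        scale=params.scale[start:stop],
        rho=params.rho[start:stop],
    )


def selection_statistics(
    d: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-PC chi-square statistics from the projection matrix.

    Returns (sigma2, stats, pvalues): sigma2[k] is the sample variance of
    column k across SNPs (unbiased, ddof=1); stats[j, k] = d[j, k]^2 /
    sigma2[k] is chi^2_1 under neutrality.
    """
    d = np.atleast_2d(np.asarray(d, dtype=np.float64))
    if d.shape[0] < 2:
        raise ParameterError("need at least 2 SNPs to estimate the variance")
    sigma2 = d.var(axis=0, ddof=ddof)
    if (sigma2 <= 0).any():
        k = int(np.argmax(sigma2 <= 0))
        raise DegenerateScanError(f"projection column {k} has zero variance")
    statistics = d**2 / sigma2[None, :]
    pvalues = stats.chi2.sf(statistics, df=1)
    return sigma2, statistics, pvalues


def combined_statistic(per_pc_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum the per-PC chi^2_1 statistics into one chi^2_K statistic."""
    per_pc_stats = np.atleast_2d(np.asarray(per_pc_stats, dtype=np.float64))
    kdim = per_pc_stats.shape[1]
    combined = per_pc_stats.sum(axis=1)
    return combined, stats.chi2.sf(combined, df=kdim)


def log10_pvalues(statistics: np.ndarray, df: int) -> np.ndarray:
    """log10 of chi-square upper-tail p, computed in log space (no underflow)."""
    return stats.chi2.logsf(statistics, df=df) / _LN10


def genomic_inflation(statistics: np.ndarray, df: int = 1) -> float:
    """lambda_GC: median observed statistic over the null chi^2_df median."""
    statistics = np.asarray(statistics, dtype=np.float64)
    if statistics.size < 1:
        raise ParameterError("need at least one statistic")
    return float(np.median(statistics) / stats.chi2.ppf(0.5, df=df))


def significance_threshold(
    num_snps: int, num_tests_per_snp: int, alpha: float = 0.05
) -> float:
    """Bonferroni p-value threshold over SNPs x tests-per-SNP."""
    if num_snps < 1 or num_tests_per_snp < 1 or alpha <= 0:
        raise ParameterError("num_snps, num_tests_per_snp and alpha must be positive")
    return alpha / (num_tests_per_snp * num_snps)


def cluster_loci(hits: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy clustering of significant SNPs into windows around lead SNPs.

    ``hits`` needs columns chrom, id, pos, p. Repeatedly take the most
    significant unassigned SNP (ties broken by lower position, then
    chromosome label) as a lead and absorb unassigned SNPs on the same
    chromosome within +/- window_bp/2 (1-based inclusive).
    """
    required = {"chrom", "id", "pos", "p"}
    if not required.issubset(hits.columns):
        raise ParameterError(f"hits must have columns {sorted(required)}")
    half = window_bp // 2
    df = hits.reset_index(drop=True).copy()
    order = df.sort_values(["p", "pos", "chrom"], kind="mergesort").index
    assigned = np.zeros(len(df), dtype=bool)
    records = []
    for idx in order:
        if assigned[idx]:
            continue
        lead = df.loc[idx]
        lo, hi = int(lead["pos"]) - half, int(lead["pos"]) + half
        members = df.index[
            (~assigned)
            & (df["chrom"] == lead["chrom"])
            & (df["pos"] >= lo)
            & (df["pos"] <= hi)
        ]
        assigned[members] = True
        records.append(
            {
                "lead_id": lead["id"],
                "chrom": lead["chrom"],
                "lead_pos": int(lead["pos"]),
                "window_start": lo,
                "window_end": hi,
                "lead_p": float(lead["p"]),
                "n_members": int(len(members)),
                "member_ids": ",".join(df.loc[members, "id"].astype(str)),
            }
        )
    return pd.DataFrame.from_records(records)


def region_freq_test(
    genotypes: np.ndarray,
    region_labels: np.ndarray,
    missing_mask: np.ndarray | None = None,
    bonferroni_factor: int = 1,
) -> pd.DataFrame:
    """Two-tailed pooled two-proportion Z-test of each region vs all others.

    ``genotypes`` is one SNP's dosage vector; allele counts in each region are
    compared against the pooled complement. The Bonferroni factor (loci x
    regions in a multi-locus scan) is supplied by the caller.
    """
    g = np.asarray(genotypes, dtype=np.float64)
    labels = np.asarray(region_labels)
    if g.shape != labels.shape:
        raise AlignmentError("genotypes and region labels differ in length")
    called = np.ones_like(g, dtype=bool)
    if missing_mask is not None:
        called = ~np.asarray(missing_mask, dtype=bool)
    records = []
    total_alt = float(g[called].sum())
    total_n = float(2 * called.sum())
    for region in pd.unique(labels):
        in_r = (labels == region) & called
        n1 = 2.0 * in_r.sum()
        if n1 == 0:
            warnings.warn(f"region {region!r} has no called alleles; skipped", stacklevel=2)
            continue
        x1 = float(g[in_r].sum())
        n2 = total_n - n1
        x2 = total_alt - x1
        if n2 == 0:
            warnings.warn("only one region has called alleles", stacklevel=2)
            continue
        p1, p2 = x1 / n1, x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = 0.0 if se == 0 else (p1 - p2) / se
        p = 2.0 * stats.norm.sf(abs(z))
        records.append(
            {
                "region": region,
                "freq_region": p1,
                "freq_rest": p2,
                "z": z,
                "p": p,
                "p_bonferroni": min(1.0, p * bonferroni_factor),
            }
        )
    return pd.DataFrame.from_records(records)


class SelectionScan:
    """Model object for the PC-differentiation scan.

    Parameters
    ----------
    scores : ndarray (K, n) or PCAResults
        PC scores of the reference PCA (possibly computed on a pruned panel).
    geno_scan : GenotypeMatrix
        The scan panel; its samples must match the score columns in order.
    meta_scan : DataFrame, optional
        Per-SNP metadata (chrom, id, pos) used for reporting and clustering.
    """

    def __init__(self, scores, geno_scan: GenotypeMatrix, meta_scan=None, params=None):
        if hasattr(scores, "scores"):  # PCAResults
            scores = scores.scores
        self.scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
        self.geno_scan = geno_scan
        if self.scores.shape[1] != geno_scan.n:
            raise AlignmentError(
                f"scores cover {self.scores.shape[1]} samples, scan panel has {geno_scan.n}"
            )
        if params is None:
            from .genotypes import compute_standardization

            params = compute_standardization(geno_scan)
        self.params = params
        self.meta = meta_scan

    def fit(
        self,
        alpha: float = 0.05,
        tests_per_snp: int | None = None,
        window_bp: int = 1_000_000,
        projection: str = "loo",
    ) -> "SelectionScanResults":
        """Run the scan and return per-SNP statistics and significance calls.

        tests_per_snp defaults to K + 1 (the K per-PC tests plus the combined
        statistic), matching the usual Bonferroni accounting.
        """
        kdim = self.scores.shape[0]
        if tests_per_snp is None:
            tests_per_snp = kdim + 1
        d = residual_projections(self.geno_scan, self.params, self.scores, projection)
        sigma2, per_pc, pvals = selection_statistics(d)
        comb, comb_p = combined_statistic(per_pc)
        threshold = significance_threshold(self.geno_scan.m, tests_per_snp, alpha)
        return SelectionScanResults(
            self, d, sigma2, per_pc, pvals, comb, comb_p, threshold, window_bp
        )


class SelectionScanResults:
    """Scan output: statistics table, inflation diagnostics, locus clustering."""

    def __init__(self, model, d, sigma2, per_pc, pvals, comb, comb_p, threshold, window_bp):
        self.model = model
        self.projections = d
        self.sigma2 = sigma2
        self.per_pc_statistics = per_pc
        self.per_pc_pvalues = pvals
        self.combined_statistics = comb
        self.combined_pvalues = comb_p
        self.threshold = threshold
        self.window_bp = window_bp

    @property
    def k(self) -> int:
        return self.per_pc_statistics.shape[1]

    def genomic_inflation(self) -> dict[str, float]:
        """lambda_GC per PC and for the combined statistic."""
        out = {
            f"PC{i + 1}": genomic_inflation(self.per_pc_statistics[:, i], df=1)
            for i in range(self.k)
        }
        out["combined"] = genomic_inflation(self.combined_statistics, df=self.k)
        return out

    def table(self) -> pd.DataFrame:
        """Per-SNP table: statistics, p-values and significance flags."""
        meta = self.model.meta
        m = self.model.geno_scan.m
        base = {
            "chrom": meta["chrom"].to_numpy() if meta is not None else ["1"] * m,
            "id": meta["id"].to_numpy() if meta is not None else [f"snp{j}" for j in range(m)],
            "pos": meta["pos"].to_numpy() if meta is not None else np.arange(1, m + 1),
        }
        for i in range(self.k):
            base[f"stat_pc{i + 1}"] = self.per_pc_statistics[:, i]
            base[f"p_pc{i + 1}"] = self.per_pc_pvalues[:, i]
            base[f"log10p_pc{i + 1}"] = log10_pvalues(self.per_pc_statistics[:, i], df=1)
        base["stat_combined"] = self.combined_statistics
        base["p_combined"] = self.combined_pvalues
        base["log10p_combined"] = log10_pvalues(self.combined_statistics, df=self.k)
        df = pd.DataFrame(base)
        pcols = [f"p_pc{i + 1}" for i in range(self.k)] + ["p_combined"]
        df["significant"] = (df[pcols].to_numpy() < self.threshold).any(axis=1)
        return df

    def loci(self) -> pd.DataFrame:
        """Cluster the significant SNPs into non-overlapping lead windows."""
        df = self.table()
        hits = df[df["significant"]].copy()
        if hits.empty:
            return pd.DataFrame(
                columns=[
                    "lead_id", "chrom", "lead_pos", "window_start", "window_end",
                    "lead_p", "n_members", "member_ids",
                ]
            )
        pcols = [f"p_pc{i + 1}" for i in range(self.k)] + ["p_combined"]
        hits["p"] = hits[pcols].min(axis=1)
        return cluster_loci(hits[["chrom", "id", "pos", "p"]], self.window_bp)

    def to_tsv(self, path) -> None:
        self.table().to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        df = self.table()
        lam = self.genomic_inflation()
        lines = [
            "PC-differentiation selection scan",
            "=" * 40,
            f"scan SNPs: {len(df)}    PCs: {self.k}",
            f"Bonferroni threshold: {self.threshold:.4g}",
            f"significant SNPs: {int(df['significant'].sum())}",
            f"loci: {len(self.loci())}",
            "",
            "genomic inflation (lambda_GC):",
        ]
        for name, value in lam.items():
            lines.append(f"  {name:>9}: {value:.4f}")
        return "\n".join(lines)
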