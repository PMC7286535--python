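"""EM (alternating least squares) principal component analysis of genotypes.

The generative model is probabilistic PCA: each standardized genotype column
y_i = C x_i + eps_i with x_i ~ N(0, I_l) and isotropic Gaussian noise. In the
zero-noise limit the EM updates collapse to alternating least squares,

    E-step:  X = (C^T C)^-1 C^T Y
    M-step:  C = Y X^T (X X^T)^-1

whose fixed point spans the top-l principal subspace of Y. Y is never
materialized: with Y = diag(s)^-1 G - rho 1_n^T, each update needs one
product of the raw {0,1,2} matrix G with l thin vectors, done either through
the Mailman plan (sub-linear per column) or a dense BLAS path, plus rank-one
and sparse missing-cell corrections.

The public surface is both functional (:func:`e_step`, :func:`m_step`,
:func:`run_em`, :func:`finalize_pcs`) and object-based
(:class:`GenotypePCA` -> :class:`PCAResults`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from . import mailman
from .exceptions import ParameterError, RankError
from .genotypes import (
    GenotypeMatrix,
    StandardizationParams,
    _row_moments,
    compute_standardization,
)
from .metrics import mev

__all__ = [
    "ArrayPanel",
    "EmState",
    "PCResult",
    "e_step",
    "m_step",
    "run_em",
    "finalize_pcs",
    "GenotypePCA",
    "PCAResults",
]


# ---------------------------------------------------------------------------
# product backends


@dataclass
class ArrayPanel:
    """Adapter presenting an arbitrary real matrix to the EM machinery.

    Used with identity standardization (mean 0, scale 1) and the dense kernel
    to iterate on a matrix Y directly, e.g. the noiseless rank-k oracles of
    the convergence tests. Not valid for the Mailman kernel, which requires
    the {0,1,2} alphabet.
    """

    values: np.ndarray
    missing_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    missing_cols: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def identity_params(self) -> StandardizationParams:
        return StandardizationParams(
            mean=np.zeros(self.m), scale=np.ones(self.m), rho=np.zeros(self.m)
        )


class _MailmanBackend:
    """G products through one shared Mailman decomposition."""

    def __init__(self, geno: GenotypeMatrix, plan: mailman.MailmanPlan | None = None):
        self.plan = plan if plan is not None else mailman.decompose(geno.values)

    def g_dot(self, B: np.ndarray) -> np.ndarray:  # (n,k) -> (m,k)
        return mailman.multiply_right_multi(self.plan, B)

    def gt_dot(self, F: np.ndarray) -> np.ndarray:  # (m,k) -> (n,k)
        return mailman.multiply_left_multi(self.plan, F)


class _DenseBackend:
    """Naive dense products; reference path and small-problem fallback."""

    def __init__(self, geno: GenotypeMatrix):
        self.gf = geno.values.astype(np.float64)

    def g_dot(self, B: np.ndarray) -> np.ndarray:
        return self.gf @ B

    def gt_dot(self, F: np.ndarray) -> np.ndarray:
        return self.gf.T @ F


def _make_backend(geno, kernel, plan):
    if isinstance(plan, (_MailmanBackend, _DenseBackend)):
        return plan
    if kernel == "mailman":
        return _MailmanBackend(geno, plan)
    if kernel == "dense":
        return _DenseBackend(geno)
    raise ParameterError(f"unknown kernel {kernel!r}")


def _solve_gram(gram: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    """Solve gram @ out = rhs, raising RankError when (numerically) singular.

    The Gram matrices here are l x l with small l, so an eigenvalue check is
    cheap and far more reliable than trusting Cholesky to fail.
    """
    eigs = np.linalg.eigvalsh(gram)
    if eigs[0] <= 1e-12 * max(eigs[-1], 1e-300):
        raise RankError(f"{what} is numerically rank deficient")
    try:
        c, low = linalg.cho_factor(gram)
    except linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise RankError(f"{what} is singular: {err}") from None
    return linalg.cho_solve((c, low), rhs)


def _apply_to_y(A, backend, params, rows, cols):
    """A @ Y for an (l, m) matrix A, with Y implicit (missing cells -> 0)."""
    a_tilde = A / params.scale[None, :]
    out = backend.gt_dot(np.ascontiguousarray(a_tilde.T)).T
    out -= (A @ params.rho)[:, None]
    if rows.size:
        # inside the plan the missing cells hold raw 0, which the rho term
        # turned into -rho_j; add it back so they standardize to exactly 0
        corr = A[:, rows] * params.rho[rows]
        np.add.at(out.T, cols, corr.T)
    return np.ascontiguousarray(out)


def _y_apply(M, backend, params, rows, cols):
    """Y @ M for an (n, l) matrix M, with Y implicit (missing cells -> 0)."""
    out = backend.g_dot(M)
    out /= params.scale[:, None]
    out -= params.rho[:, None] * M.sum(axis=0)[None, :]
    if rows.size:
        np.add.at(out, rows, params.rho[rows, None] * M[cols, :])
    return out


# ---------------------------------------------------------------------------
# EM steps


def e_step(
    C: np.ndarray,
    geno: GenotypeMatrix,
    params: StandardizationParams,
    plan=None,
    kernel: str = "mailman",
) -> np.ndarray:
    """X = (C^T C)^-1 C^T Y without materializing Y."""
    backend = _make_backend(geno, kernel, plan)
    E = _solve_gram(C.T @ C, C.T, "C^T C")
    return _apply_to_y(E, backend, params, geno.missing_rows, geno.missing_cols)


def m_step(
    X: np.ndarray,
    geno: GenotypeMatrix,
    params: StandardizationParams,
    plan=None,
    kernel: str = "mailman",
) -> np.ndarray:
    """C = Y X^T (X X^T)^-1 without materializing Y."""
    backend = _make_backend(geno, kernel, plan)
    M = _solve_gram(X @ X.T, X, "X X^T").T  # n x l
    return _y_apply(M, backend, params, geno.missing_rows, geno.missing_cols)


@dataclass
class EmState:
    """State of the alternating-least-squares iteration."""

    C: np.ndarray  # m x l latent basis
    X: np.ndarray  # l x n latent scores
    n_iterations: int
    converged: bool
    k: int
    l: int
    seed: int
    mev_changes: list[float] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)


@dataclass
class PCResult:
    """Ordered orthonormal principal components extracted from an EmState."""

    loadings: np.ndarray  # m x k, orthonormal columns
    scores: np.ndarray  # k x n
    singular_values: np.ndarray  # length k, descending

    def __post_init__(self) -> None:
        k = self.loadings.shape[1]
        if not np.allclose(self.loadings.T @ self.loadings, np.eye(k), atol=1e-8):
            raise RankError("loadings are not orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ParameterError("singular values must be nonincreasing")


def run_em(
    geno: GenotypeMatrix,
    k: int,
    l: int | None = None,
    max_iterations: int | None = None,
    seed: int = 0,
    convergence_tol: float = 1e-6,
    kernel: str = "mailman",
    params: StandardizationParams | None = None,
    plan=None,
    track_objective: bool = False,
) -> EmState:
    """Run the EM iteration from a seeded random start.

    Defaults encode standard practice for this estimator: l = 2k latent
    dimensions (early iterations of the extra directions stabilize the top k)
    and max_iterations = k, which already gives accurate subspaces across
    realistic divergence levels; convergence_tol stops earlier when the MEV
    between successive subspaces changes by less than the tolerance.
    """
    m, n = geno.m, geno.n
    if l is None:
        l = 2 * k
    if max_iterations is None:
        max_iterations = k
    if not (1 <= k <= l <= min(m, n)):
        raise ParameterError(f"need 1 <= k <= l <= min(m, n); got k={k}, l={l}")
    if max_iterations < 1:
        raise ParameterError("max_iterations must be >= 1")
    if params is None:
        params = compute_standardization(geno)
    backend = _make_backend(geno, kernel, plan)
    rows, cols = geno.missing_rows, geno.missing_cols

    if track_objective:
        if isinstance(geno, GenotypeMatrix):
            _, _, css = _row_moments(geno)
            y_sq = float((css / params.scale**2).sum())
        else:  # ArrayPanel with identity standardization
            y_sq = float((np.asarray(geno.values, dtype=np.float64) ** 2).sum())

    rng = np.random.default_rng(seed)
    C = rng.standard_normal((m, l))
    q_prev = np.linalg.qr(C)[0]
    X = None
    mev_changes: list[float] = []
    objective: list[float] = []
    converged = False
    it = 0
    while it < max_iterations:
        it += 1
        try:
            E = _solve_gram(C.T @ C, C.T, "C^T C")
            X = _apply_to_y(E, backend, params, rows, cols)
            M = _solve_gram(X @ X.T, X, "X X^T").T
        except RankError:
            # rank collapse of the iterate: re-randomize and continue
            warnings.warn("rank collapse during EM; re-randomizing basis", stacklevel=2)
            C = rng.standard_normal((m, l))
            q_prev = np.linalg.qr(C)[0]
            continue
        C = _y_apply(M, backend, params, rows, cols)
        if track_objective:
            # ||Y - CX||_F^2 at the current (C, X); one extra implicit product
            cty = _apply_to_y(np.ascontiguousarray(C.T), backend, params, rows, cols)
            objective.append(
                y_sq - 2.0 * float(np.sum(X * cty)) + float(np.sum((C.T @ C) * (X @ X.T)))
            )
        q_cur = np.linalg.qr(C)[0]
        change = 1.0 - mev(q_prev, q_cur)
        mev_changes.append(change)
        q_prev = q_cur
        if abs(change) < convergence_tol:
            converged = True
            break
    # refresh the scores against the final basis so (C, X) is self-consistent
    E = _solve_gram(C.T @ C, C.T, "C^T C")
    X = _apply_to_y(E, backend, params, rows, cols)
    return EmState(
        C=C,
        X=X,
        n_iterations=it,
        converged=converged,
        k=k,
        l=l,
        seed=seed,
        mev_changes=mev_changes,
        objective_history=objective,
    )


def finalize_pcs(
    state: EmState,
    geno: GenotypeMatrix,
    params: StandardizationParams,
    k: int | None = None,
    plan=None,
    kernel: str = "mailman",
) -> PCResult:
    """Extract ordered orthonormal PCs from the converged latent basis.

    C spans (approximately) the top-l principal subspace but its columns are
    neither orthonormal nor ordered. Orthonormalize C -> Q, project the data
    onto it (B = Q^T Y, an l x n matrix computed implicitly), take the small
    SVD B = U S V^T, and rotate: loadings = Q U[:, :k], scores = S V^T. Signs
    are fixed so each loading's largest-magnitude entry is positive.
    """
    if k is None:
        k = state.k
    if k > state.l:
        raise ParameterError(f"k={k} exceeds the fitted latent dimension l={state.l}")
    backend = _make_backend(geno, kernel, plan)
    q = np.linalg.qr(state.C)[0]
    b = _apply_to_y(
        np.ascontiguousarray(q.T), backend, params, geno.missing_rows, geno.missing_cols
    )
    u, s, vt = np.linalg.svd(b, full_matrices=False)
    loadings = q @ u[:, :k]
    scores = s[:k, None] * vt[:k, :]
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return PCResult(
        loadings=loadings * flip[None, :],
        scores=scores * flip[:, None],
        singular_values=s[:k],
    )


# ---------------------------------------------------------------------------
# model / results objects


class GenotypePCA:
    """Principal component model of a genotype panel.

    Parameters
    ----------
    genotypes : GenotypeMatrix or array-like of {0,1,2}
        The panel; zero-variance SNPs must already be removed (see
        :func:`genopca.genotypes.drop_monomorphic` / :func:`qc_filter`).
    k : int
        Number of principal components to report.
    l : int, optional
        Latent dimension of the EM iteration; defaults to 2k.
    scale_mode : {"norm", "sd"}
        Row-scaling convention (unit row norm, or sd * sqrt(n)).

    Examples
    --------
    >>> model = GenotypePCA(geno, k=5)            # doctest: +SKIP
    >>> res = model.fit(seed=1)                   # doctest: +SKIP
    >>> res.scores.shape                          # doctest: +SKIP
    (5, 10000)
    """

    def __init__(
        self,
        genotypes,
        k: int = 10,
        l: int | None = None,
        scale_mode: str = "norm",
        snp_ids=None,
        sample_ids=None,
    ):
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(np.asarray(genotypes))
        self.genotypes = genotypes
        self.k = int(k)
        self.l = 2 * self.k if l is None else int(l)
        if not (1 <= self.k <= self.l <= min(genotypes.m, genotypes.n)):
            raise ParameterError(
                f"need 1 <= k <= l <= min(m, n); got k={self.k}, l={self.l}"
            )
        self.scale_mode = scale_mode
        self.params = compute_standardization(genotypes, scale_mode=scale_mode)
        self.snp_ids = list(snp_ids) if snp_ids is not None else None
        self.sample_ids = list(sample_ids) if sample_ids is not None else None

    @classmethod
    def from_plink(cls, prefix, k: int = 10, l: int | None = None, **kwargs):
        """Build the model straight from a PLINK .bed/.bim/.fam trio."""
        from .plink import read_plink

        geno, meta, samples = read_plink(prefix)
        from .genotypes import drop_monomorphic

        geno, meta = drop_monomorphic(geno, meta)
        return cls(
            geno, k=k, l=l, snp_ids=meta["id"].tolist(), sample_ids=samples, **kwargs
        )

    def fit(
        self,
        max_iterations: int | None = None,
        tol: float = 1e-6,
        seed: int = 0,
        kernel: str = "mailman",
        track_objective: bool = False,
    ) -> "PCAResults":
        """Run the EM iteration and return a results object."""
        backend = _make_backend(self.genotypes, kernel, None)
        state = run_em(
            self.genotypes,
            self.k,
            l=self.l,
            max_iterations=max_iterations,
            seed=seed,
            convergence_tol=tol,
            params=self.params,
            plan=backend,
            track_objective=track_objective,
        )
        pcs = finalize_pcs(state, self.genotypes, self.params, self.k, plan=backend)
        return PCAResults(self, state, pcs)


class PCAResults:
    """Fitted principal components plus fit diagnostics.

    Attributes
    ----------
    loadings : ndarray (m, k)
        Orthonormal SNP loadings (left singular vectors of Y).
    scores : ndarray (k, n)
        Per-sample PC scores (singular value times right singular vector).
    singular_values : ndarray (k,)
    """

    def __init__(self, model: GenotypePCA, state: EmState, pcs: PCResult):
        self.model = model
        self.state = state
        self.loadings = pcs.loadings
        self.scores = pcs.scores
        self.singular_values = pcs.singular_values

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def explained_variance_ratio(self) -> np.ndarray:
        """Share of total standardized variance captured by each PC."""
        called, _, css = _row_moments(self.model.genotypes)
        total = float((css / self.model.params.scale**2).sum())
        return self.singular_values**2 / total

    def mev(self, reference: np.ndarray) -> float:
        """Subspace overlap with a reference set of orthonormal loadings."""
        return mev(reference, self.loadings, orthonormalize=True)

    def scores_frame(self) -> pd.DataFrame:
        ids = self.model.sample_ids or [f"sample{i}" for i in range(self.scores.shape[1])]
        cols = {f"PC{i + 1}": self.scores[i] for i in range(self.k)}
        return pd.DataFrame({"iid": ids, **cols})

    def loadings_frame(self) -> pd.DataFrame:
        ids = self.model.snp_ids or [f"snp{j}" for j in range(self.loadings.shape[0])]
        cols = {f"PC{i + 1}": self.loadings[:, i] for i in range(self.k)}
        return pd.DataFrame({"id": ids, **cols})

    def save_scores(self, path) -> None:
        """Whitespace-delimited text: sample id then the k PC scores."""
        self.scores_frame().to_csv(path, sep=" ", index=False, header=False)

    def save_loadings(self, path) -> None:
        """Whitespace-delimited text: SNP id then the k loadings."""
        self.loadings_frame().to_csv(path, sep=" ", index=False, header=False)

    def plot_scores(self, i: int = 0, j: int = 1, labels=None, ax=None):
        """Scatter the samples on two PCs, optionally colored by labels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if labels is None:
            ax.scatter(self.scores[i], self.scores[j], s=4)
        else:
            labels = np.asarray(labels)
            for lab in np.unique(labels):
                mask = labels == lab
                ax.scatter(self.scores[i, mask], self.scores[j, mask], s=4, label=str(lab))
            ax.legend()
        ax.set_xlabel(f"PC{i + 1}")
        ax.set_ylabel(f"PC{j + 1}")
        return ax

    def summary(self) -> str:
        m, n = self.model.genotypes.m, self.model.genotypes.n
        evr = self.explained_variance_ratio()
        lines = [
            "Genotype PCA (EM / alternating least squares)",
            "=" * 46,
            f"SNPs: {m}    samples: {n}",
            f"k: {self.k}    l: {self.state.l}    iterations: {self.state.n_iterations}"
            f"    converged: {self.state.converged}",
            f"scale convention: {self.model.scale_mode}",
            "",
            f"{'PC':>4} {'sing. value':>14} {'var. explained':>15}",
        ]
        for i in range(self.k):
            lines.append(f"{i + 1:>4} {self.singular_values[i]:>14.6g} {evr[i]:>15.4%}")
        return "\n".join(lines)
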