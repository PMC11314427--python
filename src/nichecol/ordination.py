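"""Ordination and permutation-based inference on distance matrices.

All permutation tests share the conventions: the observed statistic is
computed once on the original labels; the null distribution comes from
random relabelings drawn from a seeded generator; the p-value is
``(1 + #{perm >= obs}) / (1 + n_perm)`` so it is never zero and is exactly
reproducible given (matrix, labels, seed, n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import rankdata

from .diversity import DistanceMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationTest:
    name: str
    statistic: float
    n_permutations: int
    seed: int
    pvalue: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "permutations": self.n_permutations,
            "seed": self.seed,
            "pvalue": self.pvalue,
            **self.extras,
        }


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates on ordered axes plus the eigenvalue report."""

    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per retained axis, fraction of positive sum
    negative_eigenvalues: np.ndarray  # the negative tail, for the report


def _as_square(dm) -> tuple[np.ndarray, list[str]]:
    if isinstance(dm, DistanceMatrix):
        return dm.matrix, dm.samples
    arr = np.asarray(dm, float)
    return arr, [str(i) for i in range(arr.shape[0])]


def pcoa(dm, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Eigendecomposes ``-0.5 * J D^2 J`` (J the centering matrix), orders
    axes by decreasing eigenvalue, and scales coordinates by the square
    root of the eigenvalue. Negative eigenvalues (non-Euclidean input) are
    reported but neither corrected nor included in the percent-variance
    denominator.
    """
    D, samples = _as_square(dm)
    n = D.shape[0]
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        log.warning("n_axes=%d exceeds %d positive eigenvalues; truncated", n_axes, n_pos)
        n_axes = n_pos
    coords = evecs[:, :n_axes] * np.sqrt(evals[:n_axes])
    prop = evals[:n_axes] / evals[pos].sum() if n_pos else np.zeros(0)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=samples, columns=[f"PCo{i+1}" for i in range(n_axes)]
        ),
        eigenvalues=evals,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.where(labels == g)[0] for g in np.unique(labels)]


def _check_groups(groups: list[np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for idx in groups:
        if len(idx) < 2:
            raise ValueError(f"group of size 1 at indices {idx.tolist()}")


def _encode(labels: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(labels, return_inverse=True)
    return codes, int(codes.max()) + 1


def _perm_matrix(codes: np.ndarray, n_perm: int, rng) -> np.ndarray:
    return np.stack([rng.permutation(codes) for _ in range(n_perm)])


def _permanova_f_batch(d2: np.ndarray, lab: np.ndarray, a: int) -> np.ndarray:
    """Pseudo-F for each row of label codes ``lab`` (P x n)."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = np.zeros(lab.shape[0])
    for g in range(a):
        Z = (lab == g).astype(float)
        ng = Z[0].sum()
        ss_w += np.einsum("pi,ij,pj->p", Z, d2, Z) / (2.0 * ng)
    ss_a = ss_t - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_a / (a - 1)) / (ss_w / (n - a))
    f[ss_w <= 0] = np.where(ss_a[ss_w <= 0] > 0, np.inf, np.nan)
    return f


def permanova(dm, labels, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """One-way PERMANOVA pseudo-F with a label-permutation p-value.

    The pseudo-F follows Anderson's sums-of-squared-distances formulation;
    a degenerate all-zero matrix yields a NaN statistic flagged in extras.
    """
    D, _ = _as_square(dm)
    labels = np.asarray(labels)
    n = D.shape[0]
    _check_groups(_group_indices(labels))
    codes, a = _encode(labels)
    d2 = D**2
    obs = float(_permanova_f_batch(d2, codes[np.newaxis, :], a)[0])
    if not np.isfinite(obs):
        log.warning("PERMANOVA degenerate (zero within-group variance)")
        return PermutationTest("PERMANOVA", obs, n_perm, seed, np.nan,
                               {"degenerate": True})
    rng = np.random.default_rng(seed)
    f_null = _permanova_f_batch(d2, _perm_matrix(codes, n_perm, rng), a)
    p = (1 + int((f_null >= obs).sum())) / (1 + n_perm)
    return PermutationTest("PERMANOVA", obs, n_perm, seed, p)


def anosim(dm, labels, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (M/2).

    Ranks are over all M = n(n-1)/2 pairwise distances (average ties); the
    p-value comes from label permutation.
    """
    D, _ = _as_square(dm)
    labels = np.asarray(labels)
    _check_groups(_group_indices(labels))
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(D[iu])
    m = ranks.size

    def r_stat(lab):  # lab: (P, n)
        within = lab[:, iu[0]] == lab[:, iu[1]]
        n_w = within.sum(axis=1)
        r_w = (ranks * within).sum(axis=1) / n_w
        r_b = (ranks * ~within).sum(axis=1) / (m - n_w)
        return (r_b - r_w) / (m / 2.0)

    codes, _ = _encode(labels)
    obs = float(r_stat(codes[np.newaxis, :])[0])
    rng = np.random.default_rng(seed)
    r_null = r_stat(_perm_matrix(codes, n_perm, rng))
    p = (1 + int((r_null >= obs).sum())) / (1 + n_perm)
    return PermutationTest("ANOSIM", obs, n_perm, seed, p)


def _anova_f_batch(z: np.ndarray, lab: np.ndarray, a: int) -> np.ndarray:
    """One-way ANOVA F of z for each row of label codes (P x n)."""
    n = z.size
    grand = z.mean()
    ss_tot = ((z - grand) ** 2).sum()
    ss_w = np.zeros(lab.shape[0])
    for g in range(a):
        Z = lab == g
        ng = Z[0].sum()
        means = (z * Z).sum(axis=1) / ng
        ss_w += (Z * (z[np.newaxis, :] - means[:, np.newaxis]) ** 2).sum(axis=1)
    ss_b = ss_tot - ss_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_b / (a - 1)) / (ss_w / (n - a))
    f[ss_w <= 0] = np.where(ss_b[ss_w <= 0] > 0, np.inf, 0.0)
    return f


def permdisp(dm, labels, n_perm: int = 999, seed: int = 0) -> PermutationTest:
    """Homogeneity of multivariate dispersion (PERMDISP).

    Samples are embedded by PCoA (positive axes); each sample's distance
    to its own group centroid (the group mean in the embedded space) is
    the dispersion residual; the observed statistic is the one-way ANOVA F
    over those residuals, and the p-value permutes group labels over them.
    """
    D, _ = _as_square(dm)
    labels = np.asarray(labels)
    groups = _group_indices(labels)
    _check_groups(groups)
    coords = pcoa(D).coordinates.to_numpy()
    z = np.empty(D.shape[0])
    for g in groups:
        cent = coords[g].mean(axis=0)
        z[g] = np.sqrt(((coords[g] - cent) ** 2).sum(axis=1))
    codes, a = _encode(labels)
    obs = float(_anova_f_batch(z, codes[np.newaxis, :], a)[0])
    rng = np.random.default_rng(seed)
    f_null = _anova_f_batch(z, _perm_matrix(codes, n_perm, rng), a)
    p = (1 + int((f_null >= obs).sum())) / (1 + n_perm)
    return PermutationTest("PERMDISP", float(obs), n_perm, seed, p,
                           {"mean_dispersion": {str(lab): float(z[g].mean())
                                                for lab, g in zip(np.unique(labels), groups)}})


def _transform_species(Y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "hellinger":
        tot = Y.sum(axis=1, keepdims=True)
        rel = np.divide(Y, tot, out=np.zeros_like(Y, dtype=float), where=tot > 0)
        return np.sqrt(rel)
    if transform == "chord":
        nrm = np.linalg.norm(Y, axis=1, keepdims=True)
        return np.divide(Y, nrm, out=np.zeros_like(Y, dtype=float), where=nrm > 0)
    if transform == "raw":
        return Y.astype(float)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class RdaResult:
    """Constrained ordination result with a permutation test."""

    ordination: OrdinationResult
    constrained_proportion: float
    total_variance: float
    constrained_variance: float
    unconstrained_variance: float
    env_scores: pd.DataFrame  # variable x axis correlations with site scores
    species_scores: pd.DataFrame
    test: PermutationTest
    dropped_variables: list[str]


def rda(
    counts: pd.DataFrame,
    env: pd.DataFrame,
    transform: str = "hellinger",
    n_perm: int = 999,
    seed: int = 0,
) -> RdaResult:
    """Redundancy analysis of community composition on environment.

    The species table (taxa x samples) is transformed (Hellinger by
    default), column-centered; environmental variables are z-scored and
    reduced to full column rank (collinear columns dropped with a
    warning). Fitted values from the least-squares projection onto the
    environmental space are decomposed by SVD into constrained axes; axis
    percentages are reported against total variance. The global test
    permutes rows of the response and compares the pseudo-F
    ``(SS_fit / m) / (SS_res / (n - m - 1))``.
    """
    samples = list(counts.columns)
    if list(env.index) != samples:
        env = env.loc[samples]
    n = len(samples)
    if env.shape[1] >= n:
        raise ValueError("need fewer environmental variables than samples")

    Y = _transform_species(counts.to_numpy(float).T, transform)
    Y = Y - Y.mean(axis=0)
    if not np.any(Y):
        log.warning("zero species variance: RDA degenerate")

    X = env.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    names = [v for v, k in zip(env.columns, keep) if k]
    dropped = [v for v, k in zip(env.columns, keep) if not k]

    # reduce to full column rank (pivoted QR)
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag[0] * 1e-10).sum()) if diag.size else 0
    keep_cols = sorted(piv[:rank])
    if rank < X.shape[1]:
        dropped += [names[j] for j in piv[rank:]]
        log.warning("collinear environmental variables dropped: %s",
                    [names[j] for j in piv[rank:]])
    X = X[:, keep_cols]
    names = [names[j] for j in keep_cols]
    m = X.shape[1]

    Q, _ = np.linalg.qr(X)
    Yhat = Q @ (Q.T @ Y)
    ss_tot = float((Y**2).sum())
    ss_fit = float((Yhat**2).sum())
    ss_res = ss_tot - ss_fit

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = S**2 / (n - 1)
    keep_ax = eig > max(eig[0], 1e-30) * 1e-12
    eig = eig[keep_ax]
    U, S, Vt = U[:, keep_ax], S[keep_ax], Vt[keep_ax]
    total_var = ss_tot / (n - 1)
    site = U * S
    axes = [f"RDA{i+1}" for i in range(len(eig))]

    with np.errstate(invalid="ignore"):
        env_sc = np.array([
            [np.corrcoef(X[:, j], site[:, ax])[0, 1] if site[:, ax].std() > 0 else 0.0
             for ax in range(len(eig))]
            for j in range(m)
        ])

    def pseudo_f(ssf, ssr):
        if ssr <= 0:
            return np.inf if ssf > 0 else np.nan
        return (ssf / m) / (ssr / (n - m - 1))

    obs = pseudo_f(ss_fit, ss_res)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        ssf = float(((Q.T @ Yp) ** 2).sum())
        if pseudo_f(ssf, float((Yp**2).sum()) - ssf) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)

    ord_res = OrdinationResult(
        coordinates=pd.DataFrame(site, index=samples, columns=axes),
        eigenvalues=eig,
        proportion_explained=eig / total_var if total_var > 0 else eig * np.nan,
        negative_eigenvalues=np.zeros(0),
    )
    return RdaResult(
        ordination=ord_res,
        constrained_proportion=ss_fit / ss_tot if ss_tot > 0 else np.nan,
        total_variance=total_var,
        constrained_variance=ss_fit / (n - 1),
        unconstrained_variance=ss_res / (n - 1),
        env_scores=pd.DataFrame(env_sc, index=names, columns=axes),
        species_scores=pd.DataFrame(Vt.T, index=counts.index, columns=axes),
        test=PermutationTest("RDA", float(obs), n_perm, seed, p,
                             {"constrained_proportion": ss_fit / ss_tot if ss_tot > 0 else np.nan}),
        dropped_variables=dropped,
    )
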