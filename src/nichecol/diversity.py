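"""Distances, normalized dissimilarities, alpha diversity and the
turnover/nestedness partition of beta diversity."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import AnalysisConfig, UNASSIGNED
from .data import Bundle

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a metric tag."""

    samples: list[str]
    matrix: np.ndarray  # square, zero diagonal
    metric: str

    @property
    def max(self) -> float:
        return float(self.matrix.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.samples, columns=self.samples)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def bray_curtis(bundle: Bundle, relative: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples on raw counts.

    ``d(x, y) = sum |xi - yi| / sum (xi + yi)``. With ``relative=True``
    counts are first converted to per-sample relative abundances. A pair of
    empty samples gets distance 0 with a warning.
    """
    X = bundle.counts.to_numpy(float).T  # samples x taxa
    if relative:
        tot = X.sum(axis=1, keepdims=True)
        X = np.divide(X, tot, out=np.zeros_like(X), where=tot > 0)
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="braycurtis")
    if np.isnan(d).any():
        log.warning("both-empty sample pair(s): Bray-Curtis set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(list(bundle.counts.columns), squareform(d), "bray")


def euclidean_env(env: pd.DataFrame, standardize: bool = True) -> DistanceMatrix:
    """Pairwise Euclidean distance between samples' environmental profiles.

    Variables are z-scored first by default (sample SD); zero-variance
    variables are dropped under standardization with a warning.
    """
    X = env.copy()
    if standardize:
        sd = X.std(ddof=1)
        dead = sd.index[(sd == 0) | sd.isna()].tolist()
        if dead:
            log.warning("zero-variance variables dropped before z-scoring: %s", dead)
            X = X.drop(columns=dead)
            sd = sd.drop(index=dead)
        X = (X - X.mean()) / sd
    d = squareform(pdist(X.to_numpy(float), metric="euclidean"))
    return DistanceMatrix(list(env.index), d, "euclidean")


def normalized_dissimilarity(
    dm: DistanceMatrix, partition, epsilon: float = 0.001
) -> pd.DataFrame:
    """Normalized dissimilarity Xd (Bray) or Ed (Euclidean) per stage.

    Every pairwise value is divided by the global maximum over the full
    dataset plus ``epsilon``; the stage value is the mean over within-stage
    pairs only. Returns a per-stage table with the mean and pair count.
    """
    gmax = dm.max
    denom = gmax + epsilon
    norm = dm.matrix / denom
    labels = partition.labels
    rows = []
    for stage in partition.stages:
        idx = [i for i, s in enumerate(dm.samples) if labels.get(s) == stage]
        if len(idx) < 2:
            log.warning("stage %s has < 2 samples; dissimilarity undefined", stage)
            continue
        sub = norm[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        rows.append((stage, float(sub[iu].mean()), len(iu[0])))
    return pd.DataFrame(rows, columns=["stage", "mean", "n_pairs"]).set_index("stage")


def _alpha_row(counts: np.ndarray) -> dict:
    counts = counts[counts > 0]
    sobs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    chao1 = sobs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = counts / counts.sum() if counts.sum() > 0 else counts
    h = float(-(p * np.log(p)).sum()) if sobs else 0.0
    j = h / np.log(sobs) if sobs >= 2 else np.nan
    return {"Sobs": sobs, "F1": f1, "F2": f2, "Chao1": chao1, "Shannon": h, "J": j}


def alpha_diversity(bundle: Bundle, level: str = "sample", partition=None) -> pd.DataFrame:
    """Richness, Chao1 (bias-corrected), Shannon H (natural log), and
    Pielou evenness J = H / ln(Sobs), per sample or per stage.

    Chao1 uses the bias-corrected estimator
    ``Sobs + F1 (F1 - 1) / (2 (F2 + 1))``; J is undefined (NaN, flagged in
    the log) when Sobs <= 1.
    """
    if level == "sample":
        rows = {
            s: _alpha_row(bundle.counts[s].to_numpy())
            for s in bundle.counts.columns
        }
    elif level == "stage":
        if partition is None:
            raise ValueError("stage-level alpha diversity needs a partition")
        rows = {}
        for stage in partition.stages:
            samples = [
                s for s in bundle.counts.columns
                if partition.labels.get(s) == stage
            ]
            if samples:
                rows[stage] = _alpha_row(bundle.counts[samples].sum(axis=1).to_numpy())
    else:
        raise ValueError(f"unknown level {level!r}")
    out = pd.DataFrame(rows).T
    if out["J"].isna().any():
        log.info("evenness undefined for %d unit(s) with Sobs <= 1", int(out["J"].isna().sum()))
    return out


def beta_pair(x: np.ndarray, y: np.ndarray) -> dict:
    """Pairwise Sorensen-family partition of one site pair.

    On presence-absence: shared species a, uniques b and c;
    ``beta_sor = (b + c) / (2a + b + c)``,
    ``beta_sim = min(b, c) / (a + min(b, c))`` (turnover),
    ``beta_sne = beta_sor - beta_sim`` (nestedness). Undefined (NaN) when
    both sites are empty.
    """
    px, py = x > 0, y > 0
    a = int((px & py).sum())
    b = int((px & ~py).sum())
    c = int((~px & py).sum())
    if a + b + c == 0:
        log.warning("beta partition undefined for a pair of empty sites")
        return {"a": a, "b": b, "c": c, "beta_sor": np.nan, "beta_sim": np.nan, "beta_sne": np.nan}
    sor = (b + c) / (2 * a + b + c)
    sim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
    return {"a": a, "b": b, "c": c, "beta_sor": sor, "beta_sim": sim, "beta_sne": sor - sim}


def beta_multisite(counts: pd.DataFrame) -> dict:
    """Baselga multi-site Sorensen partition over a set of sites (columns).

    ``beta_SIM = S_min / (S_shared + S_min)`` and
    ``beta_SOR = (S_min + S_max) / (2 S_shared + S_min + S_max)`` with
    ``S_shared = sum_i S_i - S_T``, ``S_min = sum_{i<j} min(b_ij, b_ji)``,
    ``S_max = sum_{i<j} max(b_ij, b_ji)``; ``beta_SNE`` is the difference.
    """
    pa = (counts.to_numpy() > 0)
    present = pa.any(axis=1)
    st = int(present.sum())
    si = pa.sum(axis=0)
    shared = int(si.sum()) - st
    n = pa.shape[1]
    smin = smax = 0
    for i in range(n):
        for j in range(i + 1, n):
            bij = int((pa[:, i] & ~pa[:, j]).sum())
            bji = int((~pa[:, i] & pa[:, j]).sum())
            smin += min(bij, bji)
            smax += max(bij, bji)
    if shared + smin == 0 and smax == 0:
        return {"beta_SOR": np.nan, "beta_SIM": np.nan, "beta_SNE": np.nan}
    sim = smin / (shared + smin) if (shared + smin) > 0 else 0.0
    sor = (smin + smax) / (2 * shared + smin + smax)
    return {"beta_SOR": sor, "beta_SIM": sim, "beta_SNE": sor - sim}


def beta_partition(bundle: Bundle, partition, scope: str = "multisite") -> pd.DataFrame:
    """Turnover/nestedness partition of beta diversity per stage.

    ``scope="multisite"`` applies Baselga's multi-site partition to each
    stage's samples and reports the turnover and nestedness shares of
    total beta; ``scope="pairwise"`` returns the long-form table of all
    within-stage pairs.
    """
    labels = partition.labels
    if scope == "pairwise":
        rows = []
        for stage in partition.stages:
            samples = [s for s in bundle.counts.columns if labels.get(s) == stage]
            for i in range(len(samples)):
                for j in range(i + 1, len(samples)):
                    r = beta_pair(
                        bundle.counts[samples[i]].to_numpy(),
                        bundle.counts[samples[j]].to_numpy(),
                    )
                    rows.append({"stage": stage, "site_i": samples[i], "site_j": samples[j], **r})
        return pd.DataFrame(rows)
    if scope == "multisite":
        rows = []
        for stage in partition.stages:
            samples = [s for s in bundle.counts.columns if labels.get(s) == stage]
            if len(samples) < 2:
                continue
            r = beta_multisite(bundle.counts[samples])
            tot = r["beta_SOR"]
            rows.append(
                {
                    "stage": stage,
                    **r,
                    "turnover_share": r["beta_SIM"] / tot if tot else np.nan,
                    "nestedness_share": r["beta_SNE"] / tot if tot else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("stage")
    raise ValueError(f"unknown scope {scope!r}")


def env_summary(env: pd.DataFrame, partition) -> pd.DataFrame:
    """Per-stage mean, sample SD and CV% = 100 * SD / mean per variable.

    CV% is flagged undefined (NaN) where the mean is zero; the SD of a
    single-sample stage is undefined.
    """
    labels = partition.labels
    rows = []
    for stage in partition.stages:
        samples = [s for s in env.index if labels.get(s) == stage]
        if not samples:
            continue
        sub = env.loc[samples]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if len(samples) < 2:
            log.warning("stage %s has a single sample; SD undefined", stage)
        cv = 100.0 * sd / mean.where(mean != 0, np.nan)
        for var in env.columns:
            rows.append((stage, var, mean[var], sd[var], cv[var]))
    return pd.DataFrame(rows, columns=["stage", "variable", "mean", "sd", "cv_pct"])
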