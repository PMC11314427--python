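"""Niche metrics for colonization communities.

Resource states are the samples of a colonization stage: each species'
utilization distribution is its count profile across that stage's samples,
normalized to sum to one. On that distribution the module computes, per
species,

* the dominance index ``Di = (Ni / N) * fi`` (relative abundance times
  occurrence frequency),
* Levins' standardized niche width ``Bi = 1 / (r * sum_j Pij**2)``, which
  runs from ``1/r`` for a single-sample specialist to ``1`` for a perfectly
  even generalist,
* Pianka's symmetric niche overlap
  ``Oik = sum_j Pij Pkj / sqrt(sum_j Pij**2 * sum_j Pkj**2)``,
* the resource-occupancy change ``dOi`` built from the directed
  (MacArthur-Levins) overlap ``Aik = sum_j Pij Pkj / sum_j Pkj**2`` — the
  share of species k's utilization captured by species i — as
  ``dOi = sum_{k != i} (Aik - Aki)``: resources i takes from others minus
  resources others take from i. The pairing makes ``sum_i dOi = 0``.
* the ecological response rate ``Ri = Bi * dOi`` (product mode; a ratio
  mode ``Bi / dOi`` is available but undefined where ``dOi = 0``).

Pairwise signed differences ``Bik = Bi - Bk``, ``dOik = dOi - dOk`` and
``Rik = Ri - Rk``, together with ``Oik``, form the three-way evaluation
framework used to compare stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .data import Bundle

log = logging.getLogger(__name__)


def utilization_profiles(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized utilization profiles Pij = nij / Ni.

    Every retained species must occur at least once in the stage; species
    absent from the stage must have been dropped beforehand.
    """
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        zero = totals.index[totals == 0].tolist()
        raise ValueError(f"species with zero stage total: {zero}")
    return counts.div(totals, axis=0)


def dominance_index(counts: pd.DataFrame) -> pd.DataFrame:
    """Dominance Di = (Ni/N) * fi and occurrence frequency fi per species."""
    N = counts.to_numpy().sum()
    if N == 0:
        raise ValueError("empty stage: grand total is zero")
    Ni = counts.sum(axis=1)
    fi = (counts > 0).mean(axis=1)
    return pd.DataFrame({"Di": (Ni / N) * fi, "fi": fi})


def classify_dominant(di: pd.Series, config: AnalysisConfig) -> pd.Series:
    """Dominant iff Di >= threshold; ties at the threshold are dominant."""
    return di >= config.dominance_threshold


def niche_width(profiles: pd.DataFrame) -> pd.Series:
    """Levins' standardized niche width Bi = 1 / (r * sum_j Pij^2)."""
    r = profiles.shape[1]
    ssq = (profiles**2).sum(axis=1)
    if (ssq == 0).any():
        raise ValueError("degenerate all-zero profile")
    return 1.0 / (r * ssq)


def pianka_overlap(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pianka overlap matrix with unit diagonal."""
    P = profiles.to_numpy(float)
    cross = P @ P.T
    ssq = np.einsum("ij,ij->i", P, P)
    O = cross / np.sqrt(np.outer(ssq, ssq))
    np.fill_diagonal(O, 1.0)
    return pd.DataFrame(O, index=profiles.index, columns=profiles.index)


def directed_overlap(profiles: pd.DataFrame) -> pd.DataFrame:
    """Directed overlap Aik = sum_j Pij Pkj / sum_j Pkj^2.

    Row i, column k: the share of k's utilization captured by i. The
    diagonal is identically 1.
    """
    P = profiles.to_numpy(float)
    cross = P @ P.T
    ssq = np.einsum("ij,ij->i", P, P)
    A = cross / ssq[np.newaxis, :]
    return pd.DataFrame(A, index=profiles.index, columns=profiles.index)


def delta_overlap(profiles: pd.DataFrame, mode: str = "directed") -> tuple[pd.Series, pd.DataFrame]:
    """Resource-occupancy change dOi and the directed matrix it came from.

    ``dOi = sum_{k != i} Aik - sum_{k != i} Aki``: what species i occupies
    from every other species minus what every other species occupies from
    i. The antisymmetric pairing guarantees ``sum_i dOi = 0`` exactly.
    """
    if mode != "directed":
        raise ValueError(f"unknown delta-overlap mode {mode!r}")
    A = directed_overlap(profiles)
    M = A.to_numpy()
    d = M.sum(axis=1) - M.sum(axis=0)  # diagonal cancels
    return pd.Series(d, index=profiles.index, name="dOi"), A


def ecological_response_rate(
    bi: pd.Series, doi: pd.Series, mode: str = "product"
) -> pd.Series:
    """Ri combining niche width and occupancy change.

    Product mode (default): Ri = Bi * dOi, defined everywhere and zero for
    species in occupancy balance. Ratio mode: Ri = Bi / dOi, recorded as
    missing (with a warning) where dOi = 0.
    """
    if mode == "product":
        return (bi * doi).rename("Ri")
    if mode == "ratio":
        out = bi / doi.replace(0.0, np.nan)
        if out.isna().any():
            log.warning(
                "Ri undefined (dOi = 0) for %d species in ratio mode",
                int(out.isna().sum()),
            )
        return out.rename("Ri")
    raise ValueError(f"unknown Ri mode {mode!r}")


def stage_niche_records(stage_bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """Full per-species niche record table for one stage.

    Columns: phylum, Di, fi, Bi, dOi, Ri, dominant.
    """
    counts = stage_bundle.counts
    prof = utilization_profiles(counts)
    rec = dominance_index(counts)
    rec["Bi"] = niche_width(prof)
    doi, _ = delta_overlap(prof, config.delta_o_mode)
    rec["dOi"] = doi
    rec["Ri"] = ecological_response_rate(rec["Bi"], rec["dOi"], config.ri_mode)
    rec["dominant"] = classify_dominant(rec["Di"], config)
    rec.insert(0, "phylum", stage_bundle.taxa.reindex(rec.index))
    rec.index.name = "species"
    return rec


def overlap_tables(stage_bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """Long-form pair table with Oik and both directions of Aik."""
    prof = utilization_profiles(stage_bundle.counts)
    O = pianka_overlap(prof)
    A = directed_overlap(prof)
    sp = list(prof.index)
    rows = []
    for a in range(len(sp)):
        for b in range(len(sp)):
            if a == b:
                continue
            rows.append(
                (sp[a], sp[b], O.iat[a, b], A.iat[a, b], A.iat[b, a])
            )
    return pd.DataFrame(rows, columns=["species_i", "species_k", "Oik", "Aik", "Aki"])


def pairwise_differences(records: pd.DataFrame, overlap: pd.DataFrame) -> pd.DataFrame:
    """All ordered species pairs with Bik, dOik, Rik and Pianka Oik.

    The signed differences are antisymmetric: Bik = -Bki etc. This is the
    export behind the three-way (Oik, Bik, Rik) evaluation framework.
    """
    sp = list(records.index)
    idx = {s: i for i, s in enumerate(sp)}
    B = records["Bi"].to_numpy()
    D = records["dOi"].to_numpy()
    R = records["Ri"].to_numpy()
    Om = overlap.to_numpy()
    rows = []
    for i in sp:
        for k in sp:
            if i == k:
                continue
            a, b = idx[i], idx[k]
            rows.append((i, k, B[a] - B[b], D[a] - D[b], R[a] - R[b], Om[a, b]))
    return pd.DataFrame(
        rows, columns=["species_i", "species_k", "Bik", "dOik", "Rik", "Oik"]
    )


def group_summary(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group means of Bi, dOi, Ri and dominant-vs-rest gap statistics.

    Returns a dict with

    * ``by_dominance``: means per dominance class,
    * ``by_phylum``: means per phylum x dominance class,
    * ``gaps``: mean(dominant) - mean(non-dominant) per metric, and each
      phylum's mean minus the mean of all other species; empty groups are
      omitted.
    """
    metrics = ["Bi", "dOi", "Ri"]
    by_dom = records.groupby("dominant")[metrics].mean()
    by_phy = records.groupby(["phylum", "dominant"])[metrics].mean()

    gaps = []
    if records["dominant"].any() and (~records["dominant"]).any():
        dom = records.loc[records["dominant"], metrics].mean()
        nod = records.loc[~records["dominant"], metrics].mean()
        for m in metrics:
            gaps.append(("dominant_minus_nondominant", m, dom[m] - nod[m]))
    else:
        log.info("dominance gap omitted: one class is empty")
    for phy in records["phylum"].dropna().unique():
        inside = records["phylum"] == phy
        if inside.all() or not inside.any():
            continue
        for m in metrics:
            gaps.append(
                (f"{phy}_minus_rest", m,
                 records.loc[inside, m].mean() - records.loc[~inside, m].mean())
            )
    gaps_df = pd.DataFrame(gaps, columns=["contrast", "metric", "gap"])
    return {"by_dominance": by_dom, "by_phylum": by_phy, "gaps": gaps_df}
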