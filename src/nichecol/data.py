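"""Data model and file I/O for colonization community datasets.

A dataset bundles four aligned tables:

* abundance counts (taxa x samples, non-negative integers),
* sample metadata (collection day, replicate),
* taxon info (phylum per species),
* optional environmental variables (samples x variables).

Taxa and samples are canonicalized to lexicographic order on load so that
downstream permutation seeds reproduce regardless of input file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig, UNASSIGNED

log = logging.getLogger(__name__)

PHYLA = (
    "Heterokontophyta",
    "Cyanobacteria",
    "Chlorophyta",
    "Charophyta",
    "Cryptista",
    "other",
)


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class Bundle:
    """Validated, aligned community dataset.

    Attributes
    ----------
    counts : DataFrame
        Taxa (rows) x samples (columns), non-negative integers.
    meta : DataFrame
        Indexed by sample id, columns ``day`` and ``replicate``.
    taxa : Series
        Phylum label per taxon id.
    env : DataFrame or None
        Samples x environmental variables.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxa: pd.Series
    env: pd.DataFrame | None = None

    # -- derived totals ------------------------------------------------
    @property
    def n_samples(self) -> int:
        """r, the number of samples (resource states) in scope."""
        return self.counts.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def species_totals(self) -> pd.Series:
        """Ni: total count of each species over the samples in scope."""
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        """N: total count over all species and samples."""
        return int(self.counts.to_numpy().sum())

    def drop_empty_taxa(self) -> "Bundle":
        keep = self.counts.sum(axis=1) > 0
        return replace(
            self, counts=self.counts.loc[keep], taxa=self.taxa.loc[keep.index[keep]]
        )

    def subset_samples(self, samples: list[str]) -> "Bundle":
        counts = self.counts[samples]
        env = self.env.loc[samples] if self.env is not None else None
        return Bundle(
            counts=counts, meta=self.meta.loc[samples], taxa=self.taxa, env=env
        )


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].tolist()
        raise ValidationError(f"duplicate taxon ids: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    if counts.shape[1] < 1:
        raise ValidationError("count table has no samples")
    arr = counts.to_numpy()
    bad = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr)) & (arr >= 0)))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"negative or non-integer count at taxon {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}: {arr[i, j]!r}"
        )


def validate_bundle(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    taxa: pd.Series | None,
    env: pd.DataFrame | None,
) -> Bundle:
    """Cross-reference and canonicalize the four tables into a Bundle."""
    _check_counts(counts)

    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")
    if meta.index.duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    if (meta["day"] < 0).any():
        raise ValidationError("metadata contains negative days")

    if taxa is None:
        taxa = pd.Series("other", index=counts.index, name="phylum")
    taxa = taxa.reindex(counts.index).fillna("other")

    if env is not None:
        extra = [s for s in env.index if s not in counts.columns]
        if extra:
            log.info("env rows for %d samples outside count table dropped", len(extra))
            env = env.drop(index=extra)
        if env.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, c in zip(*np.where(env.isna().to_numpy()))
            ]
            raise ValidationError(f"missing environmental values at {cells[:5]}")

    # canonical lexicographic order so seeds reproduce across input orderings
    counts = counts.sort_index().sort_index(axis=1).astype(np.int64)
    order = list(counts.columns)
    meta = meta.loc[order]
    taxa = taxa.sort_index()
    if env is not None:
        env = env.loc[[s for s in order if s in env.index]]

    empty = counts.index[counts.sum(axis=1) == 0].tolist()
    if empty:
        log.info("%d all-zero taxa retained but flagged: %s", len(empty), empty[:10])

    return Bundle(counts=counts, meta=meta, taxa=taxa, env=env)


def load_dataset(
    count_path: str | Path,
    metadata_path: str | Path,
    taxon_path: str | Path | None = None,
    env_path: str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> Bundle:
    """Load and validate a dataset from delimited files.

    The counts file has taxon ids in the first column and one column per
    sample; metadata has columns ``sample,day,replicate``; the taxon table
    has ``species,phylum``; the environment table is wide, sample x variable.
    Tab- or comma-delimited files are both accepted.
    """

    def _read(path):
        return pd.read_csv(path, sep=None, engine="python")

    counts_raw = _read(count_path)
    counts = counts_raw.set_index(counts_raw.columns[0])
    counts.index.name = "taxon"

    meta = _read(metadata_path).set_index("sample")
    if "day" not in meta.columns:
        raise ValidationError("metadata must have a 'day' column")

    taxa = None
    if taxon_path is not None:
        tdf = _read(taxon_path)
        taxa = tdf.set_index(tdf.columns[0]).iloc[:, 0]
        taxa.name = "phylum"

    env = None
    if env_path is not None:
        edf = _read(env_path)
        env = edf.set_index(edf.columns[0]).astype(float)
        env.index.name = "sample"

    return validate_bundle(counts, meta, taxa, env)


def write_dataset(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to CSV files; load_dataset round-trips it exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["counts"] = out / "counts.csv"
    bundle.counts.to_csv(paths["counts"], index_label="taxon")
    paths["metadata"] = out / "metadata.csv"
    bundle.meta.to_csv(paths["metadata"], index_label="sample")
    paths["taxa"] = out / "taxa.csv"
    bundle.taxa.to_frame().to_csv(paths["taxa"], index_label="species")
    if bundle.env is not None:
        paths["env"] = out / "env.csv"
        bundle.env.to_csv(paths["env"], index_label="sample")
    return paths


def split_by_stage(bundle: Bundle, partition) -> dict[str, Bundle]:
    """Subset the bundle into one sub-bundle per colonization stage.

    Taxa with all-zero rows within a stage are dropped from that stage's
    scope; unassigned samples are excluded (and logged). Empty stages are
    skipped with a warning.
    """
    out: dict[str, Bundle] = {}
    labels = partition.labels
    unassigned = [s for s in bundle.counts.columns if labels.get(s, UNASSIGNED) == UNASSIGNED]
    if unassigned:
        log.info("%d samples unassigned to any stage: %s", len(unassigned), unassigned)
    for stage in partition.stages:
        samples = [s for s in bundle.counts.columns if labels.get(s) == stage]
        if not samples:
            log.warning("stage %s has no samples; skipped", stage)
            continue
        out[stage] = bundle.subset_samples(samples).drop_empty_taxa()
    return out


def group_rare_taxa(stage_bundle: Bundle, config: AnalysisConfig) -> pd.DataFrame:
    """Reporting table with rare taxa pooled into an "Other" pseudo-taxon.

    A taxon is pooled when its stage-level relative abundance is below
    ``config.rare_rel_abundance`` AND its occurrence frequency across the
    stage's samples is below ``config.rare_frequency``. Pooling is for
    reporting only; niche metrics always use the ungrouped table.
    """
    counts = stage_bundle.counts
    total = counts.to_numpy().sum()
    rel = counts.sum(axis=1) / total if total > 0 else counts.sum(axis=1) * 0.0
    freq = (counts > 0).mean(axis=1)
    rare = (rel < config.rare_rel_abundance) & (freq < config.rare_frequency)

    rows = counts.loc[~rare].copy()
    if rare.any():
        other = counts.loc[rare].sum(axis=0)
        other.name = "Other"
        rows = pd.concat([rows, other.to_frame().T])
    rows.attrs["n_grouped"] = int(rare.sum())
    return rows
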