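"""Synthetic periphytic-algal colonization series.

The generator emulates a 45-day substrate-colonization experiment sampled
every 3 days with 4 replicate scrapes per day: phylum-structured arrival
(diatoms first), richness rising through time, total cell density rising
and then declining after day 27, and near-homogeneous water chemistry.

Species fall into three latent classes that together produce the niche
structure the analysis measures:

* ``core`` — the designed dominants: early arrival (within their phylum's
  window), carrying capacity two orders of magnitude above the background,
  hence high dominance and wide, even utilization profiles;
* ``ubiquitous`` — background settlers arriving in the first days of
  their phylum's window at low carrying capacity: present almost
  everywhere at low density, so their niche widths track the dominants'
  while their dominance stays far below threshold;
* ``transient`` — the rare tail arriving continuously through the
  experiment; within any stage the recent arrivals have concentrated
  profiles (narrow niche) and act as the occupancy donors that give
  non-dominant species their large resource-occupancy changes.

Latent dynamics are logistic toward each species' capacity with a shared
community brake ``(1 - X_total / K_total)`` standing in for competition
for space and nutrients; observed counts are negative-binomial per
replicate (overdispersed scrapes). All randomness flows from one seeded
generator, so identical config + seed give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import DEFAULT_STAGE_RANGES
from .data import Bundle, validate_bundle

log = logging.getLogger(__name__)

#: Per-variable (mean, SD) of the habitat table; the canal's water
#: chemistry is nearly constant, so one set serves all stages.
DEFAULT_ENV_PARAMS: dict[str, tuple[float, float]] = {
    "TN": (1.18, 0.04),
    "NH3-N": (0.06, 0.01),
    "NO3-N": (1.09, 0.02),
    "TP": (0.03, 0.01),
    "PO4-P": (0.01, 0.00),
    "CODMn": (1.63, 0.33),
    "T": (23.67, 2.14),
    "DO": (11.52, 0.18),
    "SPC": (217.95, 1.48),
    "pH": (8.42, 0.01),
}

_PREFIX = {
    "Heterokontophyta": "Het",
    "Cyanobacteria": "Cya",
    "Chlorophyta": "Chl",
    "Charophyta": "Cha",
    "Cryptista": "Cry",
}


@dataclass
class SimulationConfig:
    """Parameters of the colonization simulator (defaults emulate the
    45-day, 3-day-interval, 4-replicate study design)."""

    pool_sizes: dict[str, int] = field(default_factory=lambda: {
        "Heterokontophyta": 90,
        "Cyanobacteria": 25,
        "Chlorophyta": 20,
        "Charophyta": 10,
        "Cryptista": 5,
    })
    #: designed high-dominance species per phylum
    n_core: dict[str, int] = field(default_factory=lambda: {
        "Heterokontophyta": 8, "Cyanobacteria": 2, "Chlorophyta": 2,
    })
    core_capacity: dict[str, float] = field(default_factory=lambda: {
        "Heterokontophyta": 2500.0, "Cyanobacteria": 1200.0, "Chlorophyta": 1200.0,
    })
    core_arrival: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "Heterokontophyta": (1, 3), "Cyanobacteria": (6, 9), "Chlorophyta": (6, 9),
    })
    #: arrival-day window of the background pool, per phylum (diatoms first)
    arrival_window: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "Heterokontophyta": (1, 40),
        "Cyanobacteria": (8, 44),
        "Chlorophyta": (10, 44),
        "Charophyta": (14, 44),
        "Cryptista": (14, 44),
    })
    ubiquitous_fraction: float = 0.45
    ubiquitous_arrival_span: int = 6  # days after the phylum window opens
    ubiquitous_capacity_meanlog: float = float(np.log(150.0))
    transient_capacity_meanlog: float = float(np.log(3.5))
    capacity_sdlog: float = 0.6
    core_capacity_sdlog: float = 0.25
    growth_range: tuple[float, float] = (0.4, 0.7)
    core_growth_range: tuple[float, float] = (0.4, 0.7)
    inoculum: float = 2.0
    core_inoculum: float = 50.0  # dominant colonizers settle at high propagule pressure
    ubiquitous_inoculum: float = 10.0  # background settlers at moderate pressure
    #: mortality per day by class: competitive losers fade as the community
    #: brake tightens, producing species replacement (turnover)
    mortality_range: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "core": (0.0, 0.0),
        "ubiquitous": (0.0, 0.05),
        "transient": (0.2, 0.4),
    })
    k_total: float = 50000.0
    decline_onset: int = 27
    decline_rate: float = 0.92  # daily multiplier after onset
    sampling_days: tuple[int, ...] = tuple(range(3, 46, 3))
    replicates: int = 4
    nb_dispersion: float = 15.0
    env_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_PARAMS)
    )
    stage_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.pool_sizes.values()):
            raise ValueError("pool sizes must be >= 0")
        days = list(self.sampling_days)
        if days != sorted(set(days)):
            raise ValueError("sampling days must be strictly increasing")
        for name in ("k_total", "decline_rate", "inoculum", "nb_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 <= self.ubiquitous_fraction <= 1.0:
            raise ValueError("ubiquitous_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _species_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for phylum, pool in cfg.pool_sizes.items():
        prefix = _PREFIX.get(phylum, phylum[:3])
        ncore = min(cfg.n_core.get(phylum, 0), pool)
        lo, hi = cfg.arrival_window.get(phylum, (1, 44))
        for i in range(pool):
            sid = f"{prefix}{i + 1:03d}"
            if i < ncore:
                klass = "core"
                a0, a1 = cfg.core_arrival.get(phylum, (lo, lo + 2))
                arrival = int(rng.integers(a0, a1 + 1))
                cap = float(rng.lognormal(
                    np.log(cfg.core_capacity.get(phylum, 1000.0)),
                    cfg.core_capacity_sdlog,
                ))
                g = float(rng.uniform(*cfg.core_growth_range))
            else:
                if rng.random() < cfg.ubiquitous_fraction:
                    klass = "ubiquitous"
                    arrival = int(rng.integers(lo, lo + cfg.ubiquitous_arrival_span + 1))
                    cap = float(rng.lognormal(
                        cfg.ubiquitous_capacity_meanlog, cfg.capacity_sdlog))
                else:
                    klass = "transient"
                    arrival = int(rng.integers(lo, hi + 1))
                    cap = float(rng.lognormal(
                        cfg.transient_capacity_meanlog, cfg.capacity_sdlog))
                g = float(rng.uniform(*cfg.growth_range))
            m = float(rng.uniform(*cfg.mortality_range.get(klass, (0.0, 0.0))))
            rows.append((sid, phylum, klass, arrival, cap, g, m))
    return pd.DataFrame(
        rows,
        columns=["species", "phylum", "class", "arrival", "capacity", "growth", "mortality"],
    ).set_index("species")


def _latent_trajectories(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Deterministic per-species expected density at each sampling day."""
    horizon = max(cfg.sampling_days)
    arrival = truth["arrival"].to_numpy()
    cap = truth["capacity"].to_numpy()
    g = truth["growth"].to_numpy()
    mort = truth["mortality"].to_numpy()
    klass = truth["class"].to_numpy()
    x0 = np.where(
        klass == "core",
        cfg.core_inoculum,
        np.where(klass == "ubiquitous", cfg.ubiquitous_inoculum, cfg.inoculum),
    )
    x = np.zeros(len(truth))
    snapshots = {}
    sampling = set(cfg.sampling_days)
    for day in range(1, horizon + 1):
        x[arrival == day] = x0[arrival == day]
        brake = max(0.0, 1.0 - x.sum() / cfg.k_total)
        alive = x > 0
        x[alive] += x[alive] * (
            g[alive] * (1.0 - x[alive] / cap[alive]) * brake - mort[alive]
        )
        np.clip(x, 0.0, None, out=x)
        if day > cfg.decline_onset:
            x *= cfg.decline_rate
        if day in sampling:
            snapshots[day] = x.copy()
    return pd.DataFrame(snapshots, index=truth.index)


def simulate_colonization(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[Bundle, pd.DataFrame]:
    """Generate an observed colonization dataset plus its ground truth.

    Returns the validated bundle (counts, metadata, taxonomy; no
    environment — see :func:`simulate_env`) and the ground-truth table of
    per-species class, arrival day, capacity and growth rate.
    """
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)

    if sum(cfg.pool_sizes.values()) == 0:
        log.warning("all species pools empty: returning empty dataset")
        counts = pd.DataFrame(
            np.zeros((0, 0), dtype=int), index=pd.Index([], name="taxon")
        )
        meta = pd.DataFrame(columns=["day", "replicate"])
        return (
            Bundle(counts=counts, meta=meta, taxa=pd.Series(dtype=object)),
            pd.DataFrame(),
        )

    truth = _species_table(cfg, rng)
    latent = _latent_trajectories(cfg, truth)

    theta = cfg.nb_dispersion
    cols = {}
    meta_rows = []
    for day in cfg.sampling_days:
        mu = latent[day].to_numpy()
        for rep in range(1, cfg.replicates + 1):
            sid = f"d{day:02d}r{rep}"
            lam = rng.gamma(theta, mu / theta)  # gamma-Poisson = NB
            cols[sid] = rng.poisson(lam)
            meta_rows.append((sid, day, rep))

    counts = pd.DataFrame(cols, index=truth.index)
    counts.index.name = "taxon"
    meta = pd.DataFrame(meta_rows, columns=["sample", "day", "replicate"]).set_index("sample")
    bundle = validate_bundle(counts, meta, truth["phylum"], None)
    return bundle, truth


def simulate_env(
    config: SimulationConfig | None = None,
    meta: pd.DataFrame | None = None,
    seed: int | None = None,
    stage_shifts: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Environmental table: each variable i.i.d. Normal(mean, SD) per sample.

    Defaults reproduce the near-homogeneous canal chemistry (per-variable
    CV% of a few percent). ``stage_shifts`` plants mean shifts per stage
    (``{"TP": {"T1": 0.02}}``) for detectable community-environment
    structure; negative draws of the non-negative variables are truncated
    at zero with a log note.
    """
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed + 1  # decouple from the count stream
    rng = np.random.default_rng(seed)
    if meta is None:
        rows = [
            (f"d{day:02d}r{rep}", day, rep)
            for day in cfg.sampling_days
            for rep in range(1, cfg.replicates + 1)
        ]
        meta = pd.DataFrame(rows, columns=["sample", "day", "replicate"]).set_index("sample")

    def stage_of(day: int) -> str | None:
        for stage, (lo, hi) in cfg.stage_ranges.items():
            if lo <= day <= hi:
                return stage
        return None

    data = {}
    for var, (mean, sd) in cfg.env_params.items():
        vals = rng.normal(mean, sd, size=len(meta)) if sd > 0 else np.full(len(meta), mean)
        if stage_shifts and var in stage_shifts:
            for i, s in enumerate(meta.index):
                st = stage_of(int(meta.loc[s, "day"]))
                if st is not None and st in stage_shifts[var]:
                    vals[i] += stage_shifts[var][st]
        n_neg = int((vals < 0).sum())
        if n_neg:
            log.info("%d negative draws of %s truncated at 0", n_neg, var)
            vals = np.clip(vals, 0.0, None)
        data[var] = vals
    return pd.DataFrame(data, index=meta.index)


def planted_fixture(kind: str, seed: int = 0):
    """Small deterministic tables with analytically known niche metrics.

    ``uniform_generalist``: one species with equal counts in all 4 samples
    (niche width exactly 1). ``single_sample_specialist``: one species in 1
    of 5 samples (width exactly 1/5). ``two_species_asym``: profiles (1, 0)
    and (0.5, 0.5) with Pianka overlap 1/sqrt(2), occupancy changes +-0.5
    and response rates 0.25 / -0.5. ``paper_shape``: a full 150-species
    three-stage colonization series from the default simulator.
    """
    def _bundle(counts: dict, days: list[int]):
        cdf = pd.DataFrame(counts).T
        cdf.index.name = "taxon"
        cdf.columns = [f"s{i+1}" for i in range(cdf.shape[1])]
        meta = pd.DataFrame(
            {"sample": cdf.columns, "day": days, "replicate": range(1, cdf.shape[1] + 1)}
        ).set_index("sample")
        return validate_bundle(cdf, meta, None, None)

    if kind == "uniform_generalist":
        return _bundle({"sp1": [5, 5, 5, 5]}, [3, 3, 3, 3])
    if kind == "single_sample_specialist":
        return _bundle({"sp1": [7, 0, 0, 0, 0]}, [3] * 5)
    if kind == "two_species_asym":
        return _bundle({"sp1": [4, 0], "sp2": [2, 2]}, [3, 3])
    if kind == "paper_shape":
        bundle, _ = simulate_colonization(SimulationConfig(seed=seed))
        return bundle
    raise ValueError(f"unknown fixture kind {kind!r}")
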