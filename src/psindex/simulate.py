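"""Simulation of parturition-date groups and the full robustness study.

Groups of birth dates are generated under five distribution families
(completely synchronous, lognormal, normal, bimodal, uniform), across a
grid of parturition-season durations and group sizes.  Generation is
two-stage: a large preliminary pool of dates is simulated for each
(family, duration) combination, and each group is a simple random
subsample of that pool.  Every non-synchronous group is then constrained
to span the whole season — it must contain a birth on day 1 and on the
season's final day.

The default study design crosses four non-degenerate families with five
season durations (10, 50, 100, 200, 365 days) and eight group sizes
(5, 10, 25, 50, 100, 500, 1000, 5000), one group per cell, plus one
completely synchronous group (season of a single day) per group size:
168 groups and 140,490 simulated mothers in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import psi_all_fast, summarize, to_relative_dates

__all__ = [
    "FAMILIES",
    "STUDY_DURATIONS",
    "STUDY_SIZES",
    "DEFAULT_SEED",
    "DEFAULT_POOL_SIZE",
    "DistributionSpec",
    "DesignCell",
    "StudyDesign",
    "default_design",
    "sample_pool",
    "draw_group",
    "enforce_span",
    "simulate_group",
    "run_study",
]

FAMILIES = ("synchronous", "lognormal", "normal", "bimodal", "uniform")

#: season durations (days) used for the non-synchronous families
STUDY_DURATIONS = (10, 50, 100, 200, 365)

#: group sizes (mothers) used for every family
STUDY_SIZES = (5, 10, 25, 50, 100, 500, 1000, 5000)

DEFAULT_SEED = 777
DEFAULT_POOL_SIZE = 100_000

# Default shape parameters, as fractions of the season duration D:
#   lognormal -- log-scale SD 0.4, median 0.15*D (early-season right skew)
#   normal    -- mean (D+1)/2, SD D/6 (~99.7% of mass in season pre-clip)
#   bimodal   -- equal mixture of normals at 0.3*D and 0.7*D, each SD D/12
DEFAULT_PARAMS = {
    "lognormal": {"sigma_log": 0.4, "median_frac": 0.15},
    "normal": {"sd_frac": 1.0 / 6.0},
    "bimodal": {"peak_fracs": (0.3, 0.7), "sd_frac": 1.0 / 12.0},
}


@dataclass(frozen=True)
class DistributionSpec:
    """A parturition-date distribution family plus its shape parameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        merged = dict(DEFAULT_PARAMS.get(self.family, {}))
        merged.update(self.params)
        for key, val in merged.items():
            if key != "peak_fracs" and val <= 0:
                raise ValueError(f"parameter {key} must be positive")
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class DesignCell:
    """One cell of the study grid: family x season duration x group size."""

    family: str
    duration: int
    size: int

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.duration < 1:
            raise ValueError("season duration must be >= 1 day")
        if self.size < 2:
            raise ValueError("group size must be >= 2 mothers")
        if self.family == "synchronous" and self.duration != 1:
            raise ValueError("synchronous family implies a 1-day season")
        if self.family != "synchronous" and self.duration < 2:
            raise ValueError(
                "non-synchronous families need a season of >= 2 days"
            )


@dataclass(frozen=True)
class StudyDesign:
    """An ordered list of design cells plus the root RNG seed."""

    cells: tuple
    seed: int = DEFAULT_SEED
    pool_size: int = DEFAULT_POOL_SIZE
    replicates: int = 1
    span_mode: str = "inject"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.span_mode not in ("inject", "reject"):
            raise ValueError("span_mode must be 'inject' or 'reject'")
        max_size = max((c.size for c in self.cells), default=0)
        if self.pool_size < max_size:
            raise ValueError("pool_size smaller than the largest group")


def default_design(
    seed: int = DEFAULT_SEED,
    families=FAMILIES,
    durations=STUDY_DURATIONS,
    sizes=STUDY_SIZES,
    replicates: int = 1,
    pool_size: int = DEFAULT_POOL_SIZE,
    span_mode: str = "inject",
    params: dict | None = None,
) -> StudyDesign:
    """The full robustness-study design.

    With the defaults this yields 8 synchronous cells (one per group size,
    1-day season) plus 4 families x 5 durations x 8 sizes = 160 cells;
    168 groups and 140,490 mothers in total.
    """
    cells = []
    if "synchronous" in families:
        for size in sizes:
            cells.append(DesignCell("synchronous", 1, size))
    for fam in families:
        if fam == "synchronous":
            continue
        for dur in durations:
            for size in sizes:
                cells.append(DesignCell(fam, dur, size))
    return StudyDesign(
        cells=tuple(cells),
        seed=seed,
        pool_size=pool_size,
        replicates=replicates,
        span_mode=span_mode,
        params=params or {},
    )


def _family_rng(seed, family, duration, *extra) -> np.random.Generator:
    # Keyed substreams: stream identity depends only on (seed, key), never
    # on the order cells are iterated.
    key = (FAMILIES.index(family), duration) + tuple(extra)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def sample_pool(
    spec: DistributionSpec,
    duration: int,
    pool_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``pool_size`` integer dates in [1, duration] from the family.

    Continuous families are sampled, rounded to the nearest integer and
    clipped to the season; the synchronous family puts every birth on
    day 1.
    """
    if duration < 1:
        raise ValueError("season duration must be >= 1 day")
    fam = spec.family
    if fam == "synchronous":
        return np.ones(pool_size, dtype=np.int64)
    if fam == "uniform":
        return rng.integers(1, duration + 1, size=pool_size, dtype=np.int64)
    if fam == "normal":
        x = rng.normal(
            (duration + 1) / 2.0,
            spec.params["sd_frac"] * duration,
            size=pool_size,
        )
    elif fam == "lognormal":
        x = rng.lognormal(
            np.log(spec.params["median_frac"] * duration),
            spec.params["sigma_log"],
            size=pool_size,
        )
    elif fam == "bimodal":
        lo, hi = spec.params["peak_fracs"]
        which = rng.integers(0, 2, size=pool_size)
        mu = np.where(which == 0, lo * duration, hi * duration)
        x = rng.normal(mu, spec.params["sd_frac"] * duration)
    else:  # pragma: no cover - guarded by DistributionSpec
        raise ValueError(f"unknown family {fam!r}")
    return np.clip(np.rint(x), 1, duration).astype(np.int64)


def draw_group(pool: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Simple random sample of ``size`` dates from the pool, without
    replacement."""
    pool = np.asarray(pool)
    if size > pool.size:
        raise ValueError("group size exceeds pool size")
    return rng.choice(pool, size=size, replace=False)


def enforce_span(dates: np.ndarray, duration: int) -> np.ndarray:
    """Force the group to span the full season (contain day 1 and day
    ``duration``) by endpoint injection.

    If day 1 is absent the group's earliest birth is moved to day 1; if the
    final day is absent the latest birth is moved there.  At most two
    positions change and the group size is preserved.
    """
    if duration < 2:
        raise ValueError("span enforcement needs a season of >= 2 days")
    d = np.asarray(dates).copy()
    if d.size < 2:
        raise ValueError("need at least 2 dates to span a season")
    if 1 not in d:
        d[np.argmin(d)] = 1
    if duration not in d:
        d[np.argmax(d)] = duration
    return d


def simulate_group(
    cell: DesignCell,
    seed: int = DEFAULT_SEED,
    pool_size: int = DEFAULT_POOL_SIZE,
    span_mode: str = "inject",
    params: dict | None = None,
    replicate: int = 0,
    pool: np.ndarray | None = None,
    max_reject_tries: int = 10_000,
) -> np.ndarray:
    """Simulate one group's date vector for a design cell.

    Synchronous cells bypass the pool: every mother gives birth on day 1.
    Otherwise a group is subsampled from the (family, duration) pool and
    span-enforced, either by endpoint injection (default) or by rejection
    resampling (``span_mode='reject'``; may be extremely slow for small
    groups under peaked distributions).
    """
    if cell.family == "synchronous":
        return np.ones(cell.size, dtype=np.int64)
    spec = DistributionSpec(cell.family, (params or {}).get(cell.family, {}))
    if pool is None:
        pool = sample_pool(
            spec, cell.duration, pool_size,
            _family_rng(seed, cell.family, cell.duration),
        )
    rng = _family_rng(seed, cell.family, cell.duration, cell.size, replicate)
    if span_mode == "inject":
        return enforce_span(draw_group(pool, cell.size, rng), cell.duration)
    for _ in range(max_reject_tries):
        g = draw_group(pool, cell.size, rng)
        if 1 in g and cell.duration in g:
            return g
    raise RuntimeError(
        f"rejection sampling failed to span [1, {cell.duration}] in "
        f"{max_reject_tries} tries for {cell}"
    )


def run_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every cell of the design and compute PSI throughout.

    Returns
    -------
    (mothers, groups)
        ``mothers`` has one row per simulated mother (group id, family,
        duration, size, replicate, date, relative date, PSI); ``groups``
        has one row per group with the PSI summary (n, mean, median, min,
        max, sample SD, CV%).
    """
    mother_rows = []
    group_rows = []
    pool_cache: dict[tuple, np.ndarray] = {}
    for rep in range(design.replicates):
        for cell in design.cells:
            key = (cell.family, cell.duration)
            if cell.family != "synchronous" and key not in pool_cache:
                spec = DistributionSpec(
                    cell.family, design.params.get(cell.family, {})
                )
                pool_cache[key] = sample_pool(
                    spec, cell.duration, design.pool_size,
                    _family_rng(design.seed, cell.family, cell.duration),
                )
            dates = simulate_group(
                cell,
                seed=design.seed,
                pool_size=design.pool_size,
                span_mode=design.span_mode,
                params=design.params,
                replicate=rep,
                pool=pool_cache.get(key),
            )
            t = to_relative_dates(dates)
            psi = psi_all_fast(t)
            gid = f"{cell.family}_d{cell.duration}_n{cell.size}_r{rep}"
            mother_rows.append(
                pd.DataFrame(
                    {
                        "group_id": gid,
                        "family": cell.family,
                        "duration": cell.duration,
                        "size": cell.size,
                        "replicate": rep,
                        "mother_index": np.arange(cell.size),
                        "date": dates,
                        "t_relative": t,
                        "psi": psi,
                    }
                )
            )
            s = summarize(psi)
            group_rows.append(
                {
                    "group_id": gid,
                    "family": cell.family,
                    "duration": cell.duration,
                    "size": cell.size,
                    "replicate": rep,
                    "n": s.n,
                    "mean_psi": s.mean,
                    "median_psi": s.median,
                    "min_psi": s.min,
                    "max_psi": s.max,
                    "sd_psi": s.sd,
                    "cv_psi_percent": s.cv_percent,
                }
            )
    mothers = pd.concat(mother_rows, ignore_index=True)
    groups = pd.DataFrame(group_rows)
    return mothers, groups
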