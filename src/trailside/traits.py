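"""Plant trait derivation and response preparation.

From the raw per-plant measurements (maximum height, maximum diameter,
bud/flower/fruit counts) this module derives the analysis variables:

* ``area`` — a rectangular proxy for plant area, height x diameter (cm^2);
* ``summed_repro`` — buds + flowers + fruits;
* ``repro_per_area`` — area-standardized reproductive output (per cm^2);
* ``relative_repro`` — repro_per_area divided by the species-wide maximum,
  so each species' most reproductive individual scores exactly 1.

It also prepares responses for the two model families: nearest-integer
rounding for the negative binomial (sizes are recorded to the mm but the
count family needs integers) and the open-interval adjustment that keeps
proportions strictly inside (0, 1) for the Beta family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "derive_traits",
    "relative_reproduction",
    "round_for_nb",
    "adjust_unit_interval",
    "select_individuals",
    "select_per_quadrat",
]

logger = logging.getLogger(__name__)

REPRO_COLUMNS = ["buds", "flowers", "fruits"]


def derive_traits(records: pd.DataFrame) -> pd.DataFrame:
    """Add area and reproduction columns; drop and log invalid rows.

    Rows with non-positive height or diameter are measurement errors and
    are excluded (logged with reasons).  Rows with missing reproduction
    counts (sedges, whose phenophases are not distinguishable in the
    field) keep ``NaN`` in all reproduction-derived columns.
    """
    table = records.copy()
    h = pd.to_numeric(table["height_cm"], errors="coerce")
    d = pd.to_numeric(table["diameter_cm"], errors="coerce")
    bad = ~((h > 0) & (d > 0))
    if bad.any():
        logger.warning(
            "excluding %d row(s) with non-positive or missing height/diameter",
            int(bad.sum()),
        )
        table = table.loc[~bad].reset_index(drop=True)
        h, d = h.loc[~bad].reset_index(drop=True), d.loc[~bad].reset_index(drop=True)
    table["area"] = h * d
    counts = table[REPRO_COLUMNS].astype("float64")
    has_repro = counts.notna().all(axis=1)
    summed = counts.sum(axis=1, skipna=False)
    table["summed_repro"] = summed.astype("Float64").astype("Int64")
    table["repro_per_area"] = np.where(has_repro, summed / table["area"], np.nan)
    return table


def relative_reproduction(table: pd.DataFrame) -> pd.DataFrame:
    """Scale area-standardized reproduction by each species' maximum.

    The maximum is taken over all transects, so exactly one (or more,
    on ties) individual per species reaches 1.  A species whose every
    individual has zero reproduction carries no information for a
    proportional model: its column is set to 0 and the species is flagged
    in ``table.attrs['noninformative_species']``.
    """
    if table.empty:
        raise ValueError("empty trait table")
    out = table.copy()
    out["relative_repro"] = np.nan
    noninformative = []
    for species, grp in out.groupby("species", sort=False):
        density = grp["repro_per_area"]
        if density.isna().all():
            continue  # no reproduction recorded for this taxon
        peak = density.max()
        if not peak > 0:
            noninformative.append(species)
            out.loc[grp.index, "relative_repro"] = 0.0
            continue
        out.loc[grp.index, "relative_repro"] = density / peak
    if noninformative:
        logger.warning(
            "species with all-zero reproduction (non-informative for the "
            "Beta model): %s",
            ", ".join(noninformative),
        )
    out.attrs["noninformative_species"] = noninformative
    return out


def round_for_nb(values, unit: str = "cm") -> np.ndarray:
    """Round measured sizes to the nearest integer for the NB family.

    Ties (x.5) round half away from zero, so the rule is platform
    independent.  Inputs are non-negative sizes in ``unit`` (cm).
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("sizes must be non-negative")
    return np.floor(v + 0.5).astype(np.int64)


def adjust_unit_interval(values, eps: float = 0.0001) -> np.ndarray:
    """Nudge exact 0 and 1 inside the open interval required by the Beta.

    0 maps to ``eps`` and 1 to ``1 - eps``; interior values are unchanged.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("values must lie in [0, 1]")
    out = v.copy()
    out[v == 0.0] = eps
    out[v == 1.0] = 1.0 - eps
    return out


def select_individuals(
    candidates: pd.DataFrame, k: int = 5, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Randomly select up to ``k`` individuals from one (quadrat, species).

    Mirrors the field protocol: when more than ``k`` individuals are
    flagged in a quadrat, ``k`` are chosen uniformly without replacement
    with a random number generator; otherwise all are measured.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(candidates) <= k:
        return candidates
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ix = rng.choice(len(candidates), size=k, replace=False)
    return candidates.iloc[np.sort(ix)]


def select_per_quadrat(table: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Apply :func:`select_individuals` to every (pair, transect, quadrat,
    species) group of a plant table."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    keys = ["pair_id", "disturbed", "quadrat", "species"]
    parts = [
        select_individuals(grp, k=k, seed=rng)
        for _, grp in table.groupby(keys, sort=True)
    ]
    if not parts:
        return table.copy()
    out = pd.concat(parts).sort_index().reset_index(drop=True)
    logger.info(
        "random selection kept %d of %d candidate plants (cap %d per quadrat)",
        len(out),
        len(table),
        k,
    )
    return out
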