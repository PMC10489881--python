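"""Synthetic paired trail-side / off-trail survey generator.

Emulates a subalpine trampling survey: permanent paired transects (one
trail-side "disturbed", one off-trail "undisturbed") laid out along hiking
trails over an elevational gradient, each transect divided into contiguous
1 m x 0.5 m quadrats.  Within quadrats, individuals of four focal taxa
(the heath *Phyllodoce empetriformis*, the heather *Cassiope mertensiana*,
the blueberry *Vaccinium ovalifolium*, and sedges *Carex* spp.) carry
size traits (maximum height and diameter) and bud/flower/fruit counts,
and each quadrat has a downward photograph from which percent vegetation
cover is later estimated.

Everything is generated from an explicit generative model with known
ground truth, so the downstream estimation stages (image cover estimation,
trait derivation, hierarchical model fits) can be tested end to end
without field data:

* size traits are zero-truncated negative binomial on a log-mean scale
  ``exp(b0 + bD*D + bE*E + bDE*D*E + u_pair)`` with per-pair random
  intercepts ``u_pair ~ Normal(0, sigma_pair^2)``;
* reproductive structures are Poisson with rate proportional to plant
  area (height x diameter), split uniformly over the three phenophases;
* quadrat cover fractions are Beta-distributed around a logit-linear
  disturbance x elevation mean, and quadrat images are painted with
  exactly ``round(p * H * W)`` green-dominant pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "SimConfig",
    "TraitEffects",
    "SpeciesParams",
    "CoverParams",
    "TransectPair",
    "SurveyDesign",
    "QuadratImage",
    "make_design",
    "simulate_traits",
    "simulate_cover_images",
    "reference_presets",
    "write_plant_table",
    "read_plant_table",
    "write_images",
]

PLANT_COLUMNS = [
    "species",
    "trail",
    "pair_id",
    "disturbed",
    "quadrat",
    "elevation_m",
    "height_cm",
    "diameter_cm",
    "buds",
    "flowers",
    "fruits",
]


# ---------------------------------------------------------------------------
# configuration and parameter containers


@dataclass(frozen=True)
class SimConfig:
    """Survey-scale simulation settings.

    ``seed`` is mandatory: identical config (including seed) must yield
    byte-identical tables and images.
    """

    seed: int
    n_pairs: int = 14
    n_quadrats: int = 10
    elevation_range: tuple[float, float] = (1580.0, 1980.0)
    max_per_quadrat: int = 5
    mean_abundance: float = 6.0
    image_size: tuple[int, int] = (64, 64)
    n_trails: int = 3
    quadrat_width_m: float = 1.0
    quadrat_depth_m: float = 0.5

    def validate(self) -> None:
        if self.n_pairs <= 0 or self.n_quadrats <= 0:
            raise ValueError("n_pairs and n_quadrats must be positive")
        if self.max_per_quadrat <= 0:
            raise ValueError("max_per_quadrat must be positive")
        lo, hi = self.elevation_range
        if not lo <= hi:
            raise ValueError("elevation_range must be (low, high)")
        if self.image_size[0] < 8 or self.image_size[1] < 8:
            raise ValueError("image size must be at least 8x8 pixels")
        if self.mean_abundance < 0:
            raise ValueError("mean_abundance must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["elevation_range"] = list(self.elevation_range)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("SimConfig requires an explicit seed")
        d["elevation_range"] = tuple(d.get("elevation_range", (1580.0, 1980.0)))
        d["image_size"] = tuple(d.get("image_size", (64, 64)))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TraitEffects:
    """Fixed effects on the model's link scale (log for sizes, logit for cover).

    ``disturbance`` is the on-trail contrast, ``elevation`` is per metre,
    ``interaction`` is the disturbance x elevation term.
    """

    intercept: float
    disturbance: float
    elevation: float
    interaction: float

    def linear_predictor(self, disturbed, elevation_m):
        d = np.asarray(disturbed, dtype=float)
        e = np.asarray(elevation_m, dtype=float)
        return (
            self.intercept
            + self.disturbance * d
            + self.elevation * e
            + self.interaction * d * e
        )


@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters for one focal species.

    ``lambda_rep`` is the expected number of reproductive structures per
    cm^2 of plant area; ``None`` marks a sedge-like taxon whose phenophases
    cannot be told apart in the field, so no reproduction columns are
    generated.  ``occupancy`` is the probability a quadrat holds any
    individuals of the species at all; it controls realized sample sizes.
    """

    name: str
    height: TraitEffects
    diameter: TraitEffects
    nb_shape: float = 2.0
    sigma_pair: float = 0.3
    lambda_rep: float | None = 0.05
    occupancy: float = 1.0

    def validate(self) -> None:
        if self.nb_shape <= 0:
            raise ValueError(f"{self.name}: NB shape must be > 0")
        if self.sigma_pair < 0:
            raise ValueError(f"{self.name}: sigma_pair must be >= 0")
        if self.lambda_rep is not None and self.lambda_rep < 0:
            raise ValueError(f"{self.name}: lambda_rep must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"{self.name}: occupancy must be in [0,1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpeciesParams":
        d = dict(d)
        d["height"] = TraitEffects(**d["height"])
        d["diameter"] = TraitEffects(**d["diameter"])
        return cls(**d)


@dataclass(frozen=True)
class CoverParams:
    """Beta model for quadrat-level green cover, logit mean link."""

    effects: TraitEffects
    precision: float = 10.0
    sigma_pair: float = 0.3

    def validate(self) -> None:
        if self.precision <= 0:
            raise ValueError("cover precision must be > 0")
        if self.sigma_pair < 0:
            raise ValueError("cover sigma_pair must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CoverParams":
        d = dict(d)
        d["effects"] = TraitEffects(**d["effects"])
        return cls(**d)


# ---------------------------------------------------------------------------
# survey design


@dataclass(frozen=True)
class TransectPair:
    """A matched trail-side / off-trail transect pair at one location."""

    pair_id: str
    trail: str
    elevation_m: float
    n_quadrats: int


@dataclass(frozen=True)
class SurveyDesign:
    pairs: tuple[TransectPair, ...]
    quadrat_width_m: float = 1.0
    quadrat_depth_m: float = 0.5

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_transects(self) -> int:
        return 2 * len(self.pairs)

    @property
    def n_quadrats_total(self) -> int:
        return 2 * sum(p.n_quadrats for p in self.pairs)

    def transects(self):
        """Yield (pair, disturbed) for every transect; disturbed in {0, 1}."""
        for pair in self.pairs:
            for disturbed in (1, 0):
                yield pair, disturbed

    def validate(self) -> None:
        if not self.pairs:
            raise ValueError("design has no transect pairs")
        for p in self.pairs:
            if p.n_quadrats < 1:
                raise ValueError(f"{p.pair_id}: n_quadrats must be >= 1")


def quadrat_id(pair_id: str, disturbed: int, quadrat: int) -> str:
    return f"{pair_id}_{'D' if disturbed else 'U'}_Q{quadrat:02d}"


def make_design(config: SimConfig) -> SurveyDesign:
    """Lay out the paired-transect survey.

    Pair elevations are drawn uniformly (seeded) within the configured
    range and are shared by the two transects of a pair, which sit at the
    same location on opposite sides of the trail edge.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    lo, hi = config.elevation_range
    elevations = rng.uniform(lo, hi, size=config.n_pairs)
    pairs = tuple(
        TransectPair(
            pair_id=f"P{i + 1:02d}",
            trail=f"T{1 + i % config.n_trails}",
            elevation_m=float(np.round(e, 1)),
            n_quadrats=config.n_quadrats,
        )
        for i, e in enumerate(elevations)
    )
    return SurveyDesign(
        pairs,
        quadrat_width_m=config.quadrat_width_m,
        quadrat_depth_m=config.quadrat_depth_m,
    )


# ---------------------------------------------------------------------------
# plant traits


def _zt_negative_binomial(rng, mean, shape, size):
    """Zero-truncated NB draws: surveyed plants cannot have zero size."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size).copy()
    p = shape / (shape + mean)
    out = rng.negative_binomial(shape, p, size=size)
    zero = out == 0
    # resample zeros; truncation mass is small at realistic means
    for _ in range(1000):
        if not zero.any():
            break
        out[zero] = rng.negative_binomial(shape, p[zero])
        zero = out == 0
    out[out == 0] = 1
    return out


def simulate_traits(
    design: SurveyDesign,
    params: SpeciesParams | Sequence[SpeciesParams],
    seed: int,
    mean_abundance: float = 6.0,
) -> pd.DataFrame:
    """Draw a plant table for every quadrat and species in the design.

    Candidate abundance per (quadrat, species) is Poisson(``mean_abundance``)
    thinned by ``occupancy``; all candidates are returned here — capping at
    the five randomly selected individuals the field protocol records is the
    job of :func:`trailside.traits.select_individuals`.  Heights/diameters
    are stored in cm at mm precision (integer NB draw plus sub-cm
    measurement jitter).
    """
    design.validate()
    species_list = [params] if isinstance(params, SpeciesParams) else list(params)
    if not species_list:
        raise ValueError("no species parameters given")
    for sp in species_list:
        sp.validate()

    rows: list[dict] = []
    for s_idx, sp in enumerate(species_list):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, s_idx]))
        u_h = rng.normal(0.0, sp.sigma_pair, size=design.n_pairs)
        u_d = rng.normal(0.0, sp.sigma_pair, size=design.n_pairs)
        for p_idx, pair in enumerate(design.pairs):
            for disturbed in (1, 0):
                eta_h = sp.height.linear_predictor(disturbed, pair.elevation_m)
                eta_d = sp.diameter.linear_predictor(disturbed, pair.elevation_m)
                mu_h = float(np.exp(eta_h + u_h[p_idx]))
                mu_d = float(np.exp(eta_d + u_d[p_idx]))
                for q in range(1, pair.n_quadrats + 1):
                    if rng.uniform() >= sp.occupancy:
                        continue
                    n = int(rng.poisson(mean_abundance))
                    if n == 0:
                        continue
                    h = _zt_negative_binomial(rng, mu_h, sp.nb_shape, (n,))
                    d = _zt_negative_binomial(rng, mu_d, sp.nb_shape, (n,))
                    jit_h = rng.uniform(-0.499, 0.499, size=n)
                    jit_d = rng.uniform(-0.499, 0.499, size=n)
                    h_cm = np.round(h + jit_h, 3)
                    d_cm = np.round(d + jit_d, 3)
                    if sp.lambda_rep is None:
                        buds = flowers = fruits = [None] * n
                    else:
                        total = rng.poisson(sp.lambda_rep * h_cm * d_cm)
                        split = np.array(
                            [rng.multinomial(t, [1 / 3, 1 / 3, 1 / 3]) for t in total]
                        ).reshape(n, 3)
                        buds, flowers, fruits = split[:, 0], split[:, 1], split[:, 2]
                    for i in range(n):
                        rows.append(
                            {
                                "species": sp.name,
                                "trail": pair.trail,
                                "pair_id": pair.pair_id,
                                "disturbed": disturbed,
                                "quadrat": q,
                                "elevation_m": pair.elevation_m,
                                "height_cm": h_cm[i],
                                "diameter_cm": d_cm[i],
                                "buds": buds[i],
                                "flowers": flowers[i],
                                "fruits": fruits[i],
                            }
                        )
    table = pd.DataFrame(rows, columns=PLANT_COLUMNS)
    for c in ("buds", "flowers", "fruits"):
        table[c] = table[c].astype("Float64").astype("Int64")
    return table


# ---------------------------------------------------------------------------
# quadrat images


@dataclass(frozen=True)
class QuadratImage:
    """8-bit RGB raster of one quadrat, pre-cropped to the quadrat frame."""

    pixels: np.ndarray  # H x W x 3 uint8
    quadrat_id: str

    def validate(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")


def _paint_quadrat(rng, height, width, n_green):
    """Paint exactly ``n_green`` green-dominant pixels (G > R and G > B),
    the rest grayscale or brown/red-dominant (G <= max(R, B))."""
    n = height * width
    img = np.empty((n, 3), dtype=np.uint8)
    order = rng.permutation(n)
    green_ix = order[:n_green]
    other_ix = order[n_green:]
    # green-dominant: G in [100, 255], R and B strictly below G
    g = rng.integers(100, 256, size=n_green)
    img[green_ix, 0] = rng.integers(0, g)
    img[green_ix, 1] = g
    img[green_ix, 2] = rng.integers(0, g)
    # non-green: half gray, half brown/red-dominant with G, B strictly < R
    n_other = other_ix.size
    gray = rng.uniform(size=n_other) < 0.5
    v = rng.integers(0, 256, size=n_other)
    img[other_ix, 0] = v
    img[other_ix, 1] = v
    img[other_ix, 2] = v
    brown_ix = other_ix[~gray]
    r = rng.integers(60, 256, size=brown_ix.size)
    img[brown_ix, 0] = r
    img[brown_ix, 1] = rng.integers(0, r)
    img[brown_ix, 2] = rng.integers(0, r)
    return img.reshape(height, width, 3)


def simulate_cover_images(
    design: SurveyDesign,
    params: CoverParams,
    config: SimConfig,
    seed: int,
) -> tuple[list[QuadratImage], pd.DataFrame]:
    """Simulate per-quadrat cover fractions and paint matching images.

    The latent cover ``p`` is Beta-distributed around a logit-linear
    disturbance x elevation mean with a per-pair random intercept; the image
    holds exactly ``round(p * H * W)`` green-dominant pixels, so the painted
    fraction (also returned) is the exact ground truth an ideal pixel
    classifier should recover.
    """
    design.validate()
    params.validate()
    config.validate()
    height, width = config.image_size
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    u = rng.normal(0.0, params.sigma_pair, size=design.n_pairs)
    images: list[QuadratImage] = []
    rows: list[dict] = []
    n_px = height * width
    for p_idx, pair in enumerate(design.pairs):
        for disturbed in (1, 0):
            eta = params.effects.linear_predictor(disturbed, pair.elevation_m)
            mu = 1.0 / (1.0 + np.exp(-(eta + u[p_idx])))
            a = mu * params.precision
            b = (1.0 - mu) * params.precision
            for q in range(1, pair.n_quadrats + 1):
                p = float(rng.beta(a, b))
                n_green = int(np.floor(p * n_px + 0.5))
                qid = quadrat_id(pair.pair_id, disturbed, q)
                images.append(
                    QuadratImage(_paint_quadrat(rng, height, width, n_green), qid)
                )
                rows.append(
                    {
                        "quadrat_id": qid,
                        "pair_id": pair.pair_id,
                        "trail": pair.trail,
                        "disturbed": disturbed,
                        "quadrat": q,
                        "elevation_m": pair.elevation_m,
                        "latent_p": p,
                        "true_fraction": n_green / n_px,
                        "n_green": n_green,
                    }
                )
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def reference_presets() -> tuple[list[SpeciesParams], CoverParams]:
    """Generator presets mirroring hierarchical-model estimates from a
    paired trail-side survey in the BC Coast Mountains subalpine.

    Disturbance effects are species- and trait-specific: strong green-cover
    loss on trails, strong height and diameter reductions in the blueberry
    (*V. ovalifolium*), diameter reduction in the heath (*P. empetriformis*),
    a null height response in the heather (*C. mertensiana*), and a sedge
    (*Carex*) height response whose sign reverses with elevation.  Elevation
    and interaction coefficients are small per-metre values chosen so that
    mid-elevation (~1780 m) mean sizes are field-realistic (roughly 8-15
    cm); NB shape, random-intercept spread, cover precision, and
    reproduction rates are configurable survey-realism choices, not
    published estimates.
    """
    presets = [
        SpeciesParams(
            name="Phyllodoce empetriformis",
            height=TraitEffects(7.04, -0.48, -0.0027, 0.0),
            diameter=TraitEffects(10.48, -7.15, -0.0047, 0.004),
            lambda_rep=0.08,
            occupancy=0.40,
        ),
        SpeciesParams(
            name="Cassiope mertensiana",
            height=TraitEffects(7.90, 0.66, -0.0031, 0.0),
            diameter=TraitEffects(9.44, -2.51, -0.0040, 0.0012),
            lambda_rep=0.08,
            occupancy=0.35,
        ),
        SpeciesParams(
            name="Vaccinium ovalifolium",
            height=TraitEffects(2.13, -4.58, 0.0003, 0.002),
            diameter=TraitEffects(6.39, -9.18, -0.0022, 0.005),
            lambda_rep=0.05,
            occupancy=0.50,
        ),
        SpeciesParams(
            name="Carex spp.",
            height=TraitEffects(22.62, -19.89, -0.0115, 0.0115),
            diameter=TraitEffects(-6.29, 11.98, 0.005, -0.0065),
            lambda_rep=None,
            occupancy=0.17,
        ),
    ]
    cover = CoverParams(
        effects=TraitEffects(6.58, -8.38, -0.003, 0.002),
        precision=10.0,
        sigma_pair=0.3,
    )
    return presets, cover


# ---------------------------------------------------------------------------
# on-disk formats


def write_plant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_plant_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PLANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plant table missing columns: {missing}")
    for c in ("buds", "flowers", "fruits"):
        table[c] = table[c].astype("Float64").astype("Int64")
    return table


def write_images(images: Sequence[QuadratImage], directory: str | Path) -> list[Path]:
    """Write one 8-bit RGB PNG per quadrat, named ``<quadrat_id>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in images:
        img.validate()
        path = directory / f"{img.quadrat_id}.png"
        Image.fromarray(img.pixels, mode="RGB").save(path)
        paths.append(path)
    return paths
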