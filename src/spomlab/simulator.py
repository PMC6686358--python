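"""Forward Markov-chain simulation and synthetic study generation.

The synthetic study emulates a multi-street annual census design:
patches laid out linearly along streets, a handful of point green
spaces, several species each evolving under its own generating model,
yearly surveys with configurable blanked (unsurveyed) years.

Updating is synchronous: colonization and extinction probabilities for
the step t -> t+1 are all evaluated on the year-t state, then every
patch draws its next state independently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from spomlab.spom_models import (
    UNOBSERVED,
    ModelSpec,
    OccupancySeries,
    ParameterVector,
    PatchNetwork,
    colonization_prob,
    connectivity,
    extinction_prob,
)

__all__ = [
    "GreenSpace",
    "StreetConfig",
    "SpeciesConfig",
    "StudyConfig",
    "SyntheticStudy",
    "generate_network",
    "street_distance_to_green_spaces",
    "simulate_series",
    "apply_missing_years",
    "generate_study",
]


@dataclass(frozen=True)
class GreenSpace:
    """A potential external seed source, reduced to a point location."""

    name: str
    location: tuple[float, float]

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.location)):
            raise ValueError("green space location must be finite")


@dataclass(frozen=True)
class StreetConfig:
    name: str
    n_patches: int
    patch_spacing: float = 8.0
    jitter: float = 1.0
    green_space_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patches < 2:
            raise ValueError("a street needs at least 2 patches")
        if self.patch_spacing <= 0:
            raise ValueError("patch_spacing must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    spec: ModelSpec
    params: ParameterVector
    longevity_class: int = 1
    max_height_cm: float = 50.0

    def __post_init__(self) -> None:
        if self.longevity_class not in (1, 2):
            raise ValueError("longevity_class must be 1 or 2")
        if self.max_height_cm <= 0:
            raise ValueError("max_height_cm must be > 0")
        self.params.validate_for(self.spec)


@dataclass(frozen=True)
class StudyConfig:
    """Full design of a synthetic multi-street, multi-species study."""

    streets: tuple[StreetConfig, ...]
    species: tuple[SpeciesConfig, ...]
    years: tuple[int, ...] = (2009, 2010, 2011, 2012, 2013, 2014, 2015)
    missing_years: tuple[int, ...] = (2013,)
    initial_occupancy_prob: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        street_names = [s.name for s in self.streets]
        if len(set(street_names)) != len(street_names):
            raise ValueError("duplicate street names")
        species_names = [s.name for s in self.species]
        if len(set(species_names)) != len(species_names):
            raise ValueError("duplicate species names")
        if not set(self.missing_years) <= set(self.years):
            raise ValueError("missing_years must be a subset of years")
        if not 0.0 <= self.initial_occupancy_prob <= 1.0:
            raise ValueError("initial_occupancy_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticStudy:
    """Output bundle of :func:`generate_study`."""

    config: StudyConfig
    networks: Mapping[str, PatchNetwork]
    series: Mapping[tuple[str, str], OccupancySeries]
    street_covariates: pd.DataFrame = field(compare=False)
    species_traits: pd.DataFrame = field(compare=False)


def _substream_seed(base_seed: int, *labels: str) -> int:
    """Stable per-label RNG substream so adding a species leaves others alone."""
    digest = hashlib.sha256(
        ("\x1f".join(map(str, labels)) + f"\x1f{base_seed}").encode()
    ).digest()
    return int.from_bytes(digest[:8], "little")


def generate_network(
    n_patches: int,
    spacing: float,
    jitter: float = 0.0,
    seed: int = 0,
    street_id: str = "street",
    origin: tuple[float, float] = (0.0, 0.0),
) -> PatchNetwork:
    """Lay ``n_patches`` on a line at ``k * spacing`` plus uniform jitter.

    Jitter is drawn along the street axis in ``[-jitter, +jitter]``.
    """
    if n_patches < 2:
        raise ValueError("n_patches must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(n_patches) * spacing
    if jitter > 0:
        x = x + rng.uniform(-jitter, jitter, size=n_patches)
    coords = np.column_stack([origin[0] + x, np.full(n_patches, origin[1])])
    ids = tuple(f"{street_id}_{k:04d}" for k in range(n_patches))
    return PatchNetwork(street_id=street_id, patch_ids=ids, coords=coords)


def street_distance_to_green_spaces(
    network: PatchNetwork, spaces: Sequence[GreenSpace]
) -> tuple[float, str]:
    """Smallest mean patch-to-space distance, and which space attains it.

    For each green space, average the Euclidean distance from every patch
    to the space; return the minimum of those means.
    """
    if not spaces:
        raise ValueError("at least one green space required")
    best_d, best_name = np.inf, None
    for space in spaces:
        d = np.linalg.norm(network.coords - np.asarray(space.location), axis=1)
        mean_d = float(d.mean())
        if mean_d < best_d:
            best_d, best_name = mean_d, space.name
    return best_d, best_name


def simulate_series(
    network: PatchNetwork,
    spec: ModelSpec,
    params: ParameterVector,
    initial: Sequence[int] | np.ndarray,
    n_steps: int,
    seed: int = 0,
    years: Sequence[int] | None = None,
) -> OccupancySeries:
    """Simulate ``n_steps`` synchronous annual transitions from ``initial``.

    Each step: compute every patch's colonization probability from the
    current state (constant for PRM, connectivity-driven for LM) and its
    extinction probability, then draw all patches' next states
    independently.  Returns a series of ``n_steps + 1`` years.
    """
    initial = np.asarray(initial)
    if initial.shape != (network.n_patches,):
        raise ValueError("initial state length must equal patch count")
    if np.any(initial == UNOBSERVED) or not np.all(np.isin(initial, (0, 1))):
        raise ValueError("initial state must be fully observed 0/1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    params.validate_for(spec)
    if years is None:
        years = tuple(range(n_steps + 1))
    else:
        years = tuple(int(y) for y in years)
        if len(years) != n_steps + 1:
            raise ValueError(f"need {n_steps + 1} year labels, got {len(years)}")

    rng = np.random.default_rng(seed)
    n = network.n_patches
    states = np.empty((n, n_steps + 1), dtype=np.int8)
    states[:, 0] = initial
    state = initial.astype(np.int8)
    for t in range(n_steps):
        if spec.family == "LM":
            s = connectivity(state, network, params.alpha)
            c = colonization_prob(spec, params, s)
        else:
            c = np.full(n, colonization_prob(spec, params))
        e = extinction_prob(spec, params, c)
        u = rng.random(n)
        nxt = np.where(state == 0, (u < c), ~(u < e)).astype(np.int8)
        states[:, t + 1] = nxt
        state = nxt
    return OccupancySeries(
        network_ref=network.street_id,
        patch_ids=network.patch_ids,
        years=years,
        states=states,
    )


def apply_missing_years(
    series: OccupancySeries, missing: Iterable[int]
) -> OccupancySeries:
    """Blank the named survey years (columns set to UNOBSERVED, labels kept)."""
    missing = tuple(missing)
    unknown = set(missing) - set(series.years)
    if unknown:
        raise ValueError(f"unknown year labels: {sorted(unknown)}")
    if not missing:
        return series
    states = series.states.copy()
    for y in missing:
        states[:, series.years.index(y)] = UNOBSERVED
    return replace(series, states=states)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Simulate one occupancy series per (street, species) pair.

    Each pair draws from an independent RNG substream derived from the
    study seed by hashing the street and species labels, so the design
    can be extended without perturbing existing draws.  Emits street
    covariate and species trait tables alongside the series.
    """
    n_steps = len(config.years) - 1
    networks: dict[str, PatchNetwork] = {}
    series: dict[tuple[str, str], OccupancySeries] = {}
    street_rows, species_rows = [], []

    for street in config.streets:
        net = generate_network(
            n_patches=street.n_patches,
            spacing=street.patch_spacing,
            jitter=street.jitter,
            seed=_substream_seed(config.rng_seed, "network", street.name),
            street_id=street.name,
        )
        networks[street.name] = net
        street_rows.append(
            {
                "street": street.name,
                "n_tree_bases": street.n_patches,
                "smallest_distance_m": street.green_space_distance,
            }
        )

    for sp in config.species:
        species_rows.append(
            {
                "species": sp.name,
                "model": sp.spec.label,
                "longevity_class": sp.longevity_class,
                "max_height_cm": sp.max_height_cm,
            }
        )
        for street in config.streets:
            net = networks[street.name]
            sub = _substream_seed(config.rng_seed, "series", street.name, sp.name)
            init_rng = np.random.default_rng(
                _substream_seed(config.rng_seed, "init", street.name, sp.name)
            )
            initial = (
                init_rng.random(net.n_patches) < config.initial_occupancy_prob
            ).astype(np.int8)
            s = simulate_series(
                net, sp.spec, sp.params, initial, n_steps, seed=sub, years=config.years
            )
            series[(street.name, sp.name)] = apply_missing_years(
                s, config.missing_years
            )

    return SyntheticStudy(
        config=config,
        networks=networks,
        series=series,
        street_covariates=pd.DataFrame(street_rows),
        species_traits=pd.DataFrame(species_rows),
    )
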