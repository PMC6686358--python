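"""Core domain types and per-patch colonization/extinction functions.

Four model variants are supported, identified by :class:`ModelSpec`:

======  ===============================  ==========================
label   colonization                     extinction
======  ===============================  ==========================
PRM     constant ``C``                   ``E * (1 - C_i)``
LM      ``1 - exp(-y * S_i)``            ``E * (1 - C_i)``
PRM+R   constant ``C``                   ``E * (1 - C_i)**R``
LM+R    ``1 - exp(-y * S_i)``            ``E * (1 - C_i)**R``
======  ===============================  ==========================

``S_i`` is the connectivity of patch *i*: the sum over the *other*
patches of their occupancy weighted by a negative-exponential dispersal
kernel ``exp(-alpha * d_ij)``.  The non-rescue extinction is the rescue
form with ``R`` pinned at 1, which makes the model nesting explicit.
A ``base_extinction="constant"`` switch is available to use ``E`` alone
for the non-rescue models instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "UNOBSERVED",
    "MODEL_LABELS",
    "PatchNetwork",
    "OccupancySeries",
    "ModelSpec",
    "ParameterVector",
    "dispersal_kernel",
    "connectivity",
    "colonization_prob",
    "extinction_prob",
]

#: Sentinel for an unobserved occupancy cell (whole survey years may be blank).
UNOBSERVED: int = -1

#: Canonical model labels in tie-break (lexicographic) order within equal k.
MODEL_LABELS = ("LM", "LM+R", "PRM", "PRM+R")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchNetwork:
    """Spatial layout of the patches of one street.

    Parameters
    ----------
    street_id
        Street label.
    patch_ids
        Ordered patch labels, one per row of ``coords``.
    coords
        ``(n, 2)`` planar coordinates in meters (already projected).
    """

    street_id: str
    patch_ids: tuple[str, ...]
    coords: np.ndarray
    dist: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {coords.shape}")
        if len(self.patch_ids) != coords.shape[0]:
            raise ValueError(
                f"{len(self.patch_ids)} patch_ids but {coords.shape[0]} coordinate rows"
            )
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise ValueError("duplicate patch_ids")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", coords)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        dist.flags.writeable = False
        object.__setattr__(self, "dist", dist)

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)


@dataclass(frozen=True)
class OccupancySeries:
    """Binary presence/absence matrix of one street, patches x survey years.

    ``states`` entries are 0 (absent), 1 (present) or :data:`UNOBSERVED`.
    Years are calendar labels and need not be contiguous; a fully blank
    column records a survey year that was skipped.
    """

    network_ref: str
    patch_ids: tuple[str, ...]
    years: tuple[int, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if not np.issubdtype(states.dtype, np.integer):
            if not np.all(np.isin(states[np.isfinite(states)], (0, 1, UNOBSERVED))):
                raise ValueError("states entries must be 0, 1 or UNOBSERVED")
            states = states.astype(np.int8)
        if states.shape != (len(self.patch_ids), len(self.years)):
            raise ValueError(
                f"states shape {states.shape} inconsistent with "
                f"{len(self.patch_ids)} patches x {len(self.years)} years"
            )
        bad = ~np.isin(states, (0, 1, UNOBSERVED))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid occupancy value {states[i, j]} at patch "
                f"{self.patch_ids[i]!r}, year {self.years[j]}"
            )
        if len(self.years) != len(set(self.years)):
            raise ValueError("duplicate year labels")
        if list(self.years) != sorted(self.years):
            raise ValueError("years must be increasing")
        if self.n_observed_years < 2:
            raise ValueError("an occupancy series needs at least 2 surveyed years")
        states = states.astype(np.int8)
        states.flags.writeable = False
        object.__setattr__(self, "states", states)

    @property
    def n_patches(self) -> int:
        return len(self.patch_ids)

    @property
    def observed_years(self) -> tuple[int, ...]:
        """Years whose column contains at least one observed cell."""
        obs = (self.states != UNOBSERVED).any(axis=0)
        return tuple(y for y, o in zip(self.years, obs) if o)

    @property
    def n_observed_years(self) -> int:
        return len(self.observed_years)


@dataclass(frozen=True)
class ModelSpec:
    """Which of the four models: family LM or PRM, with or without rescue."""

    family: Literal["LM", "PRM"]
    rescue: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("LM", "PRM"):
            raise ValueError(f"family must be 'LM' or 'PRM', got {self.family!r}")

    @property
    def label(self) -> str:
        return f"{self.family}+R" if self.rescue else self.family

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ("C", "E") if self.family == "PRM" else ("alpha", "y", "E")
        return names + ("R",) if self.rescue else names

    @property
    def k(self) -> int:
        """Number of free parameters (2, 3 or 4)."""
        return len(self.param_names)

    @classmethod
    def from_label(cls, label: str) -> "ModelSpec":
        if label not in MODEL_LABELS:
            raise ValueError(f"unknown model label {label!r}")
        family, _, rescue = label.partition("+")
        return cls(family=family, rescue=rescue == "R")


@dataclass(frozen=True)
class ParameterVector:
    """Parameters for one model.

    C : colonization probability per year (PRM family).
    E : intrinsic extinction probability per year.
    alpha : inverse mean dispersal distance, 1/m (LM family).
    y : colonization scaling per unit connectivity (LM family).
    R : rescue strength exponent; larger R means stronger rescue.
    """

    E: float
    C: float | None = None
    alpha: float | None = None
    y: float | None = None
    R: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.E <= 1.0:
            raise ValueError(f"E must be in [0, 1], got {self.E}")
        if self.C is not None and not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must be in [0, 1], got {self.C}")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.y is not None and self.y <= 0:
            raise ValueError(f"y must be > 0, got {self.y}")
        if self.R is not None and self.R < 0:
            raise ValueError(f"R must be >= 0, got {self.R}")

    def validate_for(self, spec: ModelSpec) -> None:
        """Raise unless every parameter the spec needs is present."""
        for name in spec.param_names:
            if getattr(self, name) is None:
                raise ValueError(f"model {spec.label} requires parameter {name!r}")

    def as_dict(self, spec: ModelSpec) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in spec.param_names}


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------


def dispersal_kernel(d, alpha: float):
    """Negative-exponential dispersal kernel ``exp(-alpha * d)``.

    ``1/alpha`` is the mean dispersal distance.  Accepts scalar or array
    ``d``; returns the same shape.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    out = np.exp(-alpha * d)
    return float(out) if out.ndim == 0 else out


def connectivity(
    occupancy: Sequence[int] | np.ndarray,
    network: PatchNetwork,
    alpha: float,
    i: int | None = None,
):
    """Connectivity ``S_i = sum_{j != i} O_j * exp(-alpha * d_ij)``.

    The self-term is excluded, so a patch's own occupancy never feeds its
    connectivity.  With ``i`` given, returns the scalar ``S_i``; without,
    returns the vector of ``S`` for every patch (one kernel evaluation).
    """
    occ = np.asarray(occupancy)
    if occ.shape != (network.n_patches,):
        raise ValueError(
            f"occupancy length {occ.shape} does not match {network.n_patches} patches"
        )
    if np.any(occ == UNOBSERVED) or not np.all(np.isin(occ, (0, 1))):
        raise ValueError("connectivity requires a fully observed 0/1 occupancy state")
    kernel = dispersal_kernel(network.dist, alpha)
    np.fill_diagonal(kernel, 0.0)
    s = kernel @ occ.astype(float)
    if i is None:
        return s
    if not 0 <= i < network.n_patches:
        raise IndexError(f"patch index {i} out of range")
    return float(s[i])


def colonization_prob(spec: ModelSpec, params: ParameterVector, S_i=None):
    """Per-patch colonization probability for one annual step.

    PRM family: the constant ``C`` (``S_i`` ignored).  LM family:
    ``1 - exp(-y * S_i)``.  ``S_i`` may be a scalar or an array.
    """
    params.validate_for(spec)
    if spec.family == "PRM":
        return params.C
    if S_i is None:
        raise ValueError("LM-family colonization requires connectivity S_i")
    s = np.asarray(S_i, dtype=float)
    if np.any(s < 0):
        raise ValueError("connectivity must be >= 0")
    out = -np.expm1(-params.y * s)
    return float(out) if out.ndim == 0 else out


def extinction_prob(
    spec: ModelSpec,
    params: ParameterVector,
    C_it,
    base_extinction: Literal["eq_coupled", "constant"] = "eq_coupled",
):
    """Per-patch extinction probability ``E * (1 - C_it)**R``.

    ``R`` is pinned at 1 for non-rescue models and free (``R >= 0``) for
    rescue models.  With ``base_extinction="constant"`` the non-rescue
    models use the intrinsic ``E`` alone, ignoring ``C_it``.
    """
    params.validate_for(spec)
    c = np.asarray(C_it, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("C_it must be in [0, 1]")
    if spec.rescue:
        r = params.R
    elif base_extinction == "constant":
        out = np.broadcast_to(np.asarray(params.E, dtype=float), c.shape).copy()
        return float(out) if out.ndim == 0 else out
    elif base_extinction == "eq_coupled":
        r = 1.0
    else:
        raise ValueError(f"unknown base_extinction mode {base_extinction!r}")
    out = params.E * (1.0 - c) ** r
    return float(out) if out.ndim == 0 else out
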