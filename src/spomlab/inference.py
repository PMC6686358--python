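"""Transition likelihood, maximum-likelihood fitting, and AICc selection.

An occupancy series factorizes into patch-level annual transitions.
Conditional on the year-t state, each patch moves independently:
an empty patch is colonized with probability ``C_i(t)``, an occupied
patch goes extinct with probability ``E_i(t)``.  The log-likelihood of a
parameter vector is the sum of the log transition probabilities over all
retained year pairs and patches.

Years spanning an unsurveyed census (e.g. a skipped year) are dropped by
default (``gap_policy="drop_gaps"``) so all four models are compared on
identical data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from spomlab.spom_models import (
    MODEL_LABELS,
    UNOBSERVED,
    ModelSpec,
    OccupancySeries,
    ParameterVector,
    PatchNetwork,
)

__all__ = [
    "PROB_CLAMP",
    "TransitionDataset",
    "OptimizerConfig",
    "FitResult",
    "SelectionResult",
    "build_transitions",
    "transition_loglik",
    "aicc",
    "fit_model",
    "select_model",
]

logger = logging.getLogger(__name__)

#: Probabilities are clamped to [PROB_CLAMP, 1 - PROB_CLAMP] inside the
#: likelihood only, to keep logs finite at parameter-space boundaries.
PROB_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# Transition data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionPair:
    year_t: int
    year_u: int
    state_t: np.ndarray
    state_u: np.ndarray

    @property
    def gap(self) -> bool:
        """True when more than one survey interval separates the years."""
        return self.year_u - self.year_t > 1


@dataclass(frozen=True)
class TransitionDataset:
    """Consecutive observed-year state pairs extracted from a series.

    ``patch_indices`` maps the rows of the state vectors back to rows of
    the full patch network; patches never observed in any year are
    dropped here (they carry no data), so likelihoods must subset the
    network's distance matrix accordingly.
    """

    pairs: tuple[TransitionPair, ...]
    n_transitions: int
    patch_indices: tuple[int, ...]

    @property
    def n_colonizations(self) -> int:
        return sum(int(((p.state_t == 0) & (p.state_u == 1)).sum()) for p in self.pairs)

    @property
    def n_extinctions(self) -> int:
        return sum(int(((p.state_t == 1) & (p.state_u == 0)).sum()) for p in self.pairs)

    @property
    def any_presence(self) -> bool:
        return any(p.state_t.any() or p.state_u.any() for p in self.pairs)


def build_transitions(
    series: OccupancySeries,
    gap_policy: Literal["drop_gaps", "keep_gaps"] = "drop_gaps",
) -> TransitionDataset:
    """Enumerate consecutive observed-year pairs of a series.

    Pairs spanning an unsurveyed year are dropped under ``drop_gaps``
    (the default), so likelihoods of all models are evaluated on the
    same transitions.  ``keep_gaps`` retains them flagged, for callers
    that marginalize gaps themselves.
    """
    observed = series.observed_years
    if len(observed) < 2:
        raise ValueError("need at least 2 observed years to build transitions")
    # Patches with no observation in any year carry no data; drop them so
    # they cannot perturb AICc comparisons.
    keep = np.flatnonzero((series.states != UNOBSERVED).any(axis=1))
    if keep.size == 0:
        raise ValueError("every patch is unobserved in every year")
    pairs = []
    for y_t, y_u in zip(observed[:-1], observed[1:]):
        st = series.states[keep, series.years.index(y_t)]
        su = series.states[keep, series.years.index(y_u)]
        if np.any(st == UNOBSERVED) or np.any(su == UNOBSERVED):
            raise ValueError(
                f"partially observed survey year in pair ({y_t}, {y_u}); "
                "likelihood requires fully known states"
            )
        pair = TransitionPair(year_t=y_t, year_u=y_u, state_t=st, state_u=su)
        if pair.gap and gap_policy == "drop_gaps":
            continue
        pairs.append(pair)
    if not pairs:
        raise ValueError("no usable transition pairs after gap policy")
    n = sum(p.state_t.size for p in pairs)
    return TransitionDataset(
        pairs=tuple(pairs),
        n_transitions=n,
        patch_indices=tuple(int(i) for i in keep),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _subset_dist(network: PatchNetwork, data: TransitionDataset) -> np.ndarray:
    """Distance matrix restricted to the patches retained in the data."""
    idx = data.patch_indices
    if len(idx) == network.n_patches:
        return network.dist
    if max(idx) >= network.n_patches:
        raise ValueError("transition data references patches outside the network")
    return network.dist[np.ix_(idx, idx)]


def _step_probs(
    spec: ModelSpec,
    params: ParameterVector,
    state_t: np.ndarray,
    kernel: np.ndarray | None,
    base_extinction: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patch (colonization, extinction) probabilities for one step."""
    n = state_t.size
    if spec.family == "LM":
        s = kernel @ state_t.astype(float)
        c = -np.expm1(-params.y * s)
    else:
        c = np.full(n, params.C, dtype=float)
    if spec.rescue:
        e = params.E * (1.0 - c) ** params.R
    elif base_extinction == "constant":
        e = np.full(n, params.E, dtype=float)
    else:
        e = params.E * (1.0 - c)
    return c, e


def transition_loglik(
    spec: ModelSpec,
    params: ParameterVector,
    data: TransitionDataset,
    network: PatchNetwork | None = None,
    base_extinction: Literal["eq_coupled", "constant"] = "eq_coupled",
) -> float:
    """Log-likelihood of the transition data under one model.

    Sums ``log C`` for 0->1, ``log(1-C)`` for 0->0, ``log E`` for 1->0 and
    ``log(1-E)`` for 1->1 over every retained pair and patch, with the
    colonization probability evaluated on the year-t state.
    """
    params.validate_for(spec)
    for name in spec.param_names:
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"non-finite parameter {name}")
    kernel = None
    if spec.family == "LM":
        if network is None:
            raise ValueError("LM-family likelihood requires the patch network")
        kernel = np.exp(-params.alpha * _subset_dist(network, data))
        np.fill_diagonal(kernel, 0.0)
    ll = 0.0
    for pair in data.pairs:
        c, e = _step_probs(spec, params, pair.state_t, kernel, base_extinction)
        c = np.clip(c, PROB_CLAMP, 1.0 - PROB_CLAMP)
        e = np.clip(e, PROB_CLAMP, 1.0 - PROB_CLAMP)
        empty = pair.state_t == 0
        ll += float(
            np.sum(
                np.where(
                    empty,
                    np.where(pair.state_u == 1, np.log(c), np.log1p(-c)),
                    np.where(pair.state_u == 0, np.log(e), np.log1p(-e)),
                )
            )
        )
    return ll


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    ``-2 * loglik + 2k + 2k(k+1) / (n - k - 1)``; undefined for
    ``n <= k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OptimizerConfig:
    """Multi-start derivative-free local optimization settings.

    Starts are a deterministic grid on the transformed scales (logit for
    C and E, log for alpha, y, R); the likelihood surface of the
    LM family can be multimodal in (alpha, y).
    """

    c_starts: tuple[float, ...] = (0.1, 0.5)
    e_starts: tuple[float, ...] = (0.1, 0.5)
    alpha_starts: tuple[float, ...] = (1 / 5, 1 / 50)
    y_starts: tuple[float, ...] = (0.1, 2.0)
    r_starts: tuple[float, ...] = (0.5, 2.0)
    tol: float = 1e-8
    max_iter: int = 2000
    base_extinction: Literal["eq_coupled", "constant"] = "eq_coupled"


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    mle: ParameterVector
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_restarts_used: int
    identifiable: bool = True

    def params_dict(self) -> dict[str, float]:
        return self.mle.as_dict(self.spec)


@dataclass(frozen=True)
class SelectionResult:
    street: str
    species: str
    fits: dict[str, FitResult] = field(compare=False)
    best: str = ""
    delta_aicc: dict[str, float] = field(default_factory=dict, compare=False)


def _make_negloglik(
    spec: ModelSpec,
    data: TransitionDataset,
    network: PatchNetwork | None,
    base_extinction: str,
):
    """Vectorized negative log-likelihood over the transformed parameters.

    Used by :func:`fit_model` for speed; agrees with
    :func:`transition_loglik` to floating-point roundoff.  The PRM family
    collapses to the four transition counts; the LM family evaluates all
    pairs through one kernel matrix product per call.
    """
    state_t = np.stack([p.state_t for p in data.pairs])
    state_u = np.stack([p.state_u for p in data.pairs])
    empty = state_t == 0
    col = empty & (state_u == 1)
    stay0 = empty & (state_u == 0)
    ext = ~empty & (state_u == 0)
    stay1 = ~empty & (state_u == 1)
    rescue = spec.rescue
    lo, hi = PROB_CLAMP, 1.0 - PROB_CLAMP

    if spec.family == "PRM":
        n01, n00 = int(col.sum()), int(stay0.sum())
        n10, n11 = int(ext.sum()), int(stay1.sum())

        def negll(z: np.ndarray) -> float:
            c = expit(z[0])
            e_int = expit(z[1])
            if rescue:
                e = e_int * (1.0 - c) ** np.exp(z[2])
            elif base_extinction == "constant":
                e = e_int
            else:
                e = e_int * (1.0 - c)
            c = min(max(c, lo), hi)
            e = min(max(e, lo), hi)
            return -(
                n01 * np.log(c)
                + n00 * np.log1p(-c)
                + n10 * np.log(e)
                + n11 * np.log1p(-e)
            )

        return negll

    dist = _subset_dist(network, data)
    state_t_f = state_t.astype(float)

    def negll(z: np.ndarray) -> float:
        alpha, y = np.exp(z[0]), np.exp(z[1])
        e_int = expit(z[2])
        kernel = np.exp(-alpha * dist)
        np.fill_diagonal(kernel, 0.0)
        s = state_t_f @ kernel  # kernel is symmetric
        c = -np.expm1(-y * s)
        if rescue:
            e = e_int * (1.0 - c) ** np.exp(z[3])
        elif base_extinction == "constant":
            e = np.full_like(c, e_int)
        else:
            e = e_int * (1.0 - c)
        np.clip(c, lo, hi, out=c)
        np.clip(e, lo, hi, out=e)
        return -(
            np.log(c[col]).sum()
            + np.log1p(-c[stay0]).sum()
            + np.log(e[ext]).sum()
            + np.log1p(-e[stay1]).sum()
        )

    return negll


_TRANSFORMS = {
    "C": (logit, expit),
    "E": (logit, expit),
    "alpha": (np.log, np.exp),
    "y": (np.log, np.exp),
    "R": (np.log, np.exp),
}


def _to_params(spec: ModelSpec, z: np.ndarray) -> ParameterVector:
    kwargs = {}
    for name, val in zip(spec.param_names, z):
        kwargs[name] = float(_TRANSFORMS[name][1](val))
    return ParameterVector(**kwargs)


def _start_grid(spec: ModelSpec, opt: OptimizerConfig) -> list[np.ndarray]:
    grids = {
        "C": opt.c_starts,
        "E": opt.e_starts,
        "alpha": opt.alpha_starts,
        "y": opt.y_starts,
        "R": opt.r_starts,
    }
    axes = [
        [float(_TRANSFORMS[name][0](v)) for v in grids[name]]
        for name in spec.param_names
    ]
    return [np.array(pt) for pt in product(*axes)]


def fit_model(
    spec: ModelSpec,
    data: TransitionDataset,
    network: PatchNetwork | None = None,
    opt: OptimizerConfig | None = None,
) -> FitResult:
    """Maximize the transition log-likelihood for one model.

    Parameters are optimized on transformed scales (logit for the
    probabilities C and E, log for alpha, y, R) by Nelder–Mead from a
    deterministic grid of starts; the best local optimum is kept.
    """
    opt = opt or OptimizerConfig()
    k = spec.k
    if data.n_transitions < k + 2:
        raise ValueError(
            f"need at least k+2={k + 2} transitions to fit {spec.label}, "
            f"got {data.n_transitions}"
        )
    if spec.family == "LM" and network is None:
        raise ValueError("LM-family fits require the patch network")

    neg_ll = _make_negloglik(spec, data, network, opt.base_extinction)

    best_z, best_val, any_success = None, np.inf, False
    starts = _start_grid(spec, opt)
    for z0 in starts:
        res = minimize(
            neg_ll,
            z0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-6,
                "fatol": opt.tol,
                "maxiter": opt.max_iter,
                "maxfev": opt.max_iter,
            },
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_val:
            best_val, best_z = res.fun, res.x
    mle = _to_params(spec, best_z)
    loglik = -best_val
    # An MLE pinned near a boundary of the transformed box signals a flat or
    # monotone likelihood (e.g. a series with no colonization events at all).
    identifiable = bool(np.all(np.abs(best_z) < 11.0))
    return FitResult(
        spec=spec,
        mle=mle,
        loglik=loglik,
        k=k,
        n=data.n_transitions,
        aicc=aicc(loglik, k, data.n_transitions),
        converged=any_success,
        n_restarts_used=len(starts),
        identifiable=identifiable,
    )


def select_model(
    series: OccupancySeries,
    network: PatchNetwork,
    opt: OptimizerConfig | None = None,
    street: str | None = None,
    species: str = "",
    gap_policy: Literal["drop_gaps", "keep_gaps"] = "drop_gaps",
) -> SelectionResult:
    """Fit all four models and pick the one with the smallest AICc.

    AICc ties (within 1e-9) are broken toward fewer parameters, then
    lexicographically by label.  A series with no presence at all carries
    no information and is rejected.
    """
    data = build_transitions(series, gap_policy=gap_policy)
    if not data.any_presence:
        raise ValueError(
            f"series {series.network_ref!r}/{species!r} is all-absent; "
            "no model can be selected"
        )
    fits: dict[str, FitResult] = {}
    for label in MODEL_LABELS:
        spec = ModelSpec.from_label(label)
        fits[label] = fit_model(spec, data, network, opt)
        if not fits[label].converged:
            logger.warning(
                "fit of %s on %s/%s did not report convergence",
                label,
                series.network_ref,
                species,
            )
    converged = {l: f for l, f in fits.items() if f.converged} or fits
    min_aicc = min(f.aicc for f in converged.values())
    tied = [f for f in converged.values() if f.aicc - min_aicc < 1e-9]
    best = min(tied, key=lambda f: (f.k, f.spec.label))
    return SelectionResult(
        street=street if street is not None else series.network_ref,
        species=species,
        fits=fits,
        best=best.spec.label,
        delta_aicc={l: f.aicc - best.aicc for l, f in fits.items()},
    )
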