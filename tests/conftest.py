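import math

import numpy as np
import pytest

from spomlab import (
    ModelSpec,
    OccupancySeries,
    ParameterVector,
    PatchNetwork,
    generate_network,
)


@pytest.fixture
def line3() -> PatchNetwork:
    """Three collinear patches at 0, 10, 20 m."""
    return generate_network(3, 10.0, jitter=0.0, seed=0, street_id="line3")


@pytest.fixture
def pair100() -> PatchNetwork:
    """Two patches 100 m apart."""
    return PatchNetwork(
        street_id="pair", patch_ids=("a", "b"), coords=np.array([[0.0, 0.0], [100.0, 0.0]])
    )


def random_series(
    rng: np.random.Generator, n_patches: int, n_years: int, street: str = "s"
) -> tuple[PatchNetwork, OccupancySeries]:
    """A random small network plus iid random occupancy (for oracle checks)."""
    coords = rng.uniform(0, 60, size=(n_patches, 2))
    net = PatchNetwork(
        street_id=street,
        patch_ids=tuple(f"p{i}" for i in range(n_patches)),
        coords=coords,
    )
    states = (rng.random((n_patches, n_years)) < 0.5).astype(np.int8)
    series = OccupancySeries(
        network_ref=street,
        patch_ids=net.patch_ids,
        years=tuple(range(2000, 2000 + n_years)),
        states=states,
    )
    return net, series


def brute_force_loglik(
    spec: ModelSpec,
    params: ParameterVector,
    series: OccupancySeries,
    net: PatchNetwork,
) -> float:
    """Independent transition log-likelihood: explicit loops, no shared code.

    Assumes a fully observed series with consecutive years (no gaps).
    """
    ll = 0.0
    n_years = len(series.years)
    for t in range(n_years - 1):
        for i in range(net.n_patches):
            if spec.family == "PRM":
                c = params.C
            else:
                s_i = 0.0
                for j in range(net.n_patches):
                    if j == i:
                        continue
                    d_ij = math.hypot(
                        net.coords[i, 0] - net.coords[j, 0],
                        net.coords[i, 1] - net.coords[j, 1],
                    )
                    s_i += series.states[j, t] * math.exp(-params.alpha * d_ij)
                c = 1.0 - math.exp(-params.y * s_i)
            r = params.R if spec.rescue else 1.0
            e = params.E * (1.0 - c) ** r
            c = min(max(c, 1e-12), 1 - 1e-12)
            e = min(max(e, 1e-12), 1 - 1e-12)
            before, after = series.states[i, t], series.states[i, t + 1]
            if before == 0:
                ll += math.log(c) if after == 1 else math.log(1.0 - c)
            else:
                ll += math.log(e) if after == 0 else math.log(1.0 - e)
    return ll


def random_params(rng: np.random.Generator, spec: ModelSpec) -> ParameterVector:
    kwargs = {"E": float(rng.uniform(0.05, 0.9))}
    if spec.family == "PRM":
        kwargs["C"] = float(rng.uniform(0.05, 0.9))
    else:
        kwargs["alpha"] = float(rng.uniform(0.01, 0.3))
        kwargs["y"] = float(rng.uniform(0.1, 3.0))
    if spec.rescue:
        kwargs["R"] = float(rng.uniform(0.0, 3.0))
    return ParameterVector(**kwargs)
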