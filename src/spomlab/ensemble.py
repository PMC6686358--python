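"""Best-model proportions and their regressions on covariates and traits.

Aggregates per-(street, species) best-model labels into per-unit
proportions, joins street covariates or species traits, and fits
quasi-binomial logit GLMs of (successes out of the partner count)
against a single covariate.  Point estimates equal the plain binomial
fit; the quasi-binomial dispersion (Pearson chi-square over residual
degrees of freedom) rescales the standard errors only.

Two reference tables are packaged as CSV fixtures: per-street covariates
with model percentages, and per-species traits with model percentages.
The percentages are printed rounded; :func:`counts_from_percent` inverts
them back to integer counts out of the 15 partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from spomlab.inference import SelectionResult
from spomlab.spom_models import MODEL_LABELS

__all__ = [
    "EnsembleTable",
    "GlmFit",
    "load_street_covariates",
    "load_species_traits",
    "counts_from_percent",
    "model_proportions",
    "group_mean_proportion",
    "fit_proportion_glm",
    "reproduce_paper_tables",
]


def load_street_covariates() -> pd.DataFrame:
    """Packaged per-street covariate table (15 streets)."""
    with resources.files("spomlab.data").joinpath("table1_streets.csv").open() as f:
        return pd.read_csv(f)


def load_species_traits() -> pd.DataFrame:
    """Packaged per-species trait table (15 species)."""
    with resources.files("spomlab.data").joinpath("table2_species.csv").open() as f:
        return pd.read_csv(f)


def counts_from_percent(pct: float, denom: int = 15) -> int:
    """Invert a printed rounded percentage to an integer count.

    Nearest integer to ``pct * denom / 100``, halves rounded away from
    zero (so 73% of 15 -> 11, 7% of 15 -> 1).
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage out of range: {pct}")
    return int(np.floor(pct * denom / 100.0 + 0.5))


@dataclass(frozen=True)
class EnsembleTable:
    """Best-model counts and proportions per unit (street or species)."""

    by: str
    counts: pd.DataFrame  # index = unit label, columns = model labels
    denom: int

    @property
    def proportions(self) -> pd.DataFrame:
        return self.counts / self.denom

    def overall_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def overall_fractions(self) -> pd.Series:
        total = int(self.counts.to_numpy().sum())
        return self.counts.sum(axis=0) / total


@dataclass(frozen=True)
class GlmFit:
    """Quasi-binomial logit regression of grouped proportions."""

    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    dispersion: float
    n_units: int
    pseudo_r2: float
    p_value: float


def model_proportions(
    selections: Sequence[SelectionResult],
    by: Literal["street", "species"],
) -> EnsembleTable:
    """Tabulate best-model counts per street (over species) or vice versa.

    Every unit must have the same number of partners; missing pairs are
    reported explicitly.
    """
    if by not in ("street", "species"):
        raise ValueError("by must be 'street' or 'species'")
    other = "species" if by == "street" else "street"
    units = sorted({getattr(s, by) for s in selections})
    partners = sorted({getattr(s, other) for s in selections})
    seen = {(s.street, s.species) for s in selections}
    expected = {
        (u, p) if by == "street" else (p, u) for u in units for p in partners
    }
    missing = sorted(expected - seen)
    if missing:
        raise ValueError(f"missing street-species pairs: {missing}")
    counts = pd.DataFrame(0, index=units, columns=list(MODEL_LABELS))
    for s in selections:
        counts.loc[getattr(s, by), s.best] += 1
    counts.index.name = by
    return EnsembleTable(by=by, counts=counts, denom=len(partners))


def table_to_ensemble(table: pd.DataFrame, by: str, denom: int = 15) -> EnsembleTable:
    """Build an EnsembleTable from a fixture with pct_LM/pct_LMR/pct_PRM columns."""
    counts = pd.DataFrame(
        {
            "LM": [counts_from_percent(p, denom) for p in table["pct_LM"]],
            "LM+R": [counts_from_percent(p, denom) for p in table["pct_LMR"]],
            "PRM": [counts_from_percent(p, denom) for p in table["pct_PRM"]],
            "PRM+R": 0,
        },
        index=table[by].to_numpy(),
    )
    counts.index.name = by
    return EnsembleTable(by=by, counts=counts, denom=denom)


def group_mean_proportion(
    table: EnsembleTable,
    traits: pd.DataFrame,
    model: str,
    group_by: str,
    unit_col: str | None = None,
) -> pd.Series:
    """Arithmetic mean of one model's proportion within each trait level."""
    unit_col = unit_col or table.by
    props = table.proportions[model]
    merged = traits.set_index(unit_col).join(props.rename("prop"), how="inner")
    if merged["prop"].isna().any() or len(merged) != len(table.counts):
        raise ValueError("trait table does not cover every unit")
    means = merged.groupby(group_by)["prop"].mean()
    if (merged.groupby(group_by).size() == 0).any():
        raise ValueError("empty trait group")
    return means


def fit_proportion_glm(
    successes: Iterable[int],
    covariate: Iterable[float],
    denom: int = 15,
) -> GlmFit:
    """Quasi-binomial logit GLM of (successes out of denom) on one covariate.

    Fits the grouped binomial by IRLS; the quasi-binomial dispersion is
    Pearson chi-square over ``n_units - 2`` and inflates the standard
    errors without moving the point estimates.  The p-value for the
    slope uses a t reference with ``n_units - 2`` degrees of freedom.
    """
    y = np.asarray(list(successes), dtype=float)
    x = np.asarray(list(covariate), dtype=float)
    if y.size != x.size:
        raise ValueError("successes and covariate lengths differ")
    if y.size < 3:
        raise ValueError("need at least 3 units")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if np.any((y < 0) | (y > denom)):
        raise ValueError("successes must lie in [0, denom]")
    endog = np.column_stack([y, denom - y])
    exog = sm.add_constant(x)
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        res = model.fit()
    except Exception as err:  # pragma: no cover - statsmodels raises rarely here
        raise ValueError(f"GLM failed to converge: {err}") from err
    if not np.all(np.isfinite(res.params)) or np.abs(res.params[1]) > 1e3:
        raise ValueError("non-finite or diverging coefficients (separation?)")
    df_resid = y.size - 2
    dispersion = float(res.pearson_chi2 / df_resid)
    se = np.asarray(res.bse) * np.sqrt(dispersion)
    t_stat = res.params[1] / se[1] if se[1] > 0 else np.inf
    p_value = float(2 * stats.t.sf(abs(t_stat), df_resid))
    pseudo_r2 = (
        float(1.0 - res.deviance / res.null_deviance)
        if res.null_deviance > 0
        else float("nan")
    )
    return GlmFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(se[0]),
        slope_se=float(se[1]),
        dispersion=dispersion,
        n_units=int(y.size),
        pseudo_r2=pseudo_r2,
        p_value=p_value,
    )


def reproduce_paper_tables() -> dict:
    """Recompute the headline quantities from the packaged fixture tables.

    Returns overall model fractions across the 225 street-species
    combinations, mean PRM proportion by seed-longevity class, and the
    two proportion-regression slopes (PRM vs. street distance to the
    nearest green space; LM+R vs. species maximum height).
    """
    streets = load_street_covariates()
    species = load_species_traits()
    street_tab = table_to_ensemble(streets, by="street")
    species_tab = table_to_ensemble(species, by="species")

    overall = street_tab.overall_counts()
    total = int(overall.sum())

    longevity_means = group_mean_proportion(
        species_tab, species, model="PRM", group_by="longevity_class"
    )

    prm_distance = fit_proportion_glm(
        street_tab.counts["PRM"].to_numpy(),
        streets.set_index("street").loc[
            street_tab.counts.index, "smallest_distance_m"
        ].to_numpy(),
    )
    lmr_height = fit_proportion_glm(
        species_tab.counts["LM+R"].to_numpy(),
        species.set_index("species").loc[
            species_tab.counts.index, "max_height_cm"
        ].to_numpy(),
    )

    return {
        "total_combinations": total,
        "overall_counts": {m: int(overall[m]) for m in MODEL_LABELS},
        "overall_pct": {m: 100.0 * overall[m] / total for m in MODEL_LABELS},
        "mean_prm_by_longevity": {
            int(k): float(v) for k, v in longevity_means.items()
        },
        "slope_prm_vs_distance": prm_distance.slope,
        "slope_lmr_vs_height": lmr_height.slope,
        "glm_prm_vs_distance": prm_distance,
        "glm_lmr_vs_height": lmr_height,
    }
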