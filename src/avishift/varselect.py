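"""Per-species bioclimatic variable selection.

All subsets of the eight bioclim variables with 3-5 members are
enumerated (182 combinations), screened to require at least one thermal
and one hydric member, screened for pairwise collinearity (|Pearson r|
strictly above a threshold across study cells discards the combination),
and the survivors are ranked per species by the AIC of a binomial GAM of
era-1 occupancy on the member variables.  A cross-species consensus
combination is the one appearing most often in species' top-AIC
quartiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import ceil

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .bioclim import BIOCLIM_VARS, HYDRO_VARS, THERMO_VARS

logger = logging.getLogger(__name__)

Combo = tuple[str, ...]


@dataclass
class SelectionResult:
    """AIC ranking of the surviving combinations for one species."""

    species_id: str
    table: pd.DataFrame  # columns: combo, aic, rank, top_quartile; ascending AIC

    @property
    def chosen(self) -> Combo:
        return self.table.iloc[0]["combo"]

    @property
    def top_quartile(self) -> list[Combo]:
        return list(self.table.loc[self.table["top_quartile"], "combo"])


def enumerate_combinations(
    variables: list[str] | None = None, min_size: int = 3, max_size: int = 5
) -> list[Combo]:
    """All variable subsets of sizes min..max in lexicographic order."""
    variables = sorted(variables if variables is not None else BIOCLIM_VARS)
    out: list[Combo] = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(variables, size))
    return sorted(out, key=lambda c: (len(c), c))


def screen_thermo_hydro(combos: list[Combo]) -> tuple[list[Combo], list[Combo]]:
    """Keep combinations with at least one thermal and one hydric member."""
    kept, discarded = [], []
    for combo in combos:
        members = set(combo)
        if members & THERMO_VARS and members & HYDRO_VARS:
            kept.append(combo)
        else:
            discarded.append(combo)
    return kept, discarded


def collinear_pairs(
    bioclim: pd.DataFrame, r_threshold: float = 0.7
) -> set[frozenset[str]]:
    """Variable pairs with |Pearson r| strictly above the threshold."""
    cols = [c for c in bioclim.columns]
    for c in cols:
        if bioclim[c].nunique() <= 1:
            raise ValueError(f"variable {c!r} is constant: correlation undefined")
    corr = bioclim.corr()
    pairs = set()
    for a, b in combinations(cols, 2):
        if abs(corr.loc[a, b]) > r_threshold:
            pairs.add(frozenset((a, b)))
    return pairs


def screen_collinearity(
    combos: list[Combo], bioclim: pd.DataFrame, r_threshold: float = 0.7
) -> tuple[list[Combo], list[Combo]]:
    """Discard combinations containing any collinear member pair."""
    bad = collinear_pairs(bioclim[[v for v in BIOCLIM_VARS if v in bioclim.columns]],
                          r_threshold)
    kept, discarded = [], []
    for combo in combos:
        if any(frozenset(p) in bad for p in combinations(combo, 2)):
            discarded.append(combo)
        else:
            kept.append(combo)
    return kept, discarded


def _fit_gam_aic(y: np.ndarray, X: pd.DataFrame, df_spline: int = 6) -> float:
    """AIC of a binomial GAM with a B-spline smooth per column."""
    smoother = BSplines(
        X.to_numpy(), df=[df_spline] * X.shape[1], degree=[3] * X.shape[1]
    )
    exog = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GLMGam(y, exog=exog, smoother=smoother, family=sm.families.Binomial())
        res = model.fit()
    # compute AIC from clipped fitted probabilities: under quasi-separation
    # the raw log-likelihood hits log(0) and the reported AIC is not finite
    p = np.clip(np.asarray(res.predict()), 1e-10, 1 - 1e-10)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    k = smoother.dim_basis + 1  # unpenalised fit: edf = basis dimension
    aic = -2.0 * llf + 2.0 * k
    if not np.isfinite(aic):
        raise FloatingPointError("non-finite AIC")
    return aic


def rank_by_aic(
    species_id: str,
    combos: list[Combo],
    presence: np.ndarray,
    bioclim: pd.DataFrame,
    df_spline: int = 6,
) -> SelectionResult:
    """AIC-rank surviving combinations for one species.

    One smooth binomial model per combination, fitted on all study cells
    (screening precedes the blocked cross-validation).  Combinations
    whose fit fails get +inf AIC and are logged, never fatal.  Ties are
    broken lexicographically on member names so the ranking is
    deterministic.
    """
    if not combos:
        raise ValueError("no surviving combinations to rank")
    y = np.asarray(presence, dtype=float)
    rows = []
    for combo in combos:
        try:
            aic = _fit_gam_aic(y, bioclim[list(combo)], df_spline=df_spline)
        except Exception as exc:  # non-convergence is a ranking miss, not an error
            logger.warning("GAM failed for %s %s: %s", species_id, combo, exc)
            aic = np.inf
        rows.append({"combo": combo, "aic": aic})
    table = pd.DataFrame(rows).sort_values(
        by=["aic", "combo"], key=lambda s: s if s.name == "aic" else s.map(str)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    n_top = ceil(len(table) / 4)
    table["top_quartile"] = table["rank"] <= n_top
    table = table.reset_index(drop=True)
    return SelectionResult(species_id=species_id, table=table)


def consensus_combination(
    results: list[SelectionResult],
) -> tuple[Combo, float]:
    """Most frequent top-quartile combination across species.

    Returns the winning combination and its coverage: the fraction of
    species whose top quartile contains it.  Tally ties break
    lexicographically.
    """
    if not results:
        raise ValueError("no selection results")
    tally: dict[Combo, int] = {}
    for res in results:
        for combo in res.top_quartile:
            tally[combo] = tally.get(combo, 0) + 1
    winner = min(tally, key=lambda c: (-tally[c], c))
    coverage = tally[winner] / len(results)
    return winner, coverage
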