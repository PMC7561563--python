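"""Permanent species gains/losses and normalized turnover rates.

Changes in richness between consecutive years are partitioned into gain
(colonization) and loss (extinction) rates

    Gp = G / (0.5 * (S_t1 + S_t2)),   Lp = L / (0.5 * (S_t1 + S_t2)),

where S_t1 and S_t2 are the trap's species richness at the two endpoint
years of the interval and G and L count *permanent* gains and losses:
a species is gained in a year only if it was absent in all previous
study years, and lost only if it is absent in all following study
years.  A temporary absence therefore counts as neither event.
Permanence is assessed within the observation window only, so losses
near the final year are right-censored.

Rates are computed per trap; when both endpoint richness values are
zero, the rates are undefined and flagged for exclusion downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, TraitTable, aggregate_group, group_species


@dataclass(frozen=True)
class PresenceHistory:
    """Boolean presence (count > 0) per (trap, species) across years."""

    traps: tuple
    species: tuple
    years: tuple
    presence: np.ndarray  # shape (n_traps, n_species, n_years), bool

    @classmethod
    def from_matrix(cls, matrix: CommunityMatrix, species=None) -> "PresenceHistory":
        species = tuple(species) if species is not None else matrix.species
        wide = matrix.to_wide()
        cols = [s for s in species if s in wide.columns]
        arr = (
            wide[cols]
            .to_numpy()
            .reshape(matrix.n_traps, matrix.n_years, len(cols))
            .transpose(0, 2, 1)
        )
        return cls(
            traps=matrix.traps,
            species=tuple(cols),
            years=matrix.years,
            presence=arr > 0,
        )


def permanent_gains_losses(
    presence: np.ndarray, interval: tuple[int, int]
) -> tuple[int, int]:
    """Permanent gains and losses for one trap over one interval.

    ``presence`` is a (n_species, T) boolean array for a single trap;
    ``interval`` is (t1, t2) in 1-based years with t2 = t1 + 1.

    A gain at t2 requires absence in *all* years before t2; a loss at t1
    requires absence in *all* years after t1.
    """
    presence = np.asarray(presence, dtype=bool)
    T = presence.shape[1]
    t1, t2 = interval
    if not (1 <= t1 < t2 <= T and t2 == t1 + 1):
        raise ValueError(
            f"interval {interval} outside study years 1..{T} or not consecutive"
        )
    i1, i2 = t1 - 1, t2 - 1
    absent_before = ~presence[:, :i2].any(axis=1)
    gains = presence[:, i2] & absent_before
    absent_after = ~presence[:, i2:].any(axis=1)
    losses = presence[:, i1] & absent_after
    return int(gains.sum()), int(losses.sum())


def turnover_rates(
    matrix: CommunityMatrix,
    traits: TraitTable,
    group: str = "all",
) -> pd.DataFrame:
    """Per trap x interval turnover records for one functional group.

    Returns a dataframe with columns trap, t1, t2, group, S_t1, S_t2,
    G, L, Gp, Lp and a boolean ``defined`` flag.  Gp/Lp are NaN where the
    mean endpoint richness is zero (the rates are then undefined and are
    excluded from model fits rather than imputed as 0).
    """
    if matrix.n_years < 2:
        raise ValueError("turnover needs at least 2 study years")
    members = group_species(traits, group)
    hist = PresenceHistory.from_matrix(matrix, species=members)
    richness = hist.presence.sum(axis=1)  # (n_traps, T)
    records = []
    for k, trap in enumerate(hist.traps):
        for t1 in range(1, matrix.n_years):
            t2 = t1 + 1
            G, L = permanent_gains_losses(hist.presence[k], (t1, t2))
            s1 = int(richness[k, t1 - 1])
            s2 = int(richness[k, t2 - 1])
            denom = 0.5 * (s1 + s2)
            if denom > 0:
                gp, lp = G / denom, L / denom
                defined = True
            else:
                gp = lp = np.nan
                defined = False
            records.append(
                dict(
                    trap=trap, t1=t1, t2=t2, group=group,
                    S_t1=s1, S_t2=s2, G=G, L=L, Gp=gp, Lp=lp,
                    defined=defined,
                )
            )
    return pd.DataFrame.from_records(records)


def write_turnover_csv(records: pd.DataFrame, path) -> None:
    """Write turnover records; undefined rates become empty fields."""
    records.drop(columns=["defined"]).to_csv(path, index=False, float_format="%.10g")
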