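"""Variance partitioning of community structure across predictor sets.

The explained variance of the Hellinger-transformed community is
decomposed among environment (E), year (Y) and fungal diversity (F):
RDAs are fitted for all 7 non-empty predictor subsets, each R^2 is
bias-corrected with the Ezekiel adjustment, and unique / shared
fractions are obtained by inclusion-exclusion, e.g.

    unique(E)     = adjR2(EYF) - adjR2(YF)
    shared(E,F|Y) = adjR2(EY)  - adjR2(Y) - unique(E)

Shared fractions of adjusted R^2 can legitimately be negative; they are
reported as computed and only truncated at zero when drawing the Venn
diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import HellingerMatrix, partial_rda

# re-export: the adjustment is part of this module's public surface
from .ordination import adjusted_r2  # noqa: F401

_SETS = ("E", "Y", "F", "EY", "EF", "YF", "EYF")


@dataclass(frozen=True)
class VarpartResult:
    """Adjusted-R^2 fractions for three predictor sets."""

    subset_adj_r2: dict  # 'E','Y','F','EY','EF','YF','EYF' -> adjR^2
    subset_r2: dict
    subset_df: dict
    unique: dict  # 'E','Y','F' -> unique fraction
    shared: dict  # 'EY','EF','YF','EYF' -> shared fraction
    residual: float
    n: int
    dropped_rows: int = 0

    def fractions(self) -> dict:
        out = {f"unique_{k}": v for k, v in self.unique.items()}
        out.update({f"shared_{k}": v for k, v in self.shared.items()})
        out["residual"] = self.residual
        return out

    def as_percent(self) -> dict:
        """Whole-percent report (nearest 1%), the conventional display."""
        return {k: round(100 * v) for k, v in self.fractions().items()}


def varpart3(
    Y: HellingerMatrix | np.ndarray,
    design: pd.DataFrame,
    env_term: str = "environment",
    year_term: str = "year",
    fungal_term: str = "fungal_diversity",
) -> VarpartResult:
    """Partition community variance among environment, year and fungal
    diversity.

    ``design`` holds the three predictor columns aligned with the rows
    of ``Y``; rows with missing fungal diversity are dropped (with the
    count recorded on the result).  Predictors enter additively (no
    interactions), year and environment as categorical factors and
    fungal diversity as a single numeric covariate.
    """
    vals = Y.values if isinstance(Y, HellingerMatrix) else np.asarray(Y, float)
    design = design.reset_index(drop=True)
    if len(design) != vals.shape[0]:
        raise ValueError("design rows do not align with community rows")
    keep = design[fungal_term].notna().to_numpy()
    dropped = int((~keep).sum())
    vals = vals[keep]
    design = design.loc[keep].reset_index(drop=True)
    design = design.copy()
    design[year_term] = design[year_term].astype(str)
    design[fungal_term] = design[fungal_term].astype(float)

    term_of = {"E": env_term, "Y": year_term, "F": fungal_term}
    r2, adj, dfs = {}, {}, {}
    n = vals.shape[0]
    for key in _SETS:
        terms = [term_of[c] for c in key]
        res = partial_rda(vals, design, terms)
        if n <= res.rank + 2:
            raise ValueError(
                f"too few samples (n={n}) for predictor set {key} "
                f"with {res.rank} df"
            )
        r2[key] = res.r2
        adj[key] = res.adj_r2
        dfs[key] = res.rank

    unique = {
        "E": adj["EYF"] - adj["YF"],
        "Y": adj["EYF"] - adj["EF"],
        "F": adj["EYF"] - adj["EY"],
    }
    # pairwise shared (excluding the third) and the triple overlap
    d_EY = adj["EF"] - adj["F"] - unique["E"]  # E&Y not F
    d_EF = adj["EY"] - adj["Y"] - unique["E"]  # E&F not Y
    d_YF = adj["EY"] - adj["E"] - unique["Y"]  # Y&F not E
    triple = adj["E"] - unique["E"] - d_EY - d_EF
    shared = {"EY": d_EY, "EF": d_EF, "YF": d_YF, "EYF": triple}
    residual = 1.0 - adj["EYF"]
    return VarpartResult(
        subset_adj_r2=adj, subset_r2=r2, subset_df=dfs,
        unique=unique, shared=shared, residual=residual,
        n=n, dropped_rows=dropped,
    )
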