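"""Constrained ordination of community composition.

Redundancy analysis (RDA) is a PCA of the fitted values of a
multivariate linear regression of the (transformed) community matrix on
a set of predictors; a *partial* RDA first residualizes both the
community and the predictors on conditioning variables.  Counts are
Hellinger transformed (square root of relative abundance per sample)
before ordination so that the implicit Euclidean distances are
ecologically meaningful.

Marginal significance of each term is assessed with a permutation
pseudo-F test: the tested term's fitted sum of squares given all other
terms, over the residual mean square, with the null distribution built
by Freedman-Lane permutation of the reduced-model residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, SiteTable

_RANK_TOL = 1e-9
_EIG_TOL = 1e-10  # eigenvalues below tol * total variance are dropped


@dataclass(frozen=True)
class HellingerMatrix:
    """Samples x species matrix of Hellinger-transformed abundances."""

    values: np.ndarray
    samples: pd.DataFrame  # row provenance: trap, year, environment, landscape
    species: tuple


def hellinger_transform(counts, samples: pd.DataFrame | None = None,
                        species=None) -> HellingerMatrix:
    """sqrt of row-relative abundance; all-zero rows stay zero."""
    if isinstance(counts, pd.DataFrame):
        species = tuple(counts.columns)
        if samples is None:
            samples = counts.index.to_frame(index=False)
        counts = counts.to_numpy()
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    rowsum = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(np.where(rowsum > 0, arr / np.where(rowsum == 0, 1, rowsum), 0.0))
    if samples is None:
        samples = pd.DataFrame(index=range(arr.shape[0]))
    if species is None:
        species = tuple(f"sp{j}" for j in range(arr.shape[1]))
    return HellingerMatrix(values=out, samples=samples.reset_index(drop=True),
                           species=tuple(species))


def community_to_hellinger(matrix: CommunityMatrix, sites: SiteTable) -> HellingerMatrix:
    """Hellinger matrix with trap/year/environment/landscape provenance."""
    wide = matrix.to_wide()
    meta = wide.index.to_frame(index=False)
    meta["environment"] = meta["trap"].map(sites.environment())
    meta["landscape"] = meta["trap"].map(sites.landscape()).astype(str)
    meta["fungal_diversity"] = meta["trap"].map(sites.fungal_diversity())
    return hellinger_transform(wide.to_numpy(), samples=meta,
                               species=tuple(wide.columns))


# ---------------------------------------------------------------------------
# factor designs

def term_columns(design: pd.DataFrame, term: str) -> tuple[np.ndarray, list]:
    """Treatment-coded columns for one model term.

    ``term`` is a column name or a ':'-joined interaction.  Categorical
    columns get dummies for all but the first (sorted) level; numeric
    columns enter as-is.  Interaction columns are element-wise products.
    """
    blocks = []
    names_blocks = []
    for f in term.split(":"):
        col = design[f]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names_blocks.append([f])
        else:
            levels = sorted(col.astype(str).unique())
            vals = col.astype(str).to_numpy()
            blocks.append(
                np.column_stack([(vals == l).astype(float) for l in levels[1:]])
                if len(levels) > 1 else np.zeros((len(col), 0))
            )
            names_blocks.append([f"{f}[{l}]" for l in levels[1:]])
    cols = blocks[0]
    names = names_blocks[0]
    for blk, nms in zip(blocks[1:], names_blocks[1:]):
        cols = np.einsum("ni,nj->nij", cols, blk).reshape(len(design), -1)
        names = [f"{a}:{b}" for a in names for b in nms]
    return cols, names


def build_design(design: pd.DataFrame, terms) -> tuple[np.ndarray, list]:
    cols, names = [], []
    for term in terms:
        c, n = term_columns(design, term)
        cols.append(c)
        names.extend(n)
    if cols:
        X = np.hstack(cols)
    else:
        X = np.zeros((len(design), 0))
    return X, names


def _check_full_rank(X: np.ndarray, names, n: int) -> None:
    """The raw design (with intercept) must be full column rank."""
    M = np.hstack([np.ones((n, 1)), X])
    if M.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(M, tol=None)
    if rank < M.shape[1]:
        # identify aliased columns by incremental rank
        aliased = []
        r = 1
        kept = np.ones((n, 1))
        for j, nm in enumerate(names):
            cand = np.hstack([kept, X[:, j:j + 1]])
            if np.linalg.matrix_rank(cand) == r:
                aliased.append(nm)
            else:
                kept = cand
                r += 1
        raise np.linalg.LinAlgError(
            f"design is rank deficient; aliased columns: {aliased}"
        )


def _orth_basis(M: np.ndarray, ref: float | None = None) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, rank-revealing).

    ``ref`` sets the scale against which singular values are judged;
    pass the norm of the *unresidualized* design so that a design fully
    absorbed by the conditioning projects to rank 0 instead of noise.
    """
    if M.shape[1] == 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((M.shape[0], 0))
    scale = max(s[0], ref) if ref is not None else s[0]
    rank = int((s > _RANK_TOL * scale).sum())
    return U[:, :rank]


def _residualize(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual of A after projection onto the (orthonormal) basis Q."""
    if Q.shape[1] == 0:
        return A
    return A - Q @ (Q.T @ A)


# ---------------------------------------------------------------------------
# partial RDA

@dataclass
class RDAResult:
    eigenvalues: np.ndarray  # constrained
    unconstrained_eigenvalues: np.ndarray
    total_variance: float
    r2: float
    adj_r2: float
    n: int
    rank: int  # constrained rank (model df)
    condition_df: int
    terms: list
    condition: list
    species: tuple
    samples: pd.DataFrame
    # internals for scores
    _U: np.ndarray = field(repr=False, default=None)
    _s: np.ndarray = field(repr=False, default=None)
    _V: np.ndarray = field(repr=False, default=None)
    _Yres: np.ndarray = field(repr=False, default=None)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment 1 - (1-R^2)(n-1)/(n-m-1)."""
    if n <= m + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def partial_rda(Y: HellingerMatrix | np.ndarray, design: pd.DataFrame,
                terms, condition=()) -> RDAResult:
    """Partial redundancy analysis.

    The community matrix is centered column-wise; response and term
    design are residualized on the conditioning design (plus intercept);
    the SVD of the fitted values of the residualized regression gives
    the constrained axes.  Eigenvalues are sums of squares / (n - 1).
    """
    if isinstance(Y, HellingerMatrix):
        vals, species, samples = Y.values, Y.species, Y.samples
    else:
        vals = np.asarray(Y, dtype=float)
        species = tuple(f"sp{j}" for j in range(vals.shape[1]))
        samples = design.reset_index(drop=True)
    n = vals.shape[0]
    if len(design) != n:
        raise ValueError("design rows do not align with community rows")
    terms = list(terms)
    condition = list(condition)

    Xz, _ = build_design(design, condition)
    Xt, names = build_design(design, terms)
    # the term design must be internally full rank; overlap with the
    # conditioning design is allowed (it is projected out)
    _check_full_rank(Xt, names, n)

    Yc = vals - vals.mean(axis=0)
    Qz = _orth_basis(np.hstack([np.ones((n, 1)), Xz]))
    cond_df = Qz.shape[1] - 1
    Yr = _residualize(Yc, Qz)
    Xr = _residualize(Xt, Qz)
    Qx = _orth_basis(Xr, ref=np.linalg.norm(Xt) if Xt.size else None)
    rank = Qx.shape[1]

    Yfit = Qx @ (Qx.T @ Yr)
    Yres = Yr - Yfit
    total = float((Yr ** 2).sum()) / (n - 1)

    U, s, Vt = np.linalg.svd(Yfit, full_matrices=False)
    lam = s ** 2 / (n - 1)
    keep = lam > _EIG_TOL * max(total, 1e-300)
    keep &= np.arange(len(lam)) < rank
    U, s, V, lam = U[:, keep], s[keep], Vt[keep].T, lam[keep]

    _, s_res, _ = np.linalg.svd(Yres, full_matrices=False)
    lam_res = s_res ** 2 / (n - 1)
    lam_res = lam_res[lam_res > _EIG_TOL * max(total, 1e-300)]

    r2 = float((Yfit ** 2).sum() / (Yr ** 2).sum()) if total > 0 else 0.0
    m = rank
    n_eff = n - cond_df
    adj = adjusted_r2(r2, n_eff, m) if n_eff > m + 1 else np.nan
    return RDAResult(
        eigenvalues=lam, unconstrained_eigenvalues=lam_res,
        total_variance=total, r2=r2, adj_r2=adj, n=n, rank=rank,
        condition_df=cond_df, terms=terms, condition=condition,
        species=species, samples=samples.reset_index(drop=True),
        _U=U, _s=s, _V=V, _Yres=Yr,
    )


@dataclass(frozen=True)
class PermutationTestResult:
    term: str
    f: float
    df_num: int
    df_den: int
    n_perm: int
    p: float
    seed: int


def marginal_permutation_test(
    Y: HellingerMatrix | np.ndarray,
    design: pd.DataFrame,
    terms,
    condition=(),
    term: str = None,
    n_perm: int = 999,
    seed: int = 0,
    blocks=None,
) -> PermutationTestResult:
    """Marginal (last-entry) permutation test of one term.

    pseudo-F = (SS_term / df_term) / (SS_resid / df_resid), with SS_term
    the drop in constrained SS when the term is removed from the full
    model.  The null distribution permutes reduced-model residuals
    (Freedman-Lane); ``blocks`` (a length-n label array) restricts
    permutations to within blocks, e.g. within traps, for repeated-
    measures designs.  p carries the +1 small-sample correction.
    """
    if term not in terms:
        raise ValueError(f"term {term!r} not among terms {terms}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    vals = Y.values if isinstance(Y, HellingerMatrix) else np.asarray(Y, float)
    n = vals.shape[0]
    reduced_terms = [t for t in terms if t != term]

    Xz, _ = build_design(design, list(condition))
    Qz = _orth_basis(np.hstack([np.ones((n, 1)), Xz]))
    cond_df = Qz.shape[1] - 1
    Yc = vals - vals.mean(axis=0)
    Yr = _residualize(Yc, Qz)

    Xf, _ = build_design(design, list(terms))
    Xred, _ = build_design(design, reduced_terms)
    Qf = _orth_basis(_residualize(Xf, Qz),
                     ref=np.linalg.norm(Xf) if Xf.size else None)
    Qred = _orth_basis(_residualize(Xred, Qz),
                       ref=np.linalg.norm(Xred) if Xred.size else None)
    m_full, m_red = Qf.shape[1], Qred.shape[1]
    df_num = m_full - m_red
    if df_num == 0:
        raise ValueError(f"term {term!r} adds no rank to the design")
    df_den = n - 1 - cond_df - m_full

    def stat(Ymat):
        ss_tot = (Ymat ** 2).sum()
        ss_full = ((Qf.T @ Ymat) ** 2).sum()
        ss_red = ((Qred.T @ Ymat) ** 2).sum()
        ss_term = ss_full - ss_red
        ss_res = ss_tot - ss_full
        return (ss_term / df_num) / (ss_res / df_den)

    f_obs = stat(Yr)

    # Freedman-Lane: permute residuals of the reduced model (condition +
    # remaining terms), add back the reduced fit, re-residualize.
    Qzr = _orth_basis(np.hstack([Qz, Qred]))
    fit_red = Qzr @ (Qzr.T @ Yc)
    resid_red = Yc - fit_red

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.int64)
    base = np.arange(n)
    if blocks is None:
        for k in range(n_perm):
            perms[k] = rng.permutation(n)
    else:
        blocks = np.asarray(blocks)
        idx_by_block = [np.flatnonzero(blocks == b) for b in pd.unique(blocks)]
        for k in range(n_perm):
            p = base.copy()
            for idx in idx_by_block:
                p[idx] = idx[rng.permutation(len(idx))]
            perms[k] = p

    count = 0
    chunk = max(1, int(2e7 // (n * vals.shape[1] + 1)))
    for start in range(0, n_perm, chunk):
        sel = perms[start:start + chunk]
        Ystar = fit_red[None, :, :] + resid_red[sel]  # (b, n, p)
        Ystar = Ystar - Qz @ np.matmul(Qz.T, Ystar) if Qz.shape[1] else Ystar
        ss_tot = (Ystar ** 2).sum(axis=(1, 2))
        ss_full = (np.matmul(Qf.T, Ystar) ** 2).sum(axis=(1, 2))
        ss_red = (np.matmul(Qred.T, Ystar) ** 2).sum(axis=(1, 2))
        f_perm = ((ss_full - ss_red) / df_num) / ((ss_tot - ss_full) / df_den)
        count += int((f_perm >= f_obs - 1e-12).sum())

    p = (count + 1) / (n_perm + 1)
    return PermutationTestResult(
        term=term, f=float(f_obs), df_num=df_num, df_den=df_den,
        n_perm=n_perm, p=float(p), seed=seed,
    )


def ordination_scores(rda: RDAResult, scaling: int = 2,
                      label_threshold: float = 0.2,
                      centroid_factors=None) -> pd.DataFrame:
    """Site, species and centroid scores on the constrained axes.

    Type-II (correlation) scaling: species scores are the right singular
    vectors weighted by sqrt(lambda_i / total variance); site scores are
    the data projections standardized to unit variance per axis, so the
    eigenvalue structure is carried by the species.  Type-I scaling
    preserves inter-sample distances instead.  Centroids are mean site
    scores per factor level; species exceeding ``label_threshold`` in
    absolute value on either of the first two axes are flagged for
    labelling.
    """
    if scaling not in (1, 2):
        raise ValueError("scaling must be 1 or 2")
    lam, tot = rda.eigenvalues, rda.total_variance
    n = rda.n
    proj = rda._Yres @ rda._V  # sample projections on constrained axes
    const = ((n - 1) * tot) ** 0.25  # conventional display constant
    if scaling == 2:
        species = rda._V * np.sqrt(lam / tot) * const
        sites = proj / rda._s * np.sqrt(n - 1) / const
    else:
        species = rda._V.copy()
        sites = proj

    naxes = species.shape[1]
    cols = [f"axis{i+1}" for i in range(naxes)]
    sp = pd.DataFrame(species, columns=cols)
    sp.insert(0, "entity", list(rda.species))
    sp.insert(1, "type", "species")
    top2 = sp[cols[: min(2, naxes)]].abs()
    sp["flagged"] = (top2 > label_threshold).any(axis=1)

    site = pd.DataFrame(sites, columns=cols)
    meta = rda.samples
    labels = (
        meta.astype(str).agg("/".join, axis=1)
        if len(meta.columns)
        else pd.Series([f"s{i}" for i in range(n)])
    )
    site.insert(0, "entity", labels.to_numpy())
    site.insert(1, "type", "site")
    site["flagged"] = False

    cents = []
    factors = centroid_factors
    if factors is None:
        factors = [c for c in meta.columns
                   if not pd.api.types.is_numeric_dtype(meta[c])
                   or meta[c].nunique() <= 8]
    for f in factors:
        for level, idx in meta.groupby(meta[f].astype(str)).groups.items():
            row = sites[np.asarray(idx)].mean(axis=0)
            cents.append([f"{f}={level}", "centroid", *row, False])
    cent = pd.DataFrame(cents, columns=["entity", "type", *cols, "flagged"])
    return pd.concat([site, sp, cent], ignore_index=True)
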