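"""Constrained correspondence ordination of assemblage composition (Layer 1).

Partial canonical correspondence analysis (pCCA) relates a sample x species
abundance matrix to environmental constraints after removing covariable
effects (here: collection month and air temperature).  The machinery is the
classical weighted chi-square formulation: with ``P`` the abundance matrix
scaled to sum 1, row weights ``r`` and column weights ``c``,

    Qbar = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

holds the standardized chi-square contributions whose total sum of squares
is the inertia.  Constraining projects the rows of ``Qbar`` onto the
(weighted, centered) span of the constraint matrix; the canonical
eigenvalues are the squared singular values of the projection.  Partialling
first projects both ``Qbar`` and the constraints off the covariable span.

Significance uses a restricted Monte Carlo permutation test: samples form
site-level time series (six collection periods), and each permutation applies
an independent random cyclic shift to each site's series, preserving the
temporal autocorrelation the design induces.

Abundances are log-transformed and rare species downweighted before
ordination, and forward selection with a false-discovery-rate correction
ranks candidate constraints.  Community-weighted means (CWM) and Rao's
quadratic entropy (RaoQ) of identity-based traits are passively projected
onto the fitted axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationResult",
    "transform_abundances",
    "fit_pcca",
    "restricted_permutation_test",
    "forward_select",
    "compute_cwm",
    "compute_raoq",
    "project_supplementary",
    "dummy_code",
]

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# Abundance pre-treatment


def transform_abundances(
    Y: pd.DataFrame, log: bool = True, downweight: bool = True
) -> pd.DataFrame:
    """Log-transform abundances and downweight rare species.

    ``log``: y -> ln(y + 1).  ``downweight``: a species occurring in ``f``
    samples is multiplied by ``min(1, f / (f_max / 5))`` where ``f_max`` is
    the highest occurrence count — the frequency-threshold convention of the
    ordination software lineage the field uses.
    """
    if (Y.values < 0).any():
        raise ValueError("abundances must be non-negative")
    if not np.any(Y.values > 0):
        raise ValueError("all-zero community matrix")
    out = Y.astype(float).copy()
    if log:
        out = np.log1p(out)
    if downweight:
        freq = (Y.values > 0).sum(axis=0).astype(float)
        f_max = freq.max()
        threshold = f_max / 5.0
        w = np.minimum(1.0, np.divide(freq, threshold,
                                      out=np.zeros_like(freq),
                                      where=threshold > 0))
        out = out * w[None, :]
    return out


# ---------------------------------------------------------------------------
# Core decomposition


def _chi_square_standardize(Y: np.ndarray):
    """Row/column weights and the standardized contribution matrix Qbar."""
    total = Y.sum()
    if total <= 0:
        raise ValueError("community matrix has no abundance")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep_rows = r > 0
    keep_cols = c > 0
    P = P[np.ix_(keep_rows, keep_cols)]
    r = r[keep_rows]
    c = c[keep_cols]
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return r, c, Qbar, keep_rows, keep_cols


def _weighted_basis(X: np.ndarray, r: np.ndarray, label: str = "X"):
    """Weighted-centered, sqrt(weight)-scaled orthonormal basis of X's span.

    Aliased (rank-deficient) columns are dropped with a warning; returns the
    orthonormal basis (n x rank).
    """
    if X.size == 0:
        return np.empty((len(r), 0))
    Xc = X - r @ X  # weighted column means (sum r == 1)
    Xw = Xc * np.sqrt(r)[:, None]
    q, s, _ = np.linalg.svd(Xw, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)))
    if rank < X.shape[1]:
        warnings.warn(f"{label}: {X.shape[1] - rank} aliased column(s) dropped "
                      "after weighted centering", stacklevel=2)
    return q[:, :rank]


def _project(basis: np.ndarray, M: np.ndarray) -> np.ndarray:
    return basis @ (basis.T @ M) if basis.shape[1] else np.zeros_like(M)


@dataclass
class OrdinationResult:
    """Fitted (partial) CCA.

    ``explained_fraction`` is the constrained share of the inertia that
    remains after partialling out the covariables; ``explained_adjusted``
    applies the Ezekiel-style small-sample correction.  Scores use the
    chi-square metric: site scores are linear-combination (LC) scores,
    ``wa_scores`` the weighted-average site scores, and biplot scores the
    weighted correlations of the constraints with the LC axes.
    """

    eigenvalues: np.ndarray
    total_inertia: float
    inertia_after_partial: float
    constrained_inertia: float
    explained_fraction: float
    explained_adjusted: float
    pseudo_f: float
    site_scores: pd.DataFrame
    wa_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    n_samples: int
    rank_constraints: int
    rank_covariables: int
    row_weights: np.ndarray = field(repr=False)
    _internals: dict = field(default_factory=dict, repr=False)


def _constrained_inertia(Qbar, x_basis, z_basis):
    """(constrained inertia, residual inertia, inertia after partialling)."""
    Qr = Qbar - _project(z_basis, Qbar)
    fitted = _project(x_basis, Qr)
    after = float(np.sum(Qr ** 2))
    con = float(np.sum(fitted ** 2))
    return con, after - con, after


def fit_pcca(
    Y: pd.DataFrame,
    X: pd.DataFrame | None,
    Z: pd.DataFrame | None = None,
) -> OrdinationResult:
    """Partial CCA of (transformed) abundances ``Y`` on constraints ``X``
    given covariables ``Z``.  With ``Z`` empty the result is plain CCA.

    Rows must align across the three tables.  Categorical columns of X / Z
    are dummy-coded by the caller (see :func:`dummy_code`).
    """
    Yv = np.asarray(Y, float)
    r, c, Qbar, keep_rows, keep_cols = _chi_square_standardize(Yv)
    samples = np.asarray(Y.index)[keep_rows]
    species = np.asarray(Y.columns)[keep_cols]

    Xv = (np.empty((len(samples), 0)) if X is None
          else np.asarray(X, float)[keep_rows])
    Zv = (np.empty((len(samples), 0)) if Z is None or Z.shape[1] == 0
          else np.asarray(Z, float)[keep_rows])

    z_basis = _weighted_basis(Zv, r, "covariables")
    Xres = (Xv - r @ Xv) * np.sqrt(r)[:, None]
    Xres -= _project(z_basis, Xres)
    qx, sx, _ = np.linalg.svd(Xres, full_matrices=False)
    rank_x = int(np.sum(sx > _RANK_TOL * max(1.0, sx[0] if len(sx) else 1.0)))
    if rank_x < Xv.shape[1]:
        warnings.warn(f"constraints: {Xv.shape[1] - rank_x} aliased column(s) "
                      "dropped after partialling", stacklevel=2)
    x_basis = qx[:, :rank_x]

    total_inertia = float(np.sum(Qbar ** 2))
    Qr = Qbar - _project(z_basis, Qbar)
    fitted = _project(x_basis, Qr)
    after = float(np.sum(Qr ** 2))
    U, svals, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int(np.sum(svals ** 2 > 1e-12 * max(1.0, after)))
    U, svals, Vt = U[:, :n_axes], svals[:n_axes], Vt[:n_axes]
    eig = svals ** 2
    con = float(eig.sum())
    resid = after - con

    n = len(samples)
    q = rank_x
    pz = z_basis.shape[1]
    df_resid = max(n - pz - q - 1, 1)
    pseudo_f = (con / q) / (resid / df_resid) if q and resid > 0 else np.inf

    explained = con / after if after > 0 else 0.0
    denom = max(n - pz - q - 1, 1)
    explained_adj = max(0.0, 1.0 - (1.0 - explained) * (n - pz - 1) / denom)

    axes = [f"CCA{k + 1}" for k in range(n_axes)]
    inv_sqrt_r = 1.0 / np.sqrt(r)
    lc = pd.DataFrame(inv_sqrt_r[:, None] * (U * svals), index=samples,
                      columns=axes)
    wa = pd.DataFrame(inv_sqrt_r[:, None] * (Qr @ Vt.T), index=samples,
                      columns=axes)
    sp = pd.DataFrame((1.0 / np.sqrt(c))[:, None] * Vt.T, index=species,
                      columns=axes)
    # weighted correlation of each constraint with each LC axis
    biplot = np.zeros((Xv.shape[1], n_axes))
    lcv = lc.values
    for j in range(Xv.shape[1]):
        xj = Xv[:, j] - np.sum(r * Xv[:, j])
        sx_j = np.sqrt(np.sum(r * xj ** 2))
        for k in range(n_axes):
            ak = lcv[:, k] - np.sum(r * lcv[:, k])
            sa = np.sqrt(np.sum(r * ak ** 2))
            if sx_j > 0 and sa > 0:
                biplot[j, k] = np.sum(r * xj * ak) / (sx_j * sa)
    biplot_df = pd.DataFrame(
        biplot, index=(list(X.columns) if X is not None else []), columns=axes)

    return OrdinationResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        inertia_after_partial=after,
        constrained_inertia=con,
        explained_fraction=explained,
        explained_adjusted=explained_adj,
        pseudo_f=pseudo_f,
        site_scores=lc,
        wa_scores=wa,
        species_scores=sp,
        biplot_scores=biplot_df,
        n_samples=n,
        rank_constraints=q,
        rank_covariables=pz,
        row_weights=r,
        _internals={"Qbar": Qbar, "z_basis": z_basis, "r": r,
                    "X": Xv, "Z": Zv, "keep_rows": keep_rows},
    )


# ---------------------------------------------------------------------------
# Restricted permutations (cyclic shifts within site blocks)


def _cyclic_shift_indices(blocks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row permutation applying an independent random cyclic shift per block.

    Rows of a block must already be in time order.  Length-1 blocks are
    invariant.  The zero shift is part of the permutation set.
    """
    idx = np.arange(len(blocks))
    out = idx.copy()
    for b in pd.unique(blocks):
        pos = idx[blocks == b]
        T = len(pos)
        k = int(rng.integers(T))
        out[pos] = pos[np.roll(np.arange(T), k)]
    return out


def _pseudo_f_stat(Qbar, Xv, Zv, r, n):
    z_basis = _weighted_basis(Zv, r, "covariables") if Zv.size else np.empty((n, 0))
    Xw = (Xv - r @ Xv) * np.sqrt(r)[:, None]
    Xw -= _project(z_basis, Xw)
    qx, sx, _ = np.linalg.svd(Xw, full_matrices=False)
    rank_x = int(np.sum(sx > _RANK_TOL * max(1.0, sx[0] if len(sx) else 1.0)))
    x_basis = qx[:, :rank_x]
    con, resid, _ = _constrained_inertia(Qbar, x_basis, z_basis)
    q = max(rank_x, 1)
    df_resid = max(n - z_basis.shape[1] - q - 1, 1)
    if resid <= 0:
        return np.inf, con
    return (con / q) / (resid / df_resid), con


def restricted_permutation_test(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    Z: pd.DataFrame | None,
    blocks: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Pseudo-F and permutation p for the constraints, restricted to cyclic
    shifts of each block's time series.

    Rows within a block must be time-ordered.  ``p = (1 + #{F_perm >=
    F_obs}) / (1 + n_perm)``; the identity arrangement can be drawn, so
    p is never 0.
    """
    Yv = np.asarray(Y, float)
    r, c, Qbar, keep_rows, _ = _chi_square_standardize(Yv)
    blocks = np.asarray(blocks)[keep_rows]
    n = int(keep_rows.sum())
    Xv = np.asarray(X, float)[keep_rows]
    Zv = (np.asarray(Z, float)[keep_rows] if Z is not None and Z.shape[1]
          else np.empty((n, 0)))
    sizes = pd.Series(blocks).value_counts()
    if (sizes == 1).any():
        warnings.warn("blocks of length 1 are invariant under cyclic shifts",
                      stacklevel=2)

    f_obs, _ = _pseudo_f_stat(Qbar, Xv, Zv, r, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = _cyclic_shift_indices(blocks, rng)
        f_perm, _ = _pseudo_f_stat(Qbar, Xv[perm], Zv, r, n)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# Forward selection


def dummy_code(series: pd.Series, prefix: str | None = None,
               drop_first: bool = False) -> pd.DataFrame:
    """0/1 dummies for a categorical variable (all levels kept by default)."""
    d = pd.get_dummies(series.astype(str), prefix=prefix, prefix_sep="_",
                       drop_first=drop_first).astype(float)
    if prefix is None:
        d.columns = [c.split("_", 1)[-1] if "_" in c else c for c in d.columns]
    return d


def forward_select(
    Y: pd.DataFrame,
    candidates: pd.DataFrame,
    Z: pd.DataFrame | None,
    blocks: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Greedy forward selection of constraint columns with restricted
    permutation tests and Benjamini-Hochberg FDR adjustment.

    Every candidate is reported: at each step the candidate with the largest
    conditional (extra) explained variation given the covariables and the
    already-selected set is tested and moved into the model, so the table
    lists each variable's conditional effect at its point of entry, as
    forward-selection summaries conventionally do.

    Returns a table with conditional explained variation (% of the inertia
    remaining after covariables), pseudo-F, raw and FDR-adjusted permutation
    p, selection order, and a selected flag (adjusted p <= alpha).
    """
    Yv = np.asarray(Y, float)
    r, _, Qbar, keep_rows, _ = _chi_square_standardize(Yv)
    n = int(keep_rows.sum())
    blocks_arr = np.asarray(blocks)[keep_rows]
    Zv = (np.asarray(Z, float)[keep_rows] if Z is not None and Z.shape[1]
          else np.empty((n, 0)))
    cand = {name: np.asarray(candidates[name], float)[keep_rows]
            for name in candidates.columns}
    z_basis0 = _weighted_basis(Zv, r, "covariables")
    _, _, after0 = _constrained_inertia(Qbar, np.empty((n, 0)), z_basis0)

    rng = np.random.default_rng(seed)
    rows = []
    selected: list[str] = []
    remaining = list(cand)
    step = 0
    while remaining:
        z_aug = (np.column_stack([Zv] + [cand[s][:, None] for s in selected])
                 if selected else Zv)
        gains = {}
        for name in remaining:
            zb = _weighted_basis(z_aug, r) if z_aug.size else np.empty((n, 0))
            con, _, _ = _constrained_inertia(
                Qbar, _weighted_basis_resid(cand[name][:, None], r, zb), zb)
            gains[name] = con
        best = max(gains, key=lambda k: gains[k])
        Xb = pd.DataFrame({best: cand[best]})
        Zb = pd.DataFrame(z_aug) if z_aug.size else None
        f_obs, p = restricted_permutation_test(
            pd.DataFrame(Yv[keep_rows]), Xb, Zb, blocks_arr,
            n_perm=n_perm, seed=int(rng.integers(2 ** 31 - 1)))
        rows.append({
            "variable": best,
            "conditional_explained_pct": 100.0 * gains[best] / after0,
            "pseudo_F": f_obs,
            "p": p,
            "order": step + 1,
        })
        selected.append(best)
        remaining.remove(best)
        step += 1

    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["selected"] = table["p_adj"] <= alpha
    return table


def _weighted_basis_resid(X: np.ndarray, r: np.ndarray, z_basis: np.ndarray):
    Xw = (X - r @ X) * np.sqrt(r)[:, None]
    Xw -= _project(z_basis, Xw)
    q, s, _ = np.linalg.svd(Xw, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)))
    return q[:, :rank]


# ---------------------------------------------------------------------------
# Trait summaries: CWM and RaoQ


def compute_cwm(Y: pd.DataFrame, trait_values: pd.Series) -> pd.Series:
    """Community-weighted mean of a species-level trait per sample.

    ``CWM_s = sum_i p_si x_i`` with ``p_si`` the relative abundance of
    species i in sample s.  Samples with zero total abundance yield NaN.
    Categorical traits should be one-hot encoded first (one CWM per level).
    """
    x = trait_values.reindex(Y.columns)
    if x.isna().any():
        missing = list(x.index[x.isna()])
        raise ValueError(f"trait values missing for species: {missing}")
    totals = Y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cwm = (Y.values * x.values[None, :]).sum(axis=1) / totals.values
    out = pd.Series(cwm, index=Y.index, name=trait_values.name or "cwm")
    out[totals == 0] = np.nan
    return out


def compute_raoq(Y: pd.DataFrame, D: pd.DataFrame) -> pd.Series:
    """Rao's quadratic entropy per sample: ``Q_s = sum_ij d_ij p_si p_sj``.

    ``D`` must be symmetric with zero diagonal and non-negative entries.
    With all between-species distances 1, Q reduces to the Gini-Simpson
    index ``1 - sum_i p_i^2``.
    """
    D = D.reindex(index=Y.columns, columns=Y.columns)
    Dv = D.values.astype(float)
    if np.isnan(Dv).any():
        raise ValueError("distance matrix does not cover all species")
    if not np.allclose(Dv, Dv.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (Dv < 0).any() or not np.allclose(np.diag(Dv), 0, atol=1e-12):
        raise ValueError("distances must be >= 0 with zero diagonal")
    totals = Y.sum(axis=1).values
    with np.errstate(invalid="ignore", divide="ignore"):
        P = Y.values / totals[:, None]
    q = np.einsum("si,ij,sj->s", np.nan_to_num(P), Dv, np.nan_to_num(P))
    out = pd.Series(q, index=Y.index, name="raoq")
    out[totals == 0] = np.nan
    return out


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Simple matching-based Gower distance between species from categorical
    identity traits (mean share of non-matching trait levels)."""
    cols = [c for c in traits.columns if c != "species"]
    t = traits.set_index("species")[cols].astype(str)
    n = len(t)
    d = np.zeros((n, n))
    for c in cols:
        v = t[c].values
        d += (v[:, None] != v[None, :]).astype(float)
    d /= max(len(cols), 1)
    return pd.DataFrame(d, index=t.index, columns=t.index)


# ---------------------------------------------------------------------------
# Passive projection


def project_supplementary(
    ord_result: OrdinationResult, values: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Passively project per-sample summaries (CWM, RaoQ...) as arrows.

    Arrow coordinates are the coefficients of a weighted least-squares
    regression of the (weighted-)centered value on the LC site scores; the
    eigen-structure is untouched.  Constant vectors give zero-length arrows.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame()
    scores = ord_result.site_scores
    r = ord_result.row_weights
    A = scores.values * np.sqrt(r)[:, None]
    rows = {}
    for name in values.columns:
        v = values[name].reindex(scores.index).values.astype(float)
        ok = np.isfinite(v)
        vc = v.copy()
        w = r / r[ok].sum()
        vc[~ok] = 0.0
        mean = np.sum(w[ok] * v[ok])
        resid = np.where(ok, v - mean, 0.0)
        if np.allclose(resid[ok], 0):
            warnings.warn(f"supplementary variable {name!r} is constant; "
                          "zero-length arrow", stacklevel=2)
            rows[name] = np.zeros(A.shape[1])
            continue
        b, *_ = np.linalg.lstsq(A[ok], (resid * np.sqrt(r))[ok], rcond=None)
        rows[name] = b
    return pd.DataFrame(rows, index=scores.columns).T
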