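"""Distance-residualized rank-correlation coupling statistics.

The inferential chain for every (participant, band, comparison):

1. half-vectorize the two connectivity matrices and the Euclidean
   distance matrix into matched edge vectors;
2. regress edge-wise Euclidean distance out of both connectivity
   vectors by OLS with an intercept (the distance confound: nearby
   contacts are more connected in every modality);
3. Spearman's rank correlation between the two residual vectors
   (mid-ranks for ties; two-sided p from the t approximation on
   n - 2 degrees of freedom);
4. Benjamini–Hochberg FDR across all participants and bands within a
   comparison family (bold_vs_seeg, sc_vs_seeg, sc_vs_bold).

Structure–function comparisons are restricted to edges with nonzero
structural connectivity, as direct anatomical support is the hypothesis
under test; the restriction is applied before residualization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ConnectivityMatrix,
    CouplingResult,
    EdgeVector,
    WmCouplingError,
)

__all__ = [
    "half_vectorize",
    "edges_to_matrix",
    "residualize_on_distance",
    "spearman",
    "couple_fc_fc",
    "couple_sc_fc",
    "fdr_correct",
    "summarize_bands",
    "StatsError",
    "ConstantInputError",
    "InsufficientEdgesError",
]


class StatsError(WmCouplingError):
    """Invalid statistical request."""


class ConstantInputError(StatsError):
    """A correlation was requested on a constant vector."""


class InsufficientEdgesError(StatsError):
    """Too few edges for the requested comparison."""


def half_vectorize(m: ConnectivityMatrix) -> EdgeVector:
    """Upper triangle (excluding the diagonal) in lexicographic pair order.

    A 47-node matrix yields 47*46/2 = 1081 edges.  Symmetry beyond 1e-10
    is rejected by :class:`ConnectivityMatrix` construction.
    """
    n = m.n_nodes
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack(iu)
    return EdgeVector(values=m.values[iu], pair_index=pairs, nodes=m.nodes)


def edges_to_matrix(
    edges: EdgeVector, modality: str, band: str | None = None, diagonal: float = 0.0
) -> ConnectivityMatrix:
    """Rebuild the symmetric matrix from a full (unmasked) edge vector."""
    n = len(edges.nodes)
    if edges.n_edges != n * (n - 1) // 2:
        raise StatsError("edge vector is masked; cannot rebuild a full matrix")
    out = np.full((n, n), float(diagonal))
    i, j = edges.pair_index.T
    out[i, j] = edges.values
    out[j, i] = edges.values
    return ConnectivityMatrix(values=out, nodes=edges.nodes, modality=modality, band=band)


def _check_matched(*edges: EdgeVector) -> None:
    first = edges[0]
    for e in edges[1:]:
        if e.nodes != first.nodes or not np.array_equal(e.pair_index, first.pair_index):
            raise StatsError("edge vectors have mismatched pair indices")


def residualize_on_distance(y: EdgeVector, d: EdgeVector) -> EdgeVector:
    """OLS residual of edge values on [intercept, distance].

    The residuals have exactly zero mean and zero sample covariance with
    the distance vector, removing the distance confound before rank
    correlation.
    """
    _check_matched(y, d)
    if y.n_edges < 3:
        raise StatsError("residualization needs at least 3 edges")
    dv = d.values
    if np.ptp(dv) == 0.0:
        raise ConstantInputError(
            "distance vector is constant: degenerate contact geometry "
            "(all pairs equidistant)"
        )
    x = np.column_stack([np.ones_like(dv), dv])
    beta, *_ = np.linalg.lstsq(x, y.values, rcond=None)
    resid = y.values - x @ beta
    return EdgeVector(values=resid, pair_index=y.pair_index, nodes=y.nodes)


def spearman(x: EdgeVector | np.ndarray, y: EdgeVector | np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks and a two-sided t-test p.

    rho is the Pearson correlation of the mid-rank transforms; the
    p-value uses t = rho * sqrt((n-2)/(1-rho^2)) on n - 2 degrees of
    freedom.  Perfect correlations give p at the numerical floor.
    """
    if isinstance(x, EdgeVector) and isinstance(y, EdgeVector):
        _check_matched(x, y)
        xv, yv = x.values, y.values
    else:
        xv = x.values if isinstance(x, EdgeVector) else np.asarray(x, dtype=float)
        yv = y.values if isinstance(y, EdgeVector) else np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise StatsError("spearman needs two matched 1-D vectors")
    n = xv.size
    if n < 4:
        raise StatsError("spearman needs at least 4 observations")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        p = max(p, np.finfo(float).tiny)
    return rho, p


def _finite_mask(*vectors: np.ndarray) -> np.ndarray:
    mask = np.ones(vectors[0].shape, dtype=bool)
    for v in vectors:
        mask &= np.isfinite(v)
    return mask


def _masked(e: EdgeVector, mask: np.ndarray) -> EdgeVector:
    return EdgeVector(values=e.values[mask], pair_index=e.pair_index[mask], nodes=e.nodes)


def couple_fc_fc(
    bold: ConnectivityMatrix,
    seeg: ConnectivityMatrix,
    dist: ConnectivityMatrix,
    participant: str,
    band: str,
) -> CouplingResult:
    """BOLD-FC vs SEEG-FC coupling over all regional pairs.

    Both FC edge vectors are residualized on Euclidean distance and the
    residuals rank-correlated.  Edges with undefined FC (from
    zero-variance channels) are dropped pairwise with a warning.
    """
    if not (bold.nodes == seeg.nodes == dist.nodes):
        raise StatsError("matrices have mismatched node sets or order")
    eb, es, ed = half_vectorize(bold), half_vectorize(seeg), half_vectorize(dist)
    mask = _finite_mask(eb.values, es.values, ed.values)
    if not mask.all():
        warnings.warn(
            f"dropping {int((~mask).sum())} edge(s) with undefined FC", stacklevel=2
        )
        eb, es, ed = _masked(eb, mask), _masked(es, mask), _masked(ed, mask)
    if eb.n_edges < 4:
        raise InsufficientEdgesError("fewer than 4 defined edges")
    rb = residualize_on_distance(eb, ed)
    rs = residualize_on_distance(es, ed)
    r, p = spearman(rb, rs)
    return CouplingResult(
        participant=participant, band=band, comparison="bold_vs_seeg",
        r=r, p=p, n_edges=eb.n_edges,
    )


def couple_sc_fc(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    dist: ConnectivityMatrix,
    participant: str,
    band: str,
) -> CouplingResult:
    """SC vs FC coupling over regional pairs with nonzero SC.

    All three edge vectors are restricted to pairs with at least one
    interconnecting streamline; residualization on distance happens
    within the restricted set.  The comparison label is
    ``sc_vs_bold`` for BOLD FC and ``sc_vs_seeg`` otherwise.
    """
    if not (sc.nodes == fc.nodes == dist.nodes):
        raise StatsError("matrices have mismatched node sets or order")
    esc, efc, ed = half_vectorize(sc), half_vectorize(fc), half_vectorize(dist)
    mask = (esc.values > 0) & _finite_mask(efc.values, ed.values)
    n_kept = int(mask.sum())
    if n_kept < 4:
        raise InsufficientEdgesError(
            f"insufficient nonzero structural connections ({n_kept} < 4)"
        )
    esc, efc, ed = _masked(esc, mask), _masked(efc, mask), _masked(ed, mask)
    rsc = residualize_on_distance(esc, ed)
    rfc = residualize_on_distance(efc, ed)
    r, p = spearman(rsc, rfc)
    comparison = "sc_vs_bold" if fc.modality == "bold_fc" else "sc_vs_seeg"
    return CouplingResult(
        participant=participant, band=band, comparison=comparison,
        r=r, p=p, n_edges=n_kept,
    )


STUDY_COLUMNS = ["participant", "band", "comparison", "r", "p", "n_edges"]


def results_to_table(results: list[CouplingResult]) -> pd.DataFrame:
    """Stack coupling results into a study table (one row per test)."""
    return pd.DataFrame(
        [
            {
                "participant": c.participant, "band": c.band,
                "comparison": c.comparison, "r": c.r, "p": c.p,
                "n_edges": c.n_edges,
            }
            for c in results
        ],
        columns=STUDY_COLUMNS,
    )


def fdr_correct(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up adjusted p across participants and bands.

    Adjustment is joint over all rows within each comparison family
    (all participants x all bands for that comparison), mirroring the
    correction reported with the group results.  Adds ``p_fdr`` and
    ``significant`` (p_fdr < alpha) columns.
    """
    if table.empty:
        raise StatsError("cannot FDR-correct an empty study table")
    if not ((table["p"] > 0) & (table["p"] <= 1)).all():
        raise StatsError("p-values must lie in (0, 1]")
    out = table.copy()
    out["p_fdr"] = np.nan
    for _, idx in out.groupby("comparison").groups.items():
        _, p_adj, _, _ = multipletests(out.loc[idx, "p"], method="fdr_bh")
        out.loc[idx, "p_fdr"] = p_adj
    out["significant"] = out["p_fdr"] < alpha
    return out


def summarize_bands(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(comparison, band) median r and significance counts.

    Returns one row per comparison x band with the median Spearman r
    across participants, the participant count, and (when the table has
    been FDR-corrected) the number of significant participants.
    """
    if table.empty:
        raise StatsError("cannot summarize an empty study table")
    rows = []
    for (comparison, band), grp in table.groupby(["comparison", "band"], sort=False):
        row = {
            "comparison": comparison,
            "band": band,
            "median_r": float(grp["r"].median()),
            "n_participants": int(grp["participant"].nunique()),
        }
        if "significant" in grp:
            row["n_significant"] = int(grp["significant"].sum())
        rows.append(row)
    return pd.DataFrame(rows)
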