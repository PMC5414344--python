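"""Ordination with contributions: PCA for abundances, CA for k-mer counts.

Both techniques project contigs into a low-dimensional space, but their
purpose here is not the projection alone: the per-variable and
per-individual *contributions* to each axis rank which samples (PCA) or
which oligonucleotides (CA) drive the structure, so a user can pre-select
the most informative variables before clustering or display.

PCA operates on the (optionally standardised) contigs x samples abundance
matrix.  CA operates on a contigs x k-mer contingency table: with
``P = N / n`` (n the grand total), row masses ``r`` and column masses
``c``, the standardised residual matrix is

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

whose SVD ``S = U Sigma V^T`` gives principal coordinates
``F = D_r^{-1/2} U Sigma`` (rows) and ``G = D_c^{-1/2} V Sigma``
(columns); the d-th eigenvalue is ``sigma_d**2`` and the total inertia
``sum(sigma**2)`` equals the Pearson chi-square of the table divided by n.
Row i contributes ``r_i * F_id**2 / sigma_d**2`` to axis d (column
contributions analogously), each axis's contributions summing to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import BinrefError

#: Default cap on the number of individuals (contigs) entering CA;
#: mirrors the display limit of interactive refinement front ends.
CA_MAX_INDIVIDUALS = 5000


@dataclass
class OrdinationResult:
    """Coordinates, eigenvalues and contributions of a PCA or CA.

    Dimensions are ordered by decreasing eigenvalue; ``explained``
    fractions sum to one over all dimensions, and every contribution
    column sums to one.
    """

    method: str  # "pca" | "ca"
    row_coords: pd.DataFrame  # individuals (contigs) x dims
    col_coords: pd.DataFrame  # variables x dims
    eigenvalues: np.ndarray
    explained: np.ndarray
    row_contributions: pd.DataFrame
    col_contributions: pd.DataFrame
    total_inertia: float  # total variance for PCA, chi2/n for CA

    @property
    def n_dims(self) -> int:
        return len(self.eigenvalues)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Exportable tables (coordinates, contributions, eigenvalues)."""
        eig = pd.DataFrame(
            {"eigenvalue": self.eigenvalues, "explained": self.explained},
            index=self.row_coords.columns,
        )
        return {
            "row_coords": self.row_coords,
            "col_coords": self.col_coords,
            "row_contributions": self.row_contributions,
            "col_contributions": self.col_contributions,
            "eigenvalues": eig,
        }


def _dim_labels(n: int) -> list[str]:
    return [f"dim{i + 1}" for i in range(n)]


def _canonicalize_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each axis so the largest-|loading| variable entry is positive."""
    for d in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, d])))
        if v[j, d] < 0:
            v[:, d] = -v[:, d]
            u[:, d] = -u[:, d]
    return u, v


def pca(
    matrix: pd.DataFrame, center: bool = True, scale: bool = True
) -> OrdinationResult:
    """Principal component analysis of a contigs x samples matrix.

    ``scale=True`` (the default) standardises each column to unit
    variance, i.e. correlation-matrix PCA — appropriate for DNA-RPKM
    abundances whose scales differ across samples with sequencing depth.
    Eigenvalues are those of the covariance of the processed matrix
    (denominator n-1); their sum equals its total variance.

    Contribution of variable j to axis d is its squared loading (loadings
    are unit vectors, so each axis's variable contributions sum to one);
    contribution of individual i to axis d is its squared score divided by
    the axis's total squared score.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise BinrefError("pca needs at least 2 rows and 2 variables")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise BinrefError(
                f"zero-variance column with scale=True: {matrix.columns[zero[0]]!r}"
            )
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    v = vt.T
    u, v = _canonicalize_signs(u, v)
    eig = s**2 / (n - 1)
    total = float(eig.sum())
    explained = eig / total if total > 0 else np.zeros_like(eig)
    scores = u * s  # X @ v
    dims = _dim_labels(len(eig))
    sq = scores**2
    col_sq = sq.sum(axis=0)
    row_contrib = np.divide(
        sq, col_sq, out=np.zeros_like(sq), where=col_sq > 0
    )
    return OrdinationResult(
        method="pca",
        row_coords=pd.DataFrame(scores, index=matrix.index, columns=dims),
        col_coords=pd.DataFrame(v, index=matrix.columns, columns=dims),
        eigenvalues=eig,
        explained=explained,
        row_contributions=pd.DataFrame(row_contrib, index=matrix.index, columns=dims),
        col_contributions=pd.DataFrame(v**2, index=matrix.columns, columns=dims),
        total_inertia=total,
    )


def ca(
    counts: pd.DataFrame, max_individuals: int = CA_MAX_INDIVIDUALS
) -> OrdinationResult:
    """Correspondence analysis of a non-negative contigs x k-mers table.

    All-zero rows or columns are dropped with a warning before the
    decomposition.  Tables larger than ``max_individuals`` rows are
    rejected with instructions to subset (raise the cap explicitly to
    override); the guard mirrors the interactive display limit.
    """
    N = counts.to_numpy(dtype=float)
    if (N < 0).any():
        raise BinrefError("ca requires non-negative counts")
    row_ok = N.sum(axis=1) > 0
    col_ok = N.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} all-zero row(s) and "
            f"{int((~col_ok).sum())} all-zero column(s) before CA",
            stacklevel=2,
        )
        counts = counts.loc[row_ok, col_ok]
        N = counts.to_numpy(dtype=float)
    if N.size == 0 or N.sum() == 0:
        raise BinrefError("ca requires a table with positive grand total")
    if N.shape[0] > max_individuals:
        raise BinrefError(
            f"{N.shape[0]} individuals exceed the CA cap of {max_individuals}; "
            "subset the contigs or raise max_individuals"
        )
    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    k = min(N.shape) - 1  # trivial dimension removed
    u, s, v = u[:, :k], s[:k], vt.T[:, :k]
    u, v = _canonicalize_signs(u, v)
    eig = s**2
    total = float(eig.sum())
    explained = eig / total if total > 0 else np.zeros_like(eig)
    F = (u * s) / np.sqrt(r)[:, None]
    G = (v * s) / np.sqrt(c)[:, None]
    dims = _dim_labels(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        row_contrib = np.where(eig > 0, r[:, None] * F**2 / eig, 0.0)
        col_contrib = np.where(eig > 0, c[:, None] * G**2 / eig, 0.0)
    return OrdinationResult(
        method="ca",
        row_coords=pd.DataFrame(F, index=counts.index, columns=dims),
        col_coords=pd.DataFrame(G, index=counts.columns, columns=dims),
        eigenvalues=eig,
        explained=explained,
        row_contributions=pd.DataFrame(row_contrib, index=counts.index, columns=dims),
        col_contributions=pd.DataFrame(col_contrib, index=counts.columns, columns=dims),
        total_inertia=total,
    )


def rank_variables(
    result: OrdinationResult,
    dims: Sequence[int] | None = None,
    top_n: int | None = None,
) -> list[str]:
    """Variables ordered by explained-fraction-weighted contribution.

    ``dims`` are 1-based axis numbers (default: all axes).  The score of
    variable j is ``sum_d explained_d * contribution_jd`` over the chosen
    axes; ties keep input order.  ``top_n`` larger than the number of
    variables returns them all.
    """
    available = range(1, result.n_dims + 1)
    chosen = list(available) if dims is None else sorted(set(dims))
    if any(d not in available for d in chosen):
        raise BinrefError(f"dims must be within 1..{result.n_dims}")
    idx = [d - 1 for d in chosen]
    contrib = result.col_contributions.iloc[:, idx].to_numpy()
    weights = result.explained[idx]
    # quantize so float noise cannot reorder exact ties (e.g. scaled PCA
    # over all dims scores every variable identically at 1/p); ties then
    # break by input order via the stable sort
    score = np.round(contrib @ weights, 12)
    order = np.argsort(-score, kind="stable")
    ranked = [result.col_contributions.index[i] for i in order]
    if top_n is not None:
        ranked = ranked[: max(0, top_n)]
    return ranked
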