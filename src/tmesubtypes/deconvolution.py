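"""Constrained weighted least-squares deconvolution of bulk expression.

Each bulk sample ``b`` (TPM over the reference signature genes) is modeled
as a non-negative combination of the 7 reference cell-type columns ``R``:

    minimize  sum_g w_g (b_g - sum_c R_gc x_c)^2
    subject to  x_c >= 0  and  sum_c x_c <= 1,

with gene weights ``w_g = 1 / (variability_g + eps)`` down-weighting genes
whose reference expression is unstable. The slack ``1 - sum_c x_c`` is
reported as the "uncharacterized" fraction — in prostate bulk tissue,
predominantly malignant and benign epithelial cells not represented in the
reference.

The problem is a tiny convex QP per sample. When the simplex inequality is
inactive it is solved exactly by active-set NNLS; otherwise an SLSQP solve
on the equality-constrained problem is refined by a KKT solve on the
identified active set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .containers import (
    CELL_TYPES,
    COMPONENTS,
    UNCHARACTERIZED,
    CompositionMatrix,
    ExpressionMatrix,
    ReferenceProfile,
)

logger = logging.getLogger(__name__)

#: Regularizer added to the reference variability before inversion.
WEIGHT_EPS = 1e-6


class DeconvolutionError(ValueError):
    """Raised when the bulk matrix cannot be deconvolved against the reference."""


def _solve_sample(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||Ax - b||^2 s.t. x >= 0, sum(x) <= 1 for one sample.

    Returns the 7-vector and the objective value.
    """
    x, _ = nnls(A, b)
    if x.sum() <= 1.0 + 1e-12:
        r = A @ x - b
        return x, float(r @ r)

    # Simplex constraint is active: solve with equality sum(x) = 1.
    AtA = A.T @ A
    Atb = A.T @ b

    def fun(v: np.ndarray) -> float:
        r = A @ v - b
        return 0.5 * float(r @ r)

    def grad(v: np.ndarray) -> np.ndarray:
        return AtA @ v - Atb

    x0 = x / x.sum()
    res = minimize(
        fun,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * A.shape[1],
        constraints=[{"type": "eq", "fun": lambda v: v.sum() - 1.0, "jac": lambda v: np.ones_like(v)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    sol = np.clip(res.x, 0.0, None)

    # KKT polish on the identified active set for full precision.
    free = sol > 1e-9
    if free.any():
        k = int(free.sum())
        K = np.zeros((k + 1, k + 1))
        K[:k, :k] = AtA[np.ix_(free, free)]
        K[:k, k] = 1.0
        K[k, :k] = 1.0
        rhs = np.concatenate([Atb[free], [1.0]])
        try:
            z = np.linalg.solve(K, rhs)
            if (z[:k] >= -1e-12).all():
                polished = np.zeros_like(sol)
                polished[free] = np.clip(z[:k], 0.0, None)
                if fun(polished) <= fun(sol) + 1e-15:
                    sol = polished
        except np.linalg.LinAlgError:
            pass

    sol = sol / max(sol.sum(), 1.0)  # guard: keep sum <= 1 against rounding
    r = A @ sol - b
    return sol, float(r @ r)


def fit_proportions(
    bulk: ExpressionMatrix,
    ref: ReferenceProfile,
    overlap_threshold: float = 0.8,
    mrna_scaling: np.ndarray | None = None,
) -> CompositionMatrix:
    """Estimate cell-type proportions for every sample of a TPM bulk matrix.

    Parameters
    ----------
    bulk
        TPM-normalized expression (use :func:`tmesubtypes.io.renormalize_tpm`
        for FPKM/RPKM inputs first).
    ref
        Reference profile; genes absent from ``bulk`` are dropped from the
        fit, and an overlap below ``overlap_threshold`` (fraction of
        reference genes found) is an error.
    mrna_scaling
        Optional per-cell-type mRNA-content factors (length 7). When given,
        fitted mRNA-fraction estimates are divided by their factor (the
        uncharacterized remainder by 1) and renormalized to sum to one,
        converting mRNA fractions to cell fractions. Default off.

    Returns
    -------
    CompositionMatrix
        Per-sample proportions of the 7 cell types plus ``uncharacterized``
        = 1 - fitted total, with the weighted SSR as ``fit_residual``.
    """
    if bulk.unit != "tpm":
        raise DeconvolutionError(
            f"bulk matrix is in {bulk.unit!r}; renormalize to TPM before deconvolution"
        )
    shared = ref.means.index.intersection(bulk.data.index)
    overlap = len(shared) / len(ref.means.index)
    if overlap < overlap_threshold:
        raise DeconvolutionError(
            f"only {len(shared)}/{len(ref.means.index)} reference genes present in bulk "
            f"(overlap {overlap:.2f} < threshold {overlap_threshold:.2f})"
        )
    logger.info("deconvolving %d samples on %d shared signature genes", bulk.n_samples, len(shared))

    R = ref.means.loc[shared].to_numpy()
    w = 1.0 / (ref.variability.loc[shared].to_numpy() + WEIGHT_EPS)
    sw = np.sqrt(w)
    # scale to O(1) for conditioning; proportions are scale-invariant
    scale = 1.0 / np.abs(R).max()
    A = (sw[:, None] * R) * scale
    B = (sw[:, None] * bulk.data.loc[shared].to_numpy()) * scale

    props = np.zeros((bulk.n_samples, len(COMPONENTS)))
    residuals = np.zeros(bulk.n_samples)
    for j in range(bulk.n_samples):
        x, obj = _solve_sample(A, B[:, j])
        props[j, : len(CELL_TYPES)] = x
        props[j, -1] = max(1.0 - x.sum(), 0.0)
        residuals[j] = obj / scale**2

    if mrna_scaling is not None:
        factors = np.asarray(mrna_scaling, dtype=float)
        if factors.shape != (len(CELL_TYPES),) or (factors <= 0).any():
            raise DeconvolutionError("mrna_scaling must be 7 positive factors")
        full = np.concatenate([factors, [1.0]])
        props = props / full
        props = props / props.sum(axis=1, keepdims=True)

    props = np.clip(props, 0.0, 1.0)
    props /= props.sum(axis=1, keepdims=True)
    return CompositionMatrix(
        pd.DataFrame(props, index=bulk.sample_ids, columns=list(COMPONENTS)),
        pd.Series(residuals, index=bulk.sample_ids, name="fit_residual"),
    )


def deconvolve_cohort(
    bulk: ExpressionMatrix,
    ref: ReferenceProfile,
    overlap_threshold: float = 0.8,
    mrna_scaling: np.ndarray | None = None,
) -> CompositionMatrix:
    """Batch wrapper around :func:`fit_proportions` with overlap logging."""
    shared = ref.means.index.intersection(bulk.data.index)
    logger.info(
        "cohort deconvolution: %d samples, %d/%d reference genes shared",
        bulk.n_samples,
        len(shared),
        len(ref.means.index),
    )
    return fit_proportions(bulk, ref, overlap_threshold=overlap_threshold, mrna_scaling=mrna_scaling)
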