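"""Replicator (multi-type logistic) model of clonal competition.

Clone fractions f_i evolve as df_i/dt = f_i (s_i - sum_j f_j s_j), with the
wild-type (WT) population as the implicit reference clone at s = 0.  This
system has the closed-form solution

    f_i(t) = f_i(0) exp(s_i t) / ( f_wt(0) + sum_j f_j(0) exp(s_j t) )

which both the synthetic generator and the competition fit use, so that the
fit inverts exactly the process the generator runs.  Selection coefficients
are per year; observed VAF for a heterozygous diploid variant is f_i / 2.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError, SimulationError

__all__ = ["replicator_fractions"]


def replicator_fractions(
    selection_coeffs: np.ndarray,
    initial_fractions: np.ndarray,
    times_years: np.ndarray,
) -> np.ndarray:
    """Clone-fraction trajectories under replicator dynamics.

    Parameters
    ----------
    selection_coeffs
        Per-clone fitness relative to WT, per year (WT itself is implicit
        with s = 0).
    initial_fractions
        Per-clone cell fraction at t = 0; must be non-negative and sum to
        at most 1 (the remainder is WT).
    times_years
        Evaluation times in years (need not be sorted).

    Returns
    -------
    ndarray of shape (n_times, n_clones) with each row summing to <= 1.
    """
    s = np.asarray(selection_coeffs, dtype=float)
    f0 = np.asarray(initial_fractions, dtype=float)
    t = np.atleast_1d(np.asarray(times_years, dtype=float))
    if s.shape != f0.shape or s.ndim != 1:
        raise InputError("selection_coeffs and initial_fractions must be 1-D and equal length")
    if np.any(f0 < 0) or f0.sum() > 1 + 1e-12:
        raise InputError("initial fractions must be >= 0 and sum to <= 1")
    f_wt0 = max(0.0, 1.0 - f0.sum())
    # guard against overflow for extreme s*t by shifting exponents
    expo = np.outer(t, s)
    shift = np.maximum(expo.max(axis=1, keepdims=True), 0.0)
    w = f0[None, :] * np.exp(expo - shift)
    denom = f_wt0 * np.exp(-shift[:, 0]) + w.sum(axis=1)
    frac = w / denom[:, None]
    if not np.all(np.isfinite(frac)) or np.any(frac < -1e-12) or np.any(frac.sum(axis=1) > 1 + 1e-9):
        raise SimulationError("clone fractions escaped [0, 1]; integration failure")
    return np.clip(frac, 0.0, 1.0)
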