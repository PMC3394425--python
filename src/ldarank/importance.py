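"""Aspect importance transform: θ → Θ via per-aspect normal distributions.

The same topic weight means different things on different aspects: a
weight of 0.2 on an aspect where most passages carry 0.01 marks an
unusually on-topic passage, while 0.2 on an aspect everyone carries is
unremarkable.  Each θ column t is therefore summarized by a normal
distribution with mean μ_t and standard deviation σ_t fitted over the D
retrieved passages, and each weight is replaced by its percentile under
that distribution:

    Θ[j, t] = Φ((θ[j, t] − μ_t) / σ_t)

with Φ the standard normal CDF.  A constant column (σ_t = 0) maps to
0.5 everywhere: on an aspect with no spread, all passages are equally
important.  The row sum of Θ is a passage's *aspect coverage*, used to
seed the re-ranked list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr


@dataclass
class ImportanceModel:
    """Per-aspect normal parameters and the D×T importance matrix Θ."""

    mu: np.ndarray      # length T, column means of theta
    sigma: np.ndarray   # length T, population standard deviations
    Theta: np.ndarray   # D x T, entries in [0, 1]


def column_moments(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and population standard deviations (divisor D) of θ."""
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 2 or theta.shape[0] < 1:
        raise ValueError("theta must be a D x T matrix with D >= 1")
    mu = theta.mean(axis=0)
    sigma = np.sqrt(((theta - mu) ** 2).mean(axis=0))
    return mu, sigma


def importance_matrix(theta: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Apply the per-column normal-CDF transform; σ=0 columns map to 0.5.

    A column whose spread is zero up to floating-point rounding (σ below
    machine-epsilon scale relative to its mean) is treated as constant,
    so rounding noise cannot be amplified into spurious z-scores.
    """
    theta = np.asarray(theta, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    degenerate = sigma <= 1e-12 * np.maximum(1.0, np.abs(mu))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (theta - mu) / np.where(degenerate, 1.0, sigma)
    Theta = ndtr(z)
    Theta[:, degenerate] = 0.5
    return Theta


def fit_importance(theta: np.ndarray) -> ImportanceModel:
    """Fit the per-aspect normals on θ and build Θ in one step."""
    mu, sigma = column_moments(theta)
    return ImportanceModel(mu=mu, sigma=sigma, Theta=importance_matrix(theta, mu, sigma))


def aspect_coverage(importance_row: np.ndarray) -> float:
    """Aspect coverage of one passage: Σ_t Θ[j, t], the row sum."""
    return float(np.asarray(importance_row, dtype=np.float64).sum())
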