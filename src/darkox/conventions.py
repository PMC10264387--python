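"""Stable-isotope notation: delta / ratio / alpha / epsilon conversions and
the shared Rayleigh distillation form.

Conventions
-----------
delta (per mil)
    ``delta = (R_sample / R_standard - 1) * 1000`` against a named standard
    (V-SMOW for O/H, V-PDB for C, V-CDT for S).
epsilon (per mil)
    Enrichment factor between two pools, ``eps_AB = (R_A / R_B - 1) * 1000``;
    equivalently ``(alpha - 1) * 1000``.
Rayleigh
    ``delta(f) = (1000 + delta0) * f**(-eps/1000) - 1000`` for the residual
    pool when a fraction ``f`` of the initial amount remains. With this sign
    convention ``eps > 0`` means the *residual* pool becomes enriched as it
    is consumed (the consumed flux is isotopically light) — the behaviour of
    both microbial O2 respiration and microbial sulfate reduction.
"""

from __future__ import annotations

import numpy as np

STANDARDS = ("V-SMOW", "V-PDB", "V-CDT")


def delta_to_ratio(delta, r_standard: float = 1.0):
    """Isotope ratio R from a delta value (per mil) against a standard ratio."""
    return r_standard * (1.0 + np.asarray(delta, dtype=float) / 1000.0)


def ratio_to_delta(ratio, r_standard: float = 1.0):
    """Delta value (per mil) of ratio R against a standard ratio."""
    return (np.asarray(ratio, dtype=float) / r_standard - 1.0) * 1000.0


def alpha_to_epsilon(alpha):
    """Enrichment factor (per mil) from a fractionation factor alpha."""
    return (np.asarray(alpha, dtype=float) - 1.0) * 1000.0


def epsilon_to_alpha(epsilon):
    """Fractionation factor alpha from an enrichment factor (per mil)."""
    return 1.0 + np.asarray(epsilon, dtype=float) / 1000.0


def epsilon_between(delta_a, delta_b):
    """Exact enrichment factor eps_A-B (per mil) between two pools.

    ``eps = ((1000 + delta_a) / (1000 + delta_b) - 1) * 1000``. Raises on the
    singular case ``delta_b == -1000`` (pool B devoid of the heavy isotope).
    """
    delta_a = np.asarray(delta_a, dtype=float)
    delta_b = np.asarray(delta_b, dtype=float)
    if np.any(delta_b <= -1000.0) or np.any(delta_a <= -1000.0):
        raise ValueError("delta values must exceed -1000 per mil")
    return ((1000.0 + delta_a) / (1000.0 + delta_b) - 1.0) * 1000.0


def rayleigh_residual_delta(delta0, f, epsilon):
    """Delta of the residual pool after Rayleigh consumption to fraction f.

    Parameters
    ----------
    delta0 : initial delta of the pool, per mil.
    f : fraction of the pool remaining, in (0, 1].
    epsilon : enrichment factor, per mil; positive enriches the residual.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0):
        raise ValueError("residual fraction f must be in (0, 1]; f=0 is singular")
    if np.any(f > 1.0):
        raise ValueError("residual fraction f cannot exceed 1")
    return (1000.0 + np.asarray(delta0, dtype=float)) * f ** (
        -np.asarray(epsilon, dtype=float) / 1000.0
    ) - 1000.0
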