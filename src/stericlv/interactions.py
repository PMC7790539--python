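"""Competitive interaction matrices and interface-curvature theory.

Directed pairwise competition is encoded by thresholds ``P[i, k]``: the
local concentration of species k (in carrying-capacity units) above which k
actively reduces species i.  All-to-all (ATA) competition means every
off-diagonal entry lies in (0, 1).  Matrices are sampled entrywise from a
uniform distribution of mean ``mean_p`` and full width ``delta_p``.

The curvature theory links competitive asymmetry to the geometry of the
pillared environment: an unbalanced two-species interface is stable only if
it can curve at least as much as its pair-critical curvature, while two
pillars of radius R separated by dx cap the achievable curvature.  Setting
the ensemble-average critical curvature equal to the structural cap yields
the critical structural scale below which all species can coexist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: Ensemble-calibrated proportionality constant for the pair-critical
#: curvature: with uniform sampling E|P_ik − P_ki| = ΔP/3, so a prefactor of
#: 3 makes the pair expression average to the ensemble form ΔP/(2λ⟨P⟩).
DEFAULT_CURVATURE_PREFACTOR = 3.0


class SamplingSpecError(ValueError):
    """Interaction sampling parameters violate the ATA constraints."""


@dataclass
class InteractionMatrix:
    """N×N directed competition thresholds with their sampling spec.

    Diagonal entries are stored as NaN sentinels and never read: the
    dynamics removes self-interaction terms explicitly.
    """

    N: int
    P: np.ndarray
    mean_p: float | None = None
    delta_p: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.N, self.N):
            raise ValueError("P must be N x N")

    def offdiag(self) -> np.ndarray:
        """The N(N−1) off-diagonal entries as a flat array."""
        return self.P[~np.eye(self.N, dtype=bool)]

    def is_ata(self) -> bool:
        """True iff every off-diagonal threshold lies in (0, 1)."""
        off = self.offdiag()
        return bool(np.all((off > 0) & (off < 1)))


def validate_sampling_spec(N: int, mean_p: float, delta_p: float) -> None:
    if N < 2:
        raise SamplingSpecError("need at least 2 species")
    if not (0 < mean_p < 1):
        raise SamplingSpecError(f"mean_p={mean_p} must lie in (0, 1)")
    if delta_p < 0:
        raise SamplingSpecError("delta_p must be >= 0")
    if delta_p / 2 >= mean_p:
        raise SamplingSpecError(
            f"delta_p/2 = {delta_p / 2} must be < mean_p = {mean_p}")
    if mean_p + delta_p / 2 >= 1:
        raise SamplingSpecError(
            "mean_p + delta_p/2 must be < 1 (ATA regime)")


def sample_matrix(N: int, mean_p: float = 0.25, delta_p: float = 0.0,
                  rng=None, seed: int | None = None) -> InteractionMatrix:
    """Sample an ATA interaction matrix.

    Off-diagonal entries are independent Uniform[mean_p − delta_p/2,
    mean_p + delta_p/2] draws; the constraint delta_p/2 < mean_p keeps every
    directed interaction competitive.
    """
    validate_sampling_spec(N, mean_p, delta_p)
    if rng is None:
        rng = np.random.default_rng(seed)
    P = np.full((N, N), np.nan)
    off = ~np.eye(N, dtype=bool)
    P[off] = rng.uniform(mean_p - delta_p / 2, mean_p + delta_p / 2,
                         size=N * (N - 1))
    return InteractionMatrix(N=N, P=P, mean_p=mean_p, delta_p=delta_p,
                             seed=seed)


def pair_critical_curvature(p_ik: float, p_ki: float, lam: float = 1.0,
                            prefactor: float = DEFAULT_CURVATURE_PREFACTOR,
                            ) -> float:
    """Critical interface curvature (1/λ) for one unbalanced species pair.

    Below this curvature the stronger competitor invades; a balanced pair
    (p_ik = p_ki) has zero critical curvature.  The expression is a
    proportionality; the default prefactor is calibrated so its ensemble
    average matches :func:`ensemble_critical_curvature`.
    """
    p_ik = np.asarray(p_ik, dtype=float)
    p_ki = np.asarray(p_ki, dtype=float)
    if np.any(p_ik <= 0) or np.any(p_ki <= 0):
        raise ValueError("competition thresholds must be positive")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    out = prefactor * np.abs(p_ik - p_ki) / (lam * (p_ik + p_ki))
    return float(out) if out.ndim == 0 else out


def ensemble_critical_curvature(mean_p: float, delta_p: float,
                                lam: float = 1.0) -> float:
    """Ensemble-average critical curvature ΔP/(2λ⟨P⟩), valid for small
    ΔP/⟨P⟩ (a warning is emitted above 1)."""
    if delta_p / mean_p > 1:
        warnings.warn("ensemble curvature is a small-asymmetry "
                      f"approximation; delta_p/mean_p = {delta_p / mean_p}",
                      stacklevel=2)
    return delta_p / (2.0 * lam * mean_p)


def structural_critical_curvature(R: float, dx: float) -> float:
    """Maximum curvature (1/λ) of an arc spanning two pillars.

    An interface meeting both pillar surfaces at right angles and forming a
    circular arc between pillars of radius R at center separation dx cannot
    curve more than 1 / (R·sqrt((dx/2R)² − 1)); the cap diverges as the
    pillars approach contact and vanishes at large separation.
    """
    if dx <= 2 * R:
        raise ValueError(f"dx={dx} must exceed pillar diameter {2 * R}")
    return 1.0 / (R * np.sqrt((dx / (2 * R)) ** 2 - 1.0))


def critical_structural_scale(mean_p: float, delta_p: float, R: float,
                              lam: float = 1.0) -> float:
    """Critical dx/R below which all species can coexist.

    Solves ensemble critical curvature == structural curvature cap:
    (dx/R)_crit = 2·sqrt(1 + (2λ⟨P⟩/(R·ΔP))²).  Returns +inf for ΔP = 0
    (a fully balanced ensemble is stable at every structural scale).
    """
    if delta_p < 0:
        raise ValueError("delta_p must be >= 0")
    if delta_p == 0:
        return float("inf")
    return 2.0 * np.sqrt(1.0 + (2.0 * lam * mean_p / (R * delta_p)) ** 2)
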