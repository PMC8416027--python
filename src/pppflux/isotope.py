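"""Mass-isotopologue distributions (MIDs) and their pre-processing.

A mass-isotopologue distribution describes the fractional abundances of a
metabolite pool carrying 0..n heavy carbons (mass shifts m0..mn).  This module
provides the container type, intensity normalisation, natural-abundance
correction via a binomial convolution matrix, and the mean-enrichment summary
used for steady-state labelling QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "MassIsotopologueDistribution",
    "IsotopologueMeasurement",
    "CorrectionMatrix",
    "normalize_to_mid",
    "natural_abundance_matrix",
    "apply_matrix",
    "correct_mid",
    "mean_enrichment",
    "NATURAL_13C_ABUNDANCE",
]

#: Terrestrial natural abundance of 13C (fraction of carbon atoms).
NATURAL_13C_ABUNDANCE = 0.0107

# Fractions smaller than this after constrained correction are treated as
# numerically zero before renormalisation.
_CLAMP = 1e-12


@dataclass(frozen=True)
class MassIsotopologueDistribution:
    """Fractional abundances of mass shifts m0..mn of one metabolite pool.

    Parameters
    ----------
    metabolite_id
        Short metabolite name, e.g. ``"Ru5P"``.
    n_carbons
        Number of carbon atoms in the metabolite.
    fractions
        Nonnegative vector of length ``n_carbons + 1``; it is renormalised to
        sum to one on construction.
    """

    metabolite_id: str
    n_carbons: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.metabolite_id}: n_carbons must be >= 1")
        frac = np.asarray(self.fractions, dtype=float)
        if frac.ndim != 1 or frac.size != self.n_carbons + 1:
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} "
                f"fractions (m0..m{self.n_carbons}), got {frac.size}"
            )
        if np.any(frac < 0) or not np.all(np.isfinite(frac)):
            raise ValueError(f"{self.metabolite_id}: fractions must be finite and >= 0")
        total = frac.sum()
        if total <= 0:
            raise ValueError(f"{self.metabolite_id}: fractions sum to zero")
        object.__setattr__(self, "fractions", frac / total)

    def __getitem__(self, mass_shift: int) -> float:
        return float(self.fractions[mass_shift])


@dataclass(frozen=True)
class IsotopologueMeasurement:
    """One raw MS observation of a metabolite's isotopologue envelope."""

    condition: str
    replicate: int
    time_s: float
    metabolite_id: str
    raw_intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValueError(f"{self.key}: time_s must be >= 0")
        raw = np.asarray(self.raw_intensities, dtype=float)
        object.__setattr__(self, "raw_intensities", raw)

    @property
    def key(self) -> str:
        return f"{self.condition}/rep{self.replicate}/{self.metabolite_id}/t={self.time_s}s"

    def to_mid(self) -> MassIsotopologueDistribution:
        return normalize_to_mid(self.raw_intensities, self.metabolite_id, key=self.key)


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular binomial matrix mapping theoretical to measured MIDs.

    Column ``j`` holds the measured envelope produced by a pure tracer-derived
    m\\ *j* species once every remaining carbon can be 13C at natural
    abundance ``p13C``.
    """

    n_carbons: int
    p13C: float
    entries: np.ndarray


def normalize_to_mid(
    raw_intensities: np.ndarray,
    metabolite_id: str = "metabolite",
    *,
    n_carbons: int | None = None,
    key: str | None = None,
) -> MassIsotopologueDistribution:
    """Convert raw ion-count intensities to a fractional MID.

    Fractions are the raw values divided by their sum.  If ``n_carbons``
    exceeds the number of supplied mass shifts (an instrument method that only
    monitors m0..mk), the missing high-mass channels are padded with zeros.

    Raises
    ------
    ValueError
        If any intensity is negative or all are zero; the message names the
        offending sample ``key``.
    """
    label = key or metabolite_id
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.ndim != 1 or raw.size < 1:
        raise ValueError(f"{label}: intensities must be a 1-D vector")
    if np.any(raw < 0):
        raise ValueError(f"{label}: negative intensity encountered")
    if not np.any(raw > 0):
        raise ValueError(f"{label}: all intensities are zero")
    n = raw.size - 1 if n_carbons is None else n_carbons
    if n < raw.size - 1:
        raise ValueError(f"{label}: {raw.size} intensities exceed n_carbons={n}")
    padded = np.zeros(n + 1)
    padded[: raw.size] = raw
    return MassIsotopologueDistribution(metabolite_id, n, padded / padded.sum())


def natural_abundance_matrix(n_carbons: int, p13C: float = NATURAL_13C_ABUNDANCE) -> CorrectionMatrix:
    """Build the natural-abundance convolution matrix for ``n_carbons`` atoms.

    Entry ``(i, j)`` is the probability that a species with ``j`` tracer
    labels is measured at mass shift ``i`` because ``i - j`` of its remaining
    ``n_carbons - j`` carbons are naturally 13C:

    ``C(n - j, i - j) * p^(i-j) * (1 - p)^(n - i)`` for ``i >= j``, else 0.

    Each column is a full binomial law, so columns sum to one exactly.
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    if not 0.0 <= p13C < 0.5:
        raise ValueError(f"p13C must be in [0, 0.5), got {p13C}")
    size = n_carbons + 1
    entries = np.zeros((size, size))
    for j in range(size):
        for i in range(j, size):
            entries[i, j] = (
                math.comb(n_carbons - j, i - j)
                * p13C ** (i - j)
                * (1.0 - p13C) ** (n_carbons - i)
            )
    return CorrectionMatrix(n_carbons, p13C, entries)


def apply_matrix(
    mid: MassIsotopologueDistribution, matrix: CorrectionMatrix
) -> MassIsotopologueDistribution:
    """Forward-apply natural abundance: theoretical MID -> measured MID."""
    _check_match(mid, matrix)
    return MassIsotopologueDistribution(
        mid.metabolite_id, mid.n_carbons, matrix.entries @ mid.fractions
    )


def correct_mid(
    measured: MassIsotopologueDistribution, matrix: CorrectionMatrix
) -> MassIsotopologueDistribution:
    """Remove natural-abundance contributions from a measured MID.

    Solves ``matrix @ x = measured`` for the tracer-derived MID ``x`` as a
    nonnegatively-constrained least-squares problem (direct inversion can
    produce negative fractions on noisy data), clamps numerically-zero
    entries, and renormalises.
    """
    _check_match(measured, matrix)
    x, _ = nnls(matrix.entries, measured.fractions)
    x[x < _CLAMP] = 0.0
    if x.sum() <= 0:
        raise ValueError(
            f"{measured.metabolite_id}: correction produced an all-zero MID"
        )
    return MassIsotopologueDistribution(measured.metabolite_id, measured.n_carbons, x)


def mean_enrichment(mid: MassIsotopologueDistribution) -> float:
    """Average 13C labelling of the pool: sum(i * f_i) / n_carbons, in [0, 1]."""
    shifts = np.arange(mid.n_carbons + 1)
    return float(shifts @ mid.fractions) / mid.n_carbons


def _check_match(mid: MassIsotopologueDistribution, matrix: CorrectionMatrix) -> None:
    if mid.n_carbons != matrix.n_carbons:
        raise ValueError(
            f"{mid.metabolite_id}: MID has {mid.n_carbons} carbons but the "
            f"correction matrix was built for {matrix.n_carbons}"
        )
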