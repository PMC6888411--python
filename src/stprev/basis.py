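"""Cubic B-spline bases over centred calendar time.

Survey waves are unequally spaced, so temporal trends are modelled as
regression B-splines evaluated at centred years ``t = year - center_year``
(centre year 2004 by default).  With ``L`` interior knots and boundary knots
clamped at the observed extremes, the full cubic basis has ``L + 4``
columns whose rows sum to one; the first column is dropped so that a
separate intercept stays identifiable, leaving ``K = L + 3`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "center_years", "build_basis"]

DEGREE = 3  # cubic


def center_years(years: Sequence[int], center_year: int = 2004) -> np.ndarray:
    """Calendar years minus the centre year, as floats."""
    years = np.asarray(years, dtype=float)
    if years.size == 0:
        raise ValueError("years must be nonempty")
    return years - float(center_year)


@dataclass(frozen=True)
class SplineBasis:
    """Evaluated cubic B-spline basis at the study waves.

    ``B`` is the T x K design matrix after dropping the first column of the
    clamped (L+4)-column basis; ``B_full`` keeps all L+4 columns (rows sum
    to 1) for diagnostics.
    """

    waves: tuple[int, ...]
    center_year: int
    t_values: np.ndarray = field(repr=False)
    interior_knots: tuple[float, ...]
    B: np.ndarray = field(repr=False)
    B_full: np.ndarray = field(repr=False)
    degree: int = DEGREE

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def K(self) -> int:
        """Number of usable basis columns, K = L + 3."""
        return self.B.shape[1]

    def wave_index(self, year: int) -> int:
        return self.waves.index(year)


def _full_design(t: np.ndarray, interior_knots: np.ndarray) -> np.ndarray:
    lo, hi = t[0], t[-1]
    kv = np.concatenate(
        [np.repeat(lo, DEGREE + 1), interior_knots, np.repeat(hi, DEGREE + 1)]
    )
    return BSpline.design_matrix(t, kv, DEGREE, extrapolate=False).toarray()


def build_basis(
    waves: Sequence[int],
    interior_knots: Sequence[float] = (),
    center_year: int = 2004,
) -> SplineBasis:
    """Build the clamped cubic basis at the waves, dropping the first column.

    ``interior_knots`` are on the centred scale and must lie strictly inside
    ``(min t, max t)``; duplicates are rejected (no reduced continuity).
    """
    waves = tuple(int(w) for w in waves)
    if len(waves) < 2:
        raise ValueError("need at least 2 waves")
    t = center_years(waves, center_year)
    if not np.all(np.diff(t) > 0):
        raise ValueError("waves must be strictly increasing")
    knots = np.asarray(sorted(float(k) for k in interior_knots))
    if knots.size:
        if np.any((knots <= t[0]) | (knots >= t[-1])):
            raise ValueError(
                f"interior knots must lie strictly inside ({t[0]}, {t[-1]}); got {knots}"
            )
        if np.any(np.diff(knots) == 0):
            raise ValueError("duplicate interior knots are not allowed")
    full = _full_design(t, knots)
    return SplineBasis(
        waves=waves,
        center_year=int(center_year),
        t_values=t,
        interior_knots=tuple(knots.tolist()),
        B=full[:, 1:].copy(),
        B_full=full,
    )
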