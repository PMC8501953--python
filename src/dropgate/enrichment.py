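"""Efficiency-corrected fold enrichment from RT-qPCR threshold cycles.

After sorting a target population out of a mixture, enrichment of a
target gene X relative to a reference gene R is estimated from the four
threshold cycles (Ct) of the sorted and initial samples, correcting for
the two genes' amplification efficiencies E_X and E_R (per-cycle fold
increase minus 1, so a perfectly doubling reaction has E = 1):

    E = (1 + E_R) ** (Ct_R_sorted - Ct_R_initial)
        * (1 + E_X) ** (Ct_X_initial - Ct_X_sorted)

At E_R = E_X = 1 this reduces to the classical 2**(-ddCt) form.
Efficiencies are estimated from serial-dilution standard curves: for a
d-fold dilution series, Ct rises by log2(d) / log2(1 + E) per step, so
the slope s of Ct against log2(relative concentration) gives
E = 2 ** (-1 / s) - 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QpcrMeasurement", "fold_enrichment", "efficiency_from_dilution"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct values (cycles) and amplification efficiencies for one comparison.

    Efficiencies live on the 0-1 scale (0.36 means 1.36-fold per cycle).
    """

    ct_target_sorted: float
    ct_target_initial: float
    ct_ref_sorted: float
    ct_ref_initial: float
    eff_target: float
    eff_ref: float

    def __post_init__(self) -> None:
        for name in ("ct_target_sorted", "ct_target_initial", "ct_ref_sorted", "ct_ref_initial"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("eff_target", "eff_ref"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def fold_enrichment(m: QpcrMeasurement) -> float:
    """Efficiency-corrected fold enrichment of the target after sorting.

    Returns (1+E_R)^(dCt_R) * (1+E_X)^(-dCt_X) with
    dCt_R = Ct_R_sorted - Ct_R_initial and
    dCt_X = Ct_X_sorted - Ct_X_initial. Always positive; exactly 1 when
    neither gene's Ct moved.
    """
    d_ref = m.ct_ref_sorted - m.ct_ref_initial
    d_target = m.ct_target_initial - m.ct_target_sorted
    return (1.0 + m.eff_ref) ** d_ref * (1.0 + m.eff_target) ** d_target


def efficiency_from_dilution(
    ct_series: np.ndarray | list[float],
    dilution_factor: float = 2.0,
    concentrations: np.ndarray | list[float] | None = None,
) -> float:
    """Amplification efficiency from a serial-dilution standard curve.

    Parameters
    ----------
    ct_series
        Ct values at successive dilutions (most concentrated first when
        ``concentrations`` is not given).
    dilution_factor
        Fold dilution between successive points (default 2).
    concentrations
        Optional explicit relative concentrations, overriding the implied
        ``dilution_factor**-i`` series.

    Returns
    -------
    Efficiency on the 0-1 scale, from the least-squares slope s of Ct
    versus log2(concentration): E = 2**(-1/s) - 1, clipped to [0, 1]
    with a warning when the raw estimate falls outside.
    """
    ct = np.asarray(ct_series, dtype=float)
    if ct.size < 3:
        raise ValueError("need at least 3 dilution points")
    if concentrations is None:
        if dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        conc = dilution_factor ** -np.arange(ct.size)
    else:
        conc = np.asarray(concentrations, dtype=float)
        if conc.size != ct.size or np.any(conc <= 0):
            raise ValueError("concentrations must be positive, one per Ct")
    x = np.log2(conc)
    if np.ptp(x) == 0 or np.ptp(ct) == 0:
        raise ValueError("degenerate dilution series (zero variance)")
    slope = float(stats.linregress(x, ct).slope)
    if slope >= 0:
        raise ValueError("Ct must increase with dilution (negative slope vs log2 conc)")
    eff = 2.0 ** (-1.0 / slope) - 1.0
    if not (0.0 <= eff <= 1.0):
        warnings.warn(
            f"efficiency estimate {eff:.3f} outside [0, 1]; clipping", stacklevel=2
        )
        eff = min(1.0, max(0.0, eff))
    return eff
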