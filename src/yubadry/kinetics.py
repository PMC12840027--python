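"""Thin-layer drying kinetics quantities.

Conventions: moisture is expressed either wet-basis (fraction of total
mass) or dry-basis (g water per g dry solids); the moisture ratio assumes
zero equilibrium moisture content, so MR = Mt / M0; the drying rate is the
dry-basis moisture loss per minute between two weighings; the shrinkage
rate is the percent reduction of projected area relative to the fresh
sample; the rehydration ratio is rehydrated over dry weight in percent.

All functions accept scalars or numpy arrays and validate their domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "wb_to_db",
    "db_to_wb",
    "moisture_ratio",
    "drying_rate",
    "shrinkage_rate",
    "RehydrationPair",
    "rehydration_ratio",
]


def wb_to_db(m_wb):
    """Convert wet-basis moisture (fraction of total mass) to dry basis (g/g).

    db = wb / (1 - wb).  Defined for 0 <= wb < 1.
    """
    m_wb = np.asarray(m_wb, dtype=float)
    if np.any(m_wb < 0) or np.any(m_wb >= 1):
        raise ValueError("wet-basis moisture must lie in [0, 1)")
    out = m_wb / (1.0 - m_wb)
    return out.item() if out.ndim == 0 else out


def db_to_wb(m_db):
    """Inverse of :func:`wb_to_db`: wb = db / (1 + db)."""
    m_db = np.asarray(m_db, dtype=float)
    if np.any(m_db < 0):
        raise ValueError("dry-basis moisture must be non-negative")
    out = m_db / (1.0 + m_db)
    return out.item() if out.ndim == 0 else out


def moisture_ratio(Mt, M0):
    """MR = Mt / M0 with equilibrium moisture taken as zero (dimensionless)."""
    Mt = np.asarray(Mt, dtype=float)
    M0 = np.asarray(M0, dtype=float)
    if np.any(M0 <= 0):
        raise ValueError("initial moisture content M0 must be positive")
    if np.any(Mt < 0):
        raise ValueError("moisture content Mt must be non-negative")
    out = Mt / M0
    return out.item() if out.ndim == 0 else out


def drying_rate(Mt1, Mt2, t1, t2):
    """DR = (Mt1 - Mt2) / (t2 - t1), g water / g solids / min.

    ``Mt1`` is the earlier (t1) and ``Mt2`` the later (t2) dry-basis
    moisture.  Negative values are returned as-is: they flag condensation
    or measurement noise and are meaningful to keep.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 <= t1):
        raise ValueError("t2 must be strictly greater than t1")
    out = (np.asarray(Mt1, float) - np.asarray(Mt2, float)) / (t2 - t1)
    return out.item() if out.ndim == 0 else out


def shrinkage_rate(A0, At):
    """SR = (A0 - At) / A0 * 100, percent reduction of projected area."""
    A0 = np.asarray(A0, dtype=float)
    At = np.asarray(At, dtype=float)
    if np.any(A0 <= 0):
        raise ValueError("fresh projected area A0 must be positive")
    if np.any(At < 0):
        raise ValueError("projected area At must be non-negative")
    out = (A0 - At) / A0 * 100.0
    return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class RehydrationPair:
    """Dry weight and weight after rehydration, both in grams."""

    Wd: float
    Ww: float

    def __post_init__(self) -> None:
        if self.Wd <= 0:
            raise ValueError("dry weight Wd must be positive")
        if self.Ww < 0:
            raise ValueError("rehydrated weight Ww must be non-negative")


def rehydration_ratio(pair: RehydrationPair) -> float:
    """RR = Ww / Wd * 100 (percent)."""
    return pair.Ww / pair.Wd * 100.0
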