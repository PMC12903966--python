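"""Ecoenzymatic stoichiometry: activity ratios, vector angle/length, limitation class.

Six potential activities enter the analysis: beta-glucosidase (bg) and
cellobiohydrolase (cbh) for C acquisition; beta-N-acetylglucosaminidase (nag),
leucine aminopeptidase (lap) and urease (ue) for N acquisition; acid/alkaline
phosphatase (ap) for P acquisition.  The vector representation places each
sample at

    x = ln(bg + cbh) / ln(ap)                 (C vs P investment)
    y = ln(bg + cbh) / ln(nag + lap + ue)     (C vs N investment)

with angle = degrees(atan2(x, y)) and length = sqrt(x^2 + y^2).  The angle
convention is pinned by its observable behaviour: x = y gives exactly 45
degrees, P-axis dominance (larger x) gives angles above 45 (P limitation),
larger y gives angles below 45 (N limitation); longer vectors indicate
greater C limitation.

Because the components are ratios of logarithms, every pooled activity must
exceed 1 in the working unit (nmol g^-1 h^-1 here) -- the metrics are not
invariant to unit rescaling, so activities <= 1 are rejected rather than
shifted.

A published variant of the length formula uses ln(bg)/ln(ap) (bg alone) for
the P term while the angle pools bg+cbh on both axes; ``strict_length=True``
reproduces that printed form verbatim.  The default uses consistent pooled
axes so that length^2 = x^2 + y^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .synthetic_cohort import EnzymeActivitySet

ArrayLike = Union[float, np.ndarray]

N_LIMITED = "N-limited"
P_LIMITED = "P-limited"
BALANCED = "balanced"


@dataclass(frozen=True)
class VectorMetrics:
    """Per-sample enzyme-vector metrics and limitation class."""

    eea_cn: float
    eea_np: float
    x_component: float
    y_component: float
    angle_deg: float
    length: float
    limitation_class: str


def _check_positive(**named: ArrayLike) -> None:
    for name, value in named.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"enzyme activity {name!r} must be strictly positive")


def eea_cn(activities: EnzymeActivitySet) -> float:
    """C:N enzyme activity ratio, bg / (nag + lap)."""
    denom = activities.nag + activities.lap
    if denom <= 0:
        raise ValueError("nag + lap must be strictly positive")
    return activities.bg / denom


def eea_np(activities: EnzymeActivitySet) -> float:
    """N:P enzyme activity ratio, (nag + lap + ue) / ap.

    The constituent formula for this ratio is an interpretation (it is used in
    results narratives but never written out); documented as such.
    """
    if activities.ap <= 0:
        raise ValueError("ap must be strictly positive")
    return (activities.nag + activities.lap + activities.ue) / activities.ap


def vector_components(activities: EnzymeActivitySet) -> tuple[float, float]:
    """(x, y) log-ratio components; every pooled activity must exceed 1."""
    _check_positive(bg=activities.bg, cbh=activities.cbh, nag=activities.nag,
                    lap=activities.lap, ue=activities.ue, ap=activities.ap)
    c_pool = activities.bg + activities.cbh
    n_pool = activities.nag + activities.lap + activities.ue
    for name, pool in (("bg+cbh", c_pool), ("nag+lap+ue", n_pool), ("ap", activities.ap)):
        if pool <= 1.0:
            raise ValueError(
                f"pooled activity {name} = {pool:g} is <= 1 in the working unit; "
                "log-ratio components are undefined or negative")
    return (np.log(c_pool) / np.log(activities.ap),
            np.log(c_pool) / np.log(n_pool))


def vector_angle(x_component: ArrayLike, y_component: ArrayLike) -> ArrayLike:
    """Angle in degrees; x = y gives exactly 45, larger x gives > 45."""
    x = np.asarray(x_component, dtype=float)
    y = np.asarray(y_component, dtype=float)
    if np.any((x == 0) & (y == 0)):
        raise ValueError("vector components must not both be zero")
    angle = np.degrees(np.arctan2(x, y))
    return float(angle) if angle.ndim == 0 else angle


def vector_length(activities: EnzymeActivitySet, strict_length: bool = False) -> float:
    """Vector length; ``strict_length`` uses ln(bg)/ln(ap) for the P term."""
    x, y = vector_components(activities)
    if strict_length:
        x = np.log(activities.bg) / np.log(activities.ap)
        if x <= 0:
            raise ValueError("ln(bg)/ln(ap) <= 0: bg must exceed 1 in strict mode")
    return float(np.hypot(x, y))


def classify_limitation(angle_deg: float, tolerance_deg: float = 0.0) -> str:
    """Map an angle to {N-limited, balanced, P-limited} around the 45-degree rule."""
    if angle_deg < 45.0 - tolerance_deg:
        return N_LIMITED
    if angle_deg > 45.0 + tolerance_deg:
        return P_LIMITED
    return BALANCED


def vector_metrics(activities: EnzymeActivitySet, strict_length: bool = False,
                   tolerance_deg: float = 0.0) -> VectorMetrics:
    """All per-sample metrics for one activity set."""
    x, y = vector_components(activities)
    angle = vector_angle(x, y)
    return VectorMetrics(
        eea_cn=eea_cn(activities),
        eea_np=eea_np(activities),
        x_component=x,
        y_component=y,
        angle_deg=angle,
        length=vector_length(activities, strict_length=strict_length),
        limitation_class=classify_limitation(angle, tolerance_deg),
    )


def metrics_table(cohort: pd.DataFrame, strict_length: bool = False,
                  tolerance_deg: float = 0.0) -> pd.DataFrame:
    """Vector metrics per cohort row.

    Metrics are computed per plot sample and only then averaged for group
    summaries (the group means +/- SE convention).
    """
    out = []
    for _, row in cohort.iterrows():
        act = EnzymeActivitySet(row["bg"], row["cbh"], row["nag"],
                                row["lap"], row["ue"], row["ap"])
        m = vector_metrics(act, strict_length=strict_length, tolerance_deg=tolerance_deg)
        out.append({
            "plot_id": row["plot_id"], "treatment": row["treatment"],
            "depth_cm": row["depth_cm"], "eea_cn": m.eea_cn, "eea_np": m.eea_np,
            "x_component": m.x_component, "y_component": m.y_component,
            "angle_deg": m.angle_deg, "length": m.length,
            "limitation_class": m.limitation_class,
        })
    return pd.DataFrame(out)
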