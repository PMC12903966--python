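"""Stoichiometric microbial carbon-use efficiency (CUE_ST).

The community-level estimate treats CUE as a saturating function of a scalar
S_C:N that quantifies how far enzyme allocation redresses the mismatch
between the resource C:N on offer and the microbial biomass C:N demanded:

    S_C:N  = (1 / EEA_C:N) * (B_C:N / R_C:N)
    CUE_ST = CUE_max * S_C:N / (S_C:N + K_N)

with EEA_C:N = bg / (nag + lap), B_C:N = MBC/MBN, R_C:N = DOC/TDN.  CUE_max
= 0.6 is the thermodynamic upper bound on growth efficiency and K_N = 0.5 the
half-saturation constant, so CUE_ST(K_N) = CUE_max / 2 = 0.3 exactly.  CUE_ST
is strictly increasing in S, bounded in [0, CUE_max), and depends on DOC and
TDN (and MBC, MBN) only through their ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CUE_MAX_DEFAULT = 0.6
K_N_DEFAULT = 0.5


@dataclass(frozen=True)
class CueResult:
    """S_C:N and CUE_ST for one sample, with the constants used echoed."""

    s_cn: float
    cue_st: float
    cue_max: float = CUE_MAX_DEFAULT
    k_n: float = K_N_DEFAULT


def s_cn(eea_cn: float, b_cn: float, r_cn: float) -> float:
    """The stoichiometric scalar (1/EEA_C:N) * (B_C:N / R_C:N)."""
    for name, value in (("eea_cn", eea_cn), ("b_cn", b_cn), ("r_cn", r_cn)):
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be strictly positive and finite, got {value}")
    return (1.0 / eea_cn) * (b_cn / r_cn)


def cue_st(s: float, cue_max: float = CUE_MAX_DEFAULT, k_n: float = K_N_DEFAULT) -> float:
    """Saturating CUE at scalar ``s``: 0 at s = 0, approaching ``cue_max``."""
    if s < 0:
        raise ValueError(f"s must be >= 0, got {s}")
    if cue_max <= 0 or k_n <= 0:
        raise ValueError("cue_max and k_n must be strictly positive")
    return cue_max * s / (s + k_n)


def cue_from_sample(doc: float, tdn: float, mbc: float, mbn: float,
                    bg: float, nag: float, lap: float,
                    cue_max: float = CUE_MAX_DEFAULT,
                    k_n: float = K_N_DEFAULT) -> CueResult:
    """Compose EEA_C:N -> S_C:N -> CUE_ST from one sample's raw measurements."""
    for name, value in (("doc", doc), ("tdn", tdn), ("mbc", mbc), ("mbn", mbn),
                        ("bg", bg)):
        if value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")
    if nag + lap <= 0:
        raise ValueError("nag + lap must be strictly positive")
    eea = bg / (nag + lap)
    s = s_cn(eea, mbc / mbn, doc / tdn)
    return CueResult(s, cue_st(s, cue_max, k_n), cue_max, k_n)


def cue_table(cohort: pd.DataFrame, cue_max: float = CUE_MAX_DEFAULT,
              k_n: float = K_N_DEFAULT) -> pd.DataFrame:
    """Per-row CUE table (plot_id, depth, s_cn, cue_st, constants echoed)."""
    out = []
    for _, row in cohort.iterrows():
        try:
            res = cue_from_sample(row["doc"], row["tdn"], row["mbc"], row["mbn"],
                                  row["bg"], row["nag"], row["lap"],
                                  cue_max=cue_max, k_n=k_n)
        except ValueError as err:
            raise ValueError(f"row {row['plot_id']!r}: {err}") from err
        out.append({
            "plot_id": row["plot_id"], "treatment": row["treatment"],
            "depth_cm": row["depth_cm"], "s_cn": res.s_cn, "cue_st": res.cue_st,
            "cue_max": res.cue_max, "k_n": res.k_n,
        })
    return pd.DataFrame(out)
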