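"""Descriptive analyses of an efficiency table.

Covers the cooperativity summaries (median efficiency of contexts grouped by
a pair of positions, e.g. +4/+5, with bootstrap confidence intervals), and
the composition of the efficiency distribution: fold-range, per-quartile
fractions lacking the classical -3 purine or +4G determinants, and the mean
uplift of full high-efficiency-motif matches over contexts satisfying only
the -3R/+4G rule of thumb.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tis_space import (
    BASES,
    HIGH_EFFICIENCY_MOTIF,
    POSITION_OFFSETS,
    VARIABLE_POSITIONS,
)

N_BOOT_DEFAULT = 1000


class EmptyGroupError(ValueError):
    """A position-pair group contains no scored contexts."""


class DegenerateTiesError(ValueError):
    """All efficiencies are identical; quartiles are undefined."""


def _valid(table: pd.DataFrame) -> pd.DataFrame:
    eff = table["efficiency"].to_numpy(dtype=float)
    return table[np.isfinite(eff) & (eff > 0)]


def pairwise_position_medians(
    table: pd.DataFrame,
    positions: tuple[int, int] = (4, 5),
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Median efficiency for the 16 base combinations at two positions.

    Groups every scored context by its bases at the two named positions
    (field labels from -6..-1, +4, +5) and reports the group median, size,
    and a percentile-bootstrap 95% CI of the median (``n_boot`` resamples,
    deterministic given ``seed``).  Missing rows are skipped; an empty group
    raises :class:`EmptyGroupError`.
    """
    for p in positions:
        if p not in VARIABLE_POSITIONS:
            raise ValueError(f"position {p:+d} is not a variable TIS position")
    valid = _valid(table)
    off1, off2 = (POSITION_OFFSETS[p] for p in positions)
    tis = valid["tis"].to_numpy()
    eff = valid["efficiency"].to_numpy(dtype=float)
    b1 = np.array([t[off1] for t in tis])
    b2 = np.array([t[off2] for t in tis])
    rng = np.random.default_rng(seed)
    rows = []
    for base1 in BASES:
        for base2 in BASES:
            vals = eff[(b1 == base1) & (b2 == base2)]
            if vals.size == 0:
                raise EmptyGroupError(
                    f"no contexts with {positions[0]:+d}{base1}/"
                    f"{positions[1]:+d}{base2}"
                )
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boot = np.median(vals[idx], axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
            rows.append({
                f"base_{positions[0]:+d}": base1,
                f"base_{positions[1]:+d}": base2,
                "n": int(vals.size),
                "median": float(np.median(vals)),
                "ci_low": float(lo),
                "ci_high": float(hi),
            })
    return pd.DataFrame(rows)


def quartile_composition(table: pd.DataFrame) -> dict:
    """Fold-range and quartile composition of an efficiency table.

    Quartiles are taken over efficiency ranks with deterministic
    lexicographic tie-breaking on the context sequence; quartile 4 is the
    most efficient.  Reports, per quartile, the fraction of contexts lacking
    a -3 purine and lacking a +4G, the max/min efficiency fold-range, and
    the mean percent uplift of full motif matches over contexts that carry
    -3R and +4G but do not match the full motif.
    """
    valid = _valid(table)
    if len(valid) < 4:
        raise ValueError(f"need at least 4 scored rows, got {len(valid)}")
    eff_all = valid["efficiency"].to_numpy(dtype=float)
    if np.unique(eff_all).size == 1:
        raise DegenerateTiesError(
            "all efficiencies identical; quartiles are undefined"
        )
    ordered = valid.sort_values(["efficiency", "tis"], kind="stable")
    tis = ordered["tis"].to_numpy()
    eff = ordered["efficiency"].to_numpy(dtype=float)
    n = len(ordered)
    quart = (4 * np.arange(n)) // n  # 0 = bottom, 3 = top

    off3, off4 = POSITION_OFFSETS[-3], POSITION_OFFSETS[4]
    no_minus3r = np.array([t[off3] not in "AG" for t in tis])
    no_plus4g = np.array([t[off4] != "G" for t in tis])
    frac_no_minus3r = [float(no_minus3r[quart == q].mean()) for q in range(4)]
    frac_no_plus4g = [float(no_plus4g[quart == q].mean()) for q in range(4)]

    motif = np.array([
        all(t[POSITION_OFFSETS[p]] in allowed
            for p, allowed in HIGH_EFFICIENCY_MOTIF.items())
        for t in tis
    ])
    rule = ~no_minus3r & ~no_plus4g
    uplift = float("nan")
    if motif.any() and (rule & ~motif).any():
        uplift = 100.0 * (eff[motif].mean() / eff[rule & ~motif].mean() - 1.0)
    return {
        "n": n,
        "fold_range": float(eff.max() / eff.min()),
        "frac_no_minus3R": frac_no_minus3r,
        "frac_no_plus4G": frac_no_plus4g,
        "motif_uplift_percent": uplift,
    }
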