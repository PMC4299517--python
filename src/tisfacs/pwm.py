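"""Position weight matrix models of ln(TIS efficiency).

The efficiency of start-codon recognition is modeled as a log-linear function
of the eight variable context bases,

    E = k * exp( sum_i C[b_i, i] + sum_{i<j} C[b_i, i, b_j, j] + ... ),

motivated by treating preinitiation-complex binding as an equilibrium
association (ln E proportional to a free energy that decomposes over
positions).  Order 1 uses per-position (mononucleotide) terms only; order 2
adds all C(8,2) position-pair interaction tables; order 3 adds all C(8,3)
position-triple tables.

Coefficients carry the standard sum-to-zero identifiability constraint: mono
coefficients sum to zero over bases within each position, and every
interaction table has zero margins over each of its base factors.  Fitting
uses ordinary least squares on a sum-to-zero ("effects") contrast encoding,
which enforces the constraints exactly by construction; the intercept ln(k)
absorbs the overall level.  Contexts containing an upstream AUG (which
confound the reporter with an out-of-frame ORF) and rows flagged
missing/low-confidence are excluded from training.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .tis_space import (
    BASES,
    SPACE_SIZE,
    VARIABLE_POSITIONS,
    contexts_to_digits,
    space_digits,
    space_sequences,
    space_upstream_aug_mask,
    validate_tis,
)

N_POS = len(VARIABLE_POSITIONS)
N_BASES = len(BASES)

#: Sum-to-zero contrast rows for levels A,C,G,U: the dropped level (U) is the
#: negative sum of the others, so per-position effects sum to zero exactly.
CONTRAST = np.array(
    [[1.0, 0.0, 0.0],
     [0.0, 1.0, 0.0],
     [0.0, 0.0, 1.0],
     [-1.0, -1.0, -1.0]]
)

SCHEMA_VERSION = 1


class FitError(ValueError):
    """The regression cannot be run as requested."""


class RankDeficiencyError(FitError):
    """The training design is rank deficient (missing base/position levels)."""


def encode_design(digits: np.ndarray, order: int) -> tuple[np.ndarray, list[tuple]]:
    """Sum-to-zero contrast design matrix (without intercept) for contexts.

    ``digits`` is an (n, 8) base-index array.  Order 1 yields 8x3 = 24
    columns; order 2 adds C(8,2)*9 = 252; order 3 adds C(8,3)*27 = 1512.
    The column key maps each column back to its (base, position) tuples,
    where the named base is the contrast's +1 level.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")
    n = digits.shape[0]
    z = [CONTRAST[digits[:, i]] for i in range(N_POS)]  # each (n, 3)
    cols: list[np.ndarray] = []
    keys: list[tuple] = []
    for i, pos in enumerate(VARIABLE_POSITIONS):
        cols.append(z[i])
        keys.extend(("mono", BASES[u], pos) for u in range(3))
    if order >= 2:
        for i, j in itertools.combinations(range(N_POS), 2):
            cols.append(np.einsum("nu,nv->nuv", z[i], z[j]).reshape(n, 9))
            keys.extend(
                ("pair", BASES[u], VARIABLE_POSITIONS[i],
                 BASES[v], VARIABLE_POSITIONS[j])
                for u in range(3) for v in range(3)
            )
    if order >= 3:
        for i, j, k in itertools.combinations(range(N_POS), 3):
            cols.append(
                np.einsum("nu,nv,nw->nuvw", z[i], z[j], z[k]).reshape(n, 27)
            )
            keys.extend(
                ("triple", BASES[u], VARIABLE_POSITIONS[i],
                 BASES[v], VARIABLE_POSITIONS[j],
                 BASES[w], VARIABLE_POSITIONS[k])
                for u in range(3) for v in range(3) for w in range(3)
            )
    return np.concatenate(cols, axis=1), keys


@dataclass
class PWMModel:
    """Fitted position weight matrix on ln(efficiency).

    ``mono`` is an (8, 4) array over (variable position, base A/C/G/U);
    ``pair``/``triple`` map position-index tuples (into
    ``VARIABLE_POSITIONS``) to doubly/triply centered coefficient tables.
    ``intercept`` is ln(k).  ``mono_se`` holds OLS standard errors of the
    decoded mono effects (same shape as ``mono``) when fitted from data.
    """

    order: int
    intercept: float
    mono: np.ndarray
    pair: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    triple: dict[tuple[int, int, int], np.ndarray] = field(default_factory=dict)
    mono_se: np.ndarray | None = None
    pair_se: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def ln_predict_digits(self, digits: np.ndarray) -> np.ndarray:
        ln_e = np.full(digits.shape[0], self.intercept, dtype=float)
        for i in range(N_POS):
            ln_e += self.mono[i, digits[:, i]]
        if self.order >= 2:
            for (i, j), table in self.pair.items():
                ln_e += table[digits[:, i], digits[:, j]]
        if self.order >= 3:
            for (i, j, k), table in self.triple.items():
                ln_e += table[digits[:, i], digits[:, j], digits[:, k]]
        return ln_e

    def efficiencies(self, contexts) -> np.ndarray:
        """Predicted efficiency for a sequence of validated contexts."""
        return np.exp(self.ln_predict_digits(contexts_to_digits(contexts)))

    def efficiency(self, ctx: str) -> float:
        """Predicted efficiency of a single context (validated first)."""
        return float(self.efficiencies([validate_tis(ctx)])[0])

    def space_efficiencies(self) -> np.ndarray:
        """Predictions for the full enumerated space (length 65,536)."""
        return np.exp(self.ln_predict_digits(space_digits()))


def predict_efficiency(model, ctx: str) -> float:
    """Efficiency of ``ctx`` under a model or reference-table lookup."""
    return model.efficiency(ctx)


def _decode(beta: np.ndarray, order: int) -> tuple[
    np.ndarray,
    dict[tuple[int, int], np.ndarray],
    dict[tuple[int, int, int], np.ndarray],
]:
    """Expand contrast-basis coefficients into full zero-margin tables."""
    mono = np.empty((N_POS, N_BASES))
    k = 0
    for i in range(N_POS):
        mono[i] = CONTRAST @ beta[k:k + 3]
        k += 3
    pair: dict[tuple[int, int], np.ndarray] = {}
    triple: dict[tuple[int, int, int], np.ndarray] = {}
    if order >= 2:
        for i, j in itertools.combinations(range(N_POS), 2):
            b = beta[k:k + 9].reshape(3, 3)
            pair[(i, j)] = CONTRAST @ b @ CONTRAST.T
            k += 9
    if order >= 3:
        for i, j, m in itertools.combinations(range(N_POS), 3):
            b = beta[k:k + 27].reshape(3, 3, 3)
            triple[(i, j, m)] = np.einsum(
                "au,bv,cw,uvw->abc", CONTRAST, CONTRAST, CONTRAST, b
            )
            k += 27
    return mono, pair, triple


def fit_pwm(
    table: pd.DataFrame,
    order: int = 2,
    exclude_upstream_aug: bool = True,
    exclude_flagged: bool = True,
    weights: pd.Series | None = None,
) -> PWMModel:
    """Fit a PWM of the given order to an efficiency table by OLS on ln(E).

    ``table`` needs columns ``tis`` and ``efficiency`` (and optionally
    ``flag``; rows not flagged ``ok`` are dropped when ``exclude_flagged``).
    Contexts containing an upstream AUG are excluded from training by
    default.  ``weights`` enables read-count-weighted least squares (off by
    default).  Requires at least 10x more training rows than predictors.
    """
    tis = table["tis"].to_numpy()
    eff = table["efficiency"].to_numpy(dtype=float)
    keep = np.isfinite(eff) & (eff > 0)
    n_flagged = 0
    if exclude_flagged and "flag" in table.columns:
        flag_ok = table["flag"].to_numpy() == "ok"
        n_flagged = int((keep & ~flag_ok).sum())
        keep &= flag_ok
    digits_all = contexts_to_digits(tis)
    upstream = np.array(["AUG" in t[:6] for t in tis])
    n_upstream = 0
    if exclude_upstream_aug:
        n_upstream = int((keep & upstream).sum())
        keep &= ~upstream
    digits = digits_all[keep]
    y = np.log(eff[keep])
    n = digits.shape[0]

    n_mono = 3 * N_POS
    p = 1 + n_mono
    if order >= 2:
        p += 9 * (N_POS * (N_POS - 1)) // 2
    if order >= 3:
        p += 27 * (N_POS * (N_POS - 1) * (N_POS - 2)) // 6
    if n < 10 * p:
        raise FitError(
            f"{n} training rows for {p} predictors; need at least {10 * p}"
        )

    # every base must appear at every position, else effects are inestimable
    missing = [
        (VARIABLE_POSITIONS[i], BASES[b])
        for i in range(N_POS)
        for b in range(N_BASES)
        if not (digits[:, i] == b).any()
    ]
    if missing:
        raise RankDeficiencyError(
            f"unrepresented (position, base) levels in training data: {missing}"
        )

    x_raw, keys = encode_design(digits, order)
    x = np.column_stack([np.ones(n), x_raw])
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
        if (w < 0).any():
            raise FitError("negative regression weights")
        xtx = (x * w[:, None]).T @ x
        xty = (x * w[:, None]).T @ y
    else:
        xtx = x.T @ x
        xty = x.T @ y
    solver = "cholesky"
    try:
        cho = scipy.linalg.cho_factor(xtx)
        coef = scipy.linalg.cho_solve(cho, xty)
        unscaled_cov = scipy.linalg.cho_solve(cho, np.eye(p))
    except scipy.linalg.LinAlgError as exc:
        if order < 3:
            raise RankDeficiencyError(
                f"singular design of order {order}: {exc}"
            ) from exc
        # Excluding upstream-AUG contexts structurally empties the (A,U,G)
        # cell of every consecutive upstream position-triple, so the full
        # trinucleotide interaction model is not identifiable.  Use the
        # minimum-norm least-squares solution instead.
        solver = "pseudoinverse"
        evals, evecs = scipy.linalg.eigh(xtx)
        tol = evals.max() * 1e-10
        inv = np.where(evals > tol, 1.0 / np.maximum(evals, tol), 0.0)
        unscaled_cov = (evecs * inv) @ evecs.T
        coef = unscaled_cov @ xty
    resid = y - x @ coef
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = unscaled_cov * sigma2
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")

    mono, pair, triple = _decode(coef[1:], order)
    mono_se = np.empty((N_POS, N_BASES))
    for i in range(N_POS):
        block = cov[1 + 3 * i:1 + 3 * i + 3, 1 + 3 * i:1 + 3 * i + 3]
        mono_se[i] = np.sqrt(np.diag(CONTRAST @ block @ CONTRAST.T))
    pair_se: dict[tuple[int, int], np.ndarray] = {}
    if order >= 2:
        kron = np.kron(CONTRAST, CONTRAST)  # (16, 9)
        k = 1 + 3 * N_POS
        for key in pair:
            block = cov[k:k + 9, k:k + 9]
            pair_se[key] = np.sqrt(
                np.diag(kron @ block @ kron.T)
            ).reshape(N_BASES, N_BASES)
            k += 9
    return PWMModel(
        order=order,
        intercept=float(coef[0]),
        mono=mono,
        pair=pair,
        triple=triple,
        mono_se=mono_se,
        pair_se=pair_se,
        metadata={
            "n_train": int(n),
            "n_excluded_upstream_aug": n_upstream,
            "n_excluded_flagged": n_flagged,
            "n_predictors": int(p),
            "r_squared": r2,
            "residual_sd": float(np.sqrt(sigma2)),
            "weighted": weights is not None,
            "solver": solver,
        },
    )


def coefficient_report(model: PWMModel) -> tuple[pd.DataFrame, float]:
    """Exp-scale mononucleotide coefficient matrix and exp-scale intercept.

    Rows are bases, columns position labels; a value above 1.00 enhances
    efficiency, below 1.00 reduces it.  For an order-1 model, the product of
    a context's per-position values times the intercept reproduces its
    predicted efficiency; the geometric mean of the four values at any
    position is 1.00 (zero-sum on ln scale).
    """
    df = pd.DataFrame(
        np.exp(model.mono.T),
        index=list(BASES),
        columns=[f"{p:+d}" for p in VARIABLE_POSITIONS],
    )
    return df, float(np.exp(model.intercept))


def build_reference_table(model: PWMModel) -> pd.DataFrame:
    """Model predictions for all 65,536 contexts (the full reference table).

    Upstream-AUG contexts, excluded from training, are still predicted but
    flagged ``extrapolated``.
    """
    eff = model.space_efficiencies()
    flag = np.where(space_upstream_aug_mask(), "extrapolated", "ok")
    return pd.DataFrame({
        "tis": space_sequences(),
        "efficiency": eff,
        "flag": flag,
    })


class EfficiencyLookup:
    """Reference-table backend: scores contexts by exact table lookup.

    Drop-in replacement for :class:`PWMModel` wherever predictions are
    consumed (genome scanning, leaky scanning, variant effects); built from
    a TSV with ``tis`` and ``efficiency`` columns.
    """

    def __init__(self, table: pd.DataFrame):
        eff = table.set_index("tis")["efficiency"]
        if eff.index.has_duplicates:
            dup = eff.index[eff.index.duplicated()][0]
            raise ValueError(f"duplicate context in reference table: {dup!r}")
        self._eff = eff.to_dict()

    def efficiency(self, ctx: str) -> float:
        ctx = validate_tis(ctx)
        try:
            return float(self._eff[ctx])
        except KeyError:
            raise KeyError(f"context {ctx} absent from reference table") from None

    def efficiencies(self, contexts) -> np.ndarray:
        return np.array([self.efficiency(c) for c in contexts])

    def space_efficiencies(self) -> np.ndarray:
        if len(self._eff) != SPACE_SIZE:
            raise ValueError(
                f"reference table covers {len(self._eff)} of {SPACE_SIZE} contexts"
            )
        return np.array([self._eff[t] for t in space_sequences()])
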