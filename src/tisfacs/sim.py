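"""Synthetic FACS-seq data generator for the TIS reporter library.

Emulates the sort-seq experiment end to end: a known generative model assigns
every one of the 65,536 TIS contexts a ground-truth translation efficiency
(GFP/RFP ratio); cells carrying one reporter each express that ratio with
multiplicative log-normal noise; the population is sorted into 20
equal-occupancy gates (each holding 5% of cells, off-scale cells in the
extreme gates); and each sorted subpopulation is sequenced to a fixed depth,
producing a per-gate read-count matrix, optionally rendered as barcoded
FASTQ.

The generator exists to provide a known truth for parameter-recovery tests:
the ground-truth model has exactly the mono + pairwise log-linear structure
the PWM module fits, so fitted coefficients can be compared directly with the
generating ones.

All randomness flows from a single root seed; each stage derives an
independent child stream so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tis_space import (
    BASES,
    SPACE_SIZE,
    VARIABLE_POSITIONS,
    contexts_to_digits,
    space_digits,
    space_sequences,
    validate_tis,
)

N_GATES_DEFAULT = 20
#: Default cells per library member; with 65,536 members this gives a
#: ~2×10^7-cell sort, a desk-scale stand-in for the 2×10^7 cells
#: (10^6 per gate) sorted in the original experiment.
CELLS_PER_TIS_DEFAULT = 300
#: Default sequencing depth per gate.
READS_PER_GATE_DEFAULT = 50_000
#: Default log-normal noise sigma on ln(GFP/RFP).
NOISE_SIGMA_DEFAULT = 0.25

#: One distinct 6-mer barcode per gate (DNA alphabet, as sequenced).
GATE_BARCODES = (
    "AACGTG", "ACAGCT", "ACGTAA", "AGCTCA", "ATGCGT",
    "CAAGTC", "CATCGA", "CGATAC", "CGTTGA", "CTAGGA",
    "GACTAT", "GATTCG", "GCACAA", "GGTACT", "GTCAAG",
    "TACGGT", "TCAGAC", "TGACCA", "TGGATC", "TTGCAG",
)

#: Fixed template anchors flanking the 11-mer in a simulated read
#: (DNA alphabet; the downstream anchor begins with the +6C every library
#: member shares).
UPSTREAM_ANCHOR = "ACTGACTAGT"
DOWNSTREAM_ANCHOR = "CGAATTCAGC"


class DegenerateGatesError(ValueError):
    """Quantile gates cannot be drawn (e.g. all ratios identical)."""


class EmptyGateError(ValueError):
    """A sort gate holds no cells, so reads cannot be drawn from it."""


def library_coverage_probability(n_transformants: int, space_size: int = SPACE_SIZE) -> float:
    """Probability that a given library member is present in at least one of
    ``n_transformants`` uniform draws: 1 - (1 - 1/space_size)**n."""
    if space_size < 1:
        raise ValueError(f"space_size must be >= 1, got {space_size}")
    if n_transformants < 0:
        raise ValueError(f"n_transformants must be >= 0, got {n_transformants}")
    return -math.expm1(n_transformants * math.log1p(-1.0 / space_size))


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative log-linear efficiency model with known coefficients.

    ln E(ctx) = intercept + sum_i mono[i, b_i] + sum_{i<j} pair[(i,j)][b_i, b_j]

    where ``i`` indexes the eight variable positions (order of
    ``VARIABLE_POSITIONS``) and ``b`` the base at that position (A,C,G,U).
    Mono effects sum to zero within each position; pair tables are doubly
    centered (both margins zero), mirroring the identifiability convention of
    the fitted PWM.
    """

    intercept: float
    mono: np.ndarray  # (8, 4), ln scale
    pair: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def ln_efficiency(self, digits: np.ndarray) -> np.ndarray:
        """ln(true efficiency) for an (n, 8) digit array."""
        ln_e = np.full(digits.shape[0], self.intercept, dtype=float)
        for i in range(len(VARIABLE_POSITIONS)):
            ln_e += self.mono[i, digits[:, i]]
        for (i, j), table in self.pair.items():
            ln_e += table[digits[:, i], digits[:, j]]
        return ln_e

    def true_efficiencies(self) -> np.ndarray:
        """Efficiency of every context in enumeration order (length 65,536)."""
        return np.exp(self.ln_efficiency(space_digits()))

    def efficiency(self, ctx: str) -> float:
        """True efficiency of a single context."""
        digits = contexts_to_digits([validate_tis(ctx)])
        return float(np.exp(self.ln_efficiency(digits))[0])


def sample_ground_truth(
    seed: int,
    pair_fraction: float = 0.5,
    effect_scale: float = 0.10,
    intercept: float = math.log(76.9),
) -> GroundTruthModel:
    """Draw a random ground-truth model with zero-sum effects.

    Mono effects are N(0, effect_scale^2), centered per position; pairwise
    effects are N(0, (pair_fraction*effect_scale)^2), doubly centered per
    position pair.  ``pair_fraction = 0`` gives a purely mononucleotide
    truth.  Deterministic given ``seed``.

    Defaults give an efficiency range across the space of roughly an order of
    magnitude, comparable to the ~12-fold spread observed for real TIS
    contexts, with pairwise terms strong enough that a pairwise fit clearly
    beats a mononucleotide one.
    """
    if effect_scale <= 0:
        raise ValueError(f"effect_scale must be > 0, got {effect_scale}")
    if not 0.0 <= pair_fraction <= 1.0:
        raise ValueError(f"pair_fraction must be in [0, 1], got {pair_fraction}")
    rng = np.random.default_rng(seed)
    n_pos = len(VARIABLE_POSITIONS)
    mono = rng.normal(0.0, effect_scale, size=(n_pos, len(BASES)))
    mono -= mono.mean(axis=1, keepdims=True)
    pair: dict[tuple[int, int], np.ndarray] = {}
    if pair_fraction > 0:
        sd = pair_fraction * effect_scale
        for i in range(n_pos):
            for j in range(i + 1, n_pos):
                t = rng.normal(0.0, sd, size=(len(BASES), len(BASES)))
                t -= t.mean(axis=1, keepdims=True)
                t -= t.mean(axis=0, keepdims=True)
                pair[(i, j)] = t
    return GroundTruthModel(intercept=float(intercept), mono=mono, pair=pair)


@dataclass(frozen=True)
class CellPopulation:
    """A simulated reporter-library cell population.

    ``tis_index`` holds each cell's library member as a rank into the
    enumerated space; ``ratio`` its GFP/RFP value (strictly positive).
    """

    tis_index: np.ndarray  # (n_cells,) int32
    ratio: np.ndarray  # (n_cells,) float64

    def __len__(self) -> int:
        return self.tis_index.shape[0]


def simulate_cell_population(
    model: GroundTruthModel,
    cells_per_tis: int = CELLS_PER_TIS_DEFAULT,
    noise_sigma: float = NOISE_SIGMA_DEFAULT,
    seed: int | None = None,
) -> CellPopulation:
    """Simulate ``cells_per_tis`` cells for every context in the space.

    Each cell's GFP/RFP ratio is true_efficiency * exp(eps) with
    eps ~ N(0, noise_sigma^2); ``noise_sigma = 0`` gives noiseless ratios.
    """
    if cells_per_tis < 1:
        raise ValueError(f"cells_per_tis must be >= 1, got {cells_per_tis}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    ln_true = model.ln_efficiency(space_digits())
    tis_index = np.repeat(
        np.arange(SPACE_SIZE, dtype=np.int32), cells_per_tis
    )
    ln_ratio = np.repeat(ln_true, cells_per_tis)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ln_ratio = ln_ratio + rng.normal(0.0, noise_sigma, size=ln_ratio.shape)
    return CellPopulation(tis_index=tis_index, ratio=np.exp(ln_ratio))


@dataclass(frozen=True)
class GateSpec:
    """Sort-gate layout: 19 strictly increasing GFP/RFP boundaries defining
    20 intervals; the bottom and top intervals are open-ended (off-scale
    cells collect in the extreme gates)."""

    boundaries: np.ndarray  # (n_gates - 1,) float64, strictly increasing

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("boundaries must be a non-empty 1-D array")
        if (b <= 0).any() or (np.diff(b) <= 0).any():
            raise DegenerateGatesError(
                "gate boundaries must be positive and strictly increasing"
            )
        object.__setattr__(self, "boundaries", b)

    @property
    def n_gates(self) -> int:
        return self.boundaries.size + 1

    @property
    def labels(self) -> list[str]:
        return [f"gate_{g + 1:02d}" for g in range(self.n_gates)]


def assign_gates(
    pop: CellPopulation, n_gates: int = N_GATES_DEFAULT
) -> tuple[GateSpec, np.ndarray]:
    """Sort the population into ``n_gates`` equal-occupancy gates.

    Gating is rank-based: cells are sorted by ratio and split into contiguous
    blocks whose sizes differ by at most one (exactly N/n_gates cells — 5%
    for 20 gates — when N is divisible), so equal occupancy is exact rather
    than approximated by thresholding.  Reported boundaries are the ratio at
    each block edge.

    Returns the :class:`GateSpec` and a per-cell gate index (0-based, aligned
    with the population arrays).
    """
    n = len(pop)
    if n_gates < 2:
        raise ValueError(f"n_gates must be >= 2, got {n_gates}")
    if n < n_gates:
        raise ValueError(f"population of {n} cells cannot fill {n_gates} gates")
    order = np.argsort(pop.ratio, kind="stable")
    sorted_ratio = pop.ratio[order]
    if sorted_ratio[0] == sorted_ratio[-1]:
        raise DegenerateGatesError(
            "all GFP/RFP ratios are identical; quantile gates are undefined"
        )
    base, rem = divmod(n, n_gates)
    sizes = np.full(n_gates, base, dtype=np.int64)
    sizes[:rem] += 1
    edges = np.cumsum(sizes)
    boundaries = sorted_ratio[edges[:-1]]
    if (np.diff(boundaries) <= 0).any():
        raise DegenerateGatesError(
            "tied ratios span entire gates; boundaries are not strictly increasing"
        )
    gate_index = np.empty(n, dtype=np.int32)
    gate_index[order] = np.repeat(np.arange(n_gates, dtype=np.int32), sizes)
    return GateSpec(boundaries=boundaries), gate_index


def simulate_reads(
    pop: CellPopulation,
    gate_index: np.ndarray,
    n_gates: int = N_GATES_DEFAULT,
    reads_per_gate: int = READS_PER_GATE_DEFAULT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequence each sorted subpopulation to a fixed depth.

    Per gate, ``reads_per_gate`` reads are drawn multinomially with
    probabilities proportional to per-context cell counts in that gate.
    Returns the read-count matrix: one row per context of the full space (in
    enumeration order), one integer column per gate (gate_01..gate_NN,
    ordered by increasing GFP/RFP).
    """
    if reads_per_gate < 1:
        raise ValueError(f"reads_per_gate must be >= 1, got {reads_per_gate}")
    flat = gate_index.astype(np.int64) * SPACE_SIZE + pop.tis_index
    cell_counts = np.bincount(flat, minlength=n_gates * SPACE_SIZE).reshape(
        n_gates, SPACE_SIZE
    )
    rng = np.random.default_rng(seed)
    counts = np.empty((SPACE_SIZE, n_gates), dtype=np.int64)
    for g in range(n_gates):
        total = cell_counts[g].sum()
        if total == 0:
            raise EmptyGateError(f"gate_{g + 1:02d} holds no cells")
        counts[:, g] = rng.multinomial(reads_per_gate, cell_counts[g] / total)
    labels = [f"gate_{g + 1:02d}" for g in range(n_gates)]
    return pd.DataFrame(counts, index=pd.Index(space_sequences(), name="tis"),
                        columns=labels)


def write_reads_fastq(
    matrix: pd.DataFrame,
    path,
    barcodes=GATE_BARCODES,
    upstream_anchor: str = UPSTREAM_ANCHOR,
    downstream_anchor: str = DOWNSTREAM_ANCHOR,
) -> int:
    """Render a read-count matrix as error-free barcoded FASTQ.

    Each read is barcode + upstream anchor + 11-mer (DNA alphabet) +
    downstream anchor, at constant quality; reads appear in deterministic
    (context, gate) order.  Returns the number of reads written.
    """
    if len(barcodes) < matrix.shape[1]:
        raise ValueError(
            f"{matrix.shape[1]} gates but only {len(barcodes)} barcodes"
        )
    n_written = 0
    with open(path, "w") as fh:
        for tis, row in matrix.iterrows():
            tis_dna = tis.replace("U", "T")
            for g, count in enumerate(row.to_numpy()):
                if count == 0:
                    continue
                seq = barcodes[g] + upstream_anchor + tis_dna + downstream_anchor
                qual = "I" * len(seq)
                for r in range(int(count)):
                    fh.write(f"@{tis_dna}_g{g + 1:02d}_{r}\n{seq}\n+\n{qual}\n")
                    n_written += 1
    return n_written


def simulate_facsseq(
    seed: int,
    pair_fraction: float = 0.5,
    effect_scale: float = 0.10,
    cells_per_tis: int = CELLS_PER_TIS_DEFAULT,
    noise_sigma: float = NOISE_SIGMA_DEFAULT,
    n_gates: int = N_GATES_DEFAULT,
    reads_per_gate: int = READS_PER_GATE_DEFAULT,
) -> tuple[GroundTruthModel, GateSpec, pd.DataFrame]:
    """Run the full generator: truth -> cells -> gates -> reads.

    One root seed; each stage uses an independently spawned child stream, so
    identical seeds reproduce identical outputs end to end.
    """
    root = np.random.SeedSequence(seed)
    s_truth, s_cells, s_reads = root.spawn(3)
    model = sample_ground_truth(
        np.random.default_rng(s_truth).integers(2**31),
        pair_fraction=pair_fraction,
        effect_scale=effect_scale,
    )
    pop = simulate_cell_population(
        model, cells_per_tis=cells_per_tis, noise_sigma=noise_sigma,
        seed=np.random.default_rng(s_cells).integers(2**31),
    )
    gates, gate_index = assign_gates(pop, n_gates=n_gates)
    matrix = simulate_reads(
        pop, gate_index, n_gates=n_gates, reads_per_gate=reads_per_gate,
        seed=np.random.default_rng(s_reads).integers(2**31),
    )
    return model, gates, matrix


def truth_efficiency_table(
    model: GroundTruthModel, reference: str = "GCCACCAUGGG"
) -> pd.DataFrame:
    """Noiseless efficiency table straight from a ground-truth model.

    Bypasses sorting and sequencing entirely: the ``efficiency`` column is
    the true efficiency rescaled so the reference context scores 100.  Used
    for exact parameter-recovery checks.
    """
    from .tis_space import tis_rank

    e = model.true_efficiencies()
    ref = e[tis_rank(reference)]
    return pd.DataFrame({
        "tis": space_sequences(),
        "median_ratio": e,
        "efficiency": 100.0 * e / ref,
        "n_reads": np.full(SPACE_SIZE, np.inf),
        "flag": "ok",
    })
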