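"""Reconstruction of per-TIS efficiencies from gated read counts.

Raw FACS-seq data is a matrix of read counts per (TIS context, sort gate).
This module demultiplexes barcoded reads into that matrix, equalizes
sequencing depth across gates so each barcode represents an equal fraction
of the sorted population, rebuilds each context's GFP/RFP histogram over the
gate intervals, takes its median, and rescales medians so the reference
context GCCACCAUGGG scores exactly 100 relative units.

Within-gate median interpolation is linear in ln(ratio) (cytometer gates are
approximately log-spaced); the open-ended bottom and top gates are assigned
synthetic edges one median gate-width below/above the extreme boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import sim
from .tis_space import (
    AlphabetError,
    InvalidTISError,
    REFERENCE_TIS,
    SPACE_SIZE,
    TIS_LENGTH,
    space_sequences,
    validate_tis,
)
from .sim import GateSpec

#: Rows with fewer normalized reads than this are flagged low-confidence.
LOW_READ_THRESHOLD = 20.0


class ZeroGateError(ValueError):
    """A gate column has zero total reads and cannot be depth-normalized."""


class ReferenceMissingError(ValueError):
    """The reference context has no defined median; choose another reference."""


@dataclass
class RejectTally:
    """Per-reason counts of reads discarded during demultiplexing."""

    unknown_barcode: int = 0
    bad_anchor: int = 0
    truncated_read: int = 0
    invalid_base: int = 0
    no_start_codon: int = 0

    def total(self) -> int:
        return (self.unknown_barcode + self.bad_anchor + self.truncated_read
                + self.invalid_base + self.no_start_codon)


def extract_read_counts(
    fastq,
    barcode_to_gate: dict[str, str] | None = None,
    upstream_anchor: str = sim.UPSTREAM_ANCHOR,
    downstream_anchor: str = sim.DOWNSTREAM_ANCHOR,
) -> tuple[pd.DataFrame, RejectTally]:
    """Demultiplex a FASTQ stream into a read-count matrix.

    A read contributes iff its barcode is known, both template anchors match
    exactly, and the enclosed 11-mer validates as a TIS context; everything
    else is tallied by rejection reason.  ``barcode_to_gate`` maps barcode
    sequence to gate label (default: the simulator's 20-gate barcode table);
    gate columns are ordered as the mapping's values.
    """
    if barcode_to_gate is None:
        barcode_to_gate = {
            bc: f"gate_{g + 1:02d}" for g, bc in enumerate(sim.GATE_BARCODES)
        }
    if len(set(barcode_to_gate.values())) != len(barcode_to_gate):
        raise ValueError("barcode_to_gate must be injective")
    bc_lengths = {len(bc) for bc in barcode_to_gate}
    if len(bc_lengths) != 1:
        raise ValueError("all barcodes must have equal length")
    bc_len = bc_lengths.pop()
    if not upstream_anchor or not downstream_anchor:
        raise ValueError("anchors must be non-empty")

    gate_labels = list(barcode_to_gate.values())
    gate_col = {label: i for i, label in enumerate(gate_labels)}
    counts = np.zeros((SPACE_SIZE, len(gate_labels)), dtype=np.int64)
    tally = RejectTally()

    tis_start = bc_len + len(upstream_anchor)
    tis_end = tis_start + TIS_LENGTH
    min_len = tis_end + len(downstream_anchor)

    from .tis_space import tis_rank

    rank_cache: dict[str, int] = {}
    for record in SeqIO.parse(fastq, "fastq"):
        seq = str(record.seq).upper()
        if len(seq) < min_len:
            tally.truncated_read += 1
            continue
        gate = barcode_to_gate.get(seq[:bc_len])
        if gate is None:
            tally.unknown_barcode += 1
            continue
        if (seq[bc_len:tis_start] != upstream_anchor
                or seq[tis_end:min_len] != downstream_anchor):
            tally.bad_anchor += 1
            continue
        raw = seq[tis_start:tis_end]
        try:
            tis = validate_tis(raw)
        except AlphabetError:
            tally.invalid_base += 1
            continue
        except InvalidTISError:
            tally.no_start_codon += 1
            continue
        rank = rank_cache.get(tis)
        if rank is None:
            rank = rank_cache[tis] = tis_rank(tis)
        counts[rank, gate_col[gate]] += 1
    return (
        pd.DataFrame(counts, index=pd.Index(space_sequences(), name="tis"),
                     columns=gate_labels),
        tally,
    )


def normalize_barcode_depth(matrix: pd.DataFrame) -> pd.DataFrame:
    """Rescale each gate column so all column sums equal the mean raw total.

    Row proportions within a column are unchanged, so the matrix becomes
    invariant to per-gate sequencing depth.  Raises :class:`ZeroGateError`
    naming the first empty gate.
    """
    totals = matrix.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ZeroGateError(f"gate {zero.index[0]!r} has zero total reads")
    return matrix * (totals.mean() / totals)


def _log_gate_edges(gates: GateSpec) -> np.ndarray:
    """ln-scale gate edges, extending the open-ended extreme gates by the
    median adjacent-boundary ln-gap on each side."""
    lb = np.log(gates.boundaries)
    if lb.size > 1:
        width = float(np.median(np.diff(lb)))
    else:
        width = 1.0  # single boundary: arbitrary unit extension
    return np.concatenate([[lb[0] - width], lb, [lb[-1] + width]])


def estimate_median_efficiency(row, gates: GateSpec) -> float:
    """Median GFP/RFP of one context from its per-gate read weights.

    Locates the gate containing cumulative weight 0.5 and interpolates
    linearly in ln(ratio) between that gate's edges.  An all-zero row yields
    NaN (undefined median), not an exception.
    """
    w = np.asarray(row, dtype=float)
    if w.size != gates.n_gates:
        raise ValueError(f"expected {gates.n_gates} weights, got {w.size}")
    if (w < 0).any():
        raise ValueError("negative gate weights")
    total = w.sum()
    if total <= 0:
        return float("nan")
    return float(_medians_from_weights(w[None, :], gates)[0])


def _medians_from_weights(weights: np.ndarray, gates: GateSpec) -> np.ndarray:
    """Vectorized median reconstruction for an (n, n_gates) weight array.

    Rows with zero total weight get NaN.
    """
    edges = _log_gate_edges(gates)
    totals = weights.sum(axis=1)
    out = np.full(weights.shape[0], np.nan)
    ok = totals > 0
    if not ok.any():
        return out
    w = weights[ok] / totals[ok, None]
    cum = np.cumsum(w, axis=1)
    # first gate with cumulative weight >= 0.5
    g = np.argmax(cum >= 0.5, axis=1)
    rows = np.arange(w.shape[0])
    cum_before = np.where(g > 0, cum[rows, np.maximum(g - 1, 0)], 0.0)
    frac = w[rows, g]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(frac > 0, (0.5 - cum_before) / frac, 1.0)
    ln_med = edges[g] + t * (edges[g + 1] - edges[g])
    out[ok] = np.exp(ln_med)
    return out


def medians_for_matrix(matrix: pd.DataFrame, gates: GateSpec) -> pd.Series:
    """Per-context median GFP/RFP for a (depth-normalized) count matrix."""
    med = _medians_from_weights(matrix.to_numpy(dtype=float), gates)
    return pd.Series(med, index=matrix.index, name="median_ratio")


def normalize_to_reference(
    medians: pd.Series,
    n_reads: pd.Series | None = None,
    reference: str = REFERENCE_TIS,
    low_read_threshold: float = LOW_READ_THRESHOLD,
) -> pd.DataFrame:
    """Build an efficiency table with E(reference) = 100 exactly.

    ``E(t) = 100 * median(t) / median(reference)``.  Contexts with no reads
    are flagged ``missing`` (NaN efficiency, never zero-filled); rows with
    fewer than ``low_read_threshold`` normalized reads are flagged
    ``low_reads``; all others ``ok``.
    """
    reference = validate_tis(reference)
    if reference not in medians.index:
        raise ReferenceMissingError(
            f"reference {reference} absent from the median table; pass an "
            "alternative reference context"
        )
    ref_med = medians[reference]
    if not np.isfinite(ref_med) or ref_med <= 0:
        raise ReferenceMissingError(
            f"reference {reference} has undefined median; pass an "
            "alternative reference context"
        )
    efficiency = 100.0 * medians / ref_med
    if n_reads is None:
        n_reads = pd.Series(np.inf, index=medians.index)
    flag = np.where(
        ~np.isfinite(medians.to_numpy(dtype=float)), "missing",
        np.where(n_reads.to_numpy(dtype=float) < low_read_threshold,
                 "low_reads", "ok"),
    )
    return pd.DataFrame({
        "tis": medians.index,
        "median_ratio": medians.to_numpy(dtype=float),
        "efficiency": efficiency.to_numpy(dtype=float),
        "n_reads": n_reads.to_numpy(dtype=float),
        "flag": flag,
    }).reset_index(drop=True)


def quantify(
    matrix: pd.DataFrame,
    gates: GateSpec,
    reference: str = REFERENCE_TIS,
    low_read_threshold: float = LOW_READ_THRESHOLD,
) -> pd.DataFrame:
    """Full quantification: depth-normalize, reconstruct medians, rescale.

    Returns the efficiency table (columns tis, median_ratio, efficiency,
    n_reads, flag) over every context present in the matrix.
    """
    norm = normalize_barcode_depth(matrix)
    medians = medians_for_matrix(norm, gates)
    n_reads = norm.sum(axis=1)
    table = normalize_to_reference(
        medians, n_reads, reference=reference,
        low_read_threshold=low_read_threshold,
    )
    # Medians falling in the open-ended bottom/top gates are censored: the
    # sorter collected off-scale cells there, so the reconstructed value
    # depends on the synthetic-edge convention rather than on data.  Such
    # rows keep their value but are flagged out of model training.
    lo, hi = gates.boundaries[0], gates.boundaries[-1]
    med = table["median_ratio"].to_numpy(dtype=float)
    off = np.isfinite(med) & ~((med > lo) & (med < hi))
    table.loc[off & (table["flag"] == "ok").to_numpy(), "flag"] = "off_scale"
    return table
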