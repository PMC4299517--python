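"""Genome-wide TIS scanning: annotated start codons and uORF starts.

Transcripts are provided as sequences (FASTA) plus a CDS annotation table
(1-based inclusive coordinates, GenBank convention: ``cds_start`` is the A
of the annotated AUG, ``cds_end`` the last base of the stop codon).  For
each transcript the module extracts the 11-base context of the annotated
start, finds every AUG lying entirely within the 5' UTR (a uORF start), and
scores all contexts with a PWM model or reference-table lookup.  It also
locates the truncation TIS: the nearest downstream in-frame AUG strictly
before the stop codon, whose use yields an N-terminally truncated protein.

Internally coordinates are 0-based half-open; all I/O is 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tis_space import normalize_alphabet

_AUG = re.compile("(?=AUG)")

#: Context window: 6 bases upstream, the AUG, 2 downstream.
_UPSTREAM = 6
_DOWNSTREAM = 2


@dataclass(frozen=True)
class TranscriptRecord:
    """A validated transcript with an annotated AUG-initiated CDS."""

    id: str
    sequence: str  # normalized RNA
    cds_start: int  # 1-based position of the A of the annotated AUG
    cds_end: int  # 1-based last base of the stop codon


def validate_transcript(
    tid: str, sequence: str, cds_start: int, cds_end: int
) -> TranscriptRecord:
    """Normalize and validate one transcript; raises ValueError with the
    reason on failure (non-AUG start, bad bounds, CDS not codon-multiple)."""
    seq = normalize_alphabet(sequence)
    if not 1 <= cds_start < cds_end <= len(seq):
        raise ValueError(
            f"{tid}: CDS bounds {cds_start}..{cds_end} invalid for length {len(seq)}"
        )
    if (cds_end - cds_start + 1) % 3 != 0:
        raise ValueError(f"{tid}: CDS length not a multiple of 3")
    if seq[cds_start - 1:cds_start + 2] != "AUG":
        raise ValueError(
            f"{tid}: annotated start is {seq[cds_start - 1:cds_start + 2]!r}, not AUG"
        )
    return TranscriptRecord(id=tid, sequence=seq,
                            cds_start=cds_start, cds_end=cds_end)


def load_transcripts(
    sequences: dict[str, str], annotations: pd.DataFrame
) -> tuple[list[TranscriptRecord], list[tuple[str, str]]]:
    """Join sequences with an annotation table (columns id, cds_start,
    cds_end); returns validated records plus a (id, reason) skip report."""
    records: list[TranscriptRecord] = []
    skipped: list[tuple[str, str]] = []
    annotated = set()
    for row in annotations.itertuples(index=False):
        annotated.add(row.id)
        seq = sequences.get(row.id)
        if seq is None:
            skipped.append((row.id, "missing_sequence"))
            continue
        try:
            records.append(
                validate_transcript(row.id, seq, int(row.cds_start),
                                    int(row.cds_end))
            )
        except ValueError as exc:
            skipped.append((row.id, str(exc)))
    for tid in sequences:
        if tid not in annotated:
            skipped.append((tid, "missing_annotation"))
    return records, skipped


def extract_tis_context(sequence: str, pos: int) -> tuple[str | None, str | None]:
    """11-mer context around the AUG at 1-based position ``pos``.

    Returns ``(context, None)`` or ``(None, reason)`` when the window runs
    off the transcript (``insufficient_upstream`` / ``insufficient_downstream``).
    Raises ValueError if ``pos`` is not an AUG.
    """
    if sequence[pos - 1:pos + 2] != "AUG":
        raise ValueError(f"no AUG at position {pos}")
    if pos - 1 < _UPSTREAM:
        return None, "insufficient_upstream"
    if pos + 2 + _DOWNSTREAM > len(sequence):
        return None, "insufficient_downstream"
    return sequence[pos - 1 - _UPSTREAM:pos + 2 + _DOWNSTREAM], None


def find_truncation_tis(record: TranscriptRecord) -> int | None:
    """Nearest downstream in-frame AUG strictly before the stop codon.

    Returns its 1-based position, or None when no internal in-frame AUG
    exists.
    """
    seq = record.sequence
    # last allowed codon start keeps the AUG strictly before the stop codon
    for p in range(record.cds_start + 3, record.cds_end - 4, 3):
        if seq[p - 1:p + 2] == "AUG":
            return p
    return None


def uorf_positions(record: TranscriptRecord) -> list[int]:
    """1-based positions of every AUG lying entirely within the 5' UTR
    (the codon's last base at most cds_start - 1)."""
    utr_limit = record.cds_start - 1
    return [
        m.start() + 1
        for m in _AUG.finditer(record.sequence[:utr_limit])
        if m.start() + 3 <= utr_limit
    ]


def scan_transcriptome(
    records: list[TranscriptRecord], model
) -> tuple[pd.DataFrame, dict]:
    """Score annotated and uORF TIS contexts across a transcript set.

    Returns one row per TIS (transcript id, category annotated/uORF, 1-based
    position, context or flag, efficiency) and a summary comparing each
    category's mean efficiency with the full-space mean (per-transcript
    weighting) along with its share in the space's top and bottom
    efficiency quartiles.  Contexts with insufficient flanking sequence are
    flagged and excluded from the summaries.
    """
    rows = []
    for rec in records:
        ctx, reason = extract_tis_context(rec.sequence, rec.cds_start)
        rows.append({
            "transcript_id": rec.id, "category": "annotated",
            "position": rec.cds_start, "context": ctx,
            "flag": reason or "ok",
            "efficiency": model.efficiency(ctx) if ctx else np.nan,
        })
        for pos in uorf_positions(rec):
            ctx, reason = extract_tis_context(rec.sequence, pos)
            rows.append({
                "transcript_id": rec.id, "category": "uORF",
                "position": pos, "context": ctx,
                "flag": reason or "ok",
                "efficiency": model.efficiency(ctx) if ctx else np.nan,
            })
    annotations = pd.DataFrame(
        rows, columns=["transcript_id", "category", "position",
                       "context", "flag", "efficiency"],
    )
    space = model.space_efficiencies()
    space_mean = float(space.mean())
    q25, q75 = np.percentile(space, [25, 75])
    summary: dict = {
        "space_mean": space_mean,
        "space_q25": float(q25),
        "space_q75": float(q75),
        "categories": {},
    }
    for cat in ("annotated", "uORF"):
        sub = annotations[(annotations["category"] == cat)
                          & (annotations["flag"] == "ok")]
        eff = sub["efficiency"].to_numpy(dtype=float)
        n_skipped = int((annotations["category"] == cat).sum() - len(sub))
        if eff.size == 0:
            summary["categories"][cat] = {"n": 0, "n_skipped": n_skipped}
            continue
        summary["categories"][cat] = {
            "n": int(eff.size),
            "n_skipped": n_skipped,
            "mean": float(eff.mean()),
            "mean_uplift_percent": 100.0 * (eff.mean() / space_mean - 1.0),
            "frac_top_quartile": float((eff > q75).mean()),
            "frac_bottom_quartile": float((eff < q25).mean()),
        }
    return annotations, summary
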