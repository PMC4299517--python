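"""Quantitative leaky-scanning prediction of truncated protein isoforms.

Scanning preinitiation complexes initiate at a start codon with probability
p = k*E/100, where E is the relative context efficiency (reference = 100)
and k = 0.86 converts relative efficiency to an absolute initiation
probability (estimated previously from synthetic uORF reporters).  Ribosomes
that leak past the annotated start can initiate at the nearest downstream
in-frame AUG, producing an N-terminal truncation.  The initiation ratio at
the truncation TIS relative to the annotated TIS is

    X = (1 - p(E1)) * p(E2) / p(E1)

which, away from clamping, reduces to (1 - k*E1/100) * E2/E1.  Transcripts
are binned as X >= 1.0 (truncation initiation at least matches the
annotated start), 0.50 <= X < 1.0, and X < 0.50.

The module also applies the ribosome-footprint comparison filters to an
external per-transcript count table: enough footprint reads at the annotated
TIS (>= 50), sufficient separation of the two AUGs (>= 20 bases), and no
annotated alternative 5' transcript isoform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import TranscriptRecord, extract_tis_context, find_truncation_tis

logger = logging.getLogger(__name__)

SCANNING_CONSTANT = 0.86
MIN_FOOTPRINT_READS = 50
MIN_SEPARATION = 20

CLASS_HIGH = "X>=1.0"
CLASS_MID = "0.50<=X<1.0"
CLASS_LOW = "X<0.50"


def initiation_ratio(e1: float, e2: float, k: float = SCANNING_CONSTANT) -> float:
    """Initiation ratio X of a downstream TIS relative to an upstream one.

    Efficiencies enter as initiation probabilities p = min(1, k*E/100);
    values with k*E/100 > 1 clamp to 1 (logged), since reference-scaled
    efficiencies can exceed 100.  ``e2 = 0`` gives X = 0.
    """
    if e1 <= 0:
        raise ValueError(f"upstream efficiency must be > 0, got {e1}")
    if e2 < 0:
        raise ValueError(f"downstream efficiency must be >= 0, got {e2}")
    if not 0 < k <= 1:
        raise ValueError(f"scanning constant k must be in (0, 1], got {k}")
    p1, p2 = k * e1 / 100.0, k * e2 / 100.0
    if p1 > 1.0 or p2 > 1.0:
        logger.warning(
            "initiation probability clamped to 1 (E1=%g, E2=%g, k=%g)",
            e1, e2, k,
        )
        p1, p2 = min(p1, 1.0), min(p2, 1.0)
    return (1.0 - p1) * p2 / p1


def classify_ratio(x: float) -> str:
    """Bin an initiation ratio (boundaries inclusive on the upper class)."""
    if x >= 1.0:
        return CLASS_HIGH
    if x >= 0.50:
        return CLASS_MID
    return CLASS_LOW


def predict_truncation_isoforms(
    records: list[TranscriptRecord], model, k: float = SCANNING_CONSTANT
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Leaky-scanning predictions for every transcript with a truncation TIS.

    For each transcript whose annotated context and nearest downstream
    in-frame AUG context are both defined, computes E1, E2, their separation
    in bases, X, and the X class.  Transcripts without a truncation TIS or
    with insufficient context are flagged and excluded from class counts.
    """
    rows = []
    for rec in records:
        ctx1, reason1 = extract_tis_context(rec.sequence, rec.cds_start)
        pos2 = find_truncation_tis(rec)
        if pos2 is None:
            rows.append({"transcript_id": rec.id, "flag": "no_truncation_tis"})
            continue
        ctx2, reason2 = extract_tis_context(rec.sequence, pos2)
        if ctx1 is None or ctx2 is None:
            rows.append({
                "transcript_id": rec.id,
                "flag": reason1 or reason2,
            })
            continue
        e1 = model.efficiency(ctx1)
        e2 = model.efficiency(ctx2)
        x = initiation_ratio(e1, e2, k=k)
        rows.append({
            "transcript_id": rec.id,
            "annotated_pos": rec.cds_start,
            "truncation_pos": pos2,
            "separation": pos2 - rec.cds_start,
            "annotated_context": ctx1,
            "truncation_context": ctx2,
            "E1": e1,
            "E2": e2,
            "X": x,
            "class": classify_ratio(x),
            "flag": "ok",
        })
    predictions = pd.DataFrame(rows)
    counts = {CLASS_HIGH: 0, CLASS_MID: 0, CLASS_LOW: 0}
    if "class" in predictions.columns:
        for cls, n in predictions["class"].value_counts().items():
            if isinstance(cls, str):
                counts[cls] = int(n)
    return predictions, counts


def apply_footprint_filters(
    predictions: pd.DataFrame,
    footprints: pd.DataFrame,
    min_reads: int = MIN_FOOTPRINT_READS,
    min_separation: int = MIN_SEPARATION,
) -> tuple[pd.DataFrame, dict]:
    """Keep predictions supportable by ribosome footprint data.

    ``footprints`` needs columns ``id``, ``reads_at_annotated_tis`` and
    ``alt_isoform`` (0/1).  A row survives iff reads >= ``min_reads``,
    separation >= ``min_separation``, and no alternative 5' isoform is
    annotated (boundaries inclusive).  Attrition is reported per filter
    (each dropped row counted once, in that order); prediction ids missing
    from the count table are listed, not silently dropped.
    """
    fp = footprints.set_index("id")
    if fp.index.has_duplicates:
        dup = fp.index[fp.index.duplicated()][0]
        raise ValueError(f"duplicate transcript id in footprint table: {dup!r}")
    usable = predictions[predictions.get("flag", "ok") == "ok"]
    attrition = {"low_footprint": 0, "close_tis": 0, "alt_isoform": 0,
                 "missing_ids": []}
    kept = []
    for row in usable.itertuples(index=False):
        if row.transcript_id not in fp.index:
            attrition["missing_ids"].append(row.transcript_id)
            continue
        info = fp.loc[row.transcript_id]
        if info["reads_at_annotated_tis"] < min_reads:
            attrition["low_footprint"] += 1
        elif row.separation < min_separation:
            attrition["close_tis"] += 1
        elif bool(info["alt_isoform"]):
            attrition["alt_isoform"] += 1
        else:
            kept.append(row._asdict())
    filtered = pd.DataFrame(kept, columns=list(usable.columns))
    return filtered, attrition
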