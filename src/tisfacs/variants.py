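"""Predicted effects of single-nucleotide variants in the TIS motif.

A TIS variant substitutes one base at a non-start-codon position (-6..-1,
+4, +5) of a gene's 11-base start-codon context.  Its effect is reported as
the percent change in model-predicted efficiency,

    percent_change = 100 * (E_mut - E_wt) / E_wt,

negative values meaning reduced translation.  A screening helper flags
whether the predicted direction agrees with a user-supplied expression
direction (e.g. tumor up-/down-regulation), with no statistical claims.
Scoring accepts either a fitted PWM model or a reference-table lookup.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tis_space import BASES, POSITION_OFFSETS, validate_tis

START_CODON_POSITIONS = (1, 2, 3)


class StartCodonMutationError(ValueError):
    """Start-codon positions +1..+3 are out of scope for SNV scoring."""


def apply_snv(ctx: str, position: int, alt: str) -> str:
    """Return the context with a single substitution at a field position.

    ``position`` uses field labels (-6..-1, +4, +5; no 0); substituting
    within the start codon or with ``alt`` equal to the current base is an
    error.  The input context is unchanged.
    """
    ctx = validate_tis(ctx)
    if position in START_CODON_POSITIONS:
        raise StartCodonMutationError(
            f"position {position:+d} is within the AUG start codon"
        )
    if position not in POSITION_OFFSETS:
        raise ValueError(f"invalid TIS position {position}")
    alt = alt.upper().replace("T", "U")
    if alt not in BASES:
        raise ValueError(f"alternate base must be one of {BASES}, got {alt!r}")
    offset = POSITION_OFFSETS[position]
    if ctx[offset] == alt:
        raise ValueError(
            f"alternate base {alt} equals the reference base at {position:+d}"
        )
    return ctx[:offset] + alt + ctx[offset + 1:]


def predict_variant_effect(
    model, wt_context: str, position: int, ref: str, alt: str
) -> dict:
    """Score one SNV: E_wt, E_mut, and percent change in efficiency.

    Raises ValueError if the stated reference base does not match the
    wild-type context at the given position.
    """
    wt_context = validate_tis(wt_context)
    ref = ref.upper().replace("T", "U")
    offset = POSITION_OFFSETS.get(position)
    if offset is None:
        raise ValueError(f"invalid TIS position {position}")
    if wt_context[offset] != ref:
        raise ValueError(
            f"stated reference base {ref} does not match context base "
            f"{wt_context[offset]} at position {position:+d}"
        )
    mut_context = apply_snv(wt_context, position, alt)
    e_wt = model.efficiency(wt_context)
    e_mut = model.efficiency(mut_context)
    return {
        "wt_context": wt_context,
        "mut_context": mut_context,
        "position": position,
        "ref": ref,
        "alt": alt.upper().replace("T", "U"),
        "E_wt": e_wt,
        "E_mut": e_mut,
        "percent_change": 100.0 * (e_mut - e_wt) / e_wt,
    }


def screen_variant_table(model, variants: pd.DataFrame) -> pd.DataFrame:
    """Score a variant table and flag expression-direction consistency.

    ``variants`` needs columns gene, wt_context, position (field labels,
    e.g. "-4" or "+5"), ref, alt, and direction ("up"/"down").  Adds E_wt,
    E_mut, percent_change and a consistency flag: ``consistent`` when the
    predicted sign matches the direction, ``inconsistent`` otherwise, and
    ``indeterminate`` for a zero predicted change.
    """
    rows = []
    for row in variants.itertuples(index=False):
        direction = str(row.direction).lower()
        if direction not in ("up", "down"):
            raise ValueError(
                f"unknown expression direction {row.direction!r} for "
                f"{row.gene}; expected 'up' or 'down'"
            )
        res = predict_variant_effect(
            model, row.wt_context, int(row.position), row.ref, row.alt
        )
        change = res["percent_change"]
        if change == 0:
            consistent = "indeterminate"
        elif (change > 0) == (direction == "up"):
            consistent = "consistent"
        else:
            consistent = "inconsistent"
        rows.append({
            "gene": row.gene,
            **res,
            "direction": direction,
            "consistent": consistent,
        })
    return pd.DataFrame(rows)
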