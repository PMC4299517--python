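"""Readers and writers for every external format used by the package.

Everything is plain text: FASTA/FASTQ for sequences and reads, TSV with
explicit headers for matrices and tables, JSON for gate layouts and model
serialization, YAML for pipeline configuration.  PWM models round-trip
losslessly through a schema-versioned JSON document.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import pwm as pwm_mod
from .pwm import SCHEMA_VERSION, EfficiencyLookup, PWMModel
from .sim import GateSpec
from .tis_space import BASES, REFERENCE_TIS, VARIABLE_POSITIONS, validate_tis


class ModelVersionError(ValueError):
    """Model file schema does not match this package version; migrate it."""


def read_fasta(path) -> dict[str, str]:
    """Standard multi-line FASTA into an id -> sequence mapping.

    Ids are taken to the first whitespace; duplicate ids and empty files
    are errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="tis")


def read_count_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col="tis")
    if (matrix.to_numpy() < 0).any():
        raise ValueError(f"negative read counts in {path}")
    return matrix


def write_efficiency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_efficiency_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "tis" not in table.columns or "efficiency" not in table.columns:
        raise ValueError(f"{path} lacks required columns 'tis'/'efficiency'")
    return table


def load_reference_table(path) -> EfficiencyLookup:
    """A full reference table (tis, efficiency TSV) as a scorer,
    usable wherever a fitted model is."""
    return EfficiencyLookup(read_efficiency_table(path))


def gate_spec_to_json(gates: GateSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"boundaries": [float(b) for b in gates.boundaries],
             "labels": gates.labels},
            fh, indent=1,
        )


def gate_spec_from_json(path) -> GateSpec:
    with open(path) as fh:
        payload = json.load(fh)
    return GateSpec(boundaries=np.array(payload["boundaries"], dtype=float))


def save_model(model: PWMModel, path) -> None:
    """Serialize a PWM model to schema-versioned JSON (ln-scale
    coefficients, field-coordinate position labels)."""
    pos = VARIABLE_POSITIONS
    payload = {
        "schema_version": SCHEMA_VERSION,
        "order": model.order,
        "intercept": model.intercept,
        "mono": {
            f"{pos[i]:+d}": {b: model.mono[i, k] for k, b in enumerate(BASES)}
            for i in range(len(pos))
        },
        "pair": {
            f"{pos[i]:+d},{pos[j]:+d}": {
                f"{b1}{b2}": table[k1, k2]
                for k1, b1 in enumerate(BASES)
                for k2, b2 in enumerate(BASES)
            }
            for (i, j), table in model.pair.items()
        },
        "triple": {
            f"{pos[i]:+d},{pos[j]:+d},{pos[m]:+d}": {
                f"{b1}{b2}{b3}": table[k1, k2, k3]
                for k1, b1 in enumerate(BASES)
                for k2, b2 in enumerate(BASES)
                for k3, b3 in enumerate(BASES)
            }
            for (i, j, m), table in model.triple.items()
        },
        "mono_se": (
            None if model.mono_se is None
            else [list(map(float, row)) for row in model.mono_se]
        ),
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PWMModel:
    """Load a model saved by :func:`save_model`; predictions round-trip
    bit-for-bit.  A schema mismatch raises :class:`ModelVersionError`."""
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelVersionError(
            f"model schema version {version!r} != supported {SCHEMA_VERSION}; "
            "re-fit or migrate the model file"
        )
    pos_index = {f"{p:+d}": i for i, p in enumerate(VARIABLE_POSITIONS)}
    mono = np.zeros((len(VARIABLE_POSITIONS), len(BASES)))
    for pos_label, by_base in payload["mono"].items():
        for k, b in enumerate(BASES):
            mono[pos_index[pos_label], k] = by_base[b]
    pair = {}
    for key, by_bases in payload["pair"].items():
        p1, p2 = key.split(",")
        table = np.zeros((len(BASES), len(BASES)))
        for k1, b1 in enumerate(BASES):
            for k2, b2 in enumerate(BASES):
                table[k1, k2] = by_bases[b1 + b2]
        pair[(pos_index[p1], pos_index[p2])] = table
    triple = {}
    for key, by_bases in payload["triple"].items():
        p1, p2, p3 = key.split(",")
        table = np.zeros((len(BASES),) * 3)
        for k1, b1 in enumerate(BASES):
            for k2, b2 in enumerate(BASES):
                for k3, b3 in enumerate(BASES):
                    table[k1, k2, k3] = by_bases[b1 + b2 + b3]
        triple[(pos_index[p1], pos_index[p2], pos_index[p3])] = table
    mono_se = payload.get("mono_se")
    return PWMModel(
        order=int(payload["order"]),
        intercept=float(payload["intercept"]),
        mono=mono,
        pair=pair,
        triple=triple,
        mono_se=None if mono_se is None else np.array(mono_se, dtype=float),
        metadata=payload.get("metadata", {}),
    )


def load_scorer(path):
    """A model JSON or a reference-table TSV, whichever ``path`` is."""
    text = str(path)
    if text.endswith(".json"):
        return load_model(path)
    return load_reference_table(path)


def read_annotations(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"id", "cds_start", "cds_end"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path} lacks columns {sorted(required)}")
    return table


def read_footprints(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"id", "reads_at_annotated_tis", "alt_isoform"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path} lacks columns {sorted(required)}")
    return table


def read_variants(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"position": str})
    required = {"gene", "wt_context", "position", "ref", "alt", "direction"}
    if not required.issubset(table.columns):
        raise ValueError(f"{path} lacks columns {sorted(required)}")
    table["position"] = table["position"].astype(int)
    return table


def read_tis_list(path) -> list[str]:
    """Single-column TSV of contexts with header ``tis``."""
    table = pd.read_csv(path, sep="\t")
    if "tis" not in table.columns:
        raise ValueError(f"{path} lacks a 'tis' column")
    return [validate_tis(t) for t in table["tis"]]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters, round-trippable through YAML."""

    seed: int = 0
    n_gates: int = 20
    cells_per_tis: int = 300
    reads_per_gate: int = 50_000
    noise_sigma: float = 0.25
    pair_fraction: float = 0.5
    effect_scale: float = 0.10
    pwm_order: int = 2
    low_read_threshold: float = 20.0
    reference_tis: str = REFERENCE_TIS
    leaky_k: float = 0.86
    min_footprint_reads: int = 50
    min_separation: int = 20
    paths: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        if min(self.n_gates, self.cells_per_tis, self.reads_per_gate) <= 0:
            raise ValueError("gate count, cells and reads must be positive")
        if self.low_read_threshold < 0 or self.noise_sigma < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.leaky_k <= 1:
            raise ValueError("leaky_k must be in (0, 1]")
        validate_tis(self.reference_tis)
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload).validate()


def write_coefficient_report(model: PWMModel, path) -> None:
    report, intercept = pwm_mod.coefficient_report(model)
    with open(path, "w") as fh:
        fh.write(f"# exp-scale intercept: {intercept:.6g}\n")
        report.to_csv(fh, sep="\t", index_label="base", float_format="%.4f")
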