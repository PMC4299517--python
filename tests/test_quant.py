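"""Quantification: demultiplexing, depth normalization, histogram medians,
and reference scaling."""

import numpy as np
import pandas as pd
import pytest

from tisfacs import quant, sim, tis_space
from tisfacs.sim import GateSpec


class TestExtractReadCounts:
    def test_roundtrip_through_fastq(self, tiny_matrix, tmp_path):
        # pad to 20 gate columns so the default barcode map applies
        full = tiny_matrix.reindex(
            columns=[f"gate_{g + 1:02d}" for g in range(20)], fill_value=0
        )
        path = tmp_path / "reads.fastq"
        n = sim.write_reads_fastq(full, path)
        assert n == int(full.to_numpy().sum())
        extracted, tally = quant.extract_read_counts(str(path))
        assert tally.total() == 0
        sub = extracted.loc[tiny_matrix.index, tiny_matrix.columns]
        assert (sub.to_numpy() == tiny_matrix.to_numpy()).all()
        # nothing extracted outside the fixture contexts
        assert extracted.to_numpy().sum() == tiny_matrix.to_numpy().sum()

    def test_reject_reasons(self, tmp_path):
        bc = sim.GATE_BARCODES[2]
        up, down = sim.UPSTREAM_ANCHOR, sim.DOWNSTREAM_ANCHOR
        reads = {
            "ok": bc + up + "GCCACCATGGG" + down,
            "no_start": bc + up + "GCCACCTTGGG" + down,
            "bad_anchor": bc + "A" * len(up) + "GCCACCATGGG" + down,
            "unknown_bc": "NNNNNN" + up + "GCCACCATGGG" + down,
            "invalid": bc + up + "GCCNCCATGGG" + down,
            "short": bc + up,
        }
        path = tmp_path / "reads.fastq"
        with open(path, "w") as fh:
            for name, seq in reads.items():
                fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
        matrix, tally = quant.extract_read_counts(str(path))
        assert matrix.loc["GCCACCAUGGG", "gate_03"] == 1
        assert matrix.to_numpy().sum() == 1
        assert tally.no_start_codon == 1
        assert tally.bad_anchor == 1
        assert tally.unknown_barcode == 1
        assert tally.invalid_base == 1
        assert tally.truncated_read == 1

    def test_non_injective_barcode_map_rejected(self, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.raises(ValueError, match="injective"):
            quant.extract_read_counts(
                str(path), barcode_to_gate={"AAAAAA": "g1", "CCCCCC": "g1"}
            )


class TestDepthNormalization:
    def test_equal_columns_unchanged(self, tiny_matrix):
        m = tiny_matrix.copy()
        m[:] = 3
        out = quant.normalize_barcode_depth(m)
        assert np.allclose(out.to_numpy(), 3.0)

    def test_column_sums_equalized(self, tiny_matrix):
        out = quant.normalize_barcode_depth(tiny_matrix)
        sums = out.sum(axis=0).to_numpy()
        assert np.allclose(sums, sums[0], rtol=1e-9)

    def test_scale_invariance(self, tiny_matrix):
        doubled = tiny_matrix.copy()
        doubled["gate_02"] *= 2
        a = quant.normalize_barcode_depth(tiny_matrix).to_numpy()
        b = quant.normalize_barcode_depth(doubled).to_numpy()
        # row proportions per column are unchanged by per-column scaling
        assert np.allclose(a / a.sum(0), b / b.sum(0))

    def test_zero_gate_named(self, tiny_matrix):
        m = tiny_matrix.copy()
        m["gate_04"] = 0
        with pytest.raises(quant.ZeroGateError, match="gate_04"):
            quant.normalize_barcode_depth(m)


class TestMedianEstimation:
    GATES4 = GateSpec(boundaries=np.array([1.0, 2.0, 3.0]))

    def test_uniform_weights_cross_at_two(self):
        assert quant.estimate_median_efficiency(
            [1, 1, 1, 1], self.GATES4
        ) == pytest.approx(2.0, rel=1e-12)

    def test_single_interior_gate_geometric_mean(self):
        med = quant.estimate_median_efficiency([0, 5, 0, 0], self.GATES4)
        assert med == pytest.approx(np.sqrt(1.0 * 2.0), rel=1e-12)

    def test_half_half_split_hits_boundary(self):
        med = quant.estimate_median_efficiency([0, 3, 3, 0], self.GATES4)
        assert med == pytest.approx(2.0, rel=1e-12)

    def test_all_zero_row_is_nan(self):
        assert np.isnan(
            quant.estimate_median_efficiency([0, 0, 0, 0], self.GATES4)
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            quant.estimate_median_efficiency([1, 1], self.GATES4)

    def test_monotone_in_stochastic_order(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = rng.random(4)
            # move every gate's mass one gate upward (top gate keeps its own):
            # the shifted weights are stochastically above the originals
            shifted = np.array([0.0, w[0], w[1], w[2] + w[3]])
            lo = quant.estimate_median_efficiency(w, self.GATES4)
            hi = quant.estimate_median_efficiency(shifted, self.GATES4)
            assert hi >= lo - 1e-12


class TestReferenceNormalization:
    def _medians(self, values):
        return pd.Series(values)

    def test_reference_is_exactly_100(self):
        med = pd.Series({"GCCACCAUGGG": 37.0, "AAAAAAAUGAA": 74.0})
        table = quant.normalize_to_reference(med)
        by_tis = table.set_index("tis")["efficiency"]
        assert by_tis["GCCACCAUGGG"] == 100.0
        assert by_tis["AAAAAAAUGAA"] == pytest.approx(200.0)

    def test_identical_medians_all_100(self):
        med = pd.Series({"GCCACCAUGGG": 5.0, "UUUUUUAUGUU": 5.0})
        table = quant.normalize_to_reference(med)
        assert (table["efficiency"] == 100.0).all()

    def test_idempotent(self):
        med = pd.Series({"GCCACCAUGGG": 37.0, "AAAAAAAUGAA": 11.0})
        once = quant.normalize_to_reference(med)
        twice = quant.normalize_to_reference(
            once.set_index("tis")["efficiency"]
        )
        assert np.allclose(
            once["efficiency"].to_numpy(), twice["efficiency"].to_numpy()
        )

    def test_missing_reference_suggests_alternative(self):
        med = pd.Series({"AAAAAAAUGAA": 1.0})
        with pytest.raises(quant.ReferenceMissingError, match="alternative"):
            quant.normalize_to_reference(med)

    def test_undefined_reference_median(self):
        med = pd.Series({"GCCACCAUGGG": np.nan, "AAAAAAAUGAA": 1.0})
        with pytest.raises(quant.ReferenceMissingError):
            quant.normalize_to_reference(med)

    def test_missing_rows_flagged_not_zero_filled(self):
        med = pd.Series({"GCCACCAUGGG": 10.0, "AAAAAAAUGAA": np.nan})
        reads = pd.Series({"GCCACCAUGGG": 100.0, "AAAAAAAUGAA": 0.0})
        table = quant.normalize_to_reference(med, reads).set_index("tis")
        assert table.loc["AAAAAAAUGAA", "flag"] == "missing"
        assert np.isnan(table.loc["AAAAAAAUGAA", "efficiency"])


class TestEndToEndResolution:
    def test_noiseless_recovery_within_gate_resolution(self, truth_mono):
        """With zero expression noise and exact per-gate weights, every
        reconstructed median lies within half the ln-width of the gate that
        holds the context's true ratio (interior gates)."""
        pop = sim.simulate_cell_population(
            truth_mono, cells_per_tis=10, noise_sigma=0.0
        )
        gates, gate_index = sim.assign_gates(pop)
        flat = gate_index.astype(np.int64) * tis_space.SPACE_SIZE + pop.tis_index
        cells = np.bincount(
            flat, minlength=20 * tis_space.SPACE_SIZE
        ).reshape(20, tis_space.SPACE_SIZE).T
        matrix = pd.DataFrame(
            cells, index=pd.Index(tis_space.space_sequences(), name="tis"),
            columns=gates.labels,
        )
        table = quant.quantify(matrix, gates)
        truth = truth_mono.true_efficiencies()
        est = table["median_ratio"].to_numpy()
        log_edges = np.log(gates.boundaries)
        # classify each estimate by the interior gate it landed in; the true
        # ratio lies in the same gate (or on its boundary when the tied
        # block straddles), so the error is bounded by half that gate's
        # ln-width
        gate_of_est = np.searchsorted(gates.boundaries, est)
        interior = (gate_of_est >= 1) & (gate_of_est <= 18) \
            & (table["flag"].to_numpy() != "off_scale")
        widths = np.diff(log_edges)[gate_of_est[interior] - 1]
        err = np.abs(np.log(est[interior]) - np.log(truth[interior]))
        assert (err <= widths / 2 + 1e-9).all()

    def test_pipeline_reference_flagged_rows(self, small_pipeline):
        _, _, _, table = small_pipeline
        assert set(table["flag"]).issubset(
            {"ok", "low_reads", "missing", "off_scale"}
        )
        ref = table.set_index("tis").loc["GCCACCAUGGG"]
        assert ref["efficiency"] == 100.0
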