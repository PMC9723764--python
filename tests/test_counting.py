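"""Read matching rule, streaming FASTQ counting, and experiment assembly."""

import gzip

import numpy as np
import pandas as pd
import pytest

from glycanseq import (
    CountingError,
    MatchTolerance,
    count_experiment,
    count_sample,
    generate_panel,
    match_read,
    pups_adult_design,
    simulate_reads,
)
from glycanseq.counting import match_reads

from conftest import brute_force_match, mutate_positions, random_reads


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestMatchRead:
    def test_exact_read_assigned_with_zero_mismatches(self, tiny_panel):
        read = "TTT" + tiny_panel.barcodes[0].barcode_seq
        m = match_read(read, tiny_panel)
        assert (m.status, m.lectin_name) == ("assigned", "LecA")
        assert (m.flank_mismatches, m.middle_mismatches) == (0, 0)

    def test_two_flank_one_middle_mismatches_still_assigned(self, tiny_panel):
        rng = np.random.default_rng(0)
        barcode = mutate_positions(tiny_panel.barcodes[1].barcode_seq, [0, 9, 5], rng)
        m = match_read("GGG" + barcode, tiny_panel)
        assert (m.status, m.lectin_name) == ("assigned", "LecB")
        assert (m.flank_mismatches, m.middle_mismatches) == (2, 1)

    def test_two_middle_mismatches_unassigned(self, tiny_panel):
        rng = np.random.default_rng(1)
        barcode = mutate_positions(tiny_panel.barcodes[0].barcode_seq, [4, 7], rng)
        assert match_read("AAA" + barcode, tiny_panel).status == "unassigned"

    def test_three_flank_mismatches_unassigned(self, tiny_panel):
        rng = np.random.default_rng(2)
        barcode = mutate_positions(tiny_panel.barcodes[2].barcode_seq, [0, 1, 11], rng)
        assert match_read("AAA" + barcode, tiny_panel).status == "unassigned"

    def test_equidistant_candidates_are_ambiguous(self):
        from glycanseq import LectinBarcode, LectinPanel

        from conftest import TINY_LAYOUT

        panel = LectinPanel(
            layout=TINY_LAYOUT,
            barcodes=(
                LectinBarcode("A", "AAAAAAAAAAAA"),
                LectinBarcode("B", "AAAACCAAAAAA"),  # two middle diffs
            ),
        )
        # read with one middle mismatch toward each: equally far from both
        read = "TTT" + "AAAACAAAAAAA"
        assert match_read(read, panel).status == "ambiguous"

    def test_nearer_candidate_wins_on_unequal_totals(self):
        from glycanseq import LectinBarcode, LectinPanel

        from conftest import TINY_LAYOUT

        panel = LectinPanel(
            layout=TINY_LAYOUT,
            barcodes=(
                LectinBarcode("A", "AAAAAAAAAAAA"),
                LectinBarcode("B", "CCAAACAAAAAA"),
            ),
        )
        # read is (1 flank, 0 middle) from A but (1 flank, 1 middle) from B:
        # both are candidates, A has the smaller total and wins
        read = "TTT" + "CAAAAAAAAAAA"
        m = match_read(read, panel)
        assert (m.status, m.lectin_name) == ("assigned", "A")

    def test_short_read_flagged(self, tiny_panel):
        assert match_read("TTTAAAA", tiny_panel).status == "too_short"

    def test_n_bases_count_as_mismatches(self, tiny_panel):
        barcode = tiny_panel.barcodes[0].barcode_seq
        read = "TTT" + "NN" + barcode[2:]  # 2 flank Ns
        assert match_read(read, tiny_panel).status == "assigned"
        read = "TTT" + barcode[:4] + "NN" + barcode[6:]  # 2 middle Ns
        assert match_read(read, tiny_panel).status == "unassigned"

    def test_agrees_with_brute_force_on_random_reads(self, panel39, default_tol):
        rng = np.random.default_rng(42)
        L = panel39.layout.barcode_length + panel39.prefix_trim
        # random reads plus mutated true barcodes so all statuses occur
        reads = random_reads(rng, 500, L)
        for _ in range(500):
            bc = panel39.barcodes[rng.integers(panel39.size)].barcode_seq
            k = rng.integers(0, 5)
            positions = rng.choice(panel39.layout.barcode_length, size=k, replace=False)
            reads.append("ACG" + mutate_positions(bc, positions, rng))
        status, idx, fm, mm = match_reads(reads, panel39, default_tol)
        for r, read in enumerate(reads):
            expected = brute_force_match(read, panel39, default_tol)
            assert status[r] == expected[0], read
            if expected[0] == "assigned":
                assert panel39.names[idx[r]] == expected[1]
                assert (fm[r], mm[r]) == expected[2:]


class TestCountSample:
    def test_counts_empty_file_with_warning(self, tiny_panel, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty FASTQ"):
            counts, tallies = count_sample(path, tiny_panel)
        assert counts.sum() == 0 and tallies["n_reads_total"] == 0

    def test_gzip_input_supported(self, tiny_panel, tmp_path):
        path = tmp_path / "reads.fastq.gz"
        read = "TTT" + tiny_panel.barcodes[0].barcode_seq
        with gzip.open(path, "wt") as fh:
            fh.write(f"@r0\n{read}\n+\n{'I' * len(read)}\n")
        counts, tallies = count_sample(path, tiny_panel)
        assert counts["LecA"] == 1 and tallies["n_assigned"] == 1

    def test_malformed_record_names_index(self, tiny_panel, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n-\nIIII\n")
        with pytest.raises(CountingError, match="record 1"):
            count_sample(path, tiny_panel)

    def test_status_tallies_conserve_read_total(self, tiny_panel, tmp_path):
        rng = np.random.default_rng(7)
        reads = random_reads(rng, 200, 15) + ["TTTAA"] + [
            "TTT" + b.barcode_seq for b in tiny_panel.barcodes
        ]
        path = tmp_path / "mix.fastq"
        write_fastq(path, reads)
        counts, t = count_sample(path, tiny_panel)
        assert (
            t["n_assigned"] + t["n_ambiguous"] + t["n_unassigned"] + t["n_too_short"]
            == t["n_reads_total"] == len(reads)
        )
        assert counts.sum() == t["n_assigned"]

    def test_budget_enlargement_never_loses_reads(self, panel39, tmp_path):
        rng = np.random.default_rng(8)
        L = panel39.layout.barcode_length + panel39.prefix_trim
        reads = random_reads(rng, 300, L)
        for _ in range(300):
            bc = panel39.barcodes[rng.integers(panel39.size)].barcode_seq
            positions = rng.choice(panel39.layout.barcode_length, size=rng.integers(0, 6),
                                   replace=False)
            reads.append("TGA" + mutate_positions(bc, positions, rng))
        path = tmp_path / "reads.fastq"
        write_fastq(path, reads)
        previous = -1
        for fmax, mmax in [(0, 0), (1, 0), (2, 1), (3, 2), (5, 4)]:
            _, t = count_sample(path, panel39, MatchTolerance(fmax, mmax))
            reached = t["n_assigned"] + t["n_ambiguous"]
            assert reached >= previous
            previous = reached


@pytest.fixture(scope="module")
def noiseless_run(panel39, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim0")
    design = pups_adult_design(panel39)
    sheet, truth = simulate_reads(
        panel39, design, out, depth=4000, error_rate=0.0,
        contaminant_fraction=0.0, seed=17,
    )
    return out, sheet, truth


class TestCountExperiment:
    def test_zero_noise_counts_equal_truth(self, noiseless_run, panel39):
        out, sheet, truth = noiseless_run
        cm = count_experiment(out / "samples.tsv", panel39)
        pd.testing.assert_frame_equal(
            cm.counts.astype(np.int64), truth.true_counts.astype(np.int64),
            check_names=False,
        )
        assert (cm.tallies["n_unassigned"] == 0).all()

    def test_row_sums_equal_assigned(self, noiseless_run, panel39):
        out, _sheet, _truth = noiseless_run
        cm = count_experiment(out / "samples.tsv", panel39)
        assert (cm.counts.sum(axis=1) == cm.tallies["n_assigned"]).all()

    def test_sheet_order_determines_row_order(self, noiseless_run, panel39):
        out, sheet, _truth = noiseless_run
        sheet = sheet.copy()
        sheet["fastq_path"] = [str(out / p) for p in sheet["fastq_path"]]
        reversed_sheet = sheet.iloc[::-1].reset_index(drop=True)
        a = count_experiment(sheet, panel39)
        b = count_experiment(reversed_sheet, panel39)
        assert list(b.counts.index) == list(reversed(a.counts.index))
        pd.testing.assert_frame_equal(a.counts, b.counts.iloc[::-1])

    def test_duplicate_sample_id_rejected(self, noiseless_run, panel39):
        out, sheet, _ = noiseless_run
        sheet = sheet.copy()
        sheet["fastq_path"] = [str(out / p) for p in sheet["fastq_path"]]
        dup = pd.concat([sheet, sheet.iloc[[0]]], ignore_index=True)
        with pytest.raises(CountingError, match="duplicate sample_id"):
            count_experiment(dup, panel39)

    def test_missing_fastq_fails_before_counting(self, noiseless_run, panel39):
        out, sheet, _ = noiseless_run
        sheet = sheet.copy()
        sheet.loc[0, "fastq_path"] = str(out / "nope.fastq")
        with pytest.raises(CountingError, match="not found"):
            count_experiment(sheet, panel39)

    def test_random_reads_mostly_unassigned_on_separable_panel(self, panel39, tmp_path):
        # tolerance volume is tiny relative to 4^22 sequences
        rng = np.random.default_rng(3)
        path = tmp_path / "rand.fastq"
        write_fastq(path, random_reads(rng, 100, 25))
        _, t = count_sample(path, panel39)
        assert t["n_unassigned"] >= 99
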