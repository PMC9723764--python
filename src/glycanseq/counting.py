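"""Barcode extraction and counting with region-specific mismatch tolerance.

Each read is processed by removing its first ``prefix_trim`` bases (3 by
default) and comparing the next ``barcode_length`` bases against every panel
barcode, counting mismatches separately over the flanking spans and the
middle span. A barcode is a candidate when it is within both budgets
(default: at most 2 flank mismatches and 1 middle mismatch). A read with a
single candidate is assigned; with several candidates it is assigned to the
unique one with minimal total mismatches, or tallied ``ambiguous`` on a tie;
with none it is ``unassigned``; reads shorter than prefix + barcode are
``too_short``. ``N`` bases always count as mismatches.

Matching is vectorized over chunks of reads so whole MiSeq-scale FASTQ files
stream through in seconds with memory independent of file size.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import LectinPanel

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"
TOO_SHORT = "too_short"

STATUS_TALLIES = ["n_reads_total", "n_assigned", "n_ambiguous", "n_unassigned", "n_too_short"]

_SENTINEL = np.iinfo(np.int32).max  # mismatch total for non-candidates


class CountingError(ValueError):
    """Raised on malformed FASTQ input or an invalid sample sheet."""


@dataclass(frozen=True)
class MatchTolerance:
    """Mismatch budgets of the read-to-barcode matching rule.

    ``max_flank_mismatches`` is a total over all flank spans, not a per-flank
    budget; ``prefix_trim`` bases are dropped from the read start before
    matching.
    """

    max_flank_mismatches: int = 2
    max_middle_mismatches: int = 1
    prefix_trim: int = 3

    def __post_init__(self) -> None:
        if min(self.max_flank_mismatches, self.max_middle_mismatches, self.prefix_trim) < 0:
            raise CountingError("tolerance fields must all be >= 0")

    @classmethod
    def for_panel(cls, panel: LectinPanel, max_flank_mismatches: int = 2,
                  max_middle_mismatches: int = 1) -> "MatchTolerance":
        """Default budgets with the panel's declared prefix length."""
        return cls(max_flank_mismatches, max_middle_mismatches, panel.prefix_trim)


@dataclass(frozen=True)
class BarcodeMatch:
    """Outcome of matching one read against the panel."""

    status: str
    lectin_name: str | None = None
    flank_mismatches: int | None = None
    middle_mismatches: int | None = None


@dataclass
class CountMatrix:
    """Per-sample lectin counts plus read-status tallies.

    ``counts`` is samples x lectins (non-negative integers); ``tallies`` has
    one row per sample with the ``STATUS_TALLIES`` columns. Per sample the
    four status tallies sum to ``n_reads_total`` and the lectin row sum
    equals ``n_assigned``.
    """

    counts: pd.DataFrame
    tallies: pd.DataFrame

    def __post_init__(self) -> None:
        status_sum = self.tallies[STATUS_TALLIES[1:]].sum(axis=1)
        if not (status_sum == self.tallies["n_reads_total"]).all():
            raise CountingError("status tallies do not sum to n_reads_total")
        if not (self.counts.sum(axis=1) == self.tallies["n_assigned"]).all():
            raise CountingError("lectin counts do not sum to n_assigned")

    def write(self, counts_path: str | Path, qc_path: str | Path | None = None) -> None:
        df = self.counts.copy()
        df.insert(0, "sample_id", df.index)
        df.to_csv(counts_path, sep="\t", index=False)
        if qc_path is not None:
            Path(qc_path).write_text(
                json.dumps(
                    {s: {k: int(v) for k, v in row.items()}
                     for s, row in self.tallies.iterrows()},
                    indent=2, sort_keys=True,
                )
                + "\n"
            )


def match_reads(
    seqs: Sequence[str], panel: LectinPanel, tol: MatchTolerance
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized matching of many reads.

    Returns ``(status, lectin_index, flank_mm, middle_mm)`` arrays; the
    lectin index is -1 and the mismatch counts are -1 wherever the read is
    not assigned.
    """
    n = len(seqs)
    status = np.empty(n, dtype=object)
    lectin_idx = np.full(n, -1, dtype=np.int64)
    flank_mm = np.full(n, -1, dtype=np.int64)
    middle_mm = np.full(n, -1, dtype=np.int64)

    L = panel.layout.barcode_length
    start = tol.prefix_trim
    ok_rows = [i for i, s in enumerate(seqs) if len(s) - start >= L]
    status[:] = TOO_SHORT
    if not ok_rows:
        return status, lectin_idx, flank_mm, middle_mm

    trimmed = "".join(seqs[i][start:start + L] for i in ok_rows).encode("ascii")
    reads = np.frombuffer(trimmed, dtype=np.uint8).reshape(len(ok_rows), L)
    neq = reads[:, None, :] != panel.seq_matrix()[None, :, :]
    fm = neq[:, :, panel.layout.flank_indices].sum(axis=2)
    mm = neq[:, :, panel.layout.middle_indices].sum(axis=2)
    is_cand = (fm <= tol.max_flank_mismatches) & (mm <= tol.max_middle_mismatches)
    total = np.where(is_cand, fm + mm, _SENTINEL)

    n_cand = is_cand.sum(axis=1)
    best = total.min(axis=1)
    n_best = (total == best[:, None]).sum(axis=1)
    best_idx = total.argmin(axis=1)

    ok_rows = np.asarray(ok_rows)
    none_mask = n_cand == 0
    amb_mask = (n_cand > 0) & (n_best > 1)
    asg_mask = (n_cand > 0) & (n_best == 1)
    status[ok_rows[none_mask]] = UNASSIGNED
    status[ok_rows[amb_mask]] = AMBIGUOUS
    rows = ok_rows[asg_mask]
    status[rows] = ASSIGNED
    lectin_idx[rows] = best_idx[asg_mask]
    flank_mm[rows] = fm[asg_mask, best_idx[asg_mask]]
    middle_mm[rows] = mm[asg_mask, best_idx[asg_mask]]
    return status, lectin_idx, flank_mm, middle_mm


def match_read(read_seq: str, panel: LectinPanel, tol: MatchTolerance | None = None) -> BarcodeMatch:
    """Match a single read; see module docstring for the rule."""
    if tol is None:
        tol = MatchTolerance.for_panel(panel)
    status, idx, fm, mm = match_reads([read_seq], panel, tol)
    if status[0] == ASSIGNED:
        return BarcodeMatch(ASSIGNED, panel.names[idx[0]], int(fm[0]), int(mm[0]))
    return BarcodeMatch(str(status[0]))


def _open_fastq(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open("r")


def _fastq_chunks(path: str | Path, chunk_size: int) -> Iterator[list[str]]:
    with _open_fastq(path) as fh:
        it = FastqGeneralIterator(fh)
        record_index = 0
        while True:
            chunk: list[str] = []
            try:
                for _title, seq, _qual in it:
                    record_index += 1
                    chunk.append(seq.upper())
                    if len(chunk) >= chunk_size:
                        break
            except ValueError as exc:
                raise CountingError(
                    f"{path}: malformed FASTQ record at record {record_index + 1}: {exc}"
                ) from exc
            if not chunk:
                return
            yield chunk


def count_sample(
    fastq_path: str | Path,
    panel: LectinPanel,
    tol: MatchTolerance | None = None,
    chunk_size: int = 20_000,
) -> tuple[pd.Series, dict[str, int]]:
    """Count lectin barcodes in one FASTQ file (plain or gzip), streaming.

    Returns a lectin-count Series (index = panel order) and the status-tally
    dict. An empty file yields zeros with a warning.
    """
    if tol is None:
        tol = MatchTolerance.for_panel(panel)
    counts = np.zeros(panel.size, dtype=np.int64)
    tallies = dict.fromkeys(STATUS_TALLIES, 0)
    for chunk in _fastq_chunks(fastq_path, chunk_size):
        status, idx, _fm, _mm = match_reads(chunk, panel, tol)
        tallies["n_reads_total"] += len(chunk)
        tallies["n_assigned"] += int((status == ASSIGNED).sum())
        tallies["n_ambiguous"] += int((status == AMBIGUOUS).sum())
        tallies["n_unassigned"] += int((status == UNASSIGNED).sum())
        tallies["n_too_short"] += int((status == TOO_SHORT).sum())
        assigned = idx[idx >= 0]
        if assigned.size:
            counts += np.bincount(assigned, minlength=panel.size)
    if tallies["n_reads_total"] == 0:
        warnings.warn(f"{fastq_path}: empty FASTQ, emitting all-zero counts")
    return pd.Series(counts, index=panel.names), tallies


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns sample_id, group, fastq_path."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "fastq_path"}
    missing = required - set(sheet.columns)
    if missing:
        raise CountingError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def count_experiment(
    sample_sheet: pd.DataFrame | str | Path,
    panel: LectinPanel,
    tol: MatchTolerance | None = None,
) -> CountMatrix:
    """Count every sample in sheet order into one CountMatrix.

    All FASTQ paths are checked before any counting starts; duplicate sample
    ids are rejected.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sheet_dir = Path(sample_sheet).parent
        sample_sheet = read_sample_sheet(sample_sheet)
    else:
        sheet_dir = Path(".")
    dup = sample_sheet["sample_id"][sample_sheet["sample_id"].duplicated()]
    if len(dup):
        raise CountingError(f"duplicate sample_id in sheet: {sorted(set(dup))}")

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() or path.exists() else sheet_dir / p

    paths = {row.sample_id: resolve(row.fastq_path) for row in sample_sheet.itertuples()}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise CountingError(f"FASTQ files not found: {missing}")

    rows, tally_rows = {}, {}
    for sample_id, path in paths.items():
        rows[sample_id], tally_rows[sample_id] = count_sample(path, panel, tol)
    counts = pd.DataFrame(rows).T.reindex(sample_sheet["sample_id"])
    counts.index.name = "sample_id"
    tallies = pd.DataFrame(tally_rows).T.reindex(sample_sheet["sample_id"])
    tallies.index.name = "sample_id"
    return CountMatrix(counts=counts, tallies=tallies)
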