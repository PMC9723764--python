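"""DNA-barcoded lectin panel: model, on-disk format, and separability checks.

A Glycan-seq panel conjugates each lectin to a unique DNA barcode via a
photocleavable linker; sequencing the released barcodes reports how much of
each lectin bound. During read matching the barcode is split into *flanking*
and *middle* regions with different mismatch allowances (by default up to two
mismatches summed over the flanks and one in the middle). This module models
the panel — barcode sequences, the region layout, and the number of
uninformative prefix bases trimmed from each read — reads and writes its
tab-separated representation, and verifies that the panel's barcodes are far
enough apart that no read can fall within tolerance of two lectins at once.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

Span = tuple[int, int]

_VALID_BASES = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a panel file or panel definition violates an invariant."""


def _check_spans(spans: Sequence[Span], barcode_length: int) -> None:
    covered = np.zeros(barcode_length, dtype=bool)
    for start, end in spans:
        if not (0 <= start < end <= barcode_length):
            raise PanelError(
                f"interval [{start}, {end}) is empty or outside "
                f"[0, {barcode_length})"
            )
        if covered[start:end].any():
            raise PanelError(f"interval [{start}, {end}) overlaps another region")
        covered[start:end] = True
    if not covered.all():
        missing = np.flatnonzero(~covered)
        raise PanelError(
            f"regions do not cover the barcode: positions {missing.tolist()} "
            "belong to no region"
        )


@dataclass(frozen=True)
class RegionLayout:
    """Partition of barcode positions into flanking spans and one middle span.

    Intervals are 0-based half-open, must be disjoint and non-empty, and must
    together cover exactly ``[0, barcode_length)``.
    """

    barcode_length: int
    flank_spans: tuple[Span, ...]
    middle_span: Span

    def __post_init__(self) -> None:
        if self.barcode_length < 1:
            raise PanelError("barcode_length must be positive")
        if not self.flank_spans:
            raise PanelError("at least one flank span is required")
        object.__setattr__(
            self, "flank_spans", tuple(tuple(s) for s in self.flank_spans)
        )
        object.__setattr__(self, "middle_span", tuple(self.middle_span))
        _check_spans(list(self.flank_spans) + [self.middle_span], self.barcode_length)

    @property
    def flank_indices(self) -> np.ndarray:
        """Sorted array of all positions belonging to a flank span."""
        idx = np.concatenate(
            [np.arange(start, end) for start, end in self.flank_spans]
        )
        return np.sort(idx)

    @property
    def middle_indices(self) -> np.ndarray:
        start, end = self.middle_span
        return np.arange(start, end)


#: 22-base barcode inside a 26 bp read with a 3-base trimmed prefix: flanks
#: [0,7) and [15,22), middle [7,15). The true coordinates of the assay's
#: barcodes are not public; this layout is the package's configurable default.
DEFAULT_LAYOUT = RegionLayout(
    barcode_length=22, flank_spans=((0, 7), (15, 22)), middle_span=(7, 15)
)


@dataclass(frozen=True)
class LectinBarcode:
    """One lectin's name, barcode sequence and free-text glycan specificity."""

    lectin_name: str
    barcode_seq: str
    specificity: str = ""

    def __post_init__(self) -> None:
        bad = set(self.barcode_seq) - _VALID_BASES
        if bad:
            raise PanelError(
                f"barcode for {self.lectin_name!r} contains invalid "
                f"characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class LectinPanel:
    """An ordered collection of lectin barcodes sharing one region layout.

    ``prefix_trim`` is the number of uninformative bases at the start of every
    read (3 in the original assay) that are removed before matching.
    """

    layout: RegionLayout
    barcodes: tuple[LectinBarcode, ...]
    prefix_trim: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcodes", tuple(self.barcodes))
        if len(self.barcodes) < 2:
            raise PanelError(
                "panel must contain at least 2 lectins (log-ratio analysis "
                "needs a reference partner)"
            )
        if self.prefix_trim < 0:
            raise PanelError("prefix_trim must be >= 0")
        names = [b.lectin_name for b in self.barcodes]
        dup_names = sorted({n for n in names if names.count(n) > 1})
        if dup_names:
            raise PanelError(f"duplicate lectin names: {dup_names}")
        seqs = [b.barcode_seq for b in self.barcodes]
        dup_seqs = {s for s in seqs if seqs.count(s) > 1}
        if dup_seqs:
            offenders = [
                b.lectin_name for b in self.barcodes if b.barcode_seq in dup_seqs
            ]
            raise PanelError(
                f"duplicate barcode sequences shared by lectins {offenders}"
            )
        wrong = [
            b.lectin_name
            for b in self.barcodes
            if len(b.barcode_seq) != self.layout.barcode_length
        ]
        if wrong:
            raise PanelError(
                f"barcode length != layout barcode_length "
                f"({self.layout.barcode_length}) for: {wrong}"
            )

    @property
    def size(self) -> int:
        return len(self.barcodes)

    @property
    def names(self) -> list[str]:
        return [b.lectin_name for b in self.barcodes]

    def seq_matrix(self) -> np.ndarray:
        """Barcodes as a (size, barcode_length) uint8 array of ASCII codes."""
        joined = "".join(b.barcode_seq for b in self.barcodes).encode("ascii")
        return np.frombuffer(joined, dtype=np.uint8).reshape(
            self.size, self.layout.barcode_length
        )


# ---------------------------------------------------------------------------
# On-disk format
# ---------------------------------------------------------------------------
#
# Tab-separated with one comment header line:
#
#   #layout: barcode_length=22; flanks=0-7,15-22; middle=7-15; prefix_trim=3
#   lectin_name<TAB>barcode_seq<TAB>specificity
#   SSA<TAB>ACGT...<TAB>a2-6Sia
#
# Intervals are 0-based half-open "start-end".

_HEADER_COLUMNS = ["lectin_name", "barcode_seq", "specificity"]


def _format_span(span: Span) -> str:
    return f"{span[0]}-{span[1]}"


def _parse_span(text: str) -> Span:
    m = re.fullmatch(r"(\d+)-(\d+)", text.strip())
    if not m:
        raise PanelError(f"malformed interval {text!r}; expected 'start-end'")
    return int(m.group(1)), int(m.group(2))


def _layout_line(panel: LectinPanel) -> str:
    lay = panel.layout
    flanks = ",".join(_format_span(s) for s in lay.flank_spans)
    return (
        f"#layout: barcode_length={lay.barcode_length}; flanks={flanks}; "
        f"middle={_format_span(lay.middle_span)}; prefix_trim={panel.prefix_trim}"
    )


def _parse_layout_line(line: str) -> tuple[RegionLayout, int]:
    body = line[len("#layout:"):].strip()
    fields: dict[str, str] = {}
    for chunk in body.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise PanelError(f"malformed layout entry {chunk!r}; expected key=value")
        key, value = chunk.split("=", 1)
        fields[key.strip()] = value.strip()
    missing = {"barcode_length", "flanks", "middle"} - fields.keys()
    if missing:
        raise PanelError(f"layout line missing keys: {sorted(missing)}")
    layout = RegionLayout(
        barcode_length=int(fields["barcode_length"]),
        flank_spans=tuple(_parse_span(s) for s in fields["flanks"].split(",")),
        middle_span=_parse_span(fields["middle"]),
    )
    prefix_trim = int(fields.get("prefix_trim", 3))
    return layout, prefix_trim


def load_panel(path: str | Path) -> LectinPanel:
    """Load and validate a panel from its tab-separated file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#layout:"):
        raise PanelError(f"{path}: first line must be a '#layout:' comment")
    layout, prefix_trim = _parse_layout_line(lines[0])
    rows = [ln for ln in lines[1:] if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise PanelError(f"{path}: no barcode records found")
    header = rows[0].split("\t")
    if header[:2] != _HEADER_COLUMNS[:2]:
        raise PanelError(
            f"{path}: expected header columns {_HEADER_COLUMNS}, got {header}"
        )
    barcodes = []
    for ln in rows[1:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise PanelError(f"{path}: malformed record {ln!r}")
        name, seq = parts[0], parts[1]
        spec = parts[2] if len(parts) > 2 else ""
        barcodes.append(LectinBarcode(name, seq, spec))
    return LectinPanel(layout=layout, barcodes=tuple(barcodes), prefix_trim=prefix_trim)


def write_panel(panel: LectinPanel, path: str | Path) -> None:
    """Write a panel in the tab-separated format read by :func:`load_panel`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_layout_line(panel) + "\n")
        fh.write("\t".join(_HEADER_COLUMNS) + "\n")
        for b in panel.barcodes:
            fh.write(f"{b.lectin_name}\t{b.barcode_seq}\t{b.specificity}\n")


def write_panel_fasta(panel: LectinPanel, path: str | Path) -> None:
    """Export barcodes as FASTA (record id = lectin name) for interoperability."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(b.barcode_seq), id=b.lectin_name, description=b.specificity)
        for b in panel.barcodes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Separability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeparabilityReport:
    """Pairs of barcodes a single read could match simultaneously.

    A read within tolerance of two barcodes exists iff, in every region, the
    inter-barcode mismatch count is at most twice that region's allowance
    (place half the differing positions on each side; the alphabet has 4
    letters so such a midpoint sequence always exists).
    """

    collisions: tuple[tuple[str, str, int, int], ...]  # (name_a, name_b, flank_d, middle_d)

    @property
    def ambiguous(self) -> bool:
        return bool(self.collisions)


def region_distances(panel: LectinPanel) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (flank, middle) Hamming distances between panel barcodes."""
    mat = panel.seq_matrix()
    neq = mat[:, None, :] != mat[None, :, :]
    flank_d = neq[:, :, panel.layout.flank_indices].sum(axis=2)
    middle_d = neq[:, :, panel.layout.middle_indices].sum(axis=2)
    return flank_d, middle_d


def validate_separability(panel: LectinPanel, tol=None) -> SeparabilityReport:
    """Report every barcode pair that some read could match under ``tol``.

    Report-only: an ambiguous panel is not an error here, but reads landing
    between a colliding pair will be tallied ``ambiguous`` or misassigned
    during counting, so simulated panels should be collision-free.
    """
    if tol is None:
        from .counting import MatchTolerance

        tol = MatchTolerance.for_panel(panel)
    flank_d, middle_d = region_distances(panel)
    names = panel.names
    collisions = []
    for i, j in itertools.combinations(range(panel.size), 2):
        if (
            flank_d[i, j] <= 2 * tol.max_flank_mismatches
            and middle_d[i, j] <= 2 * tol.max_middle_mismatches
        ):
            collisions.append((names[i], names[j], int(flank_d[i, j]), int(middle_d[i, j])))
    return SeparabilityReport(collisions=tuple(collisions))
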