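import numpy as np
import pytest

from glycanseq import (
    GroupDesign,
    LectinBarcode,
    LectinPanel,
    MatchTolerance,
    RegionLayout,
    generate_panel,
)

TINY_LAYOUT = RegionLayout(barcode_length=12, flank_spans=((0, 4), (8, 12)), middle_span=(4, 8))


@pytest.fixture(scope="session")
def tiny_panel() -> LectinPanel:
    """Three maximally separated 12-mers: collisions impossible at (2,1)."""
    return LectinPanel(
        layout=TINY_LAYOUT,
        barcodes=(
            LectinBarcode("LecA", "AAAAAAAAAAAA", "specA"),
            LectinBarcode("LecB", "CCCCCCCCCCCC", "specB"),
            LectinBarcode("LecC", "GGGGGGGGGGGG", "specC"),
        ),
        prefix_trim=3,
    )


@pytest.fixture(scope="session")
def panel39() -> LectinPanel:
    return generate_panel(39, seed=11)


@pytest.fixture(scope="session")
def default_tol() -> MatchTolerance:
    return MatchTolerance()


def brute_force_match(read_seq, panel, tol):
    """Independent reference matcher: literal per-barcode budget scan.

    Returns (status, lectin_name, flank_mm, middle_mm) with None fields when
    not assigned. Kept deliberately naive (pure-Python loops) so it shares no
    code path with the package implementation.
    """
    seq = read_seq[tol.prefix_trim:]
    L = panel.layout.barcode_length
    if len(seq) < L:
        return ("too_short", None, None, None)
    seq = seq[:L]
    flank_positions = []
    for start, end in panel.layout.flank_spans:
        flank_positions.extend(range(start, end))
    mid_start, mid_end = panel.layout.middle_span
    candidates = []
    for bc in panel.barcodes:
        fm = sum(seq[k] != bc.barcode_seq[k] for k in flank_positions)
        mm = sum(seq[k] != bc.barcode_seq[k] for k in range(mid_start, mid_end))
        if fm <= tol.max_flank_mismatches and mm <= tol.max_middle_mismatches:
            candidates.append((bc.lectin_name, fm, mm))
    if not candidates:
        return ("unassigned", None, None, None)
    best_total = min(fm + mm for _, fm, mm in candidates)
    best = [c for c in candidates if c[1] + c[2] == best_total]
    if len(best) == 1:
        name, fm, mm = best[0]
        return ("assigned", name, fm, mm)
    return ("ambiguous", None, None, None)


def random_reads(rng: np.random.Generator, n: int, length: int) -> list[str]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr = rng.choice(bases, size=(n, length))
    flat = arr.tobytes().decode("ascii")
    return [flat[i * length:(i + 1) * length] for i in range(n)]


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a different random base."""
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


@pytest.fixture()
def null_design(panel39) -> GroupDesign:
    """Identical compositions in both groups (global null)."""
    return GroupDesign(lectin_names=tuple(panel39.names))
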