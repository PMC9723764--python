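"""Synthetic Glycan-seq experiments: panels, compositions, and FASTQ reads.

Real Glycan-seq raw reads for this kind of study are typically not deposited,
so every downstream stage here is exercised against simulations with full
ground truth. The generator emulates the study design: two groups of mouse
gut-microbiota samples ("pups" preweaned vs "adult" weaned, n = 3 each), a
39-lectin barcode panel, ~1e5 reads per sample, and a planted elevation of
the alpha2-6-sialic-acid-binding lectins (SSA, TJAI, SNA) plus rABA in the
pups group. Reads are emitted as single-end FASTQ records of
3 uninformative prefix bases + barcode, with i.i.d. per-base substitution
errors and a fraction of unassignable random-sequence contaminant reads.

Everything is deterministic given the seed; per-read true labels are recorded
so counting can be checked read-for-read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    DEFAULT_LAYOUT,
    LectinBarcode,
    LectinPanel,
    RegionLayout,
    validate_separability,
)

CONTAMINANT = "contaminant"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Lectins the study names in its main text (the alpha2-6Sia binders SSA,
#: TJAI, SNA; the GlcNAc / Gal-beta1-3GalNAc binders rABA, rSRL, rPVL; the
#: mannose binders rGRFT, rBanana); remaining panel slots get generic names.
NAMED_LECTINS = ["SSA", "TJAI", "SNA", "rABA", "rSRL", "rPVL", "rGRFT", "rBanana"]

#: Planted pups-vs-adult effect: the four lectins the two-group comparison is
#: expected to flag, elevated in pups.
DEFAULT_EFFECT_LECTINS = ("SSA", "TJAI", "SNA", "rABA")
DEFAULT_FOLD_CHANGE = 8.0
DEFAULT_DEPTH = 100_000
DEFAULT_ERROR_RATE = 0.005
DEFAULT_CONTAMINANT_FRACTION = 0.05


class SimulationError(ValueError):
    pass


def default_lectin_names(n: int) -> list[str]:
    names = NAMED_LECTINS[:n]
    names += [f"L{i + 1:02d}" for i in range(len(names), n)]
    return names


def generate_panel(
    n_lectins: int = 39,
    layout: RegionLayout = DEFAULT_LAYOUT,
    min_separation: int = 7,
    seed: int = 0,
    names: list[str] | None = None,
    prefix_trim: int = 3,
    max_tries: int = 2000,
) -> LectinPanel:
    """Draw random barcodes with pairwise Hamming distance >= min_separation.

    With the default budgets (2 flank + 1 middle) a collision between two
    barcodes requires region distances of at most 4 + 2 = 6, so separation 7
    guarantees a collision-free panel; this is re-checked exhaustively.
    """
    if n_lectins < 2:
        raise SimulationError("n_lectins must be >= 2")
    if min_separation > layout.barcode_length:
        raise SimulationError(
            f"min_separation {min_separation} exceeds barcode length "
            f"{layout.barcode_length}; use longer barcodes"
        )
    if names is None:
        names = default_lectin_names(n_lectins)
    elif len(names) != n_lectins:
        raise SimulationError("names length must equal n_lectins")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    tries = 0
    while len(chosen) < n_lectins:
        tries += 1
        if tries > max_tries:
            raise SimulationError(
                f"could not place {n_lectins} barcodes at separation "
                f"{min_separation} in {max_tries} tries; use longer barcodes"
            )
        cand = rng.choice(_BASES, size=layout.barcode_length)
        if all((cand != c).sum() >= min_separation for c in chosen):
            chosen.append(cand)
    barcodes = tuple(
        LectinBarcode(name, bytes(code).decode("ascii"))
        for name, code in zip(names, chosen)
    )
    panel = LectinPanel(layout=layout, barcodes=barcodes, prefix_trim=prefix_trim)
    report = validate_separability(panel)
    if report.ambiguous:  # unreachable when min_separation > 2*(flank+middle) budgets
        raise SimulationError(f"generated panel is ambiguous: {report.collisions}")
    return panel


@dataclass(frozen=True)
class GroupDesign:
    """Two-group (or multi-group) design over a lectin panel.

    ``baseline`` holds per-lectin proportions (one shared vector); the
    ``effects`` fold-changes are applied to ``effect_group`` and the vector
    renormalized, mimicking group-specific glycan abundance shifts.
    ``overdispersion`` > 0 draws each sample's composition from a Dirichlet
    centred on its group composition (concentration = composition /
    overdispersion), adding between-replicate variability; 0 disables it.
    """

    lectin_names: tuple[str, ...]
    group_labels: tuple[str, ...] = ("pups", "adult")
    samples_per_group: int = 3
    baseline: tuple[float, ...] | None = None
    effects: tuple[tuple[str, float], ...] = ()
    effect_group: str = "pups"
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.samples_per_group < 1:
            raise SimulationError("samples_per_group must be >= 1")
        if not self.group_labels:
            raise SimulationError("design has no groups")
        if self.effects and self.effect_group not in self.group_labels:
            raise SimulationError(f"unknown effect_group {self.effect_group!r}")
        unknown = [l for l, _ in self.effects if l not in self.lectin_names]
        if unknown:
            raise SimulationError(f"effect lectins not in panel: {unknown}")
        if self.baseline is not None and len(self.baseline) != len(self.lectin_names):
            raise SimulationError("baseline length must match lectin count")

    def _baseline_vector(self) -> np.ndarray:
        if self.baseline is None:
            vec = np.full(len(self.lectin_names), 1.0)
        else:
            vec = np.asarray(self.baseline, dtype=float)
            if (vec < 0).any():
                raise SimulationError("baseline proportions must be non-negative")
        return vec / vec.sum()

    def group_composition(self, group: str) -> np.ndarray:
        """Renormalized composition of one group; sums to 1."""
        if group not in self.group_labels:
            raise SimulationError(f"unknown group {group!r}")
        vec = self._baseline_vector()
        if group == self.effect_group:
            for lectin, fold in self.effects:
                vec[self.lectin_names.index(lectin)] *= fold
        vec = vec / vec.sum()
        assert abs(vec.sum() - 1.0) < 1e-9
        return vec

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{g}{i + 1}"
            for g in self.group_labels
            for i in range(self.samples_per_group)
        ]

    @property
    def sample_groups(self) -> list[str]:
        return [g for g in self.group_labels for _ in range(self.samples_per_group)]


def pups_adult_design(
    panel: LectinPanel,
    fold_change: float = DEFAULT_FOLD_CHANGE,
    effect_lectins: tuple[str, ...] = DEFAULT_EFFECT_LECTINS,
    samples_per_group: int = 3,
    overdispersion: float = 0.0,
) -> GroupDesign:
    """The default study design: pups vs adult, planted effect in pups."""
    return GroupDesign(
        lectin_names=tuple(panel.names),
        effects=tuple((l, fold_change) for l in effect_lectins),
        samples_per_group=samples_per_group,
        overdispersion=overdispersion,
    )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``true_counts`` excludes contaminants; its row sums equal the per-sample
    non-contaminant read totals and, together with ``n_contaminants``, the
    requested depth. ``read_labels`` has one row per emitted FASTQ record in
    emission order.
    """

    seed: int
    compositions: pd.DataFrame  # samples x lectins, realized (post-dispersion)
    true_counts: pd.DataFrame  # samples x lectins, int
    read_labels: pd.DataFrame  # columns: sample_id, read_id, true_label
    n_contaminants: pd.Series
    error_rate: float
    contaminant_fraction: float
    depth: int


def _draw_sample_composition(design: GroupDesign, group: str, rng: np.random.Generator) -> np.ndarray:
    comp = design.group_composition(group)
    if design.overdispersion > 0:
        comp = rng.dirichlet(comp / design.overdispersion)
    return comp


def simulate_counts(
    design: GroupDesign, depth: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial per-sample lectin counts, skipping read emission.

    Returns (counts, compositions), both samples x lectins. Useful for
    power/null studies where the read-level path is not under test.
    """
    rng = np.random.default_rng(seed)
    counts, comps = {}, {}
    for sample_id, group in zip(design.sample_ids, design.sample_groups):
        comp = _draw_sample_composition(design, group, rng)
        comps[sample_id] = comp
        counts[sample_id] = rng.multinomial(depth, comp)
    names = list(design.lectin_names)
    return (
        pd.DataFrame(counts, index=names).T,
        pd.DataFrame(comps, index=names).T,
    )


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions; an error replaces the base by one of the
    other three, uniformly."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    # shift by 1..3 within the 4-letter alphabet, relative to the base's index
    idx = np.searchsorted(_BASES, reads)
    shift = rng.integers(1, 4, size=reads.shape)
    mutated = _BASES[(idx + shift) % 4]
    return np.where(mask, mutated, reads)


def simulate_reads(
    panel: LectinPanel,
    design: GroupDesign,
    out_dir: str | Path,
    depth: int = DEFAULT_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    contaminant_fraction: float = DEFAULT_CONTAMINANT_FRACTION,
    seed: int = 0,
    paired: bool = False,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Emit per-sample FASTQ files plus a sample sheet and full ground truth.

    Per sample, ``round(contaminant_fraction * depth)`` reads are uniform
    random sequence and the rest are drawn multinomially from the sample's
    composition; emission order is a seeded permutation. Each read is the
    3-base random prefix followed by the (error-mutated) barcode, with a
    constant Phred+33 quality string. With ``paired=True`` a filler mate-2
    file is also written (the matching rule only consumes read 1).

    Returns (sample_sheet, SimulationTruth); the sheet is also written to
    ``out_dir/samples.tsv`` and all parameters to ``out_dir/manifest.json``.
    """
    if not 0 <= error_rate < 0.5:
        raise SimulationError("error_rate must be in [0, 0.5)")
    if not 0 <= contaminant_fraction < 1:
        raise SimulationError("contaminant_fraction must be in [0, 1)")
    if set(design.lectin_names) != set(panel.names):
        raise SimulationError("design lectins do not match panel lectins")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    L = panel.layout.barcode_length
    prefix_len = panel.prefix_trim
    read_len = prefix_len + L
    qual = "I" * read_len
    seq_matrix = panel.seq_matrix()
    order = [panel.names.index(n) for n in design.lectin_names]

    sheet_rows, truth_frames = [], []
    comps, count_rows, contam_counts = {}, {}, {}
    n_contam = int(round(contaminant_fraction * depth))
    n_real = depth - n_contam
    for sample_id, group in zip(design.sample_ids, design.sample_groups):
        comp = _draw_sample_composition(design, group, rng)
        counts = rng.multinomial(n_real, comp)
        comps[sample_id], count_rows[sample_id] = comp, counts
        contam_counts[sample_id] = n_contam

        # true label per read, then a seeded shuffle of emission order
        label_idx = np.repeat(np.arange(len(counts)), counts)
        label_idx = np.concatenate([label_idx, np.full(n_contam, -1)])
        label_idx = rng.permutation(label_idx)

        barcode_part = np.empty((depth, L), dtype=np.uint8)
        real = label_idx >= 0
        barcode_rows = np.take(seq_matrix, np.asarray(order)[label_idx[real]], axis=0)
        barcode_part[real] = _mutate(barcode_rows, error_rate, rng)
        barcode_part[~real] = rng.choice(_BASES, size=((~real).sum(), L))
        prefix_part = rng.choice(_BASES, size=(depth, prefix_len))
        reads = np.concatenate([prefix_part, barcode_part], axis=1)

        fastq_path = out_dir / f"{sample_id}.fastq"
        labels = np.where(
            real, np.asarray(list(design.lectin_names) + [CONTAMINANT])[label_idx], CONTAMINANT
        )
        with fastq_path.open("w") as fh:
            seq_strings = (
                reads.tobytes().decode("ascii")
                if depth
                else ""
            )
            for i in range(depth):
                seq = seq_strings[i * read_len:(i + 1) * read_len]
                fh.write(f"@{sample_id}.{i + 1}\n{seq}\n+\n{qual}\n")
        if paired:
            with (out_dir / f"{sample_id}_R2.fastq").open("w") as fh:
                filler = "N" * read_len
                for i in range(depth):
                    fh.write(f"@{sample_id}.{i + 1}\n{filler}\n+\n{qual}\n")
        truth_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "read_id": [f"{sample_id}.{i + 1}" for i in range(depth)],
                    "true_label": labels,
                }
            )
        )
        sheet_rows.append(
            {"sample_id": sample_id, "group": group, "fastq_path": fastq_path.name}
        )

    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    names = list(design.lectin_names)
    truth = SimulationTruth(
        seed=seed,
        compositions=pd.DataFrame(comps, index=names).T,
        true_counts=pd.DataFrame(count_rows, index=names).T,
        read_labels=pd.concat(truth_frames, ignore_index=True),
        n_contaminants=pd.Series(contam_counts),
        error_rate=error_rate,
        contaminant_fraction=contaminant_fraction,
        depth=depth,
    )
    truth.read_labels.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    truth.true_counts.rename_axis("sample_id").to_csv(out_dir / "truth_counts.tsv", sep="\t")
    manifest = {
        "stage": "simulate",
        "seed": seed,
        "depth": depth,
        "error_rate": error_rate,
        "contaminant_fraction": contaminant_fraction,
        "groups": {g: design.samples_per_group for g in design.group_labels},
        "effects": {l: f for l, f in design.effects},
        "effect_group": design.effect_group,
        "overdispersion": design.overdispersion,
        "n_lectins": len(names),
        "paired": paired,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return sheet, truth
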