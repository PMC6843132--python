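"""From competition efficiencies to an affinity table, PWM and logo.

The saturation-mutagenesis design measures one competitor efficiency per
(position, mutant base) cell over crystal indices N5..N16 (CCAAT = N8..N12),
with the WT base at each position fixed at 1.0.  Treating efficiency as a
relative affinity, each position's base probabilities are the epsilon-floored
normalization of its affinities, giving a position probability matrix; the
information content of a column (2 + sum p log2 p) times its probabilities
gives the letter heights of the sequence logo.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .emsa import CompetitionResult
from .oligos import CCAAT_START_INDEX, Oligo, base_at

__all__ = [
    "BASES",
    "AffinityTable",
    "PWM",
    "LogoColumn",
    "AnnotationConflictError",
    "build_affinity_table",
    "affinity_to_pwm",
    "information_content",
    "pwm_to_logo",
    "compare_pwms",
    "relative_label",
    "write_jaspar",
    "read_jaspar",
    "write_pwm_json",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default crystal-index span of the saturation mutagenesis (N5..N16)
DEFAULT_POSITIONS = tuple(range(5, 17))


class AnnotationConflictError(ValueError):
    """Two competition results claim the same (position, base) cell."""


def relative_label(crystal_index: int) -> str:
    """Label of a crystal index relative to the CCAAT pentamer.

    N8..N12 are the pentamer bases C,C,A,A,T; upstream indices get -1..-3,
    downstream +1..+4.
    """
    core = CCAAT_START_INDEX
    if core <= crystal_index <= core + 4:
        return "CCAAT"[crystal_index - core]
    if crystal_index < core:
        return str(crystal_index - core)
    return f"+{crystal_index - core - 4}"


@dataclass
class AffinityTable:
    """Per-position, per-base relative affinities (WT base = 1.0)."""

    positions: tuple[int, ...]
    wt_context: dict[int, str]
    cells: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = tuple(self.positions)
        for pos in self.positions:
            wt = self.wt_context.get(pos)
            if wt not in _BASE_INDEX:
                raise ValueError(f"position {pos} lacks a valid WT base")
            self.cells.setdefault((pos, wt), 1.0)
        for (pos, base), value in self.cells.items():
            if base not in _BASE_INDEX:
                raise ValueError(f"invalid base {base!r} at position {pos}")
            if value < 0:
                raise ValueError(f"negative affinity at ({pos}, {base})")

    def affinity(self, position: int, base: str) -> float | None:
        return self.cells.get((position, base))

    def measured_bases(self, position: int) -> list[str]:
        return [b for b in BASES if (position, b) in self.cells]


def build_affinity_table(
    results: Iterable[CompetitionResult],
    wt_oligo: Oligo,
    mutant_annotations: Mapping[str, tuple[int, str]],
    positions: Sequence[int] = DEFAULT_POSITIONS,
) -> AffinityTable:
    """Assemble the per-position affinity table from competition results.

    ``mutant_annotations`` maps each mutant oligo id to its single
    (crystal position, mutant base) change relative to WT.  Oligos without
    an annotation (e.g. the WT itself, or multi-mutant controls) are
    ignored here.  Negative mean efficiencies are clamped to 0 with a
    warning; two results claiming one cell raise
    :class:`AnnotationConflictError`.
    """
    positions = tuple(positions)
    wt_context = {pos: base_at(wt_oligo, pos) for pos in positions}
    cells: dict[tuple[int, str], float] = {}
    claimed: dict[tuple[int, str], str] = {}
    for res in results:
        ann = mutant_annotations.get(res.oligo_id)
        if ann is None:
            continue
        pos, base = ann
        if pos not in wt_context:
            raise ValueError(f"annotated position {pos} outside table span {positions}")
        if base == wt_context[pos]:
            raise ValueError(
                f"oligo {res.oligo_id!r} annotated with the WT base {base} at {pos}"
            )
        key = (pos, base)
        if key in claimed:
            raise AnnotationConflictError(
                f"cell {key} claimed by both {claimed[key]!r} and {res.oligo_id!r}"
            )
        claimed[key] = res.oligo_id
        value = res.efficiency
        if value < 0:
            warnings.warn(
                f"negative mean efficiency {value:.4g} for {res.oligo_id!r} "
                "clamped to 0",
                stacklevel=2,
            )
            value = 0.0
        cells[key] = value
    return AffinityTable(positions=positions, wt_context=wt_context, cells=cells)


@dataclass
class PWM:
    """Position probability matrix with crystal/relative position labels."""

    matrix: np.ndarray                 # (width, 4), rows sum to 1
    crystal_positions: tuple[int, ...]
    pseudo_affinity: float = 0.01
    missing_policy: str = "floor"
    id: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.matrix.shape[0] != len(self.crystal_positions):
            raise ValueError("position labels must match matrix width")
        if np.any(self.matrix < 0):
            raise ValueError("PWM entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1 within 1e-9")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def relative_labels(self) -> tuple[str, ...]:
        return tuple(relative_label(p) for p in self.crystal_positions)


@dataclass(frozen=True)
class LogoColumn:
    ic_bits: float
    letter_heights: dict[str, float]


def affinity_to_pwm(
    table: AffinityTable,
    epsilon: float = 0.01,
    missing_policy: str = "floor",
    id: str = "pwm",
) -> PWM:
    """Normalize per-position affinities into base probabilities.

    Missing cells (bases never assayed at a position) are filled before
    normalization according to ``missing_policy``:

    - ``"floor"``: untested bases are assumed negligible (value epsilon) —
      appropriate for the CCAAT core, where only one transversion per
      position was assayed and the core is drawn near full height;
    - ``"wt-share"``: untested bases are assumed as competitive as WT
      (value 1.0), a conservative low-information prior;
    - ``"drop-position"``: a position with no measured non-WT cell is
      omitted from the matrix with a warning.

    Then p_j(b) = max(a_j(b), epsilon) / sum_b' max(a_j(b'), epsilon).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if missing_policy not in ("floor", "wt-share", "drop-position"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    columns: list[np.ndarray] = []
    kept_positions: list[int] = []
    for pos in table.positions:
        measured = table.measured_bases(pos)
        if missing_policy == "drop-position" and len(measured) <= 1:
            warnings.warn(f"position {pos} has no measured mutant cell; dropped",
                          stacklevel=2)
            continue
        fill = 1.0 if missing_policy == "wt-share" else epsilon
        values = np.array(
            [
                table.affinity(pos, b) if b in measured else fill
                for b in BASES
            ],
            dtype=float,
        )
        values = np.maximum(values, epsilon)
        columns.append(values / values.sum())
        kept_positions.append(pos)
    if not columns:
        raise ValueError("no positions left after applying missing policy")
    return PWM(
        matrix=np.vstack(columns),
        crystal_positions=tuple(kept_positions),
        pseudo_affinity=epsilon,
        missing_policy=missing_policy,
        id=id,
    )


def information_content(column: Sequence[float]) -> float:
    """Information content in bits of a base-probability column.

    2 + sum_b p(b) log2 p(b), with 0*log0 = 0; lies in [0, 2].
    """
    p = np.asarray(column, dtype=float)
    if p.shape != (4,):
        raise ValueError("column must be a probability 4-vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("column must sum to 1")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def pwm_to_logo(pwm: PWM) -> list[LogoColumn]:
    """Letter heights p(b) * IC per column, the sequence-logo rendering."""
    out = []
    for row in pwm.matrix:
        ic = information_content(row)
        out.append(
            LogoColumn(
                ic_bits=ic,
                letter_heights={b: float(p * ic) for b, p in zip(BASES, row)},
            )
        )
    return out


def compare_pwms(a: PWM, b: PWM, alignment_offset: int = 0) -> list[tuple[int, float]]:
    """Per-position Jensen-Shannon divergence (bits) between two matrices.

    Columns are aligned on their crystal positions after shifting ``b`` by
    ``alignment_offset`` (b's position p is compared with a's position
    p + alignment_offset).  Returns (a-position, JSD bits) pairs for the
    overlapping span; JSD in base 2 lies in [0, 1].
    """
    from scipy.spatial.distance import jensenshannon

    index_b = {p + alignment_offset: i for i, p in enumerate(b.crystal_positions)}
    out: list[tuple[int, float]] = []
    for i, pos in enumerate(a.crystal_positions):
        j = index_b.get(pos)
        if j is None:
            continue
        jsd = float(jensenshannon(a.matrix[i], b.matrix[j], base=2) ** 2)
        out.append((pos, jsd))
    if not out:
        raise ValueError("no overlapping positions after alignment")
    return out


# ---------------------------------------------------------------------------
# serialization


def write_jaspar(pwm: PWM, path) -> None:
    """Write the matrix as JASPAR-style 4-row probability text."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.id}\n")
        for i, base in enumerate(BASES):
            values = " ".join(f"{v:.6f}" for v in pwm.matrix[:, i])
            fh.write(f"{base} [ {values} ]\n")


def read_jaspar(path, crystal_start: int = 5) -> PWM:
    """Read a 4-row JASPAR-style matrix; counts are renormalized."""
    rows: dict[str, list[float]] = {}
    motif_id = "pwm"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            base = line[0]
            inner = line[line.index("[") + 1: line.index("]")]
            rows[base] = [float(tok) for tok in inner.split()]
    matrix = np.array([rows[b] for b in BASES], dtype=float).T
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    positions = tuple(range(crystal_start, crystal_start + matrix.shape[0]))
    return PWM(matrix=matrix, crystal_positions=positions, id=motif_id)


def write_pwm_json(pwm: PWM, path) -> None:
    """JSON dialect carrying position labels and normalization settings."""
    payload = {
        "id": pwm.id,
        "bases": list(BASES),
        "columns": pwm.matrix.tolist(),
        "crystal_positions": list(pwm.crystal_positions),
        "relative_labels": list(pwm.relative_labels),
        "pseudo_affinity": pwm.pseudo_affinity,
        "missing_policy": pwm.missing_policy,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
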