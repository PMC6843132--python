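"""Synthetic reference affinity table for the CAB2 CCAAT saturation design.

The published per-oligo competition efficiencies exist only as a figure
table and are not machine-readable, so this module provides a *synthetic*
stand-in: a relative-affinity table over crystal positions N5-N16 of the
CAB2 probe, modeled on the reported qualitative trends — T preferred and
WT A least preferred at -3; C/G above A=T at -2; purines preferred over the
WT T at -1; sharp losses for single transversions in each CCAAT core base
(with the second C the mildest); C preferred over the WT G at +1; purines
over pyrimidines with C worst at +2; all bases similar with WT A least
preferred at +3; A preferred at +4.  It is intended for examples, power
analyses and benchmarks, not as measured data.
"""

from __future__ import annotations

from .matrix import AffinityTable, PWM, affinity_to_pwm
from .oligos import CAB2_PROBE, Oligo

__all__ = ["cab2_wt_oligo", "synthetic_affinity_table", "synthetic_ccaat_pwm"]

# (position, base) -> relative affinity; WT bases (value 1.0) are implicit.
# Core positions N8-N12 carry a single assayed transversion each.
_CELLS: dict[tuple[int, str], float] = {
    # N5, WT A: T strongest, WT weakest
    (5, "T"): 1.6, (5, "C"): 1.3, (5, "G"): 1.2,
    # N6, WT A: T equal to WT, C/G stronger
    (6, "T"): 1.0, (6, "C"): 1.4, (6, "G"): 1.4,
    # N7, WT T: purines preferred, C weaker
    (7, "A"): 1.5, (7, "G"): 1.5, (7, "C"): 0.6,
    # CCAAT core, single transversions: sharp losses, calibrated so the
    # derived logo reproduces near-full-height core letters; the second C
    # is the mildest core loss
    (8, "A"): 0.03,    # CAB2mut C8A
    (9, "A"): 0.08,    # second C, mildest core loss
    (10, "C"): 0.03,
    (11, "C"): 0.03,
    (12, "A"): 0.03,
    # N13, WT G: C preferred
    (13, "C"): 1.4, (13, "A"): 0.9, (13, "T"): 0.8,
    # N14, WT A: purines over pyrimidines, C worst
    (14, "G"): 1.1, (14, "C"): 0.4, (14, "T"): 0.6,
    # N15, WT A: all similar, WT least preferred
    (15, "C"): 1.2, (15, "G"): 1.2, (15, "T"): 1.2,
    # N16, WT T: A preferred
    (16, "A"): 1.5, (16, "C"): 0.9, (16, "G"): 1.1,
}


def cab2_wt_oligo() -> Oligo:
    """The CAB2 (-65) probe with CCAAT-anchored crystal numbering."""
    return Oligo.from_ccaat_anchor("CAB2", CAB2_PROBE, role="probe")


def synthetic_affinity_table() -> AffinityTable:
    """Synthetic N5-N16 relative-affinity table in the CAB2 context."""
    wt = cab2_wt_oligo()
    positions = tuple(range(5, 17))
    from .oligos import base_at

    wt_context = {pos: base_at(wt, pos) for pos in positions}
    return AffinityTable(
        positions=positions, wt_context=wt_context, cells=dict(_CELLS)
    )


def synthetic_ccaat_pwm(epsilon: float = 0.01, missing_policy: str = "floor") -> PWM:
    """PWM derived from the synthetic affinity table (the worked-example matrix)."""
    return affinity_to_pwm(
        synthetic_affinity_table(),
        epsilon=epsilon,
        missing_policy=missing_policy,
        id="CCAAT-synthetic",
    )
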