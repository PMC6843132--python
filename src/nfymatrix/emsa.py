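"""Quantification of competition EMSA experiments.

A preformed NF-Y/probe complex is challenged with an unlabeled competitor
oligo at increasing dose (expressed as competitor / probe fold ratio; the
reference lane has no competitor).  For each lane the percent of probe in
the shifted (bound) band is computed from band intensities; percent bound
is regressed on the dose ratio by ordinary least squares, and the slope of
a competitor's regression line divided by the wild-type oligo's slope from
the same experiment is its *competitor efficiency* (slope/WT) — the
operational relative-affinity readout.  Efficiencies from replicate
experiments are averaged (mean, sample sd).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LaneMeasurement",
    "DosePoint",
    "DoseCurve",
    "CompetitionResult",
    "UnquantifiableLaneError",
    "DegenerateDesignError",
    "NonCompetingReferenceError",
    "percent_bound",
    "fit_slope",
    "competitor_efficiency",
    "aggregate_replicates",
    "read_lanes_tsv",
    "quantify_lanes",
    "write_efficiencies_tsv",
]


class UnquantifiableLaneError(ValueError):
    """Bound + free intensity is zero; the lane carries no signal."""


class DegenerateDesignError(ValueError):
    """All dose ratios identical; a regression slope is undefined."""


class NonCompetingReferenceError(ValueError):
    """The reference (WT) slope is below the floor; efficiencies undefined."""


@dataclass(frozen=True)
class LaneMeasurement:
    """Integrated band intensities of one gel lane (densitometry units)."""

    bound_intensity: float
    free_intensity: float

    def __post_init__(self) -> None:
        if self.bound_intensity < 0 or self.free_intensity < 0:
            raise ValueError("band intensities must be non-negative")


@dataclass(frozen=True)
class DosePoint:
    ratio: float          # competitor / probe fold ratio, >= 0
    percent_bound: float  # in [0, 100]

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("dose ratio must be non-negative")
        if not 0.0 <= self.percent_bound <= 100.0:
            raise ValueError("percent bound must lie in [0, 100]")


@dataclass(frozen=True)
class DoseCurve:
    oligo_id: str
    points: tuple[DosePoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        ratios = [p.ratio for p in self.points]
        if len(set(ratios)) < 2:
            raise ValueError("a dose curve needs >= 2 distinct ratios")
        if sum(r == 0 for r in ratios) != 1:
            raise ValueError("a dose curve needs exactly one no-competitor (ratio 0) point")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points], dtype=float)

    @property
    def percents(self) -> np.ndarray:
        return np.array([p.percent_bound for p in self.points], dtype=float)


@dataclass(frozen=True)
class CompetitionResult:
    oligo_id: str
    slope: float            # mean slope, percent bound per unit ratio
    efficiency: float       # mean slope/WT over replicates
    n_replicates: int
    sd: float = math.nan    # sample sd of efficiency; NaN when n < 2
    sign_warning: bool = False


def percent_bound(lane: LaneMeasurement) -> float:
    """Percent of probe in the bound band: 100 * bound / (bound + free)."""
    total = lane.bound_intensity + lane.free_intensity
    if total <= 0:
        raise UnquantifiableLaneError("bound + free intensity must be > 0")
    return 100.0 * lane.bound_intensity / total


def fit_slope(curve: DoseCurve) -> float:
    """OLS slope of percent bound on dose ratio (intercept fitted freely)."""
    x, y = curve.ratios, curve.percents
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all dose ratios identical")
    slope, _intercept = np.polyfit(x, y, 1)
    return float(slope)


def competitor_efficiency(
    mut_slope: float, wt_slope: float, floor: float = 1e-6
) -> tuple[float, bool]:
    """Competitor efficiency slope/WT.

    Both slopes are expected negative (competition strips probe from the
    complex).  A sign mismatch — a competitor whose fitted slope is positive
    against a negative WT slope — is reported as efficiency 0 with a warning
    flag rather than a negative efficiency.

    Returns ``(efficiency, sign_warning)``.
    """
    if abs(wt_slope) < floor:
        raise NonCompetingReferenceError(
            f"reference slope {wt_slope!r} below floor {floor!r}; "
            "the WT oligo did not compete"
        )
    ratio = mut_slope / wt_slope
    if ratio < 0:
        warnings.warn(
            "competitor slope has opposite sign to the WT slope; "
            "efficiency reported as 0",
            stacklevel=2,
        )
        return 0.0, True
    return ratio, False


def aggregate_replicates(efficiencies: Sequence[float]) -> tuple[float, float]:
    """Mean and sample sd (n-1 denominator) of replicate efficiencies.

    The sd is NaN for a single replicate.  Fewer than three replicates
    triggers a warning (the quantification protocol expects >= 3).
    """
    eff = np.asarray(list(efficiencies), dtype=float)
    if eff.size == 0:
        raise ValueError("no replicate efficiencies to aggregate")
    if eff.size < 3:
        warnings.warn(
            f"only {eff.size} replicate(s); protocol expects >= 3", stacklevel=2
        )
    mean = float(eff.mean())
    sd = float(eff.std(ddof=1)) if eff.size >= 2 else math.nan
    return mean, sd


# ---------------------------------------------------------------------------
# tabular layer


def _ensure_percent_column(df: pd.DataFrame) -> pd.DataFrame:
    """Add a percent_bound column from bound/free intensities if absent."""
    required = {"experiment_id", "replicate", "oligo_id", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lanes table missing columns: {sorted(missing)}")
    if "percent_bound" in df.columns:
        return df
    if not {"bound", "free"} <= set(df.columns):
        raise ValueError("lanes table needs bound/free or percent_bound columns")
    return df.assign(
        percent_bound=[
            percent_bound(LaneMeasurement(b, f))
            for b, f in zip(df["bound"], df["free"])
        ]
    )


def read_lanes_tsv(path) -> pd.DataFrame:
    """Read a lanes TSV into the canonical column layout.

    Expected columns: experiment_id, replicate, oligo_id, ratio and either
    (bound, free) intensity columns or a precomputed percent_bound column;
    presence of the ``percent_bound`` column selects the latter path.
    """
    return _ensure_percent_column(pd.read_csv(path, sep="\t"))


def _curves_by_replicate(df: pd.DataFrame) -> dict[tuple, dict[str, DoseCurve]]:
    """Group lanes into dose curves keyed by (experiment, replicate)."""
    out: dict[tuple, dict[str, DoseCurve]] = {}
    for (exp, rep, oligo), grp in df.groupby(["experiment_id", "replicate", "oligo_id"]):
        grp = grp.sort_values("ratio")
        curve = DoseCurve(
            oligo_id=str(oligo),
            points=tuple(
                DosePoint(float(r), float(np.clip(p, 0.0, 100.0)))
                for r, p in zip(grp["ratio"], grp["percent_bound"])
            ),
        )
        out.setdefault((exp, rep), {})[str(oligo)] = curve
    return out


def quantify_lanes(
    lanes: pd.DataFrame, wt_oligo_id: str, floor: float = 1e-6
) -> list[CompetitionResult]:
    """Full quantification of a lanes table against a WT reference oligo.

    Within each (experiment, replicate) group, every oligo's dose-curve
    slope is divided by that group's WT slope; per-oligo efficiencies are
    then aggregated across replicates.  The WT oligo itself is reported
    (efficiency identically 1 within each replicate).
    """
    curves = _curves_by_replicate(_ensure_percent_column(lanes))
    eff_by_oligo: dict[str, list[float]] = {}
    slope_by_oligo: dict[str, list[float]] = {}
    warned: set[str] = set()
    for key, group in curves.items():
        if wt_oligo_id not in group:
            warnings.warn(f"replicate {key} lacks WT oligo {wt_oligo_id!r}; skipped")
            continue
        wt_slope = fit_slope(group[wt_oligo_id])
        for oligo_id, curve in group.items():
            slope = fit_slope(curve)
            eff, flagged = competitor_efficiency(slope, wt_slope, floor=floor)
            if flagged:
                warned.add(oligo_id)
            eff_by_oligo.setdefault(oligo_id, []).append(eff)
            slope_by_oligo.setdefault(oligo_id, []).append(slope)
    results = []
    for oligo_id in sorted(eff_by_oligo):
        effs = eff_by_oligo[oligo_id]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, sd = aggregate_replicates(effs)
        results.append(
            CompetitionResult(
                oligo_id=oligo_id,
                slope=float(np.mean(slope_by_oligo[oligo_id])),
                efficiency=mean,
                n_replicates=len(effs),
                sd=sd,
                sign_warning=oligo_id in warned,
            )
        )
    return results


def write_efficiencies_tsv(results: Iterable[CompetitionResult], path) -> None:
    rows = [
        {
            "oligo_id": r.oligo_id,
            "slope": r.slope,
            "mean_efficiency": r.efficiency,
            "sd": r.sd,
            "n_replicates": r.n_replicates,
            "sign_warning": r.sign_warning,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
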