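"""Colony-count, gel-band and transformation efficiency statistics.

The screen readouts quantified here:

* cutting efficiency from a nuclease-mediated cell-killing assay,
  ``(1 - a/b) x 100`` where ``a`` counts colonies transformed with the
  targeting guide plasmid and ``b`` with the non-targeting control;
* editing efficiency from a colour screen (galK red/white or lacZ
  blue/white), ``white / (white + coloured) x 100``;
* transformation efficiency in CFU per microgram of plasmid;
* T7 endonuclease I indel rate from gel band intensities,
  ``100 x (1 - sqrt(1 - (b + c) / (a + b + c)))`` with ``a`` the undigested
  band and ``b``, ``c`` the two cleavage products.

Point estimates follow the assay formulas exactly; where the estimate is a
binomial proportion a Wilson score interval is attached (default 95%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ColonyCounts",
    "ColorScreenCounts",
    "BandIntensities",
    "EfficiencyResult",
    "cutting_efficiency",
    "editing_efficiency_color",
    "transformation_efficiency",
    "indel_rate",
    "batch_table",
]


@dataclass(frozen=True)
class ColonyCounts:
    """Cell-killing assay counts: targeting (a) vs non-targeting (b) plates."""

    a: int
    b: int

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("colony counts must be nonnegative")


@dataclass(frozen=True)
class ColorScreenCounts:
    """Colour-screen counts: white (edited) vs red/blue (unedited) colonies."""

    edited: int
    unedited: int

    def __post_init__(self):
        if self.edited < 0 or self.unedited < 0:
            raise ValueError("colony counts must be nonnegative")


@dataclass(frozen=True)
class BandIntensities:
    """T7E1 gel intensities: undigested (a) and cleavage products (b, c)."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("band intensities must be nonnegative")


@dataclass(frozen=True)
class EfficiencyResult:
    estimate: float  # percent
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if not 0 <= self.ci_low <= self.estimate <= self.ci_high <= 100:
            raise ValueError("interval must satisfy 0<=low<=est<=high<=100")


def _wilson(successes: int, n: int, confidence: float) -> tuple[float, float]:
    lo, hi = proportion_confint(
        successes, n, alpha=1 - confidence, method="wilson"
    )
    # guard against tiny numerical excursions outside [0, 1]
    return max(0.0, float(lo)), min(1.0, float(hi))


def cutting_efficiency(
    counts: ColonyCounts, confidence: float = 0.95
) -> EfficiencyResult:
    """Cell-killing cutting efficiency, ``(1 - a/b) x 100``.

    ``a > b`` (more survivors with the targeting guide than the control)
    clamps to 0% with a warning rather than reporting a negative
    efficiency.  The Wilson interval on the survival fraction a/b is
    propagated through ``1 - p``.
    """
    if counts.b == 0:
        raise ValueError("non-targeting colony count b must be positive")
    if counts.a > counts.b:
        warnings.warn(
            f"a={counts.a} exceeds b={counts.b}; efficiency clamped to 0%"
        )
    est = max(0.0, min(100.0, (1 - counts.a / counts.b) * 100))
    lo, hi = _wilson(min(counts.a, counts.b), counts.b, confidence)
    ci_low = max(0.0, (1 - hi) * 100)
    ci_high = min(100.0, (1 - lo) * 100)
    return EfficiencyResult(est, min(ci_low, est), max(ci_high, est), counts.b)


def editing_efficiency_color(
    counts: ColorScreenCounts, confidence: float = 0.95
) -> EfficiencyResult:
    """Colour-screen editing efficiency, ``white / total x 100``."""
    total = counts.edited + counts.unedited
    if total == 0:
        raise ValueError("no colonies counted")
    est = counts.edited / total * 100
    lo, hi = _wilson(counts.edited, total, confidence)
    return EfficiencyResult(est, min(lo * 100, est), max(hi * 100, est), total)


def transformation_efficiency(
    cfu: float, micrograms: float, dilution_factor: float = 1.0
) -> float:
    """Transformation efficiency in CFU per microgram of plasmid.

    ``dilution_factor`` scales plated counts back to the full reaction
    (e.g. 100 when 1/100 of the recovery volume was plated).
    """
    if micrograms <= 0:
        raise ValueError("micrograms must be positive")
    if cfu < 0:
        raise ValueError("cfu must be nonnegative")
    return cfu * dilution_factor / micrograms


def indel_rate(bands: BandIntensities) -> float:
    """T7E1 indel percentage: ``100 x (1 - sqrt(1 - (b+c)/(a+b+c)))``."""
    total = bands.a + bands.b + bands.c
    if total == 0:
        raise ValueError("all band intensities are zero")
    return 100 * (1 - math.sqrt(1 - (bands.b + bands.c) / total))


_STATS = {"cutting", "color", "transform", "indel"}


def batch_table(table: pd.DataFrame, statistic: str) -> pd.DataFrame:
    """Apply one efficiency statistic to every row of a count table.

    Expected columns: cutting -> a,b; color -> edited,unedited;
    transform -> cfu,micrograms[,dilution_factor]; indel -> a,b,c.
    Malformed rows are kept and flagged in an ``error`` column, never
    silently dropped.
    """
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    rows = []
    for _, row in table.iterrows():
        out: dict[str, object] = {"error": ""}
        try:
            if statistic == "cutting":
                r = cutting_efficiency(ColonyCounts(int(row["a"]), int(row["b"])))
            elif statistic == "color":
                r = editing_efficiency_color(
                    ColorScreenCounts(int(row["edited"]), int(row["unedited"]))
                )
            elif statistic == "transform":
                val = transformation_efficiency(
                    float(row["cfu"]),
                    float(row["micrograms"]),
                    float(row.get("dilution_factor", 1.0)),
                )
                out.update(estimate=val)
                rows.append(out)
                continue
            else:
                val = indel_rate(
                    BandIntensities(
                        float(row["a"]), float(row["b"]), float(row["c"])
                    )
                )
                out.update(estimate=val)
                rows.append(out)
                continue
            out.update(
                estimate=r.estimate, ci_low=r.ci_low, ci_high=r.ci_high, n=r.n
            )
        except (ValueError, KeyError) as exc:
            out["error"] = str(exc)
        rows.append(out)
    result = table.reset_index(drop=True).join(pd.DataFrame(rows))
    return result
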