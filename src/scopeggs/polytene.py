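"""Polytene-map distance expectations.

The historical polytene banding map of the fungus-gnat X chromosome is
organized into 14 zones of similar lengths, each with 3 sub-zones (A, B,
C), for 42 sub-zones in total.  Assuming zones also have similar
nucleotide lengths, a scaffold of length L implies a sub-zone length of
L / 42 and a zone length of L / 14; expected nucleotide distances between
landmarks are then (map distance in sub-zones) × (sub-zone length), which
can be compared with observed scaffold distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ScopeggsError

__all__ = [
    "PolyteneChromosome",
    "DistanceExpectation",
    "subzone_length",
    "zone_length",
    "expected_distance",
    "build_expectation_table",
    "round_half_away",
    "round_printed",
]

BP_PER_MB = 1_000_000.0


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (unlike banker's rounding)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def round_printed(mb: float) -> float:
    """Reporting convention for distances in Mb: 1 decimal place, except
    3 decimal places for sub-Mb values."""
    return round_half_away(mb, 3 if abs(mb) < 1.0 else 1)


@dataclass(frozen=True)
class PolyteneChromosome:
    """Zone-based length model of a polytene chromosome."""

    label: str
    scaffold_length: int  # bp
    n_zones: int = 14
    subzones_per_zone: int = 3

    def __post_init__(self):
        if self.n_zones < 1 or self.subzones_per_zone < 1:
            raise ScopeggsError("n_zones and subzones_per_zone must be >= 1")
        if self.scaffold_length <= 0:
            raise ScopeggsError("scaffold_length must be > 0")

    @property
    def n_subzones(self) -> int:
        return self.n_zones * self.subzones_per_zone


def subzone_length(chrom: PolyteneChromosome) -> float:
    """Average sub-zone length in Mb: scaffold length / total sub-zones."""
    return chrom.scaffold_length / chrom.n_subzones / BP_PER_MB


def zone_length(chrom: PolyteneChromosome) -> float:
    """Average zone length in Mb: scaffold length / zones."""
    return chrom.scaffold_length / chrom.n_zones / BP_PER_MB


def expected_distance(n_subzones: float, subzone_len_mb: float) -> float:
    """Expected nucleotide distance (Mb) spanned by ``n_subzones`` map
    sub-zones (fractional counts allowed)."""
    if n_subzones < 0:
        raise ScopeggsError("n_subzones must be >= 0")
    return n_subzones * subzone_len_mb


@dataclass(frozen=True)
class DistanceExpectation:
    """Expected vs observed nucleotide distance between two landmarks."""

    locus_1: str
    locus_2: str
    n_subzones: float
    expected_mb: float
    observed_mb: float | None = None

    @property
    def deviation_mb(self) -> float | None:
        if self.observed_mb is None:
            return None
        return self.observed_mb - self.expected_mb


def build_expectation_table(
    chrom: PolyteneChromosome,
    rows: list[tuple[str, str, float, float | None]],
) -> pd.DataFrame:
    """Expected/observed distance table for landmark pairs.

    ``rows`` are (locus_1, locus_2, n_subzones, observed_mb-or-None).
    Expected distances are reported at the printed precision (1 d.p.;
    3 d.p. below 1 Mb); deviation columns use the unrounded expectation.
    """
    sz = subzone_length(chrom)
    records = []
    for locus_1, locus_2, n_sub, observed in rows:
        exp = expected_distance(n_sub, sz)
        dev = None if observed is None else observed - exp
        records.append(
            {
                "locus_1": locus_1,
                "locus_2": locus_2,
                "n_subzones": n_sub,
                "expected_mb": round_printed(exp),
                "observed_mb": observed,
                "deviation_mb": None if dev is None else round_half_away(dev, 3),
                "rel_deviation": None if dev is None or exp == 0 else round_half_away(dev / exp, 4),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "locus_1",
            "locus_2",
            "n_subzones",
            "expected_mb",
            "observed_mb",
            "deviation_mb",
            "rel_deviation",
        ],
    )
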