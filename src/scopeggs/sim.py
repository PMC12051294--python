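"""Synthetic-data generators.

Emulate the statistical structure the downstream analyses assume:

* SCO chromosome-assignment tables under a tunable inter-chromosomal
  translocation rate ``theta`` (EGGS inputs);
* intra-chromosomal Hi-C contact pairs with a power-law distance decay
  plus planted multi-Mb "loop" anchors (fold-back-region-like dots), tight
  SV-like dots, and a matched no-loop genomic-DNA-style control
  (SCOPE inputs);
* repeat-alignment intervals concentrated around a planted centromere
  (track/centromere-localization inputs).

All generators are deterministic under their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ScopeggsError
from .eggs import ScoTable
from .scope import PairSet
from .tracks import IntervalSet

__all__ = [
    "SimScoConfig",
    "SimHicConfig",
    "LoopSpec",
    "SvSpec",
    "simulate_sco_table",
    "shuffle_assignments",
    "simulate_hic_pairs",
    "simulate_control_pairs",
    "fbr_demo_hic_config",
    "simulate_repeat_alignments",
    "derive_seed",
]


def derive_seed(root_seed: int, stream: int) -> int:
    """Deterministic per-stream sub-seed (< 2**31) from a root seed."""
    return int(np.random.SeedSequence([int(root_seed), int(stream)]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# SCO tables

@dataclass
class SimScoConfig:
    chrom_labels_a: list[str]
    sco_counts: list[int]
    theta: float
    reassignment: str = "uniform_any"  # or "uniform_other"
    seed: int = 0
    species_a: str = "speciesA"
    species_b: str = "speciesB"

    def __post_init__(self):
        if not (0.0 <= self.theta <= 1.0):
            raise ScopeggsError(f"theta must be in [0, 1], got {self.theta}")
        if len(self.chrom_labels_a) == 0:
            raise ScopeggsError("empty chromosome set")
        if len(self.sco_counts) != len(self.chrom_labels_a):
            raise ScopeggsError("sco_counts must match chrom_labels_a")
        if any(c < 0 for c in self.sco_counts) or sum(self.sco_counts) <= 0:
            raise ScopeggsError("sum of sco_counts must be > 0")
        if self.reassignment not in ("uniform_any", "uniform_other"):
            raise ScopeggsError(f"unknown reassignment mode {self.reassignment!r}")


def shuffle_assignments(
    labels: np.ndarray,
    chrom_labels: list[str],
    theta: float,
    reassignment: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Translocate each assignment with probability ``theta``.

    ``uniform_any`` draws the new chromosome uniformly over all labels
    (the original included); ``uniform_other`` over the other labels only.
    """
    labels = np.asarray(labels, dtype=object)
    out = labels.copy()
    moved = rng.random(len(labels)) < theta
    k = len(chrom_labels)
    if moved.any():
        if reassignment == "uniform_any":
            out[moved] = rng.choice(np.asarray(chrom_labels, dtype=object), size=moved.sum())
        else:
            if k < 2:
                raise ScopeggsError("uniform_other needs >= 2 chromosomes")
            idx = {l: i for i, l in enumerate(chrom_labels)}
            cur = np.array([idx[l] for l in labels[moved]])
            # uniform over the k-1 other labels: draw 0..k-2 and skip current
            draw = rng.integers(0, k - 1, size=moved.sum())
            draw = np.where(draw >= cur, draw + 1, draw)
            out[moved] = np.asarray(chrom_labels, dtype=object)[draw]
    return out


def simulate_sco_table(config: SimScoConfig) -> ScoTable:
    """SCO table where species B keeps species A's counterpart chromosome
    with probability 1−theta, else is reassigned per the config."""
    rng = np.random.default_rng(config.seed)
    chrom_a = np.repeat(
        np.asarray(config.chrom_labels_a, dtype=object), config.sco_counts
    )
    chrom_b = shuffle_assignments(
        chrom_a, config.chrom_labels_a, config.theta, config.reassignment, rng
    )
    rows = pd.DataFrame(
        {
            "ortho_id": [f"og{i:06d}" for i in range(len(chrom_a))],
            "chrom_a": chrom_a,
            "chrom_b": chrom_b,
        }
    )
    return ScoTable(
        species_a=config.species_a,
        species_b=config.species_b,
        rows=rows,
        labels_a=list(config.chrom_labels_a),
        labels_b=list(config.chrom_labels_a),
    )


# ---------------------------------------------------------------------------
# Hi-C pairs

@dataclass(frozen=True)
class LoopSpec:
    """A planted long-range interaction: both mates scatter (Gaussian,
    ``jitter_sd``) around a fixed anchor pair.  Defaults give the broad,
    fold-back-region-like dots (150 kb jitter)."""

    anchor_x: int
    anchor_y: int
    weight: float
    jitter_sd: float = 150_000.0

    def __post_init__(self):
        if self.anchor_x >= self.anchor_y:
            raise ScopeggsError("LoopSpec requires anchor_x < anchor_y")
        if self.jitter_sd < 0 or self.weight < 0:
            raise ScopeggsError("LoopSpec weight/jitter must be >= 0")


@dataclass(frozen=True)
class SvSpec:
    """A tight SV-like dot (structural-difference artifact); default 10 kb
    jitter to contrast with the much broader loop dots."""

    pos_x: int
    pos_y: int
    weight: float
    jitter_sd: float = 10_000.0

    def __post_init__(self):
        if self.jitter_sd < 0 or self.weight < 0:
            raise ScopeggsError("SvSpec weight/jitter must be >= 0")


@dataclass
class SimHicConfig:
    chrom_label: str
    chrom_length: int
    n_pairs: int
    alpha: float = 1.0
    d0: float = 10_000.0
    loops: list[LoopSpec] = field(default_factory=list)
    svs: list[SvSpec] = field(default_factory=list)
    mapq_model: tuple[float, int, int] = (0.1, 0, 60)  # (fraction_low, low, high)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 0:
            raise ScopeggsError("n_pairs must be >= 0")
        if self.chrom_length <= 0:
            raise ScopeggsError("chrom_length must be > 0")
        if self.alpha <= 0:
            raise ScopeggsError("alpha must be > 0")
        for spec in list(self.loops) + list(self.svs):
            xs = (spec.anchor_x, spec.anchor_y) if isinstance(spec, LoopSpec) else (spec.pos_x, spec.pos_y)
            for p in xs:
                if not (0 <= p < self.chrom_length):
                    raise ScopeggsError(f"anchor {p} outside chromosome [0, {self.chrom_length})")
        w = sum(s.weight for s in self.loops) + sum(s.weight for s in self.svs)
        if w > 1.0 + 1e-9:
            raise ScopeggsError("loop + SV weights exceed 1")
        frac_low = self.mapq_model[0]
        if not (0.0 <= frac_low <= 1.0):
            raise ScopeggsError("mapq_model fraction_low must be in [0, 1]")

    @property
    def background_weight(self) -> float:
        return 1.0 - sum(s.weight for s in self.loops) - sum(s.weight for s in self.svs)


def _powerlaw_distance_ppf(u: np.ndarray, alpha: float, d0: float, dmax: float) -> np.ndarray:
    """Inverse CDF of the truncated shifted power law p(d) ∝ (d+d0)^(−alpha)
    on d ∈ [0, dmax]."""
    a, b = d0, dmax + d0
    if abs(alpha - 1.0) < 1e-12:
        return a * (b / a) ** u - d0
    e = 1.0 - alpha
    return (a**e + u * (b**e - a**e)) ** (1.0 / e) - d0


def simulate_hic_pairs(config: SimHicConfig) -> PairSet:
    """Exactly ``n_pairs`` intra-chromosomal contact pairs.

    Each pair is drawn from the background (inter-mate distance from the
    truncated power law, left mate uniform over the positions that keep
    the pair on the chromosome), or from a loop/SV spec (anchors plus
    independent Gaussian jitter, clipped to bounds), according to the
    mixture weights.  Pairs are canonicalized so pos_a <= pos_b.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    n = config.n_pairs
    specs = list(config.loops) + list(config.svs)
    weights = np.array([config.background_weight] + [s.weight for s in specs])
    weights = weights / weights.sum()
    cat = rng.choice(len(weights), size=n, p=weights)

    pos_a = np.zeros(n, dtype=np.int64)
    pos_b = np.zeros(n, dtype=np.int64)

    bg = cat == 0
    n_bg = int(bg.sum())
    if n_bg:
        # left mate uniform and distance from the chromosome-wide truncated
        # law, drawn jointly by rejection so that the pair fits on the
        # chromosome.  This keeps the near-diagonal decay ridge uniform
        # along the chromosome instead of piling long-range mass into a
        # corner or boosting short distances at the right edge.
        x1 = np.empty(n_bg)
        d = np.empty(n_bg)
        todo = np.arange(n_bg)
        while len(todo):
            cx = rng.random(len(todo)) * L
            cd = _powerlaw_distance_ppf(rng.random(len(todo)), config.alpha, config.d0, L - 1)
            ok = cx + cd <= L - 1
            x1[todo[ok]] = cx[ok]
            d[todo[ok]] = cd[ok]
            todo = todo[~ok]
        pos_a[bg] = np.floor(x1).astype(np.int64)
        pos_b[bg] = np.minimum(np.floor(x1 + d).astype(np.int64), L - 1)

    for k, spec in enumerate(specs, start=1):
        sel = cat == k
        m = int(sel.sum())
        if m == 0:
            continue
        ax, ay = (
            (spec.anchor_x, spec.anchor_y)
            if isinstance(spec, LoopSpec)
            else (spec.pos_x, spec.pos_y)
        )
        x = ax + rng.normal(0.0, spec.jitter_sd, size=m) if spec.jitter_sd > 0 else np.full(m, float(ax))
        y = ay + rng.normal(0.0, spec.jitter_sd, size=m) if spec.jitter_sd > 0 else np.full(m, float(ay))
        pos_a[sel] = np.clip(np.floor(x), 0, L - 1).astype(np.int64)
        pos_b[sel] = np.clip(np.floor(y), 0, L - 1).astype(np.int64)

    lo = np.minimum(pos_a, pos_b)
    hi = np.maximum(pos_a, pos_b)

    frac_low, low_v, high_v = config.mapq_model
    mapq = np.where(rng.random(n) < frac_low, low_v, high_v).astype(np.int64)

    df = pd.DataFrame(
        {
            "chrom_a": config.chrom_label,
            "pos_a": lo,
            "chrom_b": config.chrom_label,
            "pos_b": hi,
            "mapq": mapq,
            "category": np.where(
                cat == 0,
                "background",
                np.where(cat <= len(config.loops), "loop", "sv"),
            ),
        }
    )
    return PairSet(
        df=df,
        chrom_sizes={config.chrom_label: L},
        source="simulated_hic",
    )


def simulate_control_pairs(config: SimHicConfig) -> PairSet:
    """Matched genomic-DNA-style control: same chromosome, background and
    SV dots only.  Loop specs are dropped and their probability mass is
    absorbed by the background so that ``n_pairs`` is preserved."""
    ctrl = replace(config, loops=[])
    out = simulate_hic_pairs(ctrl)
    out.source = "simulated_control"
    return out


def fbr_demo_hic_config(
    seed: int = 0, n_pairs: int = 200_000, include_svs: bool = False
) -> SimHicConfig:
    """Study-condition demo configuration: a 70.5-Mb X-like chromosome with
    the three pairwise fold-back-region loop interactions (FBR1–FBR2,
    FBR1–FBR3, FBR2–FBR3), the long-inversion breakpoint dot, a population
    of short-separation features, and (optionally) two far-separated tight
    SV dots with a matched control.

    Landmark spacing follows the polytene-map expectations (centromere to
    FBR1 ≈ 3.5 Mb, FBR1–FBR2 ≈ 10.3 Mb, FBR2–FBR3 ≈ 42.7 Mb, breakpoints
    bracketing FBR1/FBR3).  Each broad interaction carries 2% of the pairs
    (150 kb jitter).  Eight tighter features with 1.2–2.5 Mb separations
    (0.4% each, 50 kb jitter) emulate the small structural variants and
    shorter-range interaction dots that populate real long-range contact
    grids; the minimum-separation filter, not the peak caller, is what
    removes them.  Optional far-separated SV dots (1% each, 10 kb jitter)
    survive the separation filter and are only removed by subtraction
    against the matched no-loop control.  The rest is power-law-decay
    background.
    """
    L = 70_507_862
    cen = 2_500_000
    fbr1 = cen + 3_490_000
    bp5 = fbr1 - 620_000
    fbr2 = fbr1 + 10_300_000
    fbr3 = fbr2 + 42_700_000
    bp3 = fbr3 + 4_650_000
    loops = [
        LoopSpec(fbr1, fbr2, 0.02),
        LoopSpec(fbr1, fbr3, 0.02),
        LoopSpec(fbr2, fbr3, 0.02),
        LoopSpec(bp5, bp3, 0.02),
    ]
    short_features = [
        SvSpec(x, y, 0.004, jitter_sd=50_000.0)
        for x, y in [
            (9_500_000, 11_000_000),
            (20_000_000, 21_800_000),
            (27_000_000, 29_500_000),
            (33_000_000, 34_500_000),
            (40_000_000, 42_000_000),
            (47_500_000, 49_000_000),
            (54_000_000, 56_500_000),
            (65_000_000, 66_200_000),
        ]
    ]
    far_svs = (
        [SvSpec(12_000_000, 30_000_000, 0.01), SvSpec(25_500_000, 45_000_000, 0.01)]
        if include_svs
        else []
    )
    return SimHicConfig(
        chrom_label="chrX",
        chrom_length=L,
        n_pairs=n_pairs,
        loops=loops,
        svs=short_features + far_svs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Repeat alignments

def simulate_repeat_alignments(
    chrom_length: int,
    centromere_pos: int,
    n_intervals: int,
    mean_len: float = 500.0,
    decay_scale: float = 200_000.0,
    seed: int = 0,
    chrom: str = "chrX",
) -> IntervalSet:
    """Repeat-alignment intervals whose midpoints fall around a planted
    centromere with Laplace(scale=decay_scale) displacement (clipped to the
    chromosome) and exponential lengths with the given mean."""
    if not (0 <= centromere_pos < chrom_length):
        raise ScopeggsError("centromere_pos outside chromosome")
    if n_intervals < 0:
        raise ScopeggsError("n_intervals must be >= 0")
    rng = np.random.default_rng(seed)
    if decay_scale > 0:
        mids = centromere_pos + rng.laplace(0.0, decay_scale, size=n_intervals)
    else:
        mids = np.full(n_intervals, float(centromere_pos))
    mids = np.clip(mids, 0, chrom_length - 1)
    lens = np.maximum(1, np.round(rng.exponential(mean_len, size=n_intervals))).astype(np.int64)
    start = np.clip(np.floor(mids - lens / 2).astype(np.int64), 0, chrom_length - 1)
    end = np.clip(start + lens, 1, chrom_length)
    start = np.minimum(start, end - 1)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
    return IntervalSet(df=df, label="simulated_repeats", chrom_sizes={chrom: chrom_length})
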