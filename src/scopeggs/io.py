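"""Readers and writers for the standard text formats the pipeline touches.

Conventions
-----------
* internal coordinates are 0-based half-open; positions of contact mates
  are 0-based points;
* BEDPE is read 0-based with each mate position taken as its interval
  midpoint; the minimal 5-column pair format (``chrom1 pos1 chrom2 pos2
  mapq``) is 1-based points, converted on read;
* a missing MAPQ (non-numeric BEDPE score) is treated as 0, which fails
  the default MAPQ filter rather than silently passing;
* all output tables are TSV with a single ``#``-prefixed header line so
  they load directly into genome browsers.

Malformed records raise :class:`DataFormatError` carrying the line number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataFormatError, ScopeggsError
from .eggs import JointTable, ScoTable
from .scope import InteractionCall, PairSet
from .tracks import BinnedTrack, IntervalSet

__all__ = [
    "read_chrom_sizes",
    "read_pairs",
    "read_bed",
    "read_sco_tsv",
    "write_pairs",
    "write_bed",
    "write_bedgraph",
    "write_calls_tsv",
    "write_calls_bedpe",
    "write_joint_table",
    "write_matrix",
]


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``."""
    sizes: dict[str, int] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise DataFormatError("chrom sizes need 2 columns", lineno)
        chrom = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise DataFormatError(f"bad length {fields[1]!r}", lineno) from None
        if length <= 0:
            raise DataFormatError(f"non-positive length for {chrom!r}", lineno)
        if chrom in sizes:
            raise DataFormatError(f"duplicate chromosome {chrom!r}", lineno)
        sizes[chrom] = length
    return sizes


def _check_bounds(chrom, pos, chrom_sizes, lineno):
    if chrom not in chrom_sizes:
        raise DataFormatError(f"unknown chromosome {chrom!r}", lineno)
    if not (0 <= pos < chrom_sizes[chrom]):
        raise DataFormatError(f"position {pos} outside {chrom!r}", lineno)


def read_pairs(path, dialect: str, chrom_sizes: dict[str, int], source: str = "") -> PairSet:
    """Read contact pairs.

    ``dialect='bedpe'``: standard 10+-column BEDPE, mate position = interval
    midpoint, MAPQ from the score column when numeric else 0.
    ``dialect='pair5'``: minimal ``chrom1 pos1 chrom2 pos2 mapq`` with
    1-based point positions.
    """
    if dialect not in ("bedpe", "pair5"):
        raise ScopeggsError(f"unknown pair dialect {dialect!r}")
    rows = []
    for lineno, f in _lines(path):
        if dialect == "pair5":
            if len(f) < 5:
                raise DataFormatError("pair5 needs 5 columns", lineno)
            try:
                c1, p1, c2, p2, mq = f[0], int(f[1]) - 1, f[2], int(f[3]) - 1, int(f[4])
            except ValueError:
                raise DataFormatError(f"bad numeric field in {f!r}", lineno) from None
        else:
            if len(f) < 6:
                raise DataFormatError("BEDPE needs >= 6 columns", lineno)
            try:
                s1, e1, s2, e2 = int(f[1]), int(f[2]), int(f[4]), int(f[5])
            except ValueError:
                raise DataFormatError(f"bad coordinate in {f!r}", lineno) from None
            c1, c2 = f[0], f[3]
            p1, p2 = (s1 + e1) // 2, (s2 + e2) // 2
            mq = 0
            if len(f) >= 8:
                try:
                    mq = int(float(f[7]))
                except ValueError:
                    mq = 0  # missing/non-numeric score: treat as unmapped-quality
        _check_bounds(c1, p1, chrom_sizes, lineno)
        _check_bounds(c2, p2, chrom_sizes, lineno)
        if c1 == c2 and p2 < p1:
            p1, p2 = p2, p1
        rows.append((c1, p1, c2, p2, mq))
    df = pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b", "mapq"])
    return PairSet(df=df, chrom_sizes=dict(chrom_sizes), source=source or str(path))


def read_bed(path, chrom_sizes: dict[str, int] | None = None, label: str = "") -> IntervalSet:
    """Standard BED (first 3 columns), 0-based half-open."""
    rows = []
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise DataFormatError("BED needs >= 3 columns", lineno)
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise DataFormatError(f"bad coordinate in {f!r}", lineno) from None
        if start < 0 or end <= start:
            raise DataFormatError(f"invalid interval {f[0]}:{start}-{end}", lineno)
        if chrom_sizes is not None:
            if f[0] not in chrom_sizes:
                raise DataFormatError(f"unknown chromosome {f[0]!r}", lineno)
            if end > chrom_sizes[f[0]]:
                raise DataFormatError(f"interval beyond end of {f[0]!r}", lineno)
        rows.append((f[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return IntervalSet(df=df, label=label or str(path), chrom_sizes=chrom_sizes)


def read_sco_tsv(path, species_a: str = "speciesA", species_b: str = "speciesB") -> ScoTable:
    """SCO table TSV with header ``ortho_id chrom_a chrom_b``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#").strip() for c in df.columns]
    for col in ("ortho_id", "chrom_a", "chrom_b"):
        if col not in df.columns:
            raise DataFormatError(f"SCO TSV missing column {col!r}", 1)
    return ScoTable(species_a=species_a, species_b=species_b, rows=df)


def write_pairs(pairs: PairSet, path, dialect: str = "pair5") -> None:
    """Write a PairSet as 1-based pair5 or as minimal BEDPE (1-bp mate
    intervals, MAPQ in the score column)."""
    if dialect == "pair5":
        out = pd.DataFrame(
            {
                "chrom1": pairs.df["chrom_a"],
                "pos1": pairs.df["pos_a"] + 1,
                "chrom2": pairs.df["chrom_b"],
                "pos2": pairs.df["pos_b"] + 1,
                "mapq": pairs.df["mapq"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "bedpe":
        out = pd.DataFrame(
            {
                "chrom1": pairs.df["chrom_a"],
                "start1": pairs.df["pos_a"],
                "end1": pairs.df["pos_a"] + 1,
                "chrom2": pairs.df["chrom_b"],
                "start2": pairs.df["pos_b"],
                "end2": pairs.df["pos_b"] + 1,
                "name": ".",
                "score": pairs.df["mapq"],
                "strand1": "+",
                "strand2": "+",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ScopeggsError(f"unknown pair dialect {dialect!r}")


def write_bed(intervals: IntervalSet, path) -> None:
    intervals.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track: BinnedTrack, path, chrom_length: int | None = None) -> None:
    edges = track.bin_edges(chrom_length)
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            fh.write(f"{track.chrom}\t{int(edges[i])}\t{int(edges[i + 1])}\t{v:.6g}\n")


_CALL_COLUMNS = [
    "chrom",
    "anchor1_start",
    "anchor1_end",
    "anchor2_start",
    "anchor2_end",
    "summit_x",
    "summit_y",
    "summit_z",
    "n_bins",
    "separation",
    "label",
]


def write_calls_tsv(calls: list[InteractionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.anchor_1.chrom,
                        c.anchor_1.start,
                        c.anchor_1.end,
                        c.anchor_2.start,
                        c.anchor_2.end,
                        int(c.summit[0]),
                        int(c.summit[1]),
                        f"{c.summit[2]:.6g}",
                        c.n_bins,
                        int(c.separation),
                        c.label or ".",
                    )
                )
                + "\n"
            )


def write_calls_bedpe(calls: list[InteractionCall], path) -> None:
    """Interaction calls as BEDPE for genome-browser loading."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.anchor_1.chrom}\t{c.anchor_1.start}\t{c.anchor_1.end}"
                f"\t{c.anchor_2.chrom}\t{c.anchor_2.start}\t{c.anchor_2.end}"
                f"\t{c.label or '.'}\t{c.summit[2]:.6g}\t+\t+\n"
            )


def write_joint_table(joint: JointTable, path) -> None:
    """Joint probabilities with marginals appended as a final row/column."""
    df = joint.to_frame()
    df["marginal"] = joint.marginal_a
    bottom = pd.DataFrame(
        [list(joint.marginal_b) + [1.0]], index=["marginal"], columns=df.columns
    )
    out = pd.concat([df, bottom])
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(str(c) for c in out.columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, float_format="%.6g")


def write_matrix(matrix: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("#species\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        matrix.to_csv(fh, sep="\t", header=False, float_format="%.6g")
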