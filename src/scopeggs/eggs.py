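"""EGGS — Entropy of Gene Group Shuffling.

Quantifies inter-chromosomal gene shuffling between two species from the
chromosome assignments of their single-copy orthologs (SCOs).  Counting the
SCOs on every inter-species chromosome pair (plus a small pseudo-count)
yields a joint probability table; its Shannon entropy, normalized between
the minimum achievable entropy (perfectly conserved chromosomal gene sets)
and the maximum (fully shuffled, i.e. independence of the two marginal
distributions), gives the Min–Max Normalized Entropy:

    MMNE = (H_obs − H_min) / (H_max − H_min)

with H_min = (H(A) + H(B)) / 2 and H_max = H(A) + H(B), the entropy of the
product-of-marginals table.  MMNE = 0 for a species compared to itself
(before pseudo-counting), MMNE = 1 for complete independence.  Equivalently
MMNE = 1 − 2·MI(A;B)/(H(A)+H(B)), one minus a normalized mutual information.

Entropies are in bits (log base 2) with the 0·log2(0) = 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import DegenerateComparisonError, ScopeggsError

__all__ = [
    "ScoTable",
    "JointTable",
    "EntropyDecomposition",
    "build_joint_table",
    "entropy",
    "mmne",
    "pairwise_mmne_matrix",
    "mmne_matrix_from_assignments",
    "cluster_mmne_matrix",
    "linkage_to_newick",
    "counterpart_map",
]

DEFAULT_PSEUDO_COUNT = 0.1


@dataclass
class ScoTable:
    """Per-orthogroup chromosome assignments for a pair of species.

    Only SCOs placed on chromosome-scale sequences belong here; rows on
    unplaced contigs must be removed upstream.
    """

    species_a: str
    species_b: str
    rows: pd.DataFrame  # columns: ortho_id, chrom_a, chrom_b
    labels_a: list[str] | None = None
    labels_b: list[str] | None = None

    def __post_init__(self):
        required = {"ortho_id", "chrom_a", "chrom_b"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ScopeggsError(f"SCO table missing columns: {sorted(missing)}")
        if self.rows["ortho_id"].duplicated().any():
            dup = self.rows["ortho_id"][self.rows["ortho_id"].duplicated()].iloc[0]
            raise ScopeggsError(f"duplicate ortho_id in SCO table: {dup!r}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class JointTable:
    """Pseudo-counted joint/marginal SCO probability tables.

    ``counts`` includes the pseudo-count in every cell; ``raw_counts`` holds
    the observed integer counts (used for counterpart percentages).
    Marginals are exact row/column sums of ``joint_probs``.
    """

    labels_a: list[str]
    labels_b: list[str]
    counts: np.ndarray
    raw_counts: np.ndarray
    pseudo_count: float
    joint_probs: np.ndarray = field(init=False)
    marginal_a: np.ndarray = field(init=False)
    marginal_b: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        if self.counts.shape != (len(self.labels_a), len(self.labels_b)):
            raise ScopeggsError("counts shape does not match chromosome labels")
        if np.any(self.counts < 0):
            raise ScopeggsError("negative counts in joint table")
        total = self.counts.sum()
        if total <= 0:
            raise ScopeggsError("joint table has zero total count")
        self.joint_probs = self.counts / total
        self.marginal_a = self.joint_probs.sum(axis=1)
        self.marginal_b = self.joint_probs.sum(axis=0)

    def transposed(self) -> "JointTable":
        return JointTable(
            labels_a=list(self.labels_b),
            labels_b=list(self.labels_a),
            counts=self.counts.T.copy(),
            raw_counts=self.raw_counts.T.copy(),
            pseudo_count=self.pseudo_count,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.joint_probs, index=self.labels_a, columns=self.labels_b)


@dataclass(frozen=True)
class EntropyDecomposition:
    """Observed / minimum / maximum entropies (bits) and the MMNE score."""

    h_obs: float
    h_min: float
    h_max: float
    mmne: float


def entropy(probs, atol: float = 1e-6) -> float:
    """Shannon entropy in bits, −Σ p·log2(p), with 0·log2(0) = 0.

    ``probs`` may be a vector or matrix; entries must be non-negative and
    sum to 1 within ``atol``.
    """
    p = np.asarray(probs, dtype=float).ravel()
    if np.any(p < 0):
        raise ScopeggsError("entropy: negative probabilities")
    s = p.sum()
    if abs(s - 1.0) > atol:
        raise ScopeggsError(f"entropy: probabilities sum to {s!r}, not 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def build_joint_table(
    sco: ScoTable,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    arm_merge: dict[str, str] | None = None,
) -> JointTable:
    """Count SCOs on every inter-species chromosome pair and pseudo-count.

    ``arm_merge`` maps arm labels to merged chromosome labels (e.g.
    ``{"2L": "2", "2R": "2"}``) and is applied to both species' labels
    before counting, so left/right arm counts are summed.
    """
    if len(sco) == 0:
        raise ScopeggsError("empty SCO table")
    if pseudo_count < 0:
        raise ScopeggsError("pseudo_count must be >= 0")
    arm_merge = arm_merge or {}

    def merge_labels(labels):
        return None if labels is None else list(dict.fromkeys(arm_merge.get(l, l) for l in labels))

    ca = sco.rows["chrom_a"].map(lambda l: arm_merge.get(l, l))
    cb = sco.rows["chrom_b"].map(lambda l: arm_merge.get(l, l))
    labels_a = merge_labels(sco.labels_a) or sorted(ca.unique())
    labels_b = merge_labels(sco.labels_b) or sorted(cb.unique())
    unknown_a = set(ca) - set(labels_a)
    unknown_b = set(cb) - set(labels_b)
    if unknown_a or unknown_b:
        raise ScopeggsError(
            f"unknown chromosome labels: {sorted(unknown_a | unknown_b)}"
        )
    raw = (
        pd.crosstab(ca, cb)
        .reindex(index=labels_a, columns=labels_b, fill_value=0)
        .to_numpy(dtype=float)
    )
    return JointTable(
        labels_a=labels_a,
        labels_b=labels_b,
        counts=raw + pseudo_count,
        raw_counts=raw,
        pseudo_count=pseudo_count,
    )


def mmne(joint: JointTable) -> EntropyDecomposition:
    """Min–Max Normalized Entropy of a joint SCO probability table.

    h_min is the mean of the two marginal entropies; h_max is the entropy
    of the product-of-marginals (independence) table.  Raises
    :class:`DegenerateComparisonError` when h_max == h_min (single-chromosome
    comparison), where the score is 0/0.
    """
    h_obs = entropy(joint.joint_probs)
    h_a = entropy(joint.marginal_a)
    h_b = entropy(joint.marginal_b)
    h_min = (h_a + h_b) / 2.0
    h_max = entropy(np.outer(joint.marginal_a, joint.marginal_b))
    if h_max - h_min < 1e-12:
        raise DegenerateComparisonError(
            "MMNE undefined: maximum and minimum entropy coincide "
            "(fewer than 2 chromosomes in a species?)"
        )
    score = (h_obs - h_min) / (h_max - h_min)
    return EntropyDecomposition(h_obs=h_obs, h_min=h_min, h_max=h_max, mmne=score)


def pairwise_mmne_matrix(
    tables: dict[tuple[str, str], JointTable],
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Symmetric species × species matrix of MMNE scores.

    ``tables`` must hold a JointTable for every unordered species pair,
    including self-pairs (a species' SCO assignments against itself).  A
    missing (a, b) key falls back to the transposed (b, a) table.
    """
    if species is None:
        species = sorted({s for pair in tables for s in pair})
    n = len(species)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(species):
        for j, b in enumerate(species[i:], start=i):
            if (a, b) in tables:
                jt = tables[(a, b)]
            elif (b, a) in tables:
                jt = tables[(b, a)].transposed()
            else:
                raise ScopeggsError(f"missing joint table for species pair ({a}, {b})")
            score = mmne(jt).mmne
            mat[i, j] = mat[j, i] = score
    return pd.DataFrame(mat, index=species, columns=species)


def mmne_matrix_from_assignments(
    assignments: pd.DataFrame,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> pd.DataFrame:
    """MMNE matrix from a per-SCO chromosome-assignment table.

    ``assignments`` has one row per SCO and one column per species holding
    that SCO's chromosome label in the species.  Convenience front end to
    :func:`pairwise_mmne_matrix`; self-pairs compare a column to itself.
    """
    species = list(assignments.columns)
    tables: dict[tuple[str, str], JointTable] = {}
    for i, a in enumerate(species):
        for b in species[i:]:
            rows = pd.DataFrame(
                {
                    "ortho_id": [f"og{k}" for k in range(len(assignments))],
                    "chrom_a": assignments[a].to_numpy(),
                    "chrom_b": assignments[b].to_numpy(),
                }
            )
            tables[(a, b)] = build_joint_table(
                ScoTable(a, b, rows), pseudo_count=pseudo_count
            )
    return pairwise_mmne_matrix(tables, species=species)


def cluster_mmne_matrix(matrix, linkage: str = "average") -> tuple[np.ndarray, list[str]]:
    """Hierarchically cluster species treating MMNE as a distance.

    Returns the scipy linkage matrix and the leaf labels.  The diagonal is
    forced to zero (self-comparison MMNE is ~1e−4 with pseudo-counts, not
    exactly 0) and the matrix must be symmetric to 1e−8.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(l) for l in matrix.index]
        mat = matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(matrix, dtype=float)
        labels = [f"s{i}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ScopeggsError("MMNE matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ScopeggsError("MMNE matrix must be symmetric")
    if mat.shape[0] == 1:
        return np.empty((0, 4)), labels
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    condensed = ssd.squareform(mat, checks=False)
    return sch.linkage(condensed, method=linkage), labels


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    if len(link) == 0:
        return f"{labels[0]};" if labels else ";"
    tree = sch.to_tree(link)

    def render(node, parent_dist):
        bl = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def counterpart_map(
    joint: JointTable, report_threshold: float = 20.0
) -> dict[str, list[tuple[str, float]]]:
    """Counterpart chromosomes: per source chromosome, the target
    chromosome(s) carrying the highest percentages of its SCOs.

    Percentages use the raw (non-pseudo-counted) counts.  The top target is
    always reported, plus any further targets at or above
    ``report_threshold`` percent, ranked descending; ties broken by the
    declared target-label order.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for i, src in enumerate(joint.labels_a):
        row = joint.raw_counts[i]
        total = row.sum()
        if total <= 0:
            raise ScopeggsError(f"source chromosome {src!r} has zero SCOs")
        pct = 100.0 * row / total
        order = sorted(range(len(pct)), key=lambda j: (-pct[j], j))
        ranked = [(joint.labels_b[j], float(pct[j])) for j in order]
        kept = [ranked[0]] + [t for t in ranked[1:] if t[1] >= report_threshold]
        out[src] = kept
    return out
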