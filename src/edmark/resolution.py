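"""Taxonomic resolution of an amplified region.

Given aligned amplicon sequences this module quantifies how well they
separate taxa: raw nucleotide-difference counts, uncorrected p-distances,
Kimura two-parameter (K2P) distances, neighbor-joining trees with
site-bootstrap support, and an ambiguity report listing taxon pairs that an
identity-threshold assignment could not tell apart.

Gap handling follows the two standard conventions.  ``complete`` deletion
drops every alignment column containing a gap in *any* sequence before
anything else is computed (the convention used for the K2P/NJ analysis);
``pairwise`` deletion drops, per pair, only the columns gapped in either of
the two sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import GAP, ReferencePanel, SeqRecord

_TRANSITIONS = ({"A", "G"}, {"C", "T"})


class SaturationError(ValueError):
    """K2P distance undefined: substitution saturation (domain violation)."""


def _as_records(seqs) -> list[SeqRecord]:
    if isinstance(seqs, ReferencePanel):
        return list(seqs.records)
    return list(seqs)


def _retained(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != GAP and y != GAP]


def _check_equal_length(a: str, b: str) -> None:
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")


def nt_differences(a: str, b: str, gap_mode: str = "pairwise") -> int:
    """Hamming count over columns retained under the gap mode.

    For a single pair, complete and pairwise deletion retain the same
    columns; the distinction matters at matrix level (see
    :func:`distance_matrix`).
    """
    _check_equal_length(a, b)
    a, b = a.upper(), b.upper()
    return sum(1 for i in _retained(a, b) if a[i] != b[i])


def p_distance(a: str, b: str, gap_mode: str = "pairwise") -> float:
    """Proportion of differing sites among retained columns."""
    _check_equal_length(a, b)
    a, b = a.upper(), b.upper()
    idx = _retained(a, b)
    if not idx:
        raise ValueError("no retained columns (all gapped)")
    return sum(1 for i in idx if a[i] != b[i]) / len(idx)


def k2p_distance(a: str, b: str, gap_mode: str = "pairwise") -> float:
    """Kimura two-parameter distance: d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)
    with P the transition and Q the transversion proportion.
    """
    _check_equal_length(a, b)
    a, b = a.upper(), b.upper()
    idx = _retained(a, b)
    if not idx:
        raise ValueError("no retained columns (all gapped)")
    ts = tv = 0
    for i in idx:
        x, y = a[i], b[i]
        if x == y:
            continue
        if {x, y} in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    p = ts / len(idx)
    q = tv / len(idx)
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: 1-2P-Q={w1:.4f}, 1-2Q={w2:.4f} (saturation)"
        )
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


_PAIRWISE_FNS = {
    "p": p_distance,
    "k2p": k2p_distance,
    "diffs": nt_differences,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with provenance."""

    labels: list[str]
    data: np.ndarray
    model: str          # 'p' | 'k2p' | 'diffs'
    gap_mode: str       # 'complete' | 'pairwise'

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.data < 0).any() or not np.isfinite(self.data).all():
            raise ValueError("distances must be finite and non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])

    def summary(self) -> dict[str, float]:
        """min / mean / max over off-diagonal pairs."""
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.data[iu]
        return {
            "min": float(vals.min()),
            "mean": float(vals.mean()),
            "max": float(vals.max()),
        }

    def between_group_summary(self, group_a: list[str], group_b: list[str]) -> dict[str, float]:
        """min / mean / max over pairs with one member in each group."""
        ia = [self.labels.index(x) for x in group_a]
        ib = [self.labels.index(x) for x in group_b]
        vals = self.data[np.ix_(ia, ib)].ravel()
        return {
            "min": float(vals.min()),
            "mean": float(vals.mean()),
            "max": float(vals.max()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)


def complete_deletion(seqs: list[str]) -> list[str]:
    """Drop every column gapped in any sequence."""
    if not seqs:
        return []
    keep = [
        j for j in range(len(seqs[0]))
        if all(s[j] != GAP for s in seqs)
    ]
    return ["".join(s[j] for j in keep) for s in seqs]


def distance_matrix(seqs, model: str = "p", gap_mode: str = "complete") -> DistanceMatrix:
    """Full pairwise matrix over aligned sequences.

    ``seqs`` is a :class:`~edmark.seqio.ReferencePanel` or a list of
    :class:`~edmark.seqio.SeqRecord`.
    """
    records = _as_records(seqs)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    if model not in _PAIRWISE_FNS:
        raise ValueError(f"unknown model {model!r}")
    if gap_mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    labels = [r.id for r in records]
    strings = [r.seq.upper() for r in records]
    lengths = {len(s) for s in strings}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    if gap_mode == "complete":
        strings = complete_deletion(strings)
    fn = _PAIRWISE_FNS[model]
    n = len(strings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(strings[i], strings[j])
    return DistanceMatrix(labels=labels, data=d, model=model, gap_mode=gap_mode)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(matrix: DistanceMatrix):
    """Classical Saitou-Nei neighbor joining, deterministic.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label, label) pair, where an internal node inherits the smallest leaf
    label in its subtree.  Negative branch lengths are clamped to zero with
    the deficit transferred to the sister branch, so path lengths through
    the joined pair are preserved.  Returns an unrooted tree as a
    ``skbio.TreeNode`` with a trifurcating root.
    """
    from skbio import TreeNode

    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = matrix.data.astype(float).copy()
    nodes = [TreeNode(name=lbl) for lbl in matrix.labels]
    keys = list(matrix.labels)  # tie-break key: smallest leaf label in clade

    def join(i: int, j: int) -> None:
        nonlocal d, nodes, keys
        m = len(nodes)
        r = d.sum(axis=1)
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = d[i, j] - vi
        # clamp negatives, moving the deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vj = max(vj, 0.0)
        a, b = nodes[i], nodes[j]
        a.length = float(vi)
        b.length = float(vj)
        parent = TreeNode(children=[a, b])
        new_d = np.zeros((m - 1, m - 1))
        rest = [k for k in range(m) if k not in (i, j)]
        for x, kx in enumerate(rest):
            for y, ky in enumerate(rest):
                new_d[x, y] = d[kx, ky]
            new_d[x, m - 2] = new_d[m - 2, x] = 0.5 * (
                d[kx, i] + d[kx, j] - d[i, j]
            )
        d = np.maximum(new_d, 0.0)
        nodes = [nodes[k] for k in rest] + [parent]
        keys = [keys[k] for k in rest] + [min(keys[i], keys[j])]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (round(q, 10), *sorted((keys[i], keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        join(best[1], best[2])

    # final three nodes: resolve the star exactly
    from skbio import TreeNode as _TN

    (na, nb, nc) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in ((na, la), (nb, lb), (nc, lc)):
        node.length = float(max(length, 0.0))
    return _TN(children=[na, nb, nc])


def bipartitions(tree, labels: list[str] | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of a tree as canonical frozensets.

    Each internal edge splits the leaves in two; the side *not* containing
    the reference leaf (the smallest label) is stored, so the set is
    comparable across differently rooted representations.
    """
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = frozenset(leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(clade) > len(leaves) - 2:
            continue
        side = clade if ref not in clade else full - clade
        out.add(side)
    return out


def bootstrap_supports(
    seqs,
    model: str = "k2p",
    gap_mode: str = "complete",
    replicates: int = 300,
    seed: int = 0,
):
    """NJ tree on the full alignment with per-edge bootstrap support.

    Alignment columns are resampled with replacement ``replicates`` times
    (seed-controlled); each internal edge of the full-data tree is annotated
    with the percentage of replicate trees containing the same bipartition
    (stored as ``node.support`` and as the internal node name).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    records = _as_records(seqs)
    if len(records) < 4:
        raise ValueError("bootstrap supports need >= 4 taxa (internal edges)")
    labels = [r.id for r in records]
    strings = [r.seq.upper() for r in records]
    if gap_mode == "complete":
        strings = complete_deletion(strings)
    cols = np.array([list(s) for s in strings])  # taxa x sites
    n_sites = cols.shape[1]

    def tree_from(site_cols: np.ndarray):
        sub = ["".join(row) for row in site_cols]
        recs = [SeqRecord(id=l, seq=s) for l, s in zip(labels, sub)]
        dm = distance_matrix(recs, model=model, gap_mode="pairwise")
        return nj_tree(dm)

    main = tree_from(cols)
    main_bips = {}
    ref = sorted(labels)[0]
    full = frozenset(labels)
    for node in main.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(clade) > len(labels) - 2:
            continue
        side = clade if ref not in clade else full - clade
        main_bips[id(node)] = side

    counts: dict[frozenset, int] = {b: 0 for b in main_bips.values()}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        idx = rng.integers(0, n_sites, size=n_sites)
        rep = tree_from(cols[:, idx])
        rep_bips = bipartitions(rep)
        for b in counts:
            if b in rep_bips:
                counts[b] += 1

    for node in main.non_tips(include_self=False):
        key = id(node)
        if key in main_bips:
            support = 100.0 * counts[main_bips[key]] / replicates
            node.support = support
            node.name = f"{support:.0f}"
    return main


# ---------------------------------------------------------------------------
# Ambiguity report
# ---------------------------------------------------------------------------


@dataclass
class ResolutionReport:
    pairs: pd.DataFrame          # one row per sequence pair
    summary: dict[str, float]    # min/mean/max difference counts
    tolerance: int

    @property
    def ambiguous_pairs(self) -> pd.DataFrame:
        return self.pairs[self.pairs["ambiguous"]]


def resolution_report(
    diff_matrix: DistanceMatrix,
    taxonomy: dict[str, str] | None = None,
    assignment_tolerance: int = 2,
) -> ResolutionReport:
    """Flag sequence pairs an identity threshold cannot distinguish.

    A pair whose nucleotide-difference count is at or below
    ``assignment_tolerance`` is ambiguous at that tolerance: reads from one
    member can be assigned to the other.
    """
    if diff_matrix.model != "diffs":
        raise ValueError("resolution_report expects a 'diffs' matrix")
    taxonomy = taxonomy or {}
    rows = []
    labels = diff_matrix.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diffs = int(round(diff_matrix.data[i, j]))
            rows.append(
                {
                    "id_a": labels[i],
                    "id_b": labels[j],
                    "taxon_a": taxonomy.get(labels[i], labels[i]),
                    "taxon_b": taxonomy.get(labels[j], labels[j]),
                    "diffs": diffs,
                    "ambiguous": diffs <= assignment_tolerance,
                }
            )
    pairs = pd.DataFrame(rows)
    return ResolutionReport(
        pairs=pairs,
        summary={
            "min": float(pairs["diffs"].min()),
            "mean": float(pairs["diffs"].mean()),
            "max": float(pairs["diffs"].max()),
        },
        tolerance=assignment_tolerance,
    )
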