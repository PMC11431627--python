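"""Pairwise global alignment identity and neighbor-joining phylogenetics.

Whole-plasmid relatedness is summarized by pairwise global nucleotide
identity (affine gap costs; identity = matches / aligned columns excluding
terminal overhangs) and by an unrooted neighbor-joining tree built from
p-distances (1 - identity), with bootstrap support computed by resampling
the columns of the induced pairwise alignments.

NJ is the canonical Saitou–Nei agglomeration with the Studier–Keppler
Q-criterion; on an additive distance matrix it recovers the generating
topology and branch lengths exactly.  Negative branch-length estimates are
clamped to zero (noted on the node).  Trees serialize to Newick with
bootstrap support stored as internal node labels, via scikit-bio's
TreeNode, so round-trips are lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from .circular import CircularSequence, revcomp

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    identity: float
    matches: int
    columns: int
    params: dict = field(default_factory=dict)


DEFAULT_SCORES = {"match": 2, "mismatch": -3, "gap_open": 12, "gap_extend": 1}


def _nt_aligner(scores=DEFAULT_SCORES) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = scores["match"]
    aligner.mismatch_score = scores["mismatch"]
    aligner.open_gap_score = -scores["gap_open"]
    aligner.extend_gap_score = -scores["gap_extend"]
    aligner.mode = "global"
    return aligner


def percent_identity(
    a: str | CircularSequence,
    b: str | CircularSequence,
    circular: bool = False,
    scores=DEFAULT_SCORES,
) -> PairwiseAlignment:
    """Global-alignment identity between two nucleotide sequences.

    When ``circular``, ``b`` is first rotated (and strand-flipped if that
    fits better) so that it starts at the region most similar to the start
    of ``a``, making the comparison rotation-invariant.
    """
    sa = a.seq if isinstance(a, CircularSequence) else str(a).upper()
    sb = b.seq if isinstance(b, CircularSequence) else str(b).upper()
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    for s in (sa, sb):
        bad = set(s) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)}")
    if circular:
        sb = _rotate_to_start(sa, sb)
    aligner = _nt_aligner(scores)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    lead = 0
    while lead < len(ga) and (ga[lead] == "-" or gb[lead] == "-"):
        lead += 1
    tail = len(ga)
    while tail > lead and (ga[tail - 1] == "-" or gb[tail - 1] == "-"):
        tail -= 1
    cols = tail - lead
    matches = sum(1 for i in range(lead, tail) if ga[i] == gb[i] and ga[i] != "-")
    identity = matches / cols if cols else 0.0
    return PairwiseAlignment(ga, gb, identity, matches, cols, dict(scores))


def _rotate_to_start(sa: str, sb: str, probe: int = 200) -> str:
    """Rotate/flip circular sequence b to start where a starts."""
    import edlib

    probe_seq = sa[: min(probe, len(sa))]
    best = None
    for cand in (sb, revcomp(sb)):
        res = edlib.align(probe_seq, cand + cand, mode="HW", task="locations")
        if res["editDistance"] >= 0 and res["locations"]:
            key = (res["editDistance"], cand != sb)
            if best is None or key < best[0]:
                off = res["locations"][0][0] % len(sb)
                best = (key, cand[off:] + cand[:off])
    return best[1] if best else sb


# ---------------------------------------------------------------- NJ


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    root: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    def to_newick(self) -> str:
        buf = StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, s: str) -> "PhyloTree":
        return cls(TreeNode.read(StringIO(s)))

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.root)

    def path_distances(self) -> DistanceMatrix:
        return self.root.tip_tip_distances()


def _bipartitions(root: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each identified by its smaller leaf side."""
    all_tips = frozenset(t.name for t in root.tips())
    parts = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            other = all_tips - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ with the Studier–Keppler Q-matrix.

    Returns an unrooted tree written as a trifurcating root.  Negative
    branch-length estimates are clamped to 0 and the node is annotated
    with ``clamped=True``.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=i) for i in ids]
    active = list(range(n))

    def clamp(node, length):
        if length < -1e-12:
            node.clamped = True
            return 0.0
        return max(length, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        na, nb = nodes[ai], nodes[aj]
        na.length = clamp(na, li)
        nb.length = clamp(nb, lj)
        parent.extend([na, nb])
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d
        d[:-1, -1] = new_d
        d[-1, -1] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = TreeNode()
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = clamp(nodes[idx], length)
        root.append(nodes[idx])
    return root


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("inf")
    return -0.75 * math.log(1 - 4 * p / 3)


def distances_from_sequences(
    sequences: dict[str, str], circular: bool = False, correction: Optional[str] = None
) -> tuple[DistanceMatrix, dict]:
    """p-distance matrix (1 - pairwise identity) plus the cached alignments."""
    names = sorted(sequences)
    n = len(names)
    mat = np.zeros((n, n))
    alignments = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = percent_identity(sequences[names[i]], sequences[names[j]], circular=circular)
            p = 1 - aln.identity
            if correction == "jc":
                p = jukes_cantor(p)
            mat[i, j] = mat[j, i] = p
            alignments[(names[i], names[j])] = aln
    return DistanceMatrix(mat, names), alignments


def nj_tree(
    data: DistanceMatrix | dict,
    bootstrap_n: int = 0,
    seed: int = 0,
    circular: bool = False,
    correction: Optional[str] = None,
) -> PhyloTree:
    """NJ tree from a distance matrix or a named sequence set.

    With sequences and ``bootstrap_n > 0``, support for each internal
    bipartition is the fraction of replicate trees (columns of every
    induced pairwise alignment resampled with replacement) containing it;
    supports are attached as internal node labels.  Deterministic given
    ``seed``.
    """
    alignments = None
    if isinstance(data, DistanceMatrix):
        dm = data
        asym = np.abs(dm.data - dm.data.T).max()
        if asym > 1e-9:
            raise ValueError(f"distance matrix asymmetric beyond tolerance: {asym:g}")
    else:
        dm, alignments = distances_from_sequences(data, circular=circular, correction=correction)
    root = neighbor_joining(dm)
    tree = PhyloTree(root)
    if bootstrap_n > 0:
        if alignments is None:
            raise ValueError("bootstrap requires sequences, not a bare distance matrix")
        tree.supports = _bootstrap_supports(dm.ids, alignments, bootstrap_n, seed, correction)
        _attach_supports(root, tree.supports)
    return tree


def _pair_match_vector(aln: PairwiseAlignment) -> np.ndarray:
    ga, gb = aln.aligned_a, aln.aligned_b
    lead = 0
    while lead < len(ga) and (ga[lead] == "-" or gb[lead] == "-"):
        lead += 1
    tail = len(ga)
    while tail > lead and (ga[tail - 1] == "-" or gb[tail - 1] == "-"):
        tail -= 1
    return np.array([ga[i] == gb[i] and ga[i] != "-" for i in range(lead, tail)], dtype=bool)


def _bootstrap_supports(ids, alignments, n_reps, seed, correction) -> dict[frozenset, float]:
    ids = list(ids)
    n = len(ids)
    rng = np.random.default_rng(seed)
    vectors = {k: _pair_match_vector(a) for k, a in alignments.items()}
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        mat = np.zeros((n, n))
        for (na, nb), vec in vectors.items():
            cols = rng.integers(0, vec.size, size=vec.size)
            p = 1 - vec[cols].mean()
            if correction == "jc":
                p = jukes_cantor(p)
            i, j = ids.index(na), ids.index(nb)
            mat[i, j] = mat[j, i] = p
        root = neighbor_joining(DistanceMatrix(mat, ids))
        for part in _bipartitions(root):
            counts[part] = counts.get(part, 0) + 1
    return {part: c / n_reps for part, c in counts.items()}


def _attach_supports(root: TreeNode, supports: dict[frozenset, float]):
    all_tips = frozenset(t.name for t in root.tips())
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        if key in supports:
            node.name = f"{100 * supports[key]:.0f}"


def write_phylip_distances(path, dm: DistanceMatrix):
    lines = [str(len(dm.ids))]
    for name in dm.ids:
        row = "\t".join(f"{dm[name, other]:.6f}" for other in dm.ids)
        lines.append(f"{name}\t{row}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
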