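"""Percent-identity analyses, MLST scheme concatenation, and distance trees.

Pairwise identity is computed from a Needleman–Wunsch global alignment
(match +1, mismatch −1, gap −2 by default; Biopython's C aligner underneath).
Identity counts singly-gapped columns as mismatches and excludes
doubly-gapped columns from the denominator (the "alignment length"
convention). Species discrimination trees are neighbor joining on raw
p-distance; leaf coordinates in reports are 1-based inclusive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from .errors import MarkerscanError, UndefinedStatisticError
from .seqio import StrainPanel

logger = logging.getLogger(__name__)

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@dataclass(frozen=True)
class MLSTScheme:
    """A named, ordered list of housekeeping loci to concatenate."""

    name: str
    gene_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_order:
            raise MarkerscanError(f"scheme {self.name!r} has an empty gene order")
        if len(set(self.gene_order)) != len(self.gene_order):
            raise MarkerscanError(f"scheme {self.name!r} has duplicate loci")


# The five bundled schemes. The published L1 and S1 orders abbreviate some
# locus names (ptA, pur, tpi); they are normalized here to the canonical
# housekeeping-gene names so the schemes resolve against any panel.
BUILTIN_SCHEMES: dict[str, MLSTScheme] = {
    s.name: s
    for s in [
        MLSTScheme("pubMLST", ("glpF", "ilvD", "pta", "purH", "pycA", "rpoD", "tpiA")),
        MLSTScheme("S1", ("rpoD", "glpF", "ilvD", "pta", "tpiA", "pycA", "purH")),
        MLSTScheme(
            "S2", ("gyrA", "gyrB", "purH", "glpF", "pycA", "ilvD", "rpoD", "tpiA", "pta")
        ),
        MLSTScheme("S3", ("gyrB", "adk", "pycA", "pyrE", "sucC", "mutL", "aroE")),
        MLSTScheme(
            "L1", ("adk", "ccpA", "glpF", "gmk", "ilvD", "purH", "spo0A", "tpiA")
        ),
    ]
}


def load_scheme(path: str | Path) -> MLSTScheme:
    """Read a scheme definition from JSON ({"name": ..., "gene_order": [...]})."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return MLSTScheme(name=data["name"], gene_order=tuple(data["gene_order"]))


def save_scheme(scheme: MLSTScheme, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"name": scheme.name, "gene_order": list(scheme.gene_order)}, indent=2)
        + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Alignment and identity
# ---------------------------------------------------------------------------


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def global_align(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> tuple[str, str, float]:
    """Optimal Needleman–Wunsch global alignment (linear gap penalty).

    Returns the two aligned strings (gaps as '-') and the optimal score.
    Among co-optimal alignments the aligner's first reported traceback is
    returned, which is deterministic for fixed inputs.
    """
    if not a or not b:
        raise MarkerscanError("global_align requires two non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    return aln[0], aln[1], float(aln.score)


def percent_identity(a: str, b: str, **align_kwargs: float) -> float:
    """Percent identity over the global alignment: 100 × matched columns /
    alignment columns (doubly-gapped columns excluded; singly-gapped columns
    count as mismatches)."""
    if a == b:
        return 100.0
    aa, bb, _ = global_align(a, b, **align_kwargs)
    x = np.frombuffer(aa.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(bb.encode("ascii"), dtype=np.uint8)
    gap = ord("-")
    both_gap = (x == gap) & (y == gap)
    cols = int((~both_gap).sum())
    matches = int(((x == y) & ~both_gap & (x != gap)).sum())
    return 100.0 * matches / cols


def polymorphic_sites_vs_reference(seq: str, ref: str, **align_kwargs: float) -> int:
    """Number of aligned columns where both characters are in {A,C,G,T} and
    differ (gaps and ambiguous bases not counted)."""
    if seq == ref:
        return 0
    aa, bb, _ = global_align(seq, ref, **align_kwargs)
    x = np.frombuffer(aa.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(bb.encode("ascii"), dtype=np.uint8)
    acgt = np.zeros(256, dtype=bool)
    for c in "ACGT":
        acgt[ord(c)] = True
    return int((acgt[x] & acgt[y] & (x != y)).sum())


# ---------------------------------------------------------------------------
# Concatenation and distances
# ---------------------------------------------------------------------------


def concatenate_scheme(panel: StrainPanel, scheme: MLSTScheme) -> dict[str, str]:
    """Concatenate each strain's locus sequences in exact scheme order.

    Strains missing any scheme locus are excluded with a warning; a scheme
    locus entirely absent from the panel raises.
    """
    absent = [loc for loc in scheme.gene_order if loc not in panel.loci]
    if absent:
        raise MarkerscanError(
            f"scheme {scheme.name!r}: loci {absent} absent from the panel"
        )
    out: dict[str, str] = {}
    for sid in panel.strain_ids:
        if all(panel.has_cell(sid, loc) for loc in scheme.gene_order):
            out[sid] = "".join(
                panel.sequences[(sid, loc)].seq for loc in scheme.gene_order
            )
        else:
            logger.warning(
                "strain %s lacks loci for scheme %s; excluded", sid, scheme.name
            )
    return out


def p_distance_matrix(seqs: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances: proportion of differing sites over sites where
    both sequences have a base in {A,C,G,T}. Requires equal lengths."""
    labels = list(seqs)
    if len(labels) < 2:
        raise UndefinedStatisticError("p-distance needs ≥2 sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise MarkerscanError(f"unequal sequence lengths: {sorted(lengths)}")
    mat = np.empty((len(labels), lengths.pop()), dtype=np.uint8)
    for i, s in enumerate(seqs.values()):
        mat[i] = np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)
    acgt = np.zeros(256, dtype=bool)
    for c in "ACGT":
        acgt[ord(c)] = True
    valid = acgt[mat]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise UndefinedStatisticError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            d[i, j] = d[j, i] = int((mat[i][both] != mat[j][both]).sum()) / m
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the smallest (i, j) pair in current node order
    (input label order). Negative branch lengths are clamped to zero with
    the deficit transferred to the sister branch, preserving the path length
    between the joined pair. For fewer than 3 taxa a trivial tree is
    returned with a warning.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 2:
        raise UndefinedStatisticError("neighbor joining needs ≥2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    if n == 2:
        logger.warning("neighbor joining on 2 taxa: returning a single edge")
        half = dm.data[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        return root

    d = dm.data.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first argmin in row-major order == smallest (i, j) in node order
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        ni, nj = nodes[active[i]], nodes[active[j]]
        ni.length, nj.length = float(vi), float(vj)
        parent = TreeNode(children=[ni, nj])
        # distances from the new node to the remaining taxa
        gi, gj = active[i], active[j]
        new_idx = len(nodes)
        nodes.append(parent)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (gi, gj):
                continue
            dk = 0.5 * (d[gi, k] + d[gj, k] - dij)
            d[new_idx, k] = d[k, new_idx] = dk
        active = [k for k in active if k not in (gi, gj)] + [new_idx]
        # keep join order stable: new node goes last

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        node = nodes[idx]
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


def is_monophyletic(tree: TreeNode, leaf_subset: set[str]) -> bool:
    """Whether *leaf_subset* forms a clade in some rooting of *tree*
    (i.e. an edge of the unrooted tree separates it from all other leaves)."""
    all_tips = {t.name for t in tree.tips()}
    if not leaf_subset <= all_tips:
        raise KeyError(f"unknown leaves: {sorted(leaf_subset - all_tips)}")
    if len(leaf_subset) in (1, len(all_tips)):
        return True
    complement = all_tips - leaf_subset
    for node in tree.non_tips(include_self=False):
        clade = {t.name for t in node.tips()}
        if clade == leaf_subset or clade == complement:
            return True
    return False


def tree_for_scheme(panel: StrainPanel, scheme: MLSTScheme) -> TreeNode:
    """Convenience: concatenate, compute p-distances, and build the NJ tree."""
    return neighbor_joining(p_distance_matrix(concatenate_scheme(panel, scheme)))


def tree_for_locus(panel: StrainPanel, locus: str) -> TreeNode:
    return neighbor_joining(p_distance_matrix(panel.locus_seqs(locus)))


# ---------------------------------------------------------------------------
# Species-level identity summaries
# ---------------------------------------------------------------------------


def species_identity_summary(
    panel: StrainPanel, locus: str
) -> dict[str, tuple[float, float] | None]:
    """Min/max percent identity over within-species and between-species
    strain pairs at *locus*. A range is None (NA) when no such pair exists
    (single strain per species, or a single species)."""
    seqs = panel.locus_seqs(locus)
    strains = list(seqs)
    if len({panel.species_of(s) for s in strains}) < 1 or not strains:
        raise UndefinedStatisticError(f"locus {locus!r} has no sequences")
    within: list[float] = []
    between: list[float] = []
    for i, si in enumerate(strains):
        for sj in strains[i + 1 :]:
            pid = percent_identity(seqs[si], seqs[sj])
            if panel.species_of(si) == panel.species_of(sj):
                within.append(pid)
            else:
                between.append(pid)
    return {
        "within": (min(within), max(within)) if within else None,
        "between": (min(between), max(between)) if between else None,
    }


def min_between_identity(panel: StrainPanel) -> dict[str, float]:
    """Per-locus minimum between-species identity (input to marker ranking)."""
    out: dict[str, float] = {}
    for locus in panel.loci:
        summary = species_identity_summary(panel, locus)
        rng = summary["between"]
        out[locus] = rng[0] if rng is not None else float("nan")
    return out
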