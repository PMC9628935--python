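"""Per-locus typing and selection statistics for MLST marker evaluation.

For each housekeeping locus across a strain panel this module computes the
classic marker-discrimination statistics:

* allele calling — identical sequences share an allele, distinct sequences
  never do (exact string identity after uppercasing);
* number of polymorphic sites — variable alignment columns over {A,C,G,T};
* typing efficiency TE = n_alleles / n_polymorphic_sites (genotypes per
  polymorphic site; undefined for a monomorphic locus);
* Hunter–Gaston discriminatory power
  DP = 1 − Σ_j n_j(n_j−1) / (N(N−1)),
  the probability that two randomly drawn strains carry different alleles;
* Nei–Gojobori (1986) dN/dS with Jukes–Cantor correction, averaged over all
  unordered strain pairs.

Codon bookkeeping for dN/dS is precomputed once into 64×64 tables
(pathway-averaged synonymous/nonsynonymous difference counts) so pairwise
comparisons reduce to vectorized table lookups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LengthMismatchError, UndefinedStatisticError
from .seqio import StrainPanel

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Genetic code and codon tables
# ---------------------------------------------------------------------------

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

_CODON_TABLE_RAW = {
    # standard genetic code; '*' = stop
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_AA = {c: _CODON_TABLE_RAW[c] for c in ALL_CODONS}
STOP_CODONS = frozenset(c for c, aa in CODON_AA.items() if aa == "*")


def codon_index(codon: str) -> int:
    """Encode an ACGT codon as an integer in [0, 64); −1 if any base invalid."""
    try:
        return (
            16 * _BASE_IDX[codon[0]] + 4 * _BASE_IDX[codon[1]] + _BASE_IDX[codon[2]]
        )
    except KeyError:
        return -1


def _step_is_synonymous(c1: str, c2: str) -> bool:
    """A single-base step counts synonymous iff both codons are sense codons
    translating to the same amino acid; any step involving a stop is
    nonsynonymous."""
    a1, a2 = CODON_AA[c1], CODON_AA[c2]
    return a1 == a2 and a1 != "*"


def nei_gojobori_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) for one codon.

    Each position contributes the fraction of its three single-base
    alternatives that are synonymous; changes to stop codons count as
    nonsynonymous. s + n = 3 for every sense codon. Stop or ambiguous
    codons raise :class:`UndefinedStatisticError` (callers skip them).
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASE_IDX for b in codon):
        raise UndefinedStatisticError(f"ambiguous or malformed codon {codon!r}")
    if codon in STOP_CODONS:
        raise UndefinedStatisticError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _step_is_synonymous(codon, mutant):
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) differences between two codons.

    All minimal substitution pathways (orderings of the differing positions)
    are weighted equally; steps through stop codons are allowed and counted
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _step_is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precompute per-codon site counts and 64×64 pathway-averaged
    difference-count tables."""
    s_sites = np.full(64, np.nan)
    n_sites = np.full(64, np.nan)
    valid = np.zeros(64, dtype=bool)
    for i, codon in enumerate(ALL_CODONS):
        if codon in STOP_CODONS:
            continue
        s, n = nei_gojobori_sites(codon)
        s_sites[i], n_sites[i] = s, n
        valid[i] = True
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(ALL_CODONS):
        for j, c2 in enumerate(ALL_CODONS):
            if i < j:
                sd[i, j], nd[i, j] = _pathway_counts(c1, c2)
                # pathway averaging is symmetric in the endpoints
                sd[j, i], nd[j, i] = sd[i, j], nd[i, j]
    return s_sites, n_sites, valid, sd, nd


_S_SITES, _N_SITES, _SENSE, _SD, _ND = _build_tables()


def encode_codons(seq: str) -> np.ndarray:
    """Encode a DNA string into codon indices; −1 where the codon contains a
    base outside ACGT. Trailing bases beyond the last full codon are dropped."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    ncod = len(arr) // 3
    arr = arr[: 3 * ncod]
    idx = np.full(len(arr), -1, dtype=np.int64)
    for b, v in _BASE_IDX.items():
        idx[arr == ord(b)] = v
    codons = idx.reshape(ncod, 3)
    out = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
    out[(codons < 0).any(axis=1)] = -1
    return out


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan  # saturated; correction undefined
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Nei–Gojobori (dN, dS) for one coding sequence pair.

    Codons containing N/gap in either sequence, and stop codons, are skipped
    pairwise. Proportions are Jukes–Cantor corrected; a proportion ≥ 3/4
    yields NaN for that rate (saturated).
    """
    if len(seq_a) != len(seq_b):
        raise LengthMismatchError(
            f"coding sequences differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    if len(seq_a) % 3 != 0:
        raise LengthMismatchError(f"length {len(seq_a)} is not a multiple of 3")
    ca, cb = encode_codons(seq_a), encode_codons(seq_b)
    return _dnds_from_codon_indices(ca, cb)


def _dnds_from_codon_indices(ca: np.ndarray, cb: np.ndarray) -> tuple[float, float]:
    ok = (ca >= 0) & (cb >= 0) & _SENSE[np.clip(ca, 0, 63)] & _SENSE[np.clip(cb, 0, 63)]
    ca, cb = ca[ok], cb[ok]
    if ca.size == 0:
        raise UndefinedStatisticError("no comparable codons between the two sequences")
    s_sites = 0.5 * (_S_SITES[ca] + _S_SITES[cb]).sum()
    n_sites = 3.0 * ca.size - s_sites
    sd = _SD[ca, cb].sum()
    nd = _ND[ca, cb].sum()
    ps = sd / s_sites if s_sites > 0 else math.nan
    pn = nd / n_sites if n_sites > 0 else math.nan
    return _jukes_cantor(pn), _jukes_cantor(ps)


# ---------------------------------------------------------------------------
# Allele calling and per-locus statistics
# ---------------------------------------------------------------------------


@dataclass
class AlleleTable:
    """Allele assignment for one locus: strain → allele id (1..k, contiguous,
    ordered by first occurrence of each distinct sequence)."""

    locus: str
    assignment: dict[str, int]
    counts: dict[int, int]
    N: int

    @property
    def n_alleles(self) -> int:
        return len(self.counts)


@dataclass
class LocusStats:
    """One row of the per-locus summary table (None encodes NA)."""

    locus: str
    length_bp: int
    n_alleles: int
    n_polymorphic_sites: int
    dnds: float | None
    te: float | None
    dp: float


def _check_locus_seqs(locus_seqs: dict[str, str]) -> int:
    if not locus_seqs:
        raise UndefinedStatisticError("empty locus: no sequences supplied")
    lengths = {s: len(q) for s, q in locus_seqs.items()}
    distinct = set(lengths.values())
    if len(distinct) > 1:
        detail = ", ".join(f"{s}={l}" for s, l in sorted(lengths.items()))
        raise LengthMismatchError(f"unequal sequence lengths: {detail}")
    return distinct.pop()


def call_alleles(locus_seqs: dict[str, str], locus: str = "") -> AlleleTable:
    """Assign integer allele ids by exact sequence identity.

    Ids follow first-occurrence order of each distinct sequence (iteration
    order of *locus_seqs*).
    """
    _check_locus_seqs(locus_seqs)
    allele_of_seq: dict[str, int] = {}
    assignment: dict[str, int] = {}
    counts: dict[int, int] = {}
    for strain, seq in locus_seqs.items():
        seq = seq.upper()
        if seq not in allele_of_seq:
            allele_of_seq[seq] = len(allele_of_seq) + 1
        aid = allele_of_seq[seq]
        assignment[strain] = aid
        counts[aid] = counts.get(aid, 0) + 1
    return AlleleTable(locus=locus, assignment=assignment, counts=counts, N=len(assignment))


def _seq_matrix(locus_seqs: dict[str, str]) -> np.ndarray:
    length = _check_locus_seqs(locus_seqs)
    mat = np.empty((len(locus_seqs), length), dtype=np.uint8)
    for i, seq in enumerate(locus_seqs.values()):
        mat[i] = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return mat


def count_polymorphic_sites(locus_seqs: dict[str, str]) -> int:
    """Number of columns with ≥2 distinct bases from {A,C,G,T}; columns
    containing N or '-' (or anything else) in any sequence are skipped."""
    mat = _seq_matrix(locus_seqs)
    acgt = np.zeros(256, dtype=bool)
    for b in BASES:
        acgt[ord(b)] = True
    clean = acgt[mat].all(axis=0)
    variable = (mat != mat[0]).any(axis=0)
    return int((clean & variable).sum())


def typing_efficiency(n_alleles: int, n_polymorphic_sites: int) -> float:
    """TE = genotypes per polymorphic site. Undefined for a monomorphic locus."""
    if n_polymorphic_sites < 0:
        raise ValueError("negative polymorphic-site count")
    if n_polymorphic_sites == 0:
        raise UndefinedStatisticError(
            "typing efficiency undefined: locus has no polymorphic sites"
        )
    return n_alleles / n_polymorphic_sites


def discriminatory_power(allele_table: AlleleTable) -> float:
    """Hunter–Gaston index: probability two randomly drawn strains (without
    replacement) carry different alleles."""
    n = allele_table.N
    if n < 2:
        raise UndefinedStatisticError("discriminatory power requires ≥2 strains")
    same = sum(c * (c - 1) for c in allele_table.counts.values())
    return 1.0 - same / (n * (n - 1))


def locus_dnds(locus_seqs: dict[str, str]) -> float:
    """Locus-wide dN/dS: mean dN over all unordered strain pairs divided by
    mean dS over the same pairs. Saturated pairs (undefined correction) are
    excluded and logged; a zero mean dS raises (reported upstream as NA).
    """
    length = _check_locus_seqs(locus_seqs)
    if len(locus_seqs) < 2:
        raise UndefinedStatisticError("locus dN/dS requires ≥2 sequences")
    ncod = length // 3
    if ncod == 0:
        raise UndefinedStatisticError("sequences shorter than one codon")
    encoded = {s: encode_codons(q) for s, q in locus_seqs.items()}
    strains = list(encoded)
    dns, dss = [], []
    n_excluded = 0
    for a, b in itertools.combinations(strains, 2):
        dn, ds = _dnds_from_codon_indices(encoded[a], encoded[b])
        if math.isnan(dn) or math.isnan(ds):
            n_excluded += 1
            continue
        dns.append(dn)
        dss.append(ds)
    if n_excluded:
        logger.warning("locus dN/dS: excluded %d saturated pair(s)", n_excluded)
    if not dss:
        raise UndefinedStatisticError("all pairs saturated; dN/dS undefined")
    mean_ds = sum(dss) / len(dss)
    if mean_ds == 0.0:
        raise UndefinedStatisticError("mean dS is zero; dN/dS undefined")
    return (sum(dns) / len(dns)) / mean_ds


def summarize_loci(
    panel: StrainPanel, coding_loci: set[str] | None = None
) -> list[LocusStats]:
    """One :class:`LocusStats` per panel locus, in panel locus order.

    dN/dS is computed for loci in *coding_loci* (default: all loci); loci
    where a statistic is undefined get None (NA) for that cell rather than
    aborting the summary.
    """
    out: list[LocusStats] = []
    for locus in panel.loci:
        seqs = panel.locus_seqs(locus)
        if not seqs:
            logger.warning("locus %s: no sequences; skipped", locus)
            continue
        length = len(next(iter(seqs.values())))
        table = call_alleles(seqs, locus=locus)
        n_poly = count_polymorphic_sites(seqs)
        try:
            te: float | None = typing_efficiency(table.n_alleles, n_poly)
        except UndefinedStatisticError:
            te = None
        dp = discriminatory_power(table) if table.N >= 2 else 0.0
        dnds: float | None = None
        if coding_loci is None or locus in coding_loci:
            try:
                dnds = locus_dnds(seqs)
            except UndefinedStatisticError as exc:
                logger.warning("locus %s: dN/dS undefined (%s)", locus, exc)
        out.append(
            LocusStats(
                locus=locus,
                length_bp=length,
                n_alleles=table.n_alleles,
                n_polymorphic_sites=n_poly,
                dnds=dnds,
                te=te,
                dp=dp,
            )
        )
    return out


def format_locus_table(stats: list[LocusStats]) -> pd.DataFrame:
    """Render locus statistics as a display table (TE to 3 decimals, dN/dS to
    4) with a footer row carrying the dN/dS column mean. NA cells are "NA"."""
    rows = []
    for st in stats:
        rows.append(
            {
                "locus": st.locus,
                "length_bp": st.length_bp,
                "n_alleles": st.n_alleles,
                "n_polymorphic_sites": st.n_polymorphic_sites,
                "dnds": "NA" if st.dnds is None else f"{st.dnds:.4f}",
                "te": "NA" if st.te is None else f"{st.te:.3f}",
                "dp": f"{st.dp:.3f}",
            }
        )
    dnds_values = [st.dnds for st in stats if st.dnds is not None]
    mean_cell = "NA" if not dnds_values else f"{sum(dnds_values) / len(dnds_values):.4f}"
    rows.append(
        {
            "locus": "mean",
            "length_bp": "",
            "n_alleles": "",
            "n_polymorphic_sites": "",
            "dnds": mean_cell,
            "te": "",
            "dp": "",
        }
    )
    return pd.DataFrame(rows, columns=["locus", "length_bp", "n_alleles",
                                       "n_polymorphic_sites", "dnds", "te", "dp"])


def rank_markers(
    stats: list[LocusStats], identity_summary: dict[str, float]
) -> dict[str, object]:
    """Rank loci as marker candidates.

    Ranking (a): descending polymorphic sites (ties: descending allele count,
    then locus name). Ranking (b): ascending minimum inter-species identity.
    The top locus of each ranking is flagged as a candidate marker.
    *identity_summary* maps locus → minimum between-species percent identity.
    """
    if not stats:
        raise UndefinedStatisticError("cannot rank an empty locus list")
    missing = [st.locus for st in stats if st.locus not in identity_summary]
    if missing:
        raise KeyError(f"identity summary missing loci: {missing}")
    by_poly = sorted(
        stats, key=lambda st: (-st.n_polymorphic_sites, -st.n_alleles, st.locus)
    )
    by_identity = sorted(stats, key=lambda st: (identity_summary[st.locus], st.locus))
    return {
        "by_polymorphism": [st.locus for st in by_poly],
        "by_identity": [st.locus for st in by_identity],
        "candidates": {
            "most_polymorphic": by_poly[0].locus,
            "lowest_identity": by_identity[0].locus,
        },
    }
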