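"""Species-specific primer discovery and in-silico PCR.

Annealing is modelled as ungapped Hamming matching with a hard 3'-anchor:
a primer binds wherever it has at most ``max_mismatches_per_primer``
mismatches overall and zero mismatches in its 3'-terminal
``three_prime_anchor_len`` bases. Thermodynamic duplex models are
deliberately out of scope; melting temperatures use the Wallace rule
(2·(A+T) + 4·(G+C)), which is composition-only and deterministic.

A species-specific window is a stretch that is invariant across every
target-species strain yet carries at least ``min_mismatches`` differences
against the corresponding stretch of every non-target strain, with at least
one difference in the window's 3'-terminal three positions — so a primer
laid on the window amplifies all target strains and none of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, MarkerscanError, UndefinedStatisticError
from .seqio import SeqEntry, StrainPanel, reverse_complement

MIN_PRIMER_LEN = 18
MAX_PRIMER_LEN = 30


@dataclass(frozen=True)
class Primer:
    """A 5'→3' oligonucleotide with its Wallace-rule melting temperature."""

    name: str
    seq: str
    tm: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ConfigError(f"primer {self.name!r}: degenerate/illegal bases")
        if not (MIN_PRIMER_LEN <= len(self.seq) <= MAX_PRIMER_LEN):
            raise ConfigError(
                f"primer {self.name!r}: length {len(self.seq)} outside "
                f"[{MIN_PRIMER_LEN}, {MAX_PRIMER_LEN}]"
            )
        if self.tm is None:
            object.__setattr__(self, "tm", primer_tm(self.seq))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    expected_size_bp: int | None = None

    def __post_init__(self) -> None:
        if self.expected_size_bp is not None and self.expected_size_bp < (
            len(self.forward) + len(self.reverse)
        ):
            raise ConfigError(
                "expected product size smaller than the two primer footprints"
            )


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product (1-based inclusive template coordinates,
    spanning both primer footprints)."""

    template_id: str
    start: int
    end: int
    strand: str  # strand the forward primer anneals to: '+' or '-'
    mm_forward: int
    mm_reverse: int

    @property
    def product_length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PCRParams:
    max_mismatches_per_primer: int = 2
    three_prime_anchor_len: int = 3
    min_product_len: int = 50
    max_product_len: int = 5000
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.min_product_len >= self.max_product_len:
            raise ConfigError("min product length must be below max")
        if self.three_prime_anchor_len < 0 or self.max_mismatches_per_primer < 0:
            raise ConfigError("negative PCR parameter")


def primer_tm(seq: str) -> float:
    """Wallace rule: Tm = 2·(A+T) + 4·(G+C), °C."""
    if len(seq) < 10:
        raise ConfigError(f"sequence too short for a primer Tm ({len(seq)} nt)")
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def _ascii(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _scan(template: np.ndarray, pattern: np.ndarray, max_mm: int,
          anchor_slice: slice) -> list[tuple[int, int]]:
    """All ungapped placements of *pattern* with ≤max_mm mismatches and a
    clean anchor. Returns (0-based position, mismatches)."""
    if len(template) < len(pattern):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template, len(pattern))
    diff = windows != pattern
    mm = diff.sum(axis=1)
    anchored = ~diff[:, anchor_slice].any(axis=1)
    ok = np.flatnonzero((mm <= max_mm) & anchored)
    return [(int(p), int(mm[p])) for p in ok]


def match_primer(
    template: str, primer: Primer, params: PCRParams = PCRParams()
) -> list[tuple[int, str, int]]:
    """All annealing sites of *primer* on *template*.

    Plus-strand sites match the primer sequence left-to-right (3' end on the
    right); minus-strand sites match its reverse complement (3' end on the
    left). Returns (1-based start of footprint, strand, mismatches),
    ascending by position.
    """
    if len(template) < len(primer):
        raise MarkerscanError("template shorter than primer")
    t = _ascii(template)
    anchor = params.three_prime_anchor_len
    hits: list[tuple[int, str, int]] = []
    fwd = _ascii(primer.seq)
    for pos, mm in _scan(t, fwd, params.max_mismatches_per_primer,
                         slice(len(fwd) - anchor, len(fwd)) if anchor else slice(0, 0)):
        hits.append((pos + 1, "+", mm))
    rev = _ascii(reverse_complement(primer.seq))
    for pos, mm in _scan(t, rev, params.max_mismatches_per_primer,
                         slice(0, anchor)):
        hits.append((pos + 1, "-", mm))
    return sorted(hits)


def insilico_pcr(
    template: SeqEntry | str,
    pair: PrimerPair,
    params: PCRParams = PCRParams(),
) -> list[AmpliconHit]:
    """Predict PCR products of *pair* on *template*.

    A product arises from a plus-strand forward-primer site with a
    downstream minus-strand reverse-primer site (and, when
    ``search_both_strands``, the mirror orientation with the roles swapped).
    The product spans the 5' end of the forward footprint through the 5' end
    of the reverse footprint, inclusive of both footprints.
    """
    if isinstance(template, SeqEntry):
        tid, seq = template.id, template.seq
    else:
        tid, seq = "template", template
    if len(seq) < len(pair.forward) or len(seq) < len(pair.reverse):
        return []

    fwd_hits = match_primer(seq, pair.forward, params)
    rev_hits = match_primer(seq, pair.reverse, params)

    def _products(
        plus: list[tuple[int, str, int]],
        minus: list[tuple[int, str, int]],
        minus_len: int,
        strand: str,
        swap: bool,
    ) -> list[AmpliconHit]:
        out = []
        for fpos, fstrand, fmm in plus:
            if fstrand != "+":
                continue
            for rpos, rstrand, rmm in minus:
                if rstrand != "-":
                    continue
                end = rpos + minus_len - 1  # 5' end of the minus-strand primer
                length = end - fpos + 1
                if length < len(pair.forward) + len(pair.reverse):
                    continue
                if params.min_product_len <= length <= params.max_product_len:
                    mmf, mmr = (rmm, fmm) if swap else (fmm, rmm)
                    out.append(
                        AmpliconHit(
                            template_id=tid,
                            start=fpos,
                            end=end,
                            strand=strand,
                            mm_forward=mmf,
                            mm_reverse=mmr,
                        )
                    )
        return out

    hits = _products(fwd_hits, rev_hits, len(pair.reverse), "+", swap=False)
    if params.search_both_strands:
        # mirror orientation: the reverse primer anneals to the plus strand
        # and the forward primer to the minus strand
        hits += _products(rev_hits, fwd_hits, len(pair.forward), "-", swap=True)
    uniq = {(h.start, h.end, h.strand): h for h in hits}
    return sorted(uniq.values(), key=lambda h: (h.start, h.end, h.strand))


@dataclass(frozen=True)
class CandidateWindow:
    """A target-invariant window with its specificity score (the minimum
    mismatch count against any non-target strain)."""

    locus: str
    start: int  # 0-based
    seq: str
    score: int

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


def find_specific_windows(
    panel: StrainPanel,
    locus: str,
    target_species: str,
    window_len: int = 20,
    min_mismatches: int = 3,
) -> list[CandidateWindow]:
    """All windows of *window_len* that are invariant across target-species
    strains and carry ≥*min_mismatches* differences — at least one in the
    3'-terminal three positions — against every non-target strain. Sorted by
    minimum non-target mismatch count, descending (ties by position)."""
    seqs = panel.locus_seqs(locus)
    targets = [s for s in seqs if panel.species_of(s) == target_species]
    if not targets:
        raise UndefinedStatisticError(
            f"no strains of species {target_species!r} at locus {locus!r}"
        )
    others = [s for s in seqs if panel.species_of(s) != target_species]
    length = len(seqs[targets[0]])
    if window_len > length:
        return []
    tmat = np.stack([_ascii(seqs[s]) for s in targets])
    invariant = (tmat == tmat[0]).all(axis=0)
    inv_run = np.lib.stride_tricks.sliding_window_view(invariant, window_len).all(axis=1)
    starts = np.flatnonzero(inv_run)
    if len(starts) == 0:
        return []
    if not others:
        # the non-target filter is vacuous without non-target strains
        return [
            CandidateWindow(locus, int(p), seqs[targets[0]][p : p + window_len], 0)
            for p in starts
        ]

    ref = tmat[0]
    omat = np.stack([_ascii(seqs[s]) for s in others])
    diff = omat != ref[None, :]  # (n_other, length)
    win_diff = np.lib.stride_tricks.sliding_window_view(diff, window_len, axis=1)
    mm = win_diff.sum(axis=2)  # (n_other, n_windows)
    tail_ok = win_diff[:, :, window_len - 3 :].any(axis=2)
    ok_per_other = (mm >= min_mismatches) & (tail_ok | (min_mismatches == 0))
    all_ok = ok_per_other.all(axis=0)
    min_mm = mm.min(axis=0)

    out = []
    for p in starts:
        if all_ok[p]:
            out.append(
                CandidateWindow(
                    locus, int(p), seqs[targets[0]][p : p + window_len], int(min_mm[p])
                )
            )
    return sorted(out, key=lambda w: (-w.score, w.start))


def design_pairs(
    windows: list[CandidateWindow],
    product_range: tuple[int, int] = (100, 1000),
    tm_range: tuple[float, float] = (50.0, 72.0),
    max_pairs: int | None = 50,
) -> list[PrimerPair]:
    """Combine candidate windows into primer pairs.

    The forward primer is an upstream window read as-is; the reverse primer
    is the reverse complement of a downstream window. Pairs are kept when the
    product length (both footprints inclusive) is in *product_range* and both
    Tm values in *tm_range*; ranked by combined specificity score, descending
    (ties by position), truncated to *max_pairs*.
    """
    if len(windows) < 2:
        return []
    # Wallace Tm is composition-only, so a window and its reverse complement
    # share it: one Tm check covers both primer orientations
    viable = [
        w for w in windows if tm_range[0] <= primer_tm(w.seq) <= tm_range[1]
    ]
    ranked: list[tuple[int, int, CandidateWindow, CandidateWindow, int]] = []
    for w1 in viable:
        for w2 in viable:
            if w2.start < w1.end:
                continue
            product = w2.end - w1.start
            if not (product_range[0] <= product <= product_range[1]):
                continue
            ranked.append((min(w1.score, w2.score), w1.score + w2.score, w1, w2, product))
    ranked.sort(key=lambda t: (-t[0], -t[1], t[2].start, t[3].start))
    if max_pairs is not None:
        ranked = ranked[:max_pairs]
    return [
        PrimerPair(
            Primer(f"{w1.locus}-F@{w1.start + 1}", w1.seq),
            Primer(f"{w2.locus}-R@{w2.start + 1}", reverse_complement(w2.seq)),
            expected_size_bp=product,
        )
        for _, _, w1, w2, product in ranked
    ]


def specificity_report(
    pairs: list[PrimerPair],
    panel: StrainPanel,
    params: PCRParams = PCRParams(),
    loci: list[str] | None = None,
) -> pd.DataFrame:
    """Amplification matrix: one row per primer pair, one column per strain,
    cells are predicted product length(s) or "—". A ``verdict`` column reports
    SPECIFIC(species) when the amplified strains are exactly the strains of
    one species, else NOT SPECIFIC (or NO AMPLIFICATION).

    Each strain's templates are its per-locus sequences (restricted to *loci*
    when given)."""
    use_loci = loci if loci is not None else panel.loci
    rows = []
    for k, pair in enumerate(pairs):
        name = f"{pair.forward.name}/{pair.reverse.name}"
        row: dict[str, object] = {"pair": name}
        amplified: set[str] = set()
        for sid in panel.strain_ids:
            lengths: list[int] = []
            for locus in use_loci:
                if not panel.has_cell(sid, locus):
                    continue
                for hit in insilico_pcr(panel.sequences[(sid, locus)], pair, params):
                    lengths.append(hit.product_length_bp)
            if lengths:
                amplified.add(sid)
                row[sid] = ",".join(str(x) for x in sorted(lengths))
            else:
                row[sid] = "—"
        verdict = "NO AMPLIFICATION"
        if amplified:
            verdict = "NOT SPECIFIC"
            for species in panel.species_labels:
                if amplified == set(panel.strains_for_species(species)):
                    verdict = f"SPECIFIC({species})"
                    break
        row["verdict"] = verdict
        rows.append(row)
    cols = ["pair", *panel.strain_ids, "verdict"]
    return pd.DataFrame(rows, columns=cols if rows else cols)


# ---------------------------------------------------------------------------
# Primer TSV I/O (name, sequence 5'→3', pair group, expected size)
# ---------------------------------------------------------------------------


def read_primer_table(path) -> list[PrimerPair]:
    """Read primer pairs from TSV with columns name, seq, pair, role
    (F/R), expected_size_bp (optional, on the F row)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"name", "seq", "pair", "role"}
    if not needed <= set(df.columns):
        raise ConfigError(f"primer table needs columns {sorted(needed)}")
    pairs = []
    for gname, grp in df.groupby("pair", sort=False):
        roles = {rec["role"].upper(): rec for rec in grp.to_dict("records")}
        if set(roles) != {"F", "R"}:
            raise ConfigError(f"pair {gname!r} must have exactly one F and one R row")
        size = None
        if "expected_size_bp" in grp.columns:
            vals = grp["expected_size_bp"].dropna()
            if len(vals):
                size = int(float(vals.iloc[0]))
        pairs.append(
            PrimerPair(
                Primer(roles["F"]["name"], roles["F"]["seq"].upper()),
                Primer(roles["R"]["name"], roles["R"]["seq"].upper()),
                expected_size_bp=size,
            )
        )
    return pairs


def write_primer_table(pairs: list[PrimerPair], path) -> None:
    rows = []
    for i, p in enumerate(pairs, 1):
        rows.append({"name": p.forward.name, "seq": p.forward.seq, "pair": f"p{i}",
                     "role": "F", "expected_size_bp": p.expected_size_bp, "tm": p.forward.tm})
        rows.append({"name": p.reverse.name, "seq": p.reverse.seq, "pair": f"p{i}",
                     "role": "R", "expected_size_bp": "", "tm": p.reverse.tm})
    pd.DataFrame(rows, columns=["name", "seq", "pair", "role", "expected_size_bp", "tm"]).to_csv(
        path, sep="\t", index=False
    )
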