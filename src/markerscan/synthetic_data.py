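"""Synthetic multi-species strain panel generator.

Emulates the structure of a comparative-genomics panel of *Bacillus
subtilis* and four close relatives: ~5 species × 3–6 strains, 17
protein-coding housekeeping loci at their published lengths plus one
slow-evolving 16S-like locus, species divergence tuned so that
within-species identity sits near 99%, between-species identity for protein
loci falls in the published 67–82% band and the 16S-like locus stays ≥99%,
and coding loci evolve under purifying selection with a target dN/dS.

Model: a star phylogeny. Each locus gets one random root sequence; each
species ancestor is derived from the root and each strain from its species
ancestor by a fixed number of accepted point substitutions. ``p_inter`` and
``p_intra`` parameterize the target *pairwise* divergence: each branch
receives a deterministic substitution count chosen by inverting the
expected multiple-hit shrinkage (see :func:`_branch_substitutions`), so the
realized pairwise Hamming divergence centers on ``p``. Coding loci use a
codon-aware
proposal/acceptance scheme: proposals creating stop codons are always
rejected and nonsynonymous proposals are accepted with probability
``omega_target``, which makes the realized Nei–Gojobori dN/dS land near the
target. No indels are simulated, so per-locus sets are equal-length and
gap-free.

Species-specific primer windows are *planted*: window regions are frozen
against random mutation everywhere, target-species strains carry the root
window verbatim, and every non-target species ancestor receives ≥3 forced
window mismatches, at least one of them in the window's 3'-terminal three
positions.

Randomness is drawn from independent streams keyed by
(seed, locus, species, strain), so adding a strain or locus does not perturb
other sequences.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .refdata import REFERENCE_LOCUS_TABLE
from .seqio import SeqEntry, StrainPanel, write_fasta
from .typing_stats import CODON_AA, STOP_CODONS

BASES = "ACGT"
_ALTS = {b: [x for x in BASES if x != b] for b in BASES}
_SENSE_CODONS = [c for c in CODON_AA if c not in STOP_CODONS]

MIN_WINDOW_LEN = 18
MAX_WINDOW_LEN = 30


@dataclass(frozen=True)
class LocusSpec:
    """One simulated locus; p_inter/p_intra override the config defaults."""

    name: str
    length_bp: int
    coding: bool = True
    p_inter: float | None = None
    p_intra: float | None = None


@dataclass(frozen=True)
class PlantedWindow:
    """A species-specific window to plant at a fixed position (0-based)."""

    locus: str
    target_species: str
    length: int
    start: int


@dataclass
class SimConfig:
    """Study design for one synthetic panel. Defaults mirror the published
    21-strain, 5-species panel with the 17 housekeeping loci at their
    published lengths plus a 16S-like locus."""

    seed: int
    species: list[tuple[str, int]] = field(default_factory=list)
    loci: list[LocusSpec] = field(default_factory=list)
    p_inter: float = 0.25
    p_intra: float = 0.005
    omega_target: float = 0.4
    planted_windows: list[PlantedWindow] = field(default_factory=list)

    def locus(self, name: str) -> LocusSpec:
        for spec in self.loci:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def rates_for(self, spec: LocusSpec) -> tuple[float, float]:
        p_inter = spec.p_inter if spec.p_inter is not None else self.p_inter
        p_intra = spec.p_intra if spec.p_intra is not None else self.p_intra
        return p_inter, p_intra

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("no species configured")
        if not self.loci:
            raise ConfigError("no loci configured")
        if len({n for n, _ in self.species}) != len(self.species):
            raise ConfigError("duplicate species names")
        if len({s.name for s in self.loci}) != len(self.loci):
            raise ConfigError("duplicate locus names")
        if any(c < 1 for _, c in self.species):
            raise ConfigError("each species needs ≥1 strain")
        if not (0.0 < self.omega_target <= 1.0):
            raise ConfigError(f"omega_target {self.omega_target} outside (0, 1]")
        for spec in self.loci:
            p_inter, p_intra = self.rates_for(spec)
            if not (0.0 <= p_intra < p_inter <= 0.75):
                raise ConfigError(
                    f"locus {spec.name!r}: need 0 ≤ p_intra < p_inter ≤ 0.75 "
                    f"(got p_intra={p_intra}, p_inter={p_inter})"
                )
            if spec.length_bp < 3:
                raise ConfigError(f"locus {spec.name!r} too short")
        species_names = {n for n, _ in self.species}
        locus_names = {s.name for s in self.loci}
        by_locus: dict[str, list[PlantedWindow]] = {}
        for w in self.planted_windows:
            if w.locus not in locus_names:
                raise ConfigError(f"planted window on unknown locus {w.locus!r}")
            if w.target_species not in species_names:
                raise ConfigError(f"planted window for unknown species {w.target_species!r}")
            if not (MIN_WINDOW_LEN <= w.length <= MAX_WINDOW_LEN):
                raise ConfigError(
                    f"window length {w.length} outside [{MIN_WINDOW_LEN}, {MAX_WINDOW_LEN}]"
                )
            length = self.locus(w.locus).length_bp
            if w.start < 0 or w.start + w.length > length:
                raise ConfigError(
                    f"window [{w.start}, {w.start + w.length}) outside locus "
                    f"{w.locus!r} of length {length}"
                )
            by_locus.setdefault(w.locus, []).append(w)
        for locus, wins in by_locus.items():
            wins = sorted(wins, key=lambda w: w.start)
            for w1, w2 in zip(wins, wins[1:]):
                if w2.start < w1.start + w1.length:
                    raise ConfigError(
                        f"planted windows collide on locus {locus!r}: "
                        f"[{w1.start},{w1.start + w1.length}) and "
                        f"[{w2.start},{w2.start + w2.length})"
                    )


DEFAULT_SPECIES: list[tuple[str, int]] = [
    ("B_subtilis", 6),
    ("B_siamensis", 3),
    ("B_velezensis", 5),
    ("B_amyloliquefaciens", 4),
    ("B_atrophaeus", 3),
]

SIXTEEN_S_LOCUS = LocusSpec("rrs", 1550, coding=False, p_inter=0.008, p_intra=0.001)

# Planted window geometry chosen so the designed pairs reproduce the published
# product sizes: pycA 20 + 191 + 22 = 233 bp, aroE 20 + 237 + 21 = 278 bp.
DEFAULT_WINDOWS: list[PlantedWindow] = [
    PlantedWindow("pycA", "B_subtilis", 20, start=120),
    PlantedWindow("pycA", "B_subtilis", 22, start=331),
    PlantedWindow("aroE", "B_subtilis", 20, start=150),
    PlantedWindow("aroE", "B_subtilis", 21, start=407),
]


def default_config(seed: int, scale: float = 1.0) -> SimConfig:
    """The default study design. ``scale`` < 1 shrinks locus lengths
    proportionally (codon-rounded, planted windows dropped unless they fit),
    for quick property checks."""
    loci = [
        LocusSpec(
            name,
            ref.length_bp if scale == 1.0 else max(3, 3 * round(ref.length_bp * scale / 3)),
            coding=True,
        )
        for name, ref in REFERENCE_LOCUS_TABLE.items()
    ]
    rrs = SIXTEEN_S_LOCUS
    if scale != 1.0:
        rrs = LocusSpec(rrs.name, max(60, round(rrs.length_bp * scale)), False,
                        rrs.p_inter, rrs.p_intra)
    loci.append(rrs)
    cfg = SimConfig(seed=seed, species=list(DEFAULT_SPECIES), loci=loci)
    lengths = {s.name: s.length_bp for s in loci}
    cfg.planted_windows = [
        w for w in DEFAULT_WINDOWS if w.start + w.length <= lengths[w.locus]
    ]
    return cfg


@dataclass
class SimTruth:
    """Ground truth for a generated panel."""

    species_of: dict[str, str]
    allele_partition: dict[str, list[list[str]]]
    windows: list[dict]
    expected_amplicons: list[dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


# ---------------------------------------------------------------------------
# RNG plumbing
# ---------------------------------------------------------------------------


def _stream(seed: int, *key: object) -> np.random.Generator:
    """Independent, reproducible RNG stream for a (seed, *key) tuple."""
    parts = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode("utf-8")) for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(parts))


# ---------------------------------------------------------------------------
# Mutation operators
# ---------------------------------------------------------------------------


def _branch_substitutions(p: float, length: int) -> int:
    """Accepted substitutions per branch so the expected pairwise Hamming
    divergence between two branches equals the target *p*.

    Inverts two layers of multiple-hit shrinkage: the two-branch collision
    formula p = 2r − (4/3)r² (per-branch divergence r), and the with-
    replacement site-hit process r = (3/4)(1 − exp(−4n/(3L))).
    """
    if p <= 0.0:
        return 0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise ConfigError(f"target divergence {p} too close to saturation")
    r = 0.75 * (1.0 - np.sqrt(arg))
    return int(np.floor(-0.75 * length * np.log1p(-4.0 * r / 3.0)))


def _random_root(spec: LocusSpec, rng: np.random.Generator) -> str:
    if spec.coding:
        ncod = spec.length_bp // 3
        codons = [
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=ncod)
        ]
        tail = "".join(BASES[i] for i in rng.integers(0, 4, size=spec.length_bp % 3))
        return "".join(codons) + tail
    return "".join(BASES[i] for i in rng.integers(0, 4, size=spec.length_bp))


def mutate_codon_aware(
    seq: str,
    n_sub: int,
    omega_target: float,
    rng: np.random.Generator,
    frozen: np.ndarray | None = None,
) -> str:
    """Apply exactly *n_sub* accepted point substitutions under a codon-aware
    acceptance rule.

    Proposals are a uniform random site and a uniform alternative base.
    A proposal creating a stop codon is always rejected; a nonsynonymous
    proposal is accepted with probability *omega_target*; a synonymous one
    always. Sites flagged in *frozen* are never mutated. Positions past the
    last full codon are treated as neutral. Raises
    :class:`SimulationError` if the substitutions cannot be placed within a
    bounded number of proposals.
    """
    length = len(seq)
    if length % 3 not in (0, 1, 2):  # pragma: no cover - always true
        raise SimulationError("bad length")
    if n_sub < 0:
        raise SimulationError("negative substitution count")
    if n_sub == 0:
        return seq
    if frozen is not None and int((~frozen).sum()) == 0:
        raise SimulationError("all sites frozen; cannot place substitutions")
    s = list(seq)
    ncod3 = 3 * (length // 3)
    accepted = 0
    budget = 200 * n_sub + 1000
    while accepted < n_sub:
        if budget <= 0:
            raise SimulationError(
                f"could not place {n_sub} substitutions (stuck after retries)"
            )
        budget -= 1
        pos = int(rng.integers(0, length))
        if frozen is not None and frozen[pos]:
            continue
        cur = s[pos]
        alt = _ALTS[cur][int(rng.integers(0, 3))]
        if pos < ncod3:
            c0 = pos - pos % 3
            codon = "".join(s[c0 : c0 + 3])
            mutant = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_AA[codon] != CODON_AA[mutant] and rng.random() >= omega_target:
                continue
        s[pos] = alt
        accepted += 1
    return "".join(s)


def _mutate_neutral(
    seq: str, n_sub: int, rng: np.random.Generator, frozen: np.ndarray | None = None
) -> str:
    s = list(seq)
    length = len(seq)
    accepted = 0
    budget = 200 * max(n_sub, 1) + 1000
    while accepted < n_sub:
        if budget <= 0:
            raise SimulationError("could not place neutral substitutions")
        budget -= 1
        pos = int(rng.integers(0, length))
        if frozen is not None and frozen[pos]:
            continue
        s[pos] = _ALTS[s[pos]][int(rng.integers(0, 3))]
        accepted += 1
    return "".join(s)


def _force_window_mismatches(
    seq: list[str],
    window: PlantedWindow,
    coding: bool,
    rng: np.random.Generator,
    min_mismatches: int = 3,
) -> None:
    """Force ≥min_mismatches substitutions inside the window (in place),
    at least one of them within the 3'-terminal three positions; stop codons
    are avoided on coding loci."""
    w0, wlen = window.start, window.length
    positions = [w0 + wlen - 1 - int(rng.integers(0, 3))]  # one in the 3' anchor
    pool = [p for p in range(w0, w0 + wlen) if p not in positions]
    picks = rng.choice(len(pool), size=min_mismatches - 1, replace=False)
    positions += [pool[int(i)] for i in picks]
    ncod3 = 3 * (len(seq) // 3)
    for pos in positions:
        for _ in range(30):
            alt = _ALTS[seq[pos]][int(rng.integers(0, 3))]
            if coding and pos < ncod3:
                c0 = pos - pos % 3
                codon = "".join(seq[c0:c0 + 3])
                mutant = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
                if mutant in STOP_CODONS:
                    continue
            seq[pos] = alt
            break
        else:  # pragma: no cover - 30 redraws of 3 alternatives cannot all stop
            raise SimulationError("cannot place window mismatch without a stop codon")


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def generate_panel(config: SimConfig) -> tuple[StrainPanel, SimTruth]:
    """Generate a strain panel and its ground truth. Deterministic for a
    fixed config (including seed)."""
    config.validate()
    strains: list[tuple[str, str]] = []
    for sp_name, count in config.species:
        for i in range(count):
            strains.append((f"{sp_name}_{i + 1:02d}", sp_name))

    windows_by_locus: dict[str, list[PlantedWindow]] = {}
    for w in config.planted_windows:
        windows_by_locus.setdefault(w.locus, []).append(w)

    sequences: dict[tuple[str, str], SeqEntry] = {}
    truth_windows: list[dict] = []
    seed = config.seed

    for spec in config.loci:
        p_inter, p_intra = config.rates_for(spec)
        length = spec.length_bp
        n_inter = _branch_substitutions(p_inter, length)
        n_intra = _branch_substitutions(p_intra, length)

        root = _random_root(spec, _stream(seed, "root", spec.name))
        wins = sorted(windows_by_locus.get(spec.name, []), key=lambda w: w.start)
        frozen = None
        if wins:
            frozen = np.zeros(length, dtype=bool)
            for w in wins:
                frozen[w.start : w.start + w.length] = True
            for w in wins:
                truth_windows.append(
                    {
                        "locus": spec.name,
                        "target_species": w.target_species,
                        "start": w.start,
                        "length": w.length,
                        "seq": root[w.start : w.start + w.length],
                    }
                )

        for sp_name, count in config.species:
            rng_sp = _stream(seed, spec.name, sp_name)
            if spec.coding:
                ancestor = mutate_codon_aware(
                    root, n_inter, config.omega_target, rng_sp, frozen=frozen
                )
            else:
                ancestor = _mutate_neutral(root, n_inter, rng_sp, frozen=frozen)
            anc = list(ancestor)
            for wi, w in enumerate(wins):
                if w.target_species != sp_name:
                    # well over the ≥3 contract so planted windows outscore
                    # naturally divergent ones and top the candidate ranking
                    _force_window_mismatches(
                        anc, w, spec.coding,
                        _stream(seed, spec.name, sp_name, "win", wi),
                        min_mismatches=max(3, round(0.6 * w.length)),
                    )
            ancestor = "".join(anc)
            for i in range(count):
                strain_id = f"{sp_name}_{i + 1:02d}"
                rng_st = _stream(seed, spec.name, sp_name, i)
                if spec.coding:
                    final = mutate_codon_aware(
                        ancestor, n_intra, config.omega_target, rng_st, frozen=frozen
                    )
                else:
                    final = _mutate_neutral(ancestor, n_intra, rng_st, frozen=frozen)
                sequences[(strain_id, spec.name)] = SeqEntry(
                    id=strain_id, seq=final, description=spec.name
                )

    panel = StrainPanel(
        strains=strains,
        loci=[s.name for s in config.loci],
        sequences=sequences,
        reference_strain=strains[0][0],
    )

    partition: dict[str, list[list[str]]] = {}
    for spec in config.loci:
        groups: dict[str, list[str]] = {}
        for sid in panel.strain_ids:
            groups.setdefault(sequences[(sid, spec.name)].seq, []).append(sid)
        partition[spec.name] = list(groups.values())

    amplicons: list[dict] = []
    for locus, wins in windows_by_locus.items():
        wins = sorted(wins, key=lambda w: w.start)
        by_sp: dict[str, list[PlantedWindow]] = {}
        for w in wins:
            by_sp.setdefault(w.target_species, []).append(w)
        for sp_name, sp_wins in by_sp.items():
            for w1, w2 in zip(sp_wins, sp_wins[1:]):
                amplicons.append(
                    {
                        "locus": locus,
                        "target_species": sp_name,
                        "forward_start": w1.start,
                        "product_length_bp": (w2.start + w2.length) - w1.start,
                    }
                )

    truth = SimTruth(
        species_of=dict(strains),
        allele_partition=partition,
        windows=truth_windows,
        expected_amplicons=amplicons,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


def emit_dataset(panel: StrainPanel, truth: SimTruth, out_dir: str | Path) -> list[Path]:
    """Write per-locus FASTA files, the metadata TSV, and the truth JSON.
    Re-reading the files with seqio reproduces the panel exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rows = []
    for locus in panel.loci:
        fasta = out / f"{locus}.fasta"
        entries = [
            panel.sequences[(sid, locus)]
            for sid in panel.strain_ids
            if panel.has_cell(sid, locus)
        ]
        write_fasta(entries, fasta)
        written.append(fasta)
        for sid in panel.strain_ids:
            if panel.has_cell(sid, locus):
                rows.append(
                    {
                        "strain_id": sid,
                        "species": panel.species_of(sid),
                        "locus": locus,
                        "fasta_path": fasta.name,
                        "seq_id": panel.sequences[(sid, locus)].id,
                    }
                )
    meta = out / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta, sep="\t", index=False)
    written.append(meta)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    written.append(truth_path)
    return written


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML or JSON. All fields have defaults except
    ``seed``; omitted species/loci fall back to the default study design."""
    import yaml

    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict) or "seed" not in data:
        raise ConfigError(f"{path}: config must be a mapping with a 'seed' key")
    cfg = default_config(int(data["seed"]))
    if "species" in data:
        cfg.species = [(str(n), int(c)) for n, c in data["species"]]
    if "loci" in data:
        cfg.loci = [
            LocusSpec(
                name=str(d["name"]),
                length_bp=int(d["length_bp"]),
                coding=bool(d.get("coding", True)),
                p_inter=d.get("p_inter"),
                p_intra=d.get("p_intra"),
            )
            for d in data["loci"]
        ]
    for key in ("p_inter", "p_intra", "omega_target"):
        if key in data:
            setattr(cfg, key, float(data[key]))
    if "planted_windows" in data:
        cfg.planted_windows = [
            PlantedWindow(
                locus=str(d["locus"]),
                target_species=str(d["target_species"]),
                length=int(d["length"]),
                start=int(d["start"]),
            )
            for d in data["planted_windows"]
        ]
    cfg.validate()
    return cfg
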