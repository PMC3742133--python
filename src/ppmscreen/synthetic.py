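"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure the analysis assumes: promoter windows
with planted canonical/core binding-site pairs at admissible spacings,
background promoters of matched nucleotide composition, a differential
expression table with a configurable FDR stratification (defaults: 146 genes
below FDR 0.1, of which 30 below 0.01, of which 3 carry a planted site
pair), symbol ortholog maps, and pathway gene sets against a 25,504-gene
universe. Everything is a pure function of (config, seed); per-gene state is
drawn from one `numpy` Generator stream, so identical configurations produce
byte-identical files.

Planted truth is exact: windows that receive a planted structure are
resampled until their canonical-site content is exactly the planted set, so
truth tables list every canonical site and pair distance present. Chance
core (CAAG/CTTG) sites are permitted and recorded as such — they only affect
the relaxed tiers, mirroring the weak specificity of the core motif.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError
from .motif_scan import CANONICAL, CORE, FORWARD, REVERSE, Motif, scan_window
from .ppm_model import PairConstraint, PPMDefinition, Tier, classify_window
from .promoter_io import (
    GenomeSource,
    PromoterWindow,
    TranscriptRecord,
    WindowSpec,
    extract_window,
    reverse_complement,
)
from .screen import OrthologMap, PathwayGeneSet

BASES = np.array(list("ACGT"))
UNIFORM_PROBS = (0.25, 0.25, 0.25, 0.25)
#: iid approximation of mammalian genomic composition (~42% GC)
GENOMIC_LIKE_PROBS = (0.29, 0.21, 0.21, 0.29)


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in one promoter window: a two-site pair of the given
    tier, or (``n_sites`` > 2) a homotypic canonical cluster with consecutive
    start-to-start gaps ``gaps``."""

    tier: Tier = Tier.PPM
    n_sites: int = 2
    gaps: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ConfigError("a planted structure needs at least two sites")
        if self.n_sites > 2:
            if self.gaps is None or len(self.gaps) != self.n_sites - 1:
                raise ConfigError("multi-site planting needs n_sites-1 gaps")
            if self.tier is not Tier.PPM:
                raise ConfigError("multi-site clusters are canonical-only")


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_genes: int = 2500
    base_probs: tuple[float, float, float, float] = UNIFORM_PROBS
    #: optional 4x4 first-order Markov transition matrix (rows/cols in ACGT
    #: order); approximates dinucleotide bias of real promoters when set
    markov: tuple[tuple[float, float, float, float], ...] | None = None
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    pair_constraint: PairConstraint = field(default_factory=PairConstraint)
    flank: int = 60
    # planted promoter structure
    n_planted: int | None = 3
    fraction_positive: float | None = None  # overrides n_planted when set
    planted_tier: Tier = Tier.PPM
    clean_background: bool = False  # reject background windows fitting planted_tier
    # differential-expression table (limma-style output shape)
    n_fdr01: int = 30
    n_fdr1: int = 146
    n_up_fdr01: int = 14
    n_up_fdr1: int = 70
    n_planted_in_fdr01: int = 3
    min_fold_change: float = 1.2
    max_fold_change: float = 6.0
    # cross-species structure
    n_conserved: int = 10
    n_species_only: int = 20
    n_multi_a: int = 10  # co-occurrence clusters in species A (last one 4-site)
    n_multi_b: int = 8
    multi_gaps_3: tuple[int, int] = (100, 120)
    multi_gaps_4: tuple[int, int, int] = (100, 120, 100)
    ortholog_fraction: float = 0.8
    # pathway
    pathway_id: str = "pwy0001"
    pathway_size: int = 135
    pathway_universe: int = 25504
    n_selected_in_pathway: int = 3

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ConfigError("base probabilities must sum to 1")
        if not self.n_fdr01 <= self.n_fdr1:
            raise ConfigError("need n_fdr01 <= n_fdr1")
        if self.pathway_size >= self.pathway_universe:
            raise ConfigError("pathway larger than universe")

    def resolved_n_planted(self) -> int:
        if self.fraction_positive is not None:
            return int(round(self.n_genes * self.fraction_positive))
        return 0 if self.n_planted is None else self.n_planted


@dataclass(frozen=True)
class GeneTruth:
    gene_symbol: str
    planted: bool
    tier: str | None = None
    site_offsets: tuple[int, ...] = ()
    orientations: tuple[str, ...] = ()
    pair_distance: int | None = None
    n_sites: int = 0

    def to_dict(self) -> dict:
        return {
            "gene_symbol": self.gene_symbol,
            "planted": self.planted,
            "tier": self.tier,
            "site_offsets": list(self.site_offsets),
            "orientations": list(self.orientations),
            "pair_distance": self.pair_distance,
            "n_sites": self.n_sites,
        }


@dataclass
class SyntheticStudy:
    genome: GenomeSource
    transcripts: list[TranscriptRecord]
    truth: dict[str, GeneTruth]
    config: SynthConfig

    @property
    def planted_genes(self) -> list[str]:
        return [g for g, t in self.truth.items() if t.planted]

    def windows_for(self, genes: Iterable[str] | None = None) -> list[PromoterWindow]:
        wanted = None if genes is None else set(genes)
        out = []
        for rec in self.transcripts:
            if wanted is None or rec.gene_symbol in wanted:
                out.append(extract_window(self.genome, rec, self.config.window_spec))
        return out


def random_sequence(
    rng: np.random.Generator,
    length: int,
    probs: Sequence[float] = UNIFORM_PROBS,
    markov: Sequence[Sequence[float]] | None = None,
) -> str:
    """iid background by default; with ``markov`` set, a first-order chain
    whose initial base follows ``probs``."""
    if markov is None:
        return "".join(BASES[rng.choice(4, size=length, p=list(probs))])
    transition = np.asarray(markov, dtype=float)
    if transition.shape != (4, 4) or not np.allclose(transition.sum(axis=1), 1.0):
        raise ConfigError("markov must be a 4x4 row-stochastic matrix")
    states = np.empty(length, dtype=np.int64)
    states[0] = rng.choice(4, p=list(probs))
    for i in range(1, length):
        states[i] = rng.choice(4, p=transition[states[i - 1]])
    return "".join(BASES[states])


def _canonical_starts(seq: str) -> set[int]:
    return {h.start_offset for h in scan_window(seq, CANONICAL)}


def _oriented(motif: Motif, orientation: str) -> str:
    return motif.forward if orientation == FORWARD else motif.reverse


def plant_ppm_instance(
    sequence: str,
    tier: Tier,
    distance: int,
    rng: np.random.Generator,
    orientations: tuple[str, str] | None = None,
    max_tries: int = 100,
) -> tuple[str, tuple[int, int], tuple[str, str], tuple[str, str]]:
    """Write two oriented binding sites into ``sequence`` at start-to-start
    spacing exactly ``distance``. Placements that would create (or keep)
    canonical sites beyond those present before planting plus the planted
    ones are rejected and resampled. Returns
    (sequence, starts, orientations, motif names)."""
    if tier is Tier.PPM:
        motifs = (CANONICAL, CANONICAL)
    elif tier is Tier.LS_PPM:
        motifs = (CANONICAL, CORE) if rng.random() < 0.5 else (CORE, CANONICAL)
    else:
        motifs = (CORE, CORE)
    if distance + motifs[1].length > len(sequence):
        raise PlacementError(
            f"distance {distance} does not fit in a {len(sequence)}-nt window"
        )
    before = _canonical_starts(sequence)
    for _ in range(max_tries):
        orients = orientations or tuple(
            FORWARD if rng.random() < 0.5 else REVERSE for _ in range(2)
        )
        start_a = int(rng.integers(0, len(sequence) - distance - motifs[1].length + 1))
        start_b = start_a + distance
        chars = list(sequence)
        chars[start_a : start_a + motifs[0].length] = _oriented(motifs[0], orients[0])
        chars[start_b : start_b + motifs[1].length] = _oriented(motifs[1], orients[1])
        planted_seq = "".join(chars)
        planted_canon = {
            s for s, m in ((start_a, motifs[0]), (start_b, motifs[1])) if m is CANONICAL
        }
        after = _canonical_starts(planted_seq)
        if planted_canon <= after and after <= (before | planted_canon):
            return (
                planted_seq,
                (start_a, start_b),
                orients,
                (motifs[0].name, motifs[1].name),
            )
    raise PlacementError(f"no clean placement found in {max_tries} tries")


def plant_site_cluster(
    sequence: str,
    gaps: Sequence[int],
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[str, tuple[int, ...], tuple[str, ...]]:
    """Plant len(gaps)+1 canonical sites with the given consecutive
    start-to-start gaps (homotypic cluster), rejecting placements that leave
    stray canonical sites."""
    total = sum(gaps) + CANONICAL.length
    if total > len(sequence):
        raise PlacementError(f"cluster of span {total} does not fit")
    if min(gaps) < CANONICAL.length:
        raise PlacementError("cluster gaps would overlap sites")
    before = _canonical_starts(sequence)
    n_sites = len(gaps) + 1
    for _ in range(max_tries):
        start0 = int(rng.integers(0, len(sequence) - total + 1))
        starts = [start0]
        for g in gaps:
            starts.append(starts[-1] + g)
        orients = tuple(FORWARD if rng.random() < 0.5 else REVERSE for _ in range(n_sites))
        chars = list(sequence)
        for s, o in zip(starts, orients):
            chars[s : s + CANONICAL.length] = _oriented(CANONICAL, o)
        planted_seq = "".join(chars)
        after = _canonical_starts(planted_seq)
        if set(starts) <= after and after <= (before | set(starts)):
            return planted_seq, tuple(starts), orients
    raise PlacementError(f"no clean cluster placement found in {max_tries} tries")


def _background_window(
    rng: np.random.Generator, cfg: SynthConfig, require_no_canonical: bool
) -> str:
    """A background window; optionally resampled until it carries no
    canonical site at all (used under planted windows so the planted truth is
    exact)."""
    for _ in range(200):
        seq = random_sequence(rng, cfg.window_spec.length, cfg.base_probs, cfg.markov)
        if not require_no_canonical or not _canonical_starts(seq):
            return seq
    raise PlacementError("could not draw a canonical-free background window")


def _window_fits(seq: str, cfg: SynthConfig) -> bool:
    win = PromoterWindow("tmp", ("tmp",), seq, cfg.window_spec)
    ppm = PPMDefinition(
        tier=cfg.planted_tier,
        window_spec=cfg.window_spec,
        pair_constraint=cfg.pair_constraint,
    )
    return classify_window(win, ppm).fits[cfg.planted_tier]


def _make_window(
    rng: np.random.Generator, cfg: SynthConfig, spec: PlantSpec | None
) -> tuple[str, GeneTruth]:
    """Build one window sequence plus its truth record (symbol filled later)."""
    if spec is None:
        for _ in range(200):
            seq = random_sequence(rng, cfg.window_spec.length, cfg.base_probs, cfg.markov)
            if not cfg.clean_background or not _window_fits(seq, cfg):
                return seq, GeneTruth("", planted=False)
        raise PlacementError("could not draw a non-fitting background window")
    base = _background_window(rng, cfg, require_no_canonical=True)
    if spec.n_sites == 2:
        lo, hi = cfg.pair_constraint.min_distance, cfg.pair_constraint.max_distance
        distance = int(rng.integers(lo, hi + 1))
        seq, starts, orients, _names = plant_ppm_instance(base, spec.tier, distance, rng)
        return seq, GeneTruth(
            "",
            planted=True,
            tier=spec.tier.label,
            site_offsets=starts,
            orientations=orients,
            pair_distance=distance,
            n_sites=2,
        )
    seq, starts, orients = plant_site_cluster(base, spec.gaps, rng)
    return seq, GeneTruth(
        "",
        planted=True,
        tier=spec.tier.label,
        site_offsets=starts,
        orientations=orients,
        pair_distance=None,
        n_sites=spec.n_sites,
    )


def gen_genome_and_genes(
    cfg: SynthConfig,
    planting: dict[int, PlantSpec] | None = None,
    rng: np.random.Generator | None = None,
    symbol_prefix: str = "G",
    contig_prefix: str = "ctg",
) -> SyntheticStudy:
    """One contig per gene, each TSS placed so the screening window lies
    fully inside the contig; a configured subset of promoters receives a
    planted site structure. When ``planting`` is not given, the config's
    planted-gene count is planted with ``planted_tier`` pairs on the first
    genes chosen at random."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    up, down = cfg.window_spec.upstream, cfg.window_spec.downstream
    if planting is None:
        n_planted = cfg.resolved_n_planted()
        if n_planted > cfg.n_genes:
            raise ConfigError("more planted genes than genes")
        chosen = rng.choice(cfg.n_genes, size=n_planted, replace=False)
        planting = {int(i): PlantSpec(tier=cfg.planted_tier) for i in chosen}
    width = max(5, len(str(cfg.n_genes)))
    contigs: dict[str, str] = {}
    transcripts: list[TranscriptRecord] = []
    truth: dict[str, GeneTruth] = {}
    for i in range(cfg.n_genes):
        gene = f"{symbol_prefix}{i:0{width}d}"
        contig = f"{contig_prefix}{i:0{width}d}"
        window_seq, gene_truth = _make_window(rng, cfg, planting.get(i))
        flank5 = random_sequence(rng, cfg.flank, cfg.base_probs, cfg.markov)
        flank3 = random_sequence(rng, cfg.flank, cfg.base_probs, cfg.markov)
        plus_arrangement = flank5 + window_seq + flank3
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            contigs[contig] = plus_arrangement
            tss = cfg.flank + up + 1
        else:
            contigs[contig] = reverse_complement(plus_arrangement)
            tss = cfg.flank + down
        transcripts.append(
            TranscriptRecord(
                transcript_id=f"T{i:0{width}d}.1",
                gene_symbol=gene,
                contig=contig,
                strand=strand,
                tss=tss,
            )
        )
        truth[gene] = replace(gene_truth, gene_symbol=gene)
    return SyntheticStudy(
        genome=GenomeSource(contigs), transcripts=transcripts, truth=truth, config=cfg
    )


def gen_de_table(
    cfg: SynthConfig,
    truth: dict[str, GeneTruth],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign FDR values so that exactly ``n_fdr01`` genes fall below 0.01
    and ``n_fdr1`` below 0.1, placing ``n_planted_in_fdr01`` planted-promoter
    genes in the most confident stratum. Directions follow the configured
    up/down split; significant genes receive fold changes above the
    configured minimum."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    genes = list(truth)
    if cfg.n_fdr1 > len(genes):
        raise ConfigError("n_fdr1 exceeds the number of genes")
    planted = [g for g in genes if truth[g].planted]
    if cfg.n_planted_in_fdr01 > cfg.n_fdr01:
        raise ConfigError("n_planted_in_fdr01 exceeds n_fdr01")
    if cfg.n_planted_in_fdr01 > len(planted):
        raise ConfigError(
            f"want {cfg.n_planted_in_fdr01} planted genes in the FDR<0.01 stratum "
            f"but only {len(planted)} are planted"
        )
    if not (cfg.n_up_fdr01 <= cfg.n_fdr01 and cfg.n_up_fdr1 <= cfg.n_fdr1):
        raise ConfigError("up-regulated counts exceed stratum sizes")
    unplanted = [g for g in genes if not truth[g].planted]
    planted_in = [planted[i] for i in rng.choice(len(planted),
                  size=cfg.n_planted_in_fdr01, replace=False)]
    need = cfg.n_fdr1 - cfg.n_planted_in_fdr01
    if len(unplanted) < need:
        raise ConfigError("not enough unplanted genes for the DE strata")
    extra = [unplanted[i] for i in rng.choice(len(unplanted), size=need, replace=False)]
    top = planted_in + extra[: cfg.n_fdr01 - cfg.n_planted_in_fdr01]
    mid = extra[cfg.n_fdr01 - cfg.n_planted_in_fdr01 :]
    fdr = {}
    direction = {}
    fc = {}
    for rank, g in enumerate(top):
        fdr[g] = float(rng.uniform(1e-4, 9.9e-3))
        direction[g] = "up" if rank < cfg.n_up_fdr01 else "down"
    n_up_mid = cfg.n_up_fdr1 - cfg.n_up_fdr01
    for rank, g in enumerate(mid):
        fdr[g] = float(rng.uniform(1.1e-2, 9.9e-2))
        direction[g] = "up" if rank < n_up_mid else "down"
    for g in genes:
        if g in fdr:
            fc[g] = float(rng.uniform(cfg.min_fold_change, cfg.max_fold_change))
        else:
            fdr[g] = float(rng.uniform(0.11, 0.999))
            direction[g] = "up" if rng.random() < 0.5 else "down"
            fc[g] = float(rng.uniform(1.0, cfg.min_fold_change - 0.01))
    return pd.DataFrame(
        {
            "gene_symbol": genes,
            "fold_change": [fc[g] for g in genes],
            "direction": [direction[g] for g in genes],
            "fdr": [fdr[g] for g in genes],
        }
    )


@dataclass
class SpeciesPair:
    """Two synthetic species with shared (conserved) and species-specific
    planted structure, an ortholog symbol map, and one pathway gene set."""

    study_a: SyntheticStudy
    study_b: SyntheticStudy
    ortho: OrthologMap
    pathway: PathwayGeneSet
    conserved_pairs: list[tuple[str, str]]
    cooccur_a: list[str]
    cooccur_b: list[str]


def gen_species_pair(cfg: SynthConfig) -> SpeciesPair:
    """Generate the full cross-species study: in each species, single planted
    pairs for conserved and species-specific genes, plus multi-site canonical
    clusters (the co-occurrence truth; species A gets one 4-site cluster),
    on clean backgrounds so the planted gene sets are exactly recoverable."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    need = cfg.n_conserved + 2 * cfg.n_species_only + cfg.n_multi_a + cfg.n_multi_b
    if need > n:
        raise ConfigError(f"n_genes={n} too small for {need} planted genes")
    idx = [int(i) for i in rng.choice(n, size=need, replace=False)]
    conserved = idx[: cfg.n_conserved]
    pos = cfg.n_conserved
    a_only = idx[pos : pos + cfg.n_species_only]
    pos += cfg.n_species_only
    b_only = idx[pos : pos + cfg.n_species_only]
    pos += cfg.n_species_only
    multi_a = idx[pos : pos + cfg.n_multi_a]
    pos += cfg.n_multi_a
    multi_b = idx[pos : pos + cfg.n_multi_b]

    pair_spec = PlantSpec(tier=cfg.planted_tier)
    plant_a: dict[int, PlantSpec] = {i: pair_spec for i in conserved + a_only}
    for j, i in enumerate(multi_a):
        gaps = cfg.multi_gaps_4 if j == len(multi_a) - 1 else cfg.multi_gaps_3
        plant_a[i] = PlantSpec(tier=Tier.PPM, n_sites=len(gaps) + 1, gaps=tuple(gaps))
    plant_b: dict[int, PlantSpec] = {i: pair_spec for i in conserved + b_only}
    for i in multi_b:
        plant_b[i] = PlantSpec(tier=Tier.PPM, n_sites=3, gaps=tuple(cfg.multi_gaps_3))

    clean_cfg = replace(cfg, clean_background=True)
    study_a = gen_genome_and_genes(
        clean_cfg, planting=plant_a, rng=np.random.default_rng(rng.integers(2**31)),
        symbol_prefix="mG", contig_prefix="mctg",
    )
    study_b = gen_genome_and_genes(
        clean_cfg, planting=plant_b, rng=np.random.default_rng(rng.integers(2**31)),
        symbol_prefix="hG", contig_prefix="hctg",
    )
    sym_a = [t.gene_symbol for t in study_a.transcripts]
    sym_b = [t.gene_symbol for t in study_b.transcripts]

    ortho, pathway = gen_orthologs_and_pathways(
        cfg,
        truth_a=study_a.truth,
        truth_b=study_b.truth,
        selection=[sym_a[i] for i in multi_a],
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    conserved_pairs = sorted((sym_a[i], sym_b[i]) for i in conserved)
    return SpeciesPair(
        study_a=study_a,
        study_b=study_b,
        ortho=ortho,
        pathway=pathway,
        conserved_pairs=conserved_pairs,
        cooccur_a=sorted(sym_a[i] for i in multi_a),
        cooccur_b=sorted(sym_b[i] for i in multi_b),
    )


def gen_orthologs_and_pathways(
    cfg: SynthConfig,
    truth_a: dict[str, GeneTruth],
    truth_b: dict[str, GeneTruth],
    selection: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[OrthologMap, PathwayGeneSet]:
    """A 1:1 symbol map covering a configurable fraction of genes (always
    including planted genes, so conservation crossing is well-defined), and a
    pathway of configured size containing ``n_selected_in_pathway`` of the
    selection, padded with universe filler symbols."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    sym_a = list(truth_a)
    sym_b = list(truth_b)
    if len(sym_a) != len(sym_b):
        raise ConfigError("species must have equal gene counts for the 1:1 map")
    n = len(sym_a)
    forced = {
        i
        for i, (a, b) in enumerate(zip(sym_a, sym_b))
        if truth_a[a].planted or truth_b[b].planted
    }
    n_map = max(int(round(cfg.ortholog_fraction * n)), len(forced))
    optional = [i for i in range(n) if i not in forced]
    extra = [
        optional[j]
        for j in rng.choice(len(optional), size=n_map - len(forced), replace=False)
    ]
    mapped = sorted(forced | set(extra))
    ortho = OrthologMap([(sym_a[i], sym_b[i]) for i in mapped])

    n_in = min(cfg.n_selected_in_pathway, len(selection))
    if cfg.pathway_size < n_in:
        raise ConfigError("pathway smaller than its selected members")
    chosen = [selection[j] for j in rng.choice(len(selection), size=n_in, replace=False)] \
        if n_in else []
    fillers = [f"uG{j:05d}" for j in range(cfg.pathway_size - n_in)]
    pathway = PathwayGeneSet(
        pathway_id=cfg.pathway_id,
        members=frozenset(chosen) | frozenset(fillers),
        universe_size=cfg.pathway_universe,
    )
    return ortho, pathway


def gen_background_windows(
    n: int,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    symbol_prefix: str = "bg",
) -> list[PromoterWindow]:
    """Plain background promoter windows (no planting, no cleaning): the
    empirical null for the model's false-positive rate."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return [
        PromoterWindow(
            gene_symbol=f"{symbol_prefix}{i:06d}",
            transcript_ids=(f"{symbol_prefix}T{i:06d}",),
            sequence=random_sequence(rng, cfg.window_spec.length, cfg.base_probs, cfg.markov),
            window_spec=cfg.window_spec,
        )
        for i in range(n)
    ]


# --------------------------------------------------------------------------
# plain-text writers


def write_genome_fasta(genome: GenomeSource, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_table(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_symbol\tcontig\tstrand\ttss\n")
        for t in transcripts:
            fh.write(f"{t.transcript_id}\t{t.gene_symbol}\t{t.contig}\t{t.strand}\t{t.tss}\n")


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index=False)


def write_ortholog_tsv(ortho: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol_a\tsymbol_b\n")
        for a, b in ortho.pairs:
            fh.write(f"{a}\t{b}\n")


def write_pathway_tsv(pathway: PathwayGeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway_id\tgene_symbol\n")
        for g in sorted(pathway.members):
            fh.write(f"{pathway.pathway_id}\t{g}\n")


def write_truth_json(truth: dict[str, GeneTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({g: t.to_dict() for g, t in truth.items()}, fh, indent=1)
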