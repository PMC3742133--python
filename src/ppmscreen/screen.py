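"""Pipeline stages: training sets, model validation, genome-wide screening,
cross-species conservation crossing, co-occurrence selection, and pathway
over-representation.

Gene-level semantics throughout: every deduplicated alternative promoter of a
gene is classified and a gene counts as fitting a tier if ANY of its windows
fits ("unique protein-coding genes" aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, StatError
from .ppm_model import (
    TIERS,
    MatchEvidence,
    PPMDefinition,
    Tier,
    classify_window,
)
from .promoter_io import PromoterWindow
from .stats import (
    ContingencyTable,
    ValidationReport,
    chi2_yates,
    validation_report,
)

DE_COLUMNS = ("gene_symbol", "fold_change", "direction", "fdr")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table (gene_symbol, fold_change,
    direction, fdr), as produced upstream by a limma-style analysis."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"DE table {path} is missing required column(s): {', '.join(missing)}"
        )
    if ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise FormatError(f"DE table {path}: fdr values must lie in [0, 1]")
    if (df["fold_change"] < 1).any():
        raise FormatError(
            f"DE table {path}: fold_change must be >= 1 with a direction flag"
        )
    if not df["direction"].isin(["up", "down"]).all():
        raise FormatError(f"DE table {path}: direction must be 'up' or 'down'")
    return df


@dataclass
class TrainingSets:
    """Positive genes (most confident differential expression) and a random
    negative promoter set drawn from the gene universe."""

    positive: list[str]
    negative: list[str]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ConfigError(f"training sets overlap: {sorted(overlap)[:5]}")


def build_training_sets(
    de: pd.DataFrame,
    universe: Sequence[str],
    fdr_cut: float = 0.01,
    n_neg: int = 2000,
    seed: int = 0,
) -> TrainingSets:
    """Positives = genes with fdr < ``fdr_cut``; negatives = ``n_neg`` genes
    sampled uniformly without replacement from the universe minus positives,
    reproducibly under ``seed``."""
    positives = list(dict.fromkeys(de.loc[de["fdr"] < fdr_cut, "gene_symbol"]))
    missing = set(positives) - set(universe)
    if missing:
        raise ConfigError(
            f"positive genes absent from the universe: {sorted(missing)[:5]}"
        )
    pool = sorted(set(universe) - set(positives))
    if len(pool) < n_neg:
        raise ConfigError(
            f"universe leaves only {len(pool)} candidates for a negative set of {n_neg}"
        )
    rng = np.random.default_rng(seed)
    negative = [pool[i] for i in rng.choice(len(pool), size=n_neg, replace=False)]
    return TrainingSets(positive=positives, negative=negative, seed=seed)


def _genes_fitting(
    windows: Iterable[PromoterWindow], ppm: PPMDefinition
) -> dict[Tier, set[str]]:
    fitting: dict[Tier, set[str]] = {tier: set() for tier in TIERS}
    for win in windows:
        evidence = classify_window(win, ppm)
        for tier in TIERS:
            if evidence.fits[tier]:
                fitting[tier].add(win.gene_symbol)
    return fitting


def validate_ppm(
    pos_windows: Sequence[PromoterWindow],
    neg_windows: Sequence[PromoterWindow],
    ppm: PPMDefinition | None = None,
    conf: float = 0.95,
) -> ValidationReport:
    """Count genes fitting each tier in the (+) and (-) sets and derive the
    validation surface (fold enrichment, Fisher p, sensitivity/specificity
    with exact CIs) per tier. Windows should be deduplicated."""
    if not pos_windows or not neg_windows:
        raise ConfigError("both training sets must contain at least one window")
    ppm = ppm or PPMDefinition()
    pos_genes = sorted({w.gene_symbol for w in pos_windows})
    neg_genes = sorted({w.gene_symbol for w in neg_windows})
    pos_fit = _genes_fitting(pos_windows, ppm)
    neg_fit = _genes_fitting(neg_windows, ppm)
    tables = []
    for tier in TIERS:
        ph = len(pos_fit[tier] & set(pos_genes))
        nh = len(neg_fit[tier] & set(neg_genes))
        tables.append(
            (
                tier.label,
                ContingencyTable(
                    pos_hit=ph,
                    pos_miss=len(pos_genes) - ph,
                    neg_hit=nh,
                    neg_miss=len(neg_genes) - nh,
                ),
            )
        )
    return validation_report(tables, conf)


@dataclass
class ScreenHit:
    """One gene retrieved by the genome-wide screen, with the evidence of its
    best-scoring promoter window."""

    gene_symbol: str
    transcript_ids: tuple[str, ...]
    fits: dict[Tier, bool]
    canonical_site_count: int
    admissible_pair_count: int

    def __post_init__(self) -> None:
        if self.admissible_pair_count < 1:
            raise ConfigError("a reported screen hit must carry at least one pair")


def _best_evidence(evidences: list[MatchEvidence], tier: Tier) -> MatchEvidence:
    return min(
        evidences,
        key=lambda ev: (
            -len(ev.pairs_by_tier[tier]),
            -ev.canonical_hit_count,
            min(ev.window.transcript_ids),
        ),
    )


def screen_genome(
    windows: Sequence[PromoterWindow], ppm: PPMDefinition | None = None
) -> list[ScreenHit]:
    """One ScreenHit per unique gene with at least one window fitting
    ``ppm.tier``. Site/pair counts come from the best window (max pair count,
    then max canonical count, then lexicographically first transcript id).
    Output sorted by gene symbol."""
    ppm = ppm or PPMDefinition()
    by_gene: dict[str, list[MatchEvidence]] = {}
    for win in windows:
        evidence = classify_window(win, ppm)
        if evidence.fits[ppm.tier]:
            by_gene.setdefault(win.gene_symbol, []).append(evidence)
    hits = []
    for gene in sorted(by_gene):
        best = _best_evidence(by_gene[gene], ppm.tier)
        hits.append(
            ScreenHit(
                gene_symbol=gene,
                transcript_ids=best.window.transcript_ids,
                fits=dict(best.fits),
                canonical_site_count=best.canonical_hit_count,
                admissible_pair_count=len(best.pairs_by_tier[ppm.tier]),
            )
        )
    return hits


class OrthologMap:
    """Symmetric 1:1-ish symbol map between two species."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs = list(pairs)
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}
        for a, b in self.pairs:
            self.a_to_b[a] = b
            self.b_to_a[b] = a

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise FormatError(f"ortholog map {path} needs two symbol columns")
        cols = df.columns[:2]
        return cls(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))

    def __len__(self) -> int:
        return len(self.pairs)


def conserved_intersection(
    hits_a: Sequence[ScreenHit],
    hits_b: Sequence[ScreenHit],
    ortho: OrthologMap,
) -> list[tuple[str, str]]:
    """Ortholog pairs whose genes appear in both species' screen selections.
    Deliberately position- and orientation-free: only the presence of an
    admissible pair in each species is required."""
    genes_a = {h.gene_symbol for h in hits_a}
    genes_b = {h.gene_symbol for h in hits_b}
    out = [
        (a, b)
        for a, b in ortho.pairs
        if a in genes_a and b in genes_b
    ]
    out.sort()
    return out


def cooccurrence_select(
    hits: Sequence[ScreenHit], min_sites: int = 3, min_pairs: int = 2
) -> list[ScreenHit]:
    """Select genes whose promoters carry multiple interacting sites: at
    least ``min_sites`` canonical sites forming at least ``min_pairs``
    admissible pairs; ranked by pair count desc, site count desc, symbol."""
    selected = [
        h
        for h in hits
        if h.canonical_site_count >= min_sites and h.admissible_pair_count >= min_pairs
    ]
    selected.sort(
        key=lambda h: (-h.admissible_pair_count, -h.canonical_site_count, h.gene_symbol)
    )
    return selected


@dataclass(frozen=True)
class PathwayGeneSet:
    """A pathway's member symbols with the size of the gene universe the
    enrichment is assessed against (default: 25,504 unique ccds genes)."""

    pathway_id: str
    members: frozenset[str]
    universe_size: int = 25504

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"pathway {self.pathway_id} has no members")
        if len(self.members) >= self.universe_size:
            raise ConfigError("pathway cannot be as large as the universe")

    @classmethod
    def from_tsv(cls, path: str | Path, universe_size: int = 25504) -> "PathwayGeneSet":
        df = pd.read_csv(path, sep="\t")
        if not {"pathway_id", "gene_symbol"} <= set(df.columns):
            raise FormatError(
                f"pathway table {path} needs pathway_id and gene_symbol columns"
            )
        ids = df["pathway_id"].unique()
        if len(ids) != 1:
            raise FormatError(f"pathway table {path} must describe one pathway")
        return cls(str(ids[0]), frozenset(df["gene_symbol"].astype(str)), universe_size)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    n_selected: int
    n_in_pathway: int
    pathway_size: int
    universe_size: int
    fold: float
    chi2_stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "n_selected": self.n_selected,
            "n_in_pathway": self.n_in_pathway,
            "pathway_size": self.pathway_size,
            "universe_size": self.universe_size,
            "fold": self.fold,
            "chi2_stat": self.chi2_stat,
            "p_value": self.p_value,
            "p_below_1e4": self.p_value < 1e-4,
        }


def pathway_enrichment(
    selected: Sequence[str], pathway: PathwayGeneSet
) -> EnrichmentResult:
    """Over-representation of ``selected`` genes in the pathway against the
    universe: fold = (in_pathway/|selected|) / (|pathway|/universe); p from
    the Yates-corrected chi-square on the selected-vs-rest 2x2 table."""
    genes = list(dict.fromkeys(selected))
    if not genes:
        raise ConfigError("selection is empty")
    n_sel = len(genes)
    n_path = len(pathway.members)
    universe = pathway.universe_size
    if universe < n_sel + n_path:
        raise ConfigError("universe too small for selection and pathway")
    a = sum(1 for g in genes if g in pathway.members)
    fold = (a / n_sel) / (n_path / universe)
    table = ContingencyTable(
        pos_hit=a,
        pos_miss=n_sel - a,
        neg_hit=n_path - a,
        neg_miss=universe - n_sel - (n_path - a),
    )
    try:
        stat, p = chi2_yates(table)
    except StatError:
        stat, p = float("nan"), float("nan")
    return EnrichmentResult(
        pathway_id=pathway.pathway_id,
        n_selected=n_sel,
        n_in_pathway=a,
        pathway_size=n_path,
        universe_size=universe,
        fold=fold,
        chi2_stat=stat,
        p_value=p,
    )
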