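"""Gene-set enrichment by contingency test and ortholog-family categorisation.

The enrichment question — are members of a curated gene set (e.g. mammalian
obesity orthologs) over-represented among differentially expressed genes? —
is answered with a 2×2 Pearson chi-square on (in-set / not-in-set) ×
(DE / not-DE) over an explicit gene universe.

Ortholog gene families are categorised from per-species copy counts of a
focal species against a reference species: one-to-one (1,1), expansion
(more focal copies), contraction (fewer focal copies), many-to-many (equal
multi-copy), and species-specific families present in only one species.
Upstream of family building, per-gene transcript selection keeps the
longest CDS and drops peptides shorter than 50 amino acids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger("lncflux")

FAMILY_CATEGORIES = (
    "one_to_one",
    "expansion",
    "contraction",
    "many_to_many",
    "focal_specific",
    "reference_specific",
)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: in-set/out; cols: DE/not
    chi_square: float
    p_value: float
    odds_ratio: float
    continuity_added: bool = False


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    copy_counts: dict[str, int]
    category: str


@dataclass(frozen=True)
class CdsRecord:
    gene_id: str
    transcript_id: str
    cds_length: int
    peptide_length: int


def contingency_enrichment(
    gene_set: set, de_set: set, universe: set, yates: bool = False
) -> ContingencyResult:
    """Pearson chi-square enrichment of ``gene_set`` among ``de_set``.

    Both sets are intersected with the universe before tabulation. Yates
    continuity correction is off by default. The odds ratio gets a 0.5
    continuity increment only when a zero cell exists (flagged in the
    result). Expected cells < 5 trigger a warning recommending an exact
    test.
    """
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set) & set(universe)
    de_set = set(de_set) & set(universe)
    if gene_set == set(universe) or not gene_set:
        raise ValueError("gene set equals the universe or is empty: degenerate margin")
    if de_set == set(universe) or not de_set:
        raise ValueError("DE set equals the universe or is empty: degenerate margin")
    a = len(gene_set & de_set)
    b = len(gene_set - de_set)
    c = len(de_set - gene_set)
    d = len(universe) - a - b - c
    table = [[a, b], [c, d]]
    chi2, p, _, expected = stats.chi2_contingency(
        table, correction=yates
    )
    if (expected < 5).any():
        warnings.warn(
            "expected cell count < 5; consider an exact test", stacklevel=2
        )
    continuity = 0 in (a, b, c, d)
    if continuity:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return ContingencyResult(
        table=((a, b), (c, d)),
        chi_square=float(chi2),
        p_value=float(p),
        odds_ratio=float(orr),
        continuity_added=continuity,
    )


def select_longest_cds(records: list[CdsRecord], min_peptide_aa: int = 50) -> list[CdsRecord]:
    """One transcript per gene (longest CDS; ties to the lexicographically
    smaller transcript id), then drop peptides shorter than 50 aa
    ("fewer than 50" is strict, so exactly 50 is kept)."""
    by_gene: dict[str, CdsRecord] = {}
    for rec in records:
        cur = by_gene.get(rec.gene_id)
        if (
            cur is None
            or rec.cds_length > cur.cds_length
            or (rec.cds_length == cur.cds_length and rec.transcript_id < cur.transcript_id)
        ):
            by_gene[rec.gene_id] = rec
    return [
        by_gene[g] for g in sorted(by_gene) if by_gene[g].peptide_length >= min_peptide_aa
    ]


def categorize_pair(focal_count: int, reference_count: int) -> str:
    """Category of one family from its (focal, reference) copy counts."""
    f, r = focal_count, reference_count
    if f < 0 or r < 0:
        raise ValueError("copy counts must be non-negative")
    if f == 0 and r == 0:
        raise ValueError("family absent from both species")
    if f == 0:
        return "reference_specific"
    if r == 0:
        return "focal_specific"
    if f == 1 and r == 1:
        return "one_to_one"
    if f > r:
        return "expansion"
    if f < r:
        return "contraction"
    return "many_to_many"


def categorize_families(
    table: pd.DataFrame, focal: str, reference: str
) -> tuple[list[FamilyRecord], dict[str, float]]:
    """Categorise families from a long-format membership table.

    ``table`` columns: family_id, species, gene_id. Proportions are over
    families containing at least one focal-species gene.
    """
    required = {"family_id", "species", "gene_id"}
    if not required <= set(table.columns):
        raise ValueError(f"family table needs columns {sorted(required)}")
    counts = (
        table.groupby(["family_id", "species"])["gene_id"].nunique().unstack(fill_value=0)
    )
    for sp in (focal, reference):
        if sp not in counts.columns:
            counts[sp] = 0
    records = []
    for family_id, row in counts.sort_index().iterrows():
        f, r = int(row[focal]), int(row[reference])
        records.append(
            FamilyRecord(
                family_id=str(family_id),
                copy_counts={focal: f, reference: r},
                category=categorize_pair(f, r),
            )
        )
    with_focal = [rec for rec in records if rec.copy_counts[focal] > 0]
    denom = len(with_focal)
    proportions = {
        cat: (
            sum(rec.category == cat for rec in with_focal) / denom if denom else 0.0
        )
        for cat in FAMILY_CATEGORIES
    }
    return records, proportions


def de_proportion_by_category(
    records: list[FamilyRecord],
    de_set: set,
    focal_gene_map: dict[str, list[str]],
) -> dict[str, float | None]:
    """Fraction of focal genes that are DE, per family category.

    ``focal_gene_map`` maps family_id to its focal-species gene ids. A
    category with no focal genes reports ``None`` (undefined), not 0.
    """
    totals: dict[str, int] = {cat: 0 for cat in FAMILY_CATEGORIES}
    hits: dict[str, int] = {cat: 0 for cat in FAMILY_CATEGORIES}
    for rec in records:
        genes = focal_gene_map.get(rec.family_id, [])
        totals[rec.category] += len(genes)
        hits[rec.category] += sum(g in de_set for g in genes)
    return {
        cat: (hits[cat] / totals[cat]) if totals[cat] else None
        for cat in FAMILY_CATEGORIES
    }
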