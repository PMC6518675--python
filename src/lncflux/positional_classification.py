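"""Strand-aware positional classification of lncRNAs and cis-candidate calls.

Each putative lncRNA is assigned to exactly one of five categories relative
to its nearest protein-coding gene:

- ``sense_genic``       — overlapping the gene span, same strand
- ``sense_intergenic``  — non-overlapping, same strand
- ``convergent``        — non-overlapping, opposite strand, 3'-ends facing,
                          within the proximal window
- ``divergent``         — non-overlapping, opposite strand, 5'-ends facing,
                          within the proximal window
- ``antisense_intergenic`` — opposite strand, farther than the proximal
                          window from the nearest gene

Two opposite-strand transcripts on a line always face either 3'-to-3' or
5'-to-5'; the convergent/divergent labels are reserved for the
promoter/terminator-proximal configurations (default window 10 kb, the same
span as the cis window), and distal opposite-strand lncRNAs fall in the
generic antisense-intergenic class. An overlapping opposite-strand lncRNA —
a configuration the five-class taxonomy has no dedicated name for — is
resolved by the same facing-ends rule evaluated at distance zero (relative
midpoints along the gene's orientation) and logged.

Distances are measured between genomic spans (closest ends, exon structure
ignored) and are signed relative to the *gene's* strand: negative when the
lncRNA lies downstream of the gene's 3' end, positive when upstream of its
5' end, zero when overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .genome import AnnotationSet, GeneModel, TranscriptModel

logger = logging.getLogger("lncflux")

CATEGORIES = (
    "sense_intergenic",
    "sense_genic",
    "convergent",
    "divergent",
    "antisense_intergenic",
)

DEFAULT_CIS_WINDOW = 10_000


@dataclass(frozen=True)
class LncRNARecord:
    transcript_id: str
    category: str
    nearest_gene_id: str | None
    signed_distance: int | None
    cis_candidate: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _span_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open spans; 0 when they overlap or abut."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def _signed_gap(lnc: TranscriptModel, gene: GeneModel) -> int:
    """Gap signed by position relative to the gene's strand.

    Negative downstream of the gene's 3' end, positive upstream of its 5'
    end, 0 when the spans overlap.
    """
    gap = _span_gap(lnc.start, lnc.end, gene.start, gene.end)
    if gap == 0 and not (lnc.end <= gene.start or gene.end <= lnc.start):
        return 0
    lnc_is_right = lnc.start >= gene.end
    if gene.strand == "+":
        return -gap if lnc_is_right else gap
    return gap if lnc_is_right else -gap


def nearest_gene(
    lnc: TranscriptModel, genes: AnnotationSet | list[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest protein-coding gene and signed span distance.

    Ties on the unsigned gap break toward the lexicographically smaller
    gene id. Returns ``(None, None)`` when the chromosome has no gene.
    """
    gene_list = _gene_list(genes)
    candidates = [g for g in gene_list if g.chromosome == lnc.chromosome]
    if not candidates:
        logger.warning(
            "no gene on chromosome %s for %s; no-neighbor sentinel returned",
            lnc.chromosome,
            lnc.transcript_id,
        )
        return None, None
    best = min(
        candidates,
        key=lambda g: (_span_gap(lnc.start, lnc.end, g.start, g.end), g.gene_id),
    )
    return best.gene_id, _signed_gap(lnc, best)


def _gene_list(genes: AnnotationSet | list[GeneModel]) -> list[GeneModel]:
    if isinstance(genes, AnnotationSet):
        gl = genes.genes(biotype="protein_coding")
        return gl if gl else genes.genes()
    return list(genes)


def _overlaps(lnc: TranscriptModel, gene: GeneModel) -> bool:
    return lnc.start < gene.end and gene.start < lnc.end


def classify_lncrna(
    lnc: TranscriptModel,
    genes: AnnotationSet | list[GeneModel],
    window: int = DEFAULT_CIS_WINDOW,
    proximal_window: int | None = None,
) -> LncRNARecord:
    """Assign the positional category relative to the nearest gene.

    ``window`` is the cis-candidate span; ``proximal_window`` bounds the
    convergent/divergent calls and defaults to ``window``.
    """
    if lnc.strand not in "+-":
        raise ValueError(f"lncRNA {lnc.transcript_id} has no usable strand")
    if proximal_window is None:
        proximal_window = window
    gene_list = _gene_list(genes)
    gene_id, signed = nearest_gene(lnc, gene_list)
    if gene_id is None:
        # no neighbor on the chromosome: intergenic by the strandless rule
        return LncRNARecord(lnc.transcript_id, "sense_intergenic", None, None, False)
    gene = next(g for g in gene_list if g.gene_id == gene_id)
    same_strand = lnc.strand == gene.strand
    overlapping = _overlaps(lnc, gene)
    if overlapping:
        if same_strand:
            category = "sense_genic"
        else:
            # no antisense-genic class exists; use the facing-ends rule on
            # relative midpoints along the gene's orientation
            lnc_mid = lnc.start + lnc.end
            gene_mid = gene.start + gene.end
            downstream = (
                lnc_mid >= gene_mid if gene.strand == "+" else lnc_mid <= gene_mid
            )
            category = "convergent" if downstream else "divergent"
            logger.info(
                "opposite-strand overlap for %s on %s resolved to %s",
                lnc.transcript_id,
                gene_id,
                category,
            )
    elif same_strand:
        category = "sense_intergenic"
    else:
        gap = abs(signed)
        if gap > proximal_window:
            category = "antisense_intergenic"
        elif signed < 0:
            category = "convergent"  # lnc past the gene's 3' end: 3'-3' facing
        else:
            category = "divergent"  # lnc before the gene's 5' end: 5'-5' facing
    cis = abs(signed) <= window
    return LncRNARecord(lnc.transcript_id, category, gene_id, signed, cis)


def classify_all(
    lncs: AnnotationSet,
    genes: AnnotationSet | list[GeneModel],
    window: int = DEFAULT_CIS_WINDOW,
    proximal_window: int | None = None,
) -> list[LncRNARecord]:
    gene_list = _gene_list(genes)
    return [
        classify_lncrna(t, gene_list, window=window, proximal_window=proximal_window)
        for t in lncs
    ]


def cis_candidates(
    lncs: AnnotationSet,
    genes: AnnotationSet | list[GeneModel],
    window: int = DEFAULT_CIS_WINDOW,
) -> list[tuple[str, str, int]]:
    """All (lncRNA, gene) pairs whose span gap is ≤ window (inclusive).

    Not restricted to the nearest gene; returns signed distances under the
    gene-strand convention. Sorted by (lncRNA id, gene id).
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    gene_list = _gene_list(genes)
    out: list[tuple[str, str, int]] = []
    for lnc in lncs:
        for g in gene_list:
            if g.chromosome != lnc.chromosome:
                continue
            if _span_gap(lnc.start, lnc.end, g.start, g.end) <= window:
                out.append((lnc.transcript_id, g.gene_id, _signed_gap(lnc, g)))
    return sorted(out)
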