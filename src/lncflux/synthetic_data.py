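"""Seeded synthetic fixtures emulating the study's data structure.

Generates, with planted ground truth: a toy genome annotation
(non-overlapping multi-exon protein-coding genes plus lncRNAs constructed
geometrically for each of the five positional categories), candidate
assembled transcripts engineered to exercise every stage of the discovery
filter cascade, an FPKM-like expression matrix over the 3-tissue × 2-
treatment × 3-replicate design with planted tissue/treatment effects and
correlated lncRNA–mRNA pairs, an ortholog family table with planted
category proportions, and a gene set enriched among the planted DE genes.

Every output is a pure function of the ``SimulationConfig`` (one seed, one
``numpy.random.default_rng`` stream consumed in a fixed order), so a fixed
config yields byte-identical files.

Noise model: replicate noise is additive Gaussian on the log2 scale
(log-normal FPKM). Planted correlated pairs share a per-sample Gaussian
latent factor with loading sqrt(rho) so the expected Pearson correlation
between the two members equals ``pair_correlation``; pair members carry no
tissue or treatment effects so the planted correlation is not confounded.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_stats import ExpressionMatrix
from .genome import AnnotationSet, TranscriptModel, write_gtf, write_transcript_fasta
from .positional_classification import CATEGORIES

DEFAULT_TISSUES = ("liver", "abdominal_adipose", "subcutaneous_adipose")

DEFAULT_FAMILY_PROPORTIONS = {
    "one_to_one": 0.60,
    "expansion": 0.10,
    "contraction": 0.10,
    "many_to_many": 0.05,
    "focal_specific": 0.10,
    "reference_specific": 0.05,
}

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the study design
    (3 tissues × 2 treatments × 3 biological replicates)."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 4_000_000
    n_genes: int = 200
    n_lncrna_per_category: int = 6
    n_samples_per_group: int = 3
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    de_fraction: float = 0.10
    de_log2fc: float = 3.0
    pair_correlation: float = 0.95
    noise_sd: float = 0.15
    tissue_effect_sd: float = 1.5
    n_correlated_pairs: int = 10
    min_intergenic_gap: int = 25_000
    n_decoys_per_kind: int = 2
    n_families: int = 100
    family_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_PROPORTIONS)
    )
    focal_species: str = "goose"
    reference_species: str = "human"

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes",
            "chromosome_length",
            "n_genes",
            "n_lncrna_per_category",
            "n_samples_per_group",
            "n_families",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0 <= self.pair_correlation <= 1:
            raise ValueError("pair_correlation must lie in [0, 1]")
        if self.noise_sd < 0 or self.tissue_effect_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        total = sum(self.family_proportions.values())
        if total > 1 + 1e-9:
            raise ValueError("family proportions must sum to <= 1")
        if any(v < 0 for v in self.family_proportions.values()):
            raise ValueError("family proportions must be non-negative")
        if 5 * self.n_lncrna_per_category > self.n_genes:
            raise ValueError(
                "need at least one host gene per planted lncRNA: "
                "n_genes >= 5 * n_lncrna_per_category"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{t}.{trt}.{r}"
            for t in self.tissues
            for trt in ("control", "high_intake")
            for r in range(1, self.n_samples_per_group + 1)
        ]

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream per generation step."""
        child = np.random.SeedSequence(
            [self.seed, zlib.crc32(stream.encode()) % (2**31)]
        )
        return np.random.default_rng(child)


@dataclass
class GroundTruth:
    """Planted labels for every downstream stage."""

    lncrna_categories: dict[str, str] = field(default_factory=dict)
    lncrna_host_gene: dict[str, str] = field(default_factory=dict)
    de_features: dict[str, list[str]] = field(default_factory=dict)
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    family_categories: dict[str, str] = field(default_factory=dict)
    expected_survivors: list[str] = field(default_factory=list)
    decoy_stage: dict[str, str] = field(default_factory=dict)
    gene_set: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_pairs"] = [tuple(p) for p in raw.get("planted_pairs", [])]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _make_exons(rng: np.random.Generator, start: int, n_exons: int,
                exon_len_range=(150, 600), intron_len_range=(200, 1500)):
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len_range))
        exons.append((pos, pos + length))
        pos += length
        if i < n_exons - 1:
            pos += int(rng.integers(*intron_len_range))
    return tuple(exons)


def generate_annotation(config: SimulationConfig) -> tuple[AnnotationSet, GroundTruth]:
    """Place non-overlapping multi-exon genes and plant lncRNAs of all five
    positional categories around dedicated host genes.

    Genes are spaced by at least ``min_intergenic_gap`` (default 25 kb) so
    each lncRNA's nearest gene is unambiguously its host. Raises when the
    chromosomes cannot hold the requested features.
    """
    rng = config.rng("annotation")
    margin = config.min_intergenic_gap + 5_000
    transcripts: list[TranscriptModel] = []
    gene_slots: list[tuple[str, TranscriptModel]] = []  # (chrom, gene transcript)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: margin for c in chrom_names}
    chrom_i = 0
    for gi in range(config.n_genes):
        n_exons = int(rng.integers(2, 6))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(config.n_chromosomes):
            chrom = chrom_names[chrom_i % config.n_chromosomes]
            start = cursors[chrom]
            exons = _make_exons(rng, start, n_exons)
            if exons[-1][1] + margin <= config.chromosome_length:
                gene_id = f"gene{gi + 1:04d}"
                t = TranscriptModel(
                    transcript_id=f"{gene_id}.t1",
                    gene_id=gene_id,
                    chromosome=chrom,
                    strand=strand,
                    exons=exons,
                    biotype="protein_coding",
                )
                transcripts.append(t)
                gene_slots.append((chrom, t))
                cursors[chrom] = t.end + config.min_intergenic_gap
                chrom_i += 1
                placed = True
                break
            chrom_i += 1
        if not placed:
            raise ValueError(
                "chromosomes too short for the requested gene count: increase "
                "chromosome_length or reduce n_genes/min_intergenic_gap"
            )

    truth = GroundTruth()
    # one dedicated host gene per planted lncRNA, in placement order
    hosts = iter(gene_slots)
    lnc_i = 0
    gap = config.min_intergenic_gap
    for category in CATEGORIES:
        for _ in range(config.n_lncrna_per_category):
            chrom, host = next(hosts)
            lnc_i += 1
            lnc_id = f"lnc{lnc_i:04d}"
            n_exons = int(rng.integers(2, 4))
            # keep planted lncRNAs compact so distances stay unambiguous
            exon_rng = (150, 350)
            intron_rng = (100, 400)
            if category == "sense_genic":
                strand = host.strand
                start = host.start + 50
                exons = _make_exons(rng, start, 2, (100, 200), (100, 200))
                if exons[-1][1] >= host.end:  # stay inside the gene span
                    exons = ((host.start + 10, host.start + 160),
                             (host.start + 260, host.start + 410))
            else:
                if category == "sense_intergenic":
                    strand = host.strand
                    d = int(rng.integers(1_000, 8_000))
                    side = "right" if rng.random() < 0.5 else "left"
                elif category == "convergent":
                    strand = "-" if host.strand == "+" else "+"
                    d = int(rng.integers(1_000, 8_000))
                    side = "right" if host.strand == "+" else "left"  # downstream
                elif category == "divergent":
                    strand = "-" if host.strand == "+" else "+"
                    d = int(rng.integers(1_000, 8_000))
                    side = "left" if host.strand == "+" else "right"  # upstream
                else:  # antisense_intergenic: opposite strand, beyond 10 kb
                    strand = "-" if host.strand == "+" else "+"
                    lo = 10_250
                    hi = max(lo + 1, (gap - 2_000) // 2)
                    d = int(rng.integers(lo, hi))
                    side = "right" if rng.random() < 0.5 else "left"
                span_budget = 1_200
                probe = _make_exons(rng, 0, n_exons, exon_rng, intron_rng)
                while probe[-1][1] > span_budget:
                    probe = _make_exons(rng, 0, 2, (150, 250), (100, 200))
                span = probe[-1][1]
                if side == "right":
                    start = host.end + d
                else:
                    start = host.start - d - span
                exons = tuple((s + start, e + start) for s, e in probe)
            lnc = TranscriptModel(
                transcript_id=lnc_id,
                gene_id=lnc_id,
                chromosome=chrom,
                strand=strand,
                exons=exons,
                biotype="lncRNA",
            )
            transcripts.append(lnc)
            truth.lncrna_categories[lnc_id] = category
            truth.lncrna_host_gene[lnc_id] = host.gene_id
    return AnnotationSet(transcripts), truth


def split_annotation(annotation: AnnotationSet) -> tuple[AnnotationSet, AnnotationSet]:
    """(protein-coding reference, planted lncRNAs)."""
    ref = [t for t in annotation if t.biotype == "protein_coding"]
    lnc = [t for t in annotation if t.biotype == "lncRNA"]
    return AnnotationSet(ref), AnnotationSet(lnc)


# ---------------------------------------------------------------------------
# Candidate transcripts + sequences (for the filter cascade)
# ---------------------------------------------------------------------------


def _noncoding_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no ORF of >= 100 codons (rejection sampled)."""
    from .transcript_filtering import _longest_orf_codons

    bases = np.array(list("ACGT"))
    for _ in range(100):
        seq = "".join(rng.choice(bases, size=length))
        if _longest_orf_codons(seq) < 100:
            return seq
    raise RuntimeError("failed to draw a non-coding sequence")  # pragma: no cover


def _coding_sequence(rng: np.random.Generator, n_codons: int = 150) -> str:
    """Sequence containing an uninterrupted ORF of ``n_codons`` codons."""
    safe = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS and a + b + c != "ATG"
    ]
    body = "".join(rng.choice(safe, size=n_codons - 1))
    prefix = "".join(rng.choice(np.array(list("CT")), size=7))
    return prefix + "ATG" + body + "TAA"


def generate_candidates(
    config: SimulationConfig, annotation: AnnotationSet, truth: GroundTruth
) -> tuple[list[TranscriptModel], GroundTruth]:
    """Candidate assembled transcripts: the planted lncRNAs (which survive
    the cascade) plus decoys removed at each stage (reference copies '=',
    contained 'c', sub-200-bp, coding-potential-positive and mono-exonic)."""
    rng = config.rng("candidates")
    reference, lncs = split_annotation(annotation)
    candidates: list[TranscriptModel] = []
    for t in lncs:
        seq = _noncoding_sequence(rng, t.spliced_length)
        candidates.append(t.with_sequence(seq))
        truth.expected_survivors.append(t.transcript_id)
    ref_list = list(reference)
    tail_chrom = ref_list[-1].chromosome
    tail = max(t.end for t in reference.on_chromosome(tail_chrom)) + 15_000
    for k in range(config.n_decoys_per_kind):
        host = ref_list[int(rng.integers(0, len(ref_list)))]
        tid = f"decoy_eq{k + 1}"
        candidates.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tid,
                chromosome=host.chromosome,
                strand=host.strand,
                exons=host.exons,
                biotype="",
            ).with_sequence(_noncoding_sequence(rng, host.spliced_length))
        )
        truth.decoy_stage[tid] = "class"

        host2 = ref_list[int(rng.integers(0, len(ref_list)))]
        es, ee = host2.exons[0]
        inner = (es + 5, min(ee - 5, es + 125))  # mono-exonic, inside one exon
        tid = f"decoy_contained{k + 1}"
        candidates.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tid,
                chromosome=host2.chromosome,
                strand=host2.strand,
                exons=(inner,),
            ).with_sequence(_noncoding_sequence(rng, inner[1] - inner[0]))
        )
        truth.decoy_stage[tid] = "class"

        tid = f"decoy_short{k + 1}"
        start = tail
        exons = ((start, start + 80), (start + 300, start + 380))
        candidates.append(
            TranscriptModel(
                transcript_id=tid, gene_id=tid, chromosome=tail_chrom,
                strand="+", exons=exons,
            ).with_sequence(_noncoding_sequence(rng, 160))
        )
        truth.decoy_stage[tid] = "length"
        tail += 2_000

        tid = f"decoy_coding{k + 1}"
        seq = _coding_sequence(rng)
        half = len(seq) // 2
        exons = ((tail, tail + half), (tail + half + 500, tail + half + 500 + (len(seq) - half)))
        candidates.append(
            TranscriptModel(
                transcript_id=tid, gene_id=tid, chromosome=tail_chrom,
                strand="+", exons=exons,
            ).with_sequence(seq)
        )
        truth.decoy_stage[tid] = "coding"
        tail += 3_000

        tid = f"decoy_monoexonic{k + 1}"
        exons = ((tail, tail + 600),)
        candidates.append(
            TranscriptModel(
                transcript_id=tid, gene_id=tid, chromosome=tail_chrom,
                strand="+", exons=exons,
            ).with_sequence(_noncoding_sequence(rng, 600))
        )
        truth.decoy_stage[tid] = "monoexonic"
        tail += 2_000
    return candidates, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: SimulationConfig, annotation: AnnotationSet, truth: GroundTruth
) -> ExpressionMatrix:
    """FPKM-like matrix with planted tissue effects, treatment effects on
    DE features, and latent-factor-correlated lncRNA–mRNA pairs.

    log2 model per feature f and sample s:
    ``base_f + tissue_effect(f, tissue_s) + de_shift(f, s) + noise``;
    FPKM = 2**log2value (log-normal, hence all values >= 0). Pair members
    replace tissue/DE terms by a shared latent factor with loading
    sqrt(pair_correlation) scaled by ``noise_sd``.
    """
    rng = config.rng("expression")
    gene_ids = sorted({t.gene_id for t in annotation if t.biotype == "protein_coding"})
    lnc_ids = sorted({t.transcript_id for t in annotation if t.biotype == "lncRNA"})
    features = gene_ids + lnc_ids
    known = set(features)
    for tissue, ids in truth.de_features.items():
        unknown = set(ids) - known
        if unknown:
            raise ValueError(f"unknown DE feature ids for {tissue}: {sorted(unknown)}")

    sample_ids = config.sample_ids
    meta = pd.DataFrame(
        [
            {
                "tissue": t,
                "treatment": trt,
                "replicate": r,
            }
            for t in config.tissues
            for trt in ("control", "high_intake")
            for r in range(1, config.n_samples_per_group + 1)
        ],
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # planted correlated pairs: lncRNA x, coding gene y; both excluded from
    # tissue and DE effects so their correlation is the latent factor's
    n_pairs = min(config.n_correlated_pairs, len(lnc_ids), len(gene_ids))
    pair_lncs = lnc_ids[:n_pairs]
    pair_genes = gene_ids[-n_pairs:]
    pair_members = set(pair_lncs) | set(pair_genes)
    if not truth.planted_pairs:
        truth.planted_pairs = [
            (l, g, config.pair_correlation) for l, g in zip(pair_lncs, pair_genes)
        ]

    # planted DE features per tissue (never pair members)
    if not truth.de_features:
        eligible = [f for f in features if f not in pair_members]
        n_de = int(round(config.de_fraction * len(eligible)))
        for tissue in config.tissues:
            chosen = list(rng.choice(eligible, size=n_de, replace=False))
            truth.de_features[tissue] = sorted(chosen)

    n_f, n_s = len(features), len(sample_ids)
    f_index = {f: i for i, f in enumerate(features)}
    base = rng.normal(4.0, 1.5, size=n_f)
    log2m = np.tile(base[:, None], (1, n_s))

    tissue_of = meta["tissue"].to_numpy()
    treatment_of = meta["treatment"].to_numpy()
    tissue_effects = {
        t: rng.normal(0.0, config.tissue_effect_sd, size=n_f) for t in config.tissues
    }
    for j in range(n_s):
        log2m[:, j] += tissue_effects[tissue_of[j]]

    de_signs: dict[tuple[str, str], float] = {}
    for tissue in config.tissues:
        for fid in truth.de_features.get(tissue, []):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            de_signs[(tissue, fid)] = sign
            i = f_index[fid]
            mask = (tissue_of == tissue) & (treatment_of == "high_intake")
            log2m[i, mask] += sign * config.de_log2fc

    noise = rng.normal(0.0, 1.0, size=(n_f, n_s)) * config.noise_sd
    # latent factor per pair
    rho = config.pair_correlation
    for l, g, _ in truth.planted_pairs:
        z = rng.normal(0.0, 1.0, size=n_s)
        for fid in (l, g):
            i = f_index[fid]
            eps = rng.normal(0.0, 1.0, size=n_s)
            log2m[i, :] = base[i] + config.noise_sd * (
                np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            )
            noise[i, :] = 0.0
    log2m += noise

    values = pd.DataFrame(
        np.power(2.0, log2m), index=pd.Index(features, name="feature_id"),
        columns=sample_ids,
    )
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# Ortholog families and gene set
# ---------------------------------------------------------------------------


def generate_family_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Long-format family membership table with planted category labels."""
    rng = config.rng("families")
    n = config.n_families
    planned: list[str] = []
    for cat, prop in sorted(config.family_proportions.items()):
        planned.extend([cat] * int(round(prop * n)))
    while len(planned) < n:
        planned.append("one_to_one")
    planned = planned[:n]
    truth = GroundTruth()
    rows = []
    focal, reference = config.focal_species, config.reference_species
    for i, cat in enumerate(planned):
        fam = f"fam{i + 1:04d}"
        if cat == "one_to_one":
            f, r = 1, 1
        elif cat == "expansion":
            f = int(rng.integers(2, 5))
            r = int(rng.integers(1, f))
        elif cat == "contraction":
            r = int(rng.integers(2, 5))
            f = int(rng.integers(1, r))
        elif cat == "many_to_many":
            f = r = int(rng.integers(2, 5))
        elif cat == "focal_specific":
            f, r = int(rng.integers(1, 4)), 0
        else:  # reference_specific
            f, r = 0, int(rng.integers(1, 4))
        truth.family_categories[fam] = cat
        for j in range(f):
            rows.append({"family_id": fam, "species": focal, "gene_id": f"{fam}.{focal}.{j + 1}"})
        for j in range(r):
            rows.append({"family_id": fam, "species": reference, "gene_id": f"{fam}.{reference}.{j + 1}"})
    return pd.DataFrame(rows, columns=["family_id", "species", "gene_id"]), truth


def generate_gene_set(
    config: SimulationConfig,
    annotation: AnnotationSet,
    truth: GroundTruth,
    tissue: str | None = None,
    de_weight: float = 0.5,
    size: int = 30,
) -> list[str]:
    """A gene set enriched among the planted DE genes of one tissue
    (half drawn from planted DE genes, half from the rest), emulating a
    curated disease-ortholog list."""
    rng = config.rng("gene_set")
    tissue = tissue or config.tissues[0]
    gene_ids = sorted({t.gene_id for t in annotation if t.biotype == "protein_coding"})
    de = [g for g in truth.de_features.get(tissue, []) if g in set(gene_ids)]
    non_de = [g for g in gene_ids if g not in set(de)]
    n_de = min(len(de), int(round(size * de_weight)))
    n_other = min(len(non_de), size - n_de)
    chosen = list(rng.choice(de, size=n_de, replace=False)) + list(
        rng.choice(non_de, size=n_other, replace=False)
    )
    truth.gene_set = sorted(chosen)
    return truth.gene_set


# ---------------------------------------------------------------------------
# Fixture bundle on disk
# ---------------------------------------------------------------------------


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every fixture and write the file bundle; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_annotation(config)
    reference, _ = split_annotation(annotation)
    candidates, truth = generate_candidates(config, annotation, truth)
    expr = generate_expression(config, annotation, truth)
    families, fam_truth = generate_family_table(config)
    truth.family_categories = fam_truth.family_categories
    generate_gene_set(config, annotation, truth)

    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "candidates_gtf": outdir / "candidates.gtf",
        "candidates_fasta": outdir / "candidates.fa",
        "expression_tsv": outdir / "expression.tsv",
        "samples_tsv": outdir / "samples.tsv",
        "families_tsv": outdir / "families.tsv",
        "gene_set_txt": outdir / "gene_set.txt",
        "truth_json": outdir / "ground_truth.json",
    }
    write_gtf(reference, paths["reference_gtf"])
    write_gtf(candidates, paths["candidates_gtf"])
    write_transcript_fasta(candidates, paths["candidates_fasta"])
    expr.write(paths["expression_tsv"], paths["samples_tsv"])
    families.to_csv(paths["families_tsv"], sep="\t", index=False)
    with open(paths["gene_set_txt"], "w") as fh:
        fh.write("\n".join(truth.gene_set) + "\n")
    truth.to_json(paths["truth_json"])
    return paths
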