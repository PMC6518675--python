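"""lncRNA discovery filter cascade.

Candidate assembled transcripts are compared against a reference annotation
and filtered in four ordered stages:

1. **class** — drop candidates whose structure matches a reference
   transcript: class code ``=`` (identical intron chain) or ``c``
   (contained, intron-compatible). Strand-unknown candidates are also
   removed here, under a separate ``unstranded`` counter.
2. **length** — drop candidates with spliced (summed exon) length < 200 bp.
3. **coding** — drop candidates whose coding-potential score exceeds 1.
   The built-in score is longest-ORF-length-in-codons / 100, so the
   threshold corresponds to an open reading frame of ~100 codons;
   externally computed scores (e.g. from an SVM classifier) can be loaded
   from a TSV and override the built-in score per transcript.
4. **monoexonic** — drop single-exon candidates.

Survivors are the putative lncRNA set. Each removed transcript is
attributed to the first stage it fails, and the report satisfies
``input_count == sum(removed_by.values()) + len(surviving_ids)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genome import AnnotationSet, TranscriptModel

logger = logging.getLogger("lncflux")

REMOVED_CLASS_CODES = frozenset({"=", "c"})
_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class ClassCode:
    """Structural relation of a candidate to the reference annotation.

    ``=`` identical intron chain (same strand; terminal exon ends may
    differ); ``c`` contained within a same-strand reference transcript and
    intron-compatible; ``u`` no exonic overlap with any reference
    transcript; ``x`` exonic overlap on the opposite strand only; ``o``
    other (partial same-strand exonic overlap).
    """

    code: str
    matched_reference_id: str = ""

    def __post_init__(self) -> None:
        if self.code not in {"=", "c", "u", "o", "x"}:
            raise ValueError(f"unknown class code {self.code!r}")
        if self.code in REMOVED_CLASS_CODES and not self.matched_reference_id:
            raise ValueError(f"class {self.code!r} requires a matched reference id")


@dataclass(frozen=True)
class CodingScore:
    transcript_id: str
    score: float
    source: str = "builtin"  # builtin | external

    def __post_init__(self) -> None:
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"non-finite coding score for {self.transcript_id}")


@dataclass
class FilterParams:
    min_length: int = 200
    max_coding_score: float = 1.0
    min_exons: int = 2


@dataclass
class FilterReport:
    input_count: int
    removed_by: dict[str, int]
    surviving_ids: list[str]
    class_codes: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        if self.input_count != sum(self.removed_by.values()) + len(self.surviving_ids):
            raise AssertionError("filter report does not account for every input")


def _is_contained(candidate: TranscriptModel, ref: TranscriptModel) -> bool:
    """Candidate exon chain contained in ref and intron-compatible."""
    if candidate.start < ref.start or candidate.end > ref.end:
        return False
    if candidate.n_exons == 1:
        s, e = candidate.exons[0]
        return any(rs <= s and e <= re for rs, re in ref.exons)
    cand_introns = candidate.introns
    ref_introns = ref.introns
    k = len(cand_introns)
    for j in range(len(ref_introns) - k + 1):
        if ref_introns[j : j + k] == cand_introns:
            # terminal exons must stay inside the flanking reference exons
            if (
                candidate.exons[0][0] >= ref.exons[j][0]
                and candidate.exons[-1][1] <= ref.exons[j + k][1]
            ):
                return True
    return False


def assign_class_code(candidate: TranscriptModel, reference: AnnotationSet) -> ClassCode:
    """Classify a candidate against the reference annotation.

    Precedence when several reference transcripts are relevant:
    ``=`` > ``c`` > ``o`` > ``x``; ``u`` when nothing overlaps. Matched
    reference ids are resolved to the lexicographically smallest for
    determinism.
    """
    if not candidate.exons:  # unreachable via TranscriptModel, kept for raw use
        raise ValueError(f"candidate {candidate.transcript_id} has zero exons")
    equal_ids: list[str] = []
    contained_ids: list[str] = []
    same_strand_overlap = False
    opposite_overlap = False
    for ref in reference.on_chromosome(candidate.chromosome):
        if not candidate.overlaps_exonic(ref):
            continue
        if ref.strand == candidate.strand and candidate.strand in "+-":
            same_strand_overlap = True
            if candidate.introns == ref.introns:
                equal_ids.append(ref.transcript_id)
            elif _is_contained(candidate, ref):
                contained_ids.append(ref.transcript_id)
        else:
            opposite_overlap = True
    if equal_ids:
        return ClassCode("=", min(equal_ids))
    if contained_ids:
        return ClassCode("c", min(contained_ids))
    if same_strand_overlap:
        return ClassCode("o")
    if opposite_overlap:
        return ClassCode("x")
    return ClassCode("u")


def _longest_orf_codons(sequence: str) -> int:
    """Longest ORF in codons over the three forward frames.

    An ORF starts at ATG and runs in-frame to the first stop codon; the
    codon count includes the start and excludes the stop. An ORF with no
    in-frame stop before the sequence end counts to the last full codon.
    """
    seq = sequence.upper()
    best = 0
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                codons = 0
                j = i
                while j + 3 <= n:
                    codon = seq[j : j + 3]
                    if codon in _STOP_CODONS:
                        break
                    codons += 1
                    j += 3
                best = max(best, codons)
                i = j + 3  # restart past this ORF's stop
            else:
                i += 3
    return best


def builtin_coding_score(t: TranscriptModel) -> CodingScore:
    """ORF-length-based coding-potential score.

    ``score = longest_orf_codons / 100`` so that the removal threshold of 1
    corresponds to a ~100-codon open reading frame. Deterministic; requires
    the spliced sequence and a length of at least 200 nt.
    """
    if t.sequence is None:
        raise ValueError(
            f"transcript {t.transcript_id} has no sequence; supply an external "
            "score table instead"
        )
    if len(t.sequence) < 200:
        raise ValueError(
            f"transcript {t.transcript_id} sequence shorter than 200 nt"
        )
    return CodingScore(t.transcript_id, _longest_orf_codons(t.sequence) / 100.0)


def load_external_scores(path: str | Path) -> list[CodingScore]:
    """Load a two-column TSV (transcript_id, score) of external scores.

    Duplicate transcript ids resolve last-wins with a logged warning; a
    header row named ``transcript_id`` is tolerated.
    """
    out: dict[str, CodingScore] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            tid, raw = parts[0], parts[1]
            if lineno == 1 and tid == "transcript_id":
                continue
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {raw!r}"
                ) from exc
            if tid in out:
                logger.warning("duplicate external score for %s; last value wins", tid)
            out[tid] = CodingScore(tid, score, source="external")
    return list(out.values())


def filter_candidates(
    candidates: list[TranscriptModel],
    reference: AnnotationSet,
    scores: list[CodingScore] | None = None,
    params: FilterParams | None = None,
) -> tuple[AnnotationSet, FilterReport]:
    """Run the four-stage discovery cascade; survivors are putative lncRNAs."""
    params = params or FilterParams()
    # provided scores (builtin or external) take precedence over on-the-fly
    # builtin computation; within the provided list, later entries win
    provided = {s.transcript_id: s for s in (scores or [])}

    removed_by: dict[str, int] = {"class": 0, "length": 0, "coding": 0, "monoexonic": 0}
    unstranded = 0
    survivors: list[TranscriptModel] = []
    class_codes: dict[str, str] = {}
    for cand in candidates:
        if cand.strand == ".":
            unstranded += 1
            class_codes[cand.transcript_id] = "."
            continue
        code = assign_class_code(cand, reference)
        class_codes[cand.transcript_id] = code.code
        if code.code in REMOVED_CLASS_CODES:
            removed_by["class"] += 1
            continue
        if cand.spliced_length < params.min_length:
            removed_by["length"] += 1
            continue
        if cand.transcript_id in provided:
            score = provided[cand.transcript_id]
        elif cand.sequence is not None:
            score = builtin_coding_score(cand)
        else:
            raise ValueError(
                f"transcript {cand.transcript_id} has neither a sequence nor an "
                "external coding score"
            )
        if score.score > params.max_coding_score:
            removed_by["coding"] += 1
            continue
        if cand.n_exons < params.min_exons:
            removed_by["monoexonic"] += 1
            continue
        survivors.append(cand)
    if unstranded:
        removed_by["unstranded"] = unstranded
    removed_by = {k: v for k, v in removed_by.items() if v or k in
                  ("class", "length", "coding", "monoexonic")}
    report = FilterReport(
        input_count=len(candidates),
        removed_by=removed_by,
        surviving_ids=[t.transcript_id for t in survivors],
        class_codes=class_codes,
    )
    report.check()
    return AnnotationSet(survivors), report
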