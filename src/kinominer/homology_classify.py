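"""Best-hit homology classification of kinase domains.

Each detected catalytic domain is aligned locally (Smith-Waterman, affine
gaps, BLOSUM62, gap open 11 / extend 1 -- the classic protein-search
defaults) against every entry of a labeled reference catalog.  The
group/family/subfamily of the best hit is transferred when its E-value
passes the classification cutoff (default 1e-10); proteins without such a
hit are flagged ``species_specific``, and proteins whose distinct domains
confidently hit two different groups are flagged ``ambiguous`` for
phylogenetic resolution.

Alignment E-values follow Karlin-Altschul statistics,
``E = K * m * n * exp(-lambda * S)``, with the published gapped-BLOSUM62
constants held in :data:`KARLIN_ALTSCHUL`.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .domain_scan import DomainHit
from .io_formats import (
    AlignmentResult,
    Classification,
    ProteinRecord,
    ReferenceKinase,
)

#: (lambda, K) for BLOSUM62 with gap open 11, extend 1 (gapped regime).
KARLIN_ALTSCHUL = (0.267, 0.041)

#: Default classification cutoff.
CLASSIFY_CUTOFF = 1e-10


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open)
    aligner.extend_gap_score = -(gap_extend)
    return aligner


def align_local(query: str, subject: str, *,
                query_id: str = "query", subject_id: str = "subject",
                gap_open: float = 11.0, gap_extend: float = 1.0,
                karlin_altschul: tuple[float, float] = KARLIN_ALTSCHUL,
                ) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    if not query or not subject:
        raise ValueError("align_local requires non-empty sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    raw = float(alignments.score)
    lam, k = karlin_altschul
    e = k * len(query) * len(subject) * math.exp(-lam * raw)
    if raw <= 0:
        return AlignmentResult(query_id, subject_id, 0.0, e, 0.0, 1)
    best = alignments[0]
    counts = best.counts()
    aligned_length = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / aligned_length
    bits = (lam * raw - math.log(k)) / math.log(2.0)
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=bits,
        e_value=e,
        percent_identity=identity,
        aligned_length=int(aligned_length),
    )


def _best(hits: Iterable[AlignmentResult]) -> AlignmentResult:
    """Deterministic best hit: min E, then max bit score, then subject id."""
    return min(hits, key=lambda h: (h.e_value, -h.score, h.subject_id))


def classify_protein(protein_id: str,
                     hits: Sequence[AlignmentResult],
                     taxonomy: Mapping[str, ReferenceKinase],
                     cutoff: float = CLASSIFY_CUTOFF) -> Classification:
    """Assign labels from the best reference hit.

    ``hits`` are alignments of the protein's domain(s) against the catalog;
    ``AlignmentResult.query_id`` distinguishes distinct domains of one
    protein (e.g. ``"prot/12-290"``).  A protein whose distinct domains hit
    references from two or more different groups, each at or below the
    cutoff, is flagged ``ambiguous``.  Without any hit at the cutoff the
    protein is ``species_specific``; the nearest labels are still recorded.
    """
    hits = [h for h in hits]
    if not hits:
        return Classification(protein_id=protein_id, status="species_specific")

    best = _best(hits)
    ref = taxonomy[best.subject_id]

    # groups supported per distinct domain at the cutoff
    domain_groups: set[str] = set()
    by_domain: dict[str, list[AlignmentResult]] = {}
    for h in hits:
        by_domain.setdefault(h.query_id, []).append(h)
    for domain_hits in by_domain.values():
        b = _best(domain_hits)
        if b.e_value <= cutoff:
            domain_groups.add(taxonomy[b.subject_id].group)

    if len(domain_groups) >= 2:
        status = "ambiguous"
    elif best.e_value <= cutoff:
        status = "classified"
    else:
        status = "species_specific"

    return Classification(
        protein_id=protein_id,
        group=ref.group,
        family=ref.family,
        subfamily=ref.subfamily or "",
        status=status,
        evidence=best,
    )


def reconcile_annotation(classification: Classification,
                         prior_annotation: str,
                         cutoff: float = 1e-2) -> Classification:
    """Compare the homology evidence with a prior functional annotation.

    A protein with evidence at the (non-stringent) cutoff whose prior
    annotation lacks any kinase designation gets an "annotation improved"
    note; a prior kinase annotation without supporting evidence gets a
    "kinase call not supported" note.  Labels are never changed here.
    """
    has_evidence = (classification.evidence is not None
                    and classification.evidence.e_value <= cutoff)
    prior_is_kinase = "kinase" in prior_annotation.lower()
    note = ""
    if has_evidence and not prior_is_kinase:
        label = "/".join(x for x in (classification.group,
                                     classification.family,
                                     classification.subfamily) if x)
        note = f"annotation improved: {label}"
    elif not has_evidence and prior_is_kinase:
        note = "kinase call not supported"
    classification.annotation_note = note
    return classification


def classify_proteome(proteins: Sequence[ProteinRecord],
                      domain_hits: Mapping[str, Sequence[DomainHit]],
                      catalog: Sequence[ReferenceKinase],
                      cutoff: float = CLASSIFY_CUTOFF) -> list[Classification]:
    """Classify every domain-bearing protein against the reference catalog."""
    taxonomy = {ref.id: ref for ref in catalog}
    by_id = {p.id: p for p in proteins}
    out: list[Classification] = []
    for protein_id in sorted(domain_hits):
        protein = by_id[protein_id]
        alignments: list[AlignmentResult] = []
        for hit in domain_hits[protein_id]:
            domain_seq = protein.sequence[hit.start:hit.end]
            qid = f"{protein_id}/{hit.start}-{hit.end}"
            for ref in catalog:
                alignments.append(
                    align_local(domain_seq, ref.domain_sequence,
                                query_id=qid, subject_id=ref.id)
                )
        out.append(classify_protein(protein_id, alignments, taxonomy, cutoff))
    return out
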