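"""Strain assignment of candidate symbiont loci in a double infection.

A doubly infected genotype yields a mixed assembly; a singly infected
relative yields a clean reference assembly of the CI strain.  Candidate
loci (*wmk* homologs, *cifA/B* pairs, WO prophage serine-recombinase
copies) found in both are assigned to the CI or MK strain from three kinds
of evidence:

* membership of a strain-private region of the reference (private sequence
  belongs to the reference/CI strain);
* identity classes — a mixed-assembly copy identical to a reference copy
  is sequence the CI strain carries, while a copy with no identical
  reference counterpart must come from the co-infecting MK strain;
* collapsed-copy prediction — a fragmented mixed assembly that shows fewer
  identical copies than the reference likely collapsed them.

Homology search itself is out of scope: the module consumes hit tables in
the standard 12-column tabular format (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "HomologHit",
    "StrainAssignment",
    "PseudogeneReport",
    "read_hit_table",
    "assign_hits",
    "predict_collapsed_copies",
    "percent_identity",
    "pseudogene_check",
]

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_STOPS = {"TAA", "TAG", "TGA"}
_IUPAC = set("ACGTN")


@dataclass(frozen=True)
class HomologHit:
    """One homology hit of a query locus against an assembly."""

    query_name: str
    assembly_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    identity_pct: float = 100.0
    aligned_span: tuple[int, int] | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.start >= self.end:
            raise ValueError("hit start must precede end")


@dataclass
class StrainAssignment:
    hit: HomologHit
    assigned_strain: str  # ci_strain | mk_strain | shared | unresolved
    evidence: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("every assignment must carry at least one evidence tag")


def read_hit_table(path: str | Path, assembly_id: str) -> list[HomologHit]:
    """Read a 12-column tabular hit file into :class:`HomologHit` records.

    Subject coordinates are normalized so start < end, with strand '-'
    when the raw subject interval was reversed.
    """
    df = pd.read_csv(path, sep="\t", names=_HIT_COLUMNS, comment="#")
    hits = []
    for row in df.itertuples():
        s, e = int(row.sstart), int(row.send)
        strand = "+" if s <= e else "-"
        hits.append(
            HomologHit(
                query_name=str(row.qseqid),
                assembly_id=assembly_id,
                contig=str(row.sseqid),
                start=min(s, e),
                end=max(s, e) + 1,  # tabular hits are inclusive; store end-exclusive
                strand=strand,
                identity_pct=float(row.pident),
                aligned_span=(int(row.qstart), int(row.qend)),
            )
        )
    return hits


def _overlap_fraction(hit: HomologHit, regions) -> float:
    span = hit.end - hit.start
    overlap = 0
    for s, e in regions:
        overlap += max(0, min(hit.end, e) - max(hit.start, s))
    return overlap / span if span else 0.0


def _same_copy(a: HomologHit, b: HomologHit, identity_tol: float) -> bool:
    """Whether two hits of one query represent identical copies.

    With sequences available, compare them positionally; otherwise fall
    back on identity to the shared query (identical copies align to the
    query with the same percent identity, within ``identity_tol``).
    """
    if a.query_name != b.query_name:
        return False
    if a.sequence is not None and b.sequence is not None:
        if len(a.sequence) != len(b.sequence):
            return False
        return percent_identity(a.sequence, b.sequence) >= 100.0 - identity_tol
    return abs(a.identity_pct - b.identity_pct) <= identity_tol


def assign_hits(
    hits_reference: list[HomologHit],
    hits_mixed: list[HomologHit],
    private_regions,
    identity_tol: float = 0.0,
    min_overlap: float = 0.5,
    reference_length: int | None = None,
) -> list[StrainAssignment]:
    """Assign every hit to a strain.  Rules, in order:

    1. a reference-assembly hit with >= ``min_overlap`` of its span inside a
       strain-private region -> ci_strain (the private sequence exists only
       in the reference/CI strain); partial overlaps below the threshold
       are flagged unresolved;
    2. a mixed-assembly hit identical (within ``identity_tol``) to a
       reference hit inherits that copy's assignment — ci_strain when the
       reference copy is private, shared otherwise;
    3. a mixed-assembly hit with no identical reference counterpart ->
       mk_strain (a unique copy must come from the co-infecting strain);
    4. reference hits outside private regions are shared.

    Assignments are returned in input order (reference hits first) and are
    invariant to the ordering of either hit list.
    """
    if reference_length is not None:
        for hit in hits_reference:
            if hit.end - 1 > reference_length:
                raise ValueError(
                    f"hit {hit.query_name} extends beyond the reference "
                    f"({hit.end - 1} > {reference_length}): coordinate mismatch"
                )

    ref_assign: dict[int, StrainAssignment] = {}
    out: list[StrainAssignment] = []
    for hit in hits_reference:
        frac = _overlap_fraction(hit, private_regions)
        if frac >= min_overlap:
            a = StrainAssignment(
                hit, "ci_strain", ["private_region_membership"],
                note=f"{frac:.0%} of span inside a strain-private region",
            )
        elif frac > 0:
            a = StrainAssignment(
                hit, "unresolved", ["private_region_membership"],
                note=f"only {frac:.0%} of span overlaps a private region",
            )
        else:
            a = StrainAssignment(
                hit, "shared", ["identity_class"],
                note="backbone copy of the reference assembly",
            )
        ref_assign[id(hit)] = a
        out.append(a)

    for hit in hits_mixed:
        partners = [r for r in hits_reference if _same_copy(hit, r, identity_tol)]
        if partners:
            strains = {ref_assign[id(r)].assigned_strain for r in partners}
            if "ci_strain" in strains:
                strain, tags = "ci_strain", ["identity_class",
                                             "private_region_membership"]
                note = "identical to a private-region reference copy"
            else:
                strain, tags = "shared", ["identity_class"]
                note = "identical to a reference backbone copy"
            out.append(StrainAssignment(hit, strain, tags, note=note))
        else:
            out.append(
                StrainAssignment(
                    hit, "mk_strain", ["unique_copy"],
                    note="no identical counterpart in the reference assembly",
                )
            )
    return out


def predict_collapsed_copies(
    reference_copy_count: int, mixed_copy_count: int
) -> tuple[int, bool]:
    """Predict the true copy number in the mixed assembly.

    A fragmented assembly can collapse identical copies onto one contig:
    if the mixed assembly shows fewer identical copies than the reference,
    the reference count is the better estimate and the collapsed flag is
    set.
    """
    if reference_copy_count < 0 or mixed_copy_count < 0:
        raise ValueError("copy counts must be non-negative")
    if mixed_copy_count < reference_copy_count:
        return reference_copy_count, True
    return mixed_copy_count, False


def percent_identity(
    seq_a: str, seq_b: str, span: tuple[int, int] | None = None
) -> float:
    """Ungapped positional identity, as a percentage at 0.1 resolution.

    ``span`` is a 1-based inclusive base range (e.g. bases 27-873) applied
    to both sequences.  Sequences (after slicing) must have equal length;
    unequal spans need a prior alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if span is not None:
        s, e = span
        if s < 1 or e < s:
            raise ValueError("span must be 1-based with start <= end")
        if len(seq_a) < e or len(seq_b) < e:
            raise ValueError("both sequences must cover the requested span")
        seq_a, seq_b = seq_a[s - 1 : e], seq_b[s - 1 : e]
    if len(seq_a) != len(seq_b):
        raise ValueError(
            "compared spans have unequal length: align the sequences first"
        )
    a, b = seq_a.upper(), seq_b.upper()
    matches = sum(x == y for x, y in zip(a, b))
    return round(100.0 * matches / len(a), 1)


@dataclass
class PseudogeneReport:
    premature_stop_codon_index: int | None
    next_start_codon_offset: int | None
    intact: bool


def pseudogene_check(
    seq: str, frame_start: int = 1, premature_frac: float = 0.9
) -> PseudogeneReport:
    """Scan an ORF for a premature in-frame stop codon.

    The sequence is read in the frame beginning at ``frame_start``
    (1-based).  A stop whose codon index precedes ``premature_frac`` of the
    expected ORF length marks the copy as pseudogenized; the report then
    carries the 1-based offset of the next ATG downstream of that stop (a
    candidate re-initiation site).  A stop at or beyond the threshold — a
    normal terminal stop — leaves the ORF intact.
    """
    s = seq.upper()
    if len(s) < 3:
        raise ValueError("sequence must be at least one codon long")
    extra = set(s) - _IUPAC
    if extra:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(extra)}")
    coding = s[frame_start - 1 :]
    n_codons = len(coding) // 3
    threshold = premature_frac * n_codons
    for i in range(n_codons):
        codon = coding[3 * i : 3 * i + 3]
        if codon in _STOPS:
            codon_index = i + 1
            if codon_index < threshold:
                stop_end = frame_start - 1 + 3 * (i + 1)  # 0-based, past the stop
                nxt = s.find("ATG", stop_end)
                return PseudogeneReport(
                    premature_stop_codon_index=codon_index,
                    next_start_codon_offset=nxt + 1 if nxt != -1 else None,
                    intact=False,
                )
            break
    return PseudogeneReport(
        premature_stop_codon_index=None, next_start_codon_offset=None, intact=True
    )
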