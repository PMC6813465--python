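"""Identity-based taxonomic annotation with clade/genus identity cutoffs.

Queries (OTU or clone sequences) are assigned against a labeled reference
set by optimal pairwise alignment identity.  Assignment follows the
two-tier convention used for anaerobic-fungal ITS1: identity strictly
above the clade cutoff (default 98%) transfers genus and clade; strictly
above the genus cutoff (default 95%) transfers genus only; anything else
is unannotated (NA; NA).  A clade here is a named species or an
uncultivated species-level subgroup nested inside a genus.

Global (end-to-end) alignment identity stands in for local database
search identity: queries and references are same-region amplicons, so an
end-to-end alignment honors the cutoff semantics without an external
search tool.  For truncated queries against full-length references a
semi-global mode (free end gaps on the reference) is provided so flank
truncation is not penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO

__all__ = [
    "Taxon",
    "ReferenceRecord",
    "ReferenceDB",
    "AnnotationParams",
    "pairwise_identity",
    "assign_taxonomy",
    "annotate_read_pair",
]

NA = None


@dataclass(frozen=True)
class Taxon:
    """Genus/clade pair; either level may be unassigned (None = NA)."""

    genus: str | None = None
    clade: str | None = None

    def __post_init__(self) -> None:
        if self.clade is not None and self.genus is None:
            raise ValueError("a clade cannot be assigned without a genus")

    @property
    def label(self) -> str:
        return f"{self.genus or 'NA'};{self.clade or 'NA'}"

    @classmethod
    def from_label(cls, label: str) -> "Taxon":
        genus, _, clade = label.partition(";")
        return cls(
            genus if genus and genus != "NA" else None,
            clade if clade and clade != "NA" else None,
        )


@dataclass(frozen=True)
class ReferenceRecord:
    ref_id: str
    sequence: str
    taxon: Taxon


@dataclass
class ReferenceDB:
    """Labeled reference sequences (a local stand-in for a curated ITS1 DB)."""

    records: list[ReferenceRecord]

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ref_ids in reference DB")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceDB":
        """Read references from FASTA with ``genus;clade`` as the description."""
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            label = rec.description.split(None, 1)[1] if " " in rec.description else ""
            records.append(
                ReferenceRecord(rec.id, str(rec.seq).upper(), Taxon.from_label(label))
            )
        if not records:
            raise ValueError(f"{path}: no reference records")
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.ref_id} {r.taxon.label}\n{r.sequence}\n")


@dataclass(frozen=True)
class AnnotationParams:
    """Cutoffs (percent identity, strict inequalities) and alignment scoring."""

    clade_cutoff: float = 98.0
    genus_cutoff: float = 95.0
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if not self.clade_cutoff > self.genus_cutoff:
            raise ValueError("clade cutoff must exceed genus cutoff")


DEFAULT_PARAMS = AnnotationParams()

_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(params: AnnotationParams, semiglobal: bool) -> Align.PairwiseAligner:
    key = (params.match_score, params.mismatch_score, params.gap_score, semiglobal)
    if key not in _aligner_cache:
        aligner = Align.PairwiseAligner(
            match_score=params.match_score,
            mismatch_score=params.mismatch_score,
            open_gap_score=params.gap_score,
            extend_gap_score=params.gap_score,
            mode="global",
        )
        if semiglobal:
            # free end gaps in the query row, i.e. the target (reference)
            # may overhang the query without penalty
            aligner.end_deletion_score = 0.0
        _aligner_cache[key] = aligner
    return _aligner_cache[key]


def _identity_from_alignment(target_row: str, query_row: str,
                             trim_end_gaps: bool) -> tuple[float, int]:
    """Percent identity and aligned-column count from gapped row strings."""
    n = len(target_row)
    lo, hi = 0, n
    if trim_end_gaps:
        while lo < n and (target_row[lo] == "-" or query_row[lo] == "-"):
            lo += 1
        while hi > lo and (target_row[hi - 1] == "-" or query_row[hi - 1] == "-"):
            hi -= 1
    columns = hi - lo
    if columns == 0:
        return 0.0, 0
    matches = sum(
        1 for i in range(lo, hi) if target_row[i] == query_row[i] != "-"
    )
    return 100.0 * matches / columns, columns


def pairwise_identity(
    query: str,
    subject: str,
    params: AnnotationParams = DEFAULT_PARAMS,
    mode: str = "global",
) -> float:
    """Percent identity under an optimal pairwise alignment.

    ``global`` counts every alignment column (matches / columns, end gaps
    included), and is symmetric.  ``semiglobal`` leaves end gaps on the
    subject unpenalized and excludes end-gap columns from the denominator,
    for truncated queries against full-length subjects.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    semiglobal = mode == "semiglobal"
    if mode not in ("global", "semiglobal"):
        raise ValueError(f"unknown mode {mode!r}")
    if not semiglobal:
        # canonical argument order: co-optimal alignments can differ in
        # identity, and the aligner's tie-breaking depends on which
        # sequence is which; sorting makes the global mode symmetric
        subject, query = sorted((subject, query))
    aln = _aligner(params, semiglobal).align(subject, query)[0]
    identity, _ = _identity_from_alignment(aln[0], aln[1], trim_end_gaps=semiglobal)
    return identity


def _classify(identity: float, taxon: Taxon, params: AnnotationParams) -> Taxon:
    if identity > params.clade_cutoff:
        return taxon
    if identity > params.genus_cutoff:
        return Taxon(taxon.genus, None)
    return Taxon(None, None)


def assign_taxonomy(
    query: str,
    db: ReferenceDB,
    params: AnnotationParams = DEFAULT_PARAMS,
    mode: str = "global",
) -> tuple[Taxon, float, str]:
    """Best-hit annotation of a query against the reference DB.

    Returns ``(taxon, best_identity, best_ref_id)``.  The best hit is the
    record with highest identity; ties break toward higher aligned-column
    coverage of the reference, then lexicographic ref_id.  Cutoffs are
    applied strictly (identity must exceed, not equal, the cutoff).
    """
    if not db.records:
        raise ValueError("empty reference DB")
    semiglobal = mode == "semiglobal"
    best: tuple[float, float, list[str]] | None = None  # (-id, -cov) keyed
    best_rec: ReferenceRecord | None = None
    best_identity = 0.0
    for rec in sorted(db.records, key=lambda r: r.ref_id):
        aln = _aligner(params, semiglobal).align(rec.sequence, query)[0]
        identity, columns = _identity_from_alignment(
            aln[0], aln[1], trim_end_gaps=semiglobal
        )
        coverage = columns / len(rec.sequence)
        key = (identity, coverage)
        if best is None or key > best:
            best = key
            best_rec = rec
            best_identity = identity
    assert best_rec is not None
    return _classify(best_identity, best_rec.taxon, params), best_identity, best_rec.ref_id


def annotate_read_pair(
    fwd_segment: str,
    rev_segment: str,
    db: ReferenceDB,
    params: AnnotationParams = DEFAULT_PARAMS,
) -> tuple[Taxon, float, str]:
    """Annotate a paired-read OTU (or clone read-pair) against the DB.

    The forward segment and the reverse-complemented reverse segment are
    each aligned semi-globally to every reference; a record's identity is
    the length-weighted mean over the two segments.  This mirrors
    annotating truncated paired amplicon reads whose unread middle must
    not count against identity.
    """
    from .reference_io import reverse_complement

    rev_on_template = reverse_complement(rev_segment)
    if not db.records:
        raise ValueError("empty reference DB")
    best_key: tuple[float, str] | None = None
    best_rec: ReferenceRecord | None = None
    best_identity = 0.0
    aligner = _aligner(params, semiglobal=True)
    wf, wr = len(fwd_segment), len(rev_on_template)
    for rec in sorted(db.records, key=lambda r: r.ref_id):
        ident = 0.0
        for seg, w in ((fwd_segment, wf), (rev_on_template, wr)):
            aln = aligner.align(rec.sequence, seg)[0]
            seg_id, _ = _identity_from_alignment(aln[0], aln[1], trim_end_gaps=True)
            ident += seg_id * w
        ident /= wf + wr
        key = (ident, rec.ref_id)
        if best_key is None or ident > best_key[0]:
            best_key = key
            best_rec = rec
            best_identity = ident
    assert best_rec is not None
    return _classify(best_identity, best_rec.taxon, params), best_identity, best_rec.ref_id
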