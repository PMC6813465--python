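"""Clone-library sequence I/O, primer location, and amplicon trimming.

Anaerobic-fungal ITS1 clone libraries are sets of Sanger-sequenced plasmid
inserts spanning the partial 18S rRNA gene (~310 b), the full ITS1 region
(192-282 b) and the partial 5.8S rRNA gene (116 b).  High-throughput
sequencing uses a nested primer pair (ARISA primers carrying UniTag adapter
prefixes) that sits inside those flanks, so each clone must be trimmed down
to the barcoded-amplicon template before reads can be simulated from it.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "Clone",
    "CloneLibrary",
    "PrimerScheme",
    "DEFAULT_SCHEME",
    "FastaParseError",
    "PrimerSiteError",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "match_primer",
    "trim_to_amplicon",
    "its1_length",
    "predict_amplicon_sizes",
]

# IUPAC nucleotide codes, used for degenerate primer positions.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SUBJECT_ALPHABET = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into a clone library."""


class PrimerSiteError(ValueError):
    """Raised when a primer site is absent or ambiguous in a clone."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Clone:
    """One unique cloned sequence with its observed multiplicity."""

    clone_id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"clone {self.clone_id!r}: empty sequence")
        bad = set(self.sequence) - SUBJECT_ALPHABET
        if bad:
            raise ValueError(
                f"clone {self.clone_id!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.count < 1:
            raise ValueError(f"clone {self.clone_id!r}: count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CloneLibrary:
    """Per-strain set of unique cloned sequences with counts.

    ``sum(c.count for c in clones)`` is the number of sequenced clones;
    ``len(clones)`` is the number of unique sequences.
    """

    strain_id: str
    clones: list[Clone]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(ids) != len(set(ids)):
            raise ValueError(f"library {self.strain_id!r}: duplicate clone ids")

    @property
    def n_clones(self) -> int:
        """Total clone instances (sum of counts)."""
        return sum(c.count for c in self.clones)

    def __iter__(self) -> Iterable[Clone]:
        return iter(self.clones)


@dataclass(frozen=True)
class PrimerScheme:
    """Barcoded-amplicon primer pair with adapter prefixes and flank sizes.

    The printed oligos carry UniTag adapter prefixes; only the 3' core anneals
    to the template.  ``reverse_primer`` is given 5'->3' on the opposite
    strand, as primers conventionally are, and is matched on the deposited
    strand as its reverse complement.  ``flank_18S_len``/``flank_58S_len``
    are the conserved genic flanks of the *clone* amplicon and define the
    ITS1-length arithmetic.
    """

    forward_primer: str
    reverse_primer: str
    adapter_prefix_len_fwd: int = 18
    adapter_prefix_len_rev: int = 18
    flank_18S_len: int = 310
    flank_58S_len: int = 116

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward_primer),
                             ("reverse", self.reverse_primer)):
            if not primer:
                raise ValueError(f"{name} primer is empty")
            bad = set(primer) - set(IUPAC_CODES)
            if bad:
                raise ValueError(f"{name} primer: non-IUPAC characters {sorted(bad)}")
        if self.adapter_prefix_len_fwd < 0 or self.adapter_prefix_len_rev < 0:
            raise ValueError("adapter prefix lengths must be non-negative")
        if self.flank_18S_len <= 0 or self.flank_58S_len <= 0:
            raise ValueError("flank lengths must be positive")

    @property
    def forward_core(self) -> str:
        """Template-annealing part of the forward primer (adapter stripped)."""
        return self.forward_primer[self.adapter_prefix_len_fwd:]

    @property
    def reverse_core(self) -> str:
        """Template-annealing part of the reverse primer (adapter stripped)."""
        return self.reverse_primer[self.adapter_prefix_len_rev:]


#: ARISA primer pair with UniTag adapter prefixes (Neo 18S For / Neo 5.8S Rev);
#: the first 18 bases of each printed oligo are the adapter.
DEFAULT_SCHEME = PrimerScheme(
    forward_primer="GAGCCGTAGCCAGTCTGCAATCCTTCGGATTGGCT",
    reverse_primer="GCCGTGACCGTGACATCGCGAGAACCAAGAGATCCA",
)


_COUNT_RE = re.compile(r"\bcount=(\d+)\b")


def read_fasta(path: str | Path, strain_id: str | None = None) -> CloneLibrary:
    """Read a clone-library FASTA into a :class:`CloneLibrary`.

    One clone per record.  A header token ``count=N`` sets the clone's
    multiplicity (defaults to 1), so a library of 14 clones with 8 unique
    sequences is stored as 8 records.  Sequences are uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    clones: list[Clone] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            m = _COUNT_RE.search(record.description)
            count = int(m.group(1)) if m else 1
            try:
                clones.append(Clone(record.id, str(record.seq).upper(), count))
            except ValueError as exc:
                raise FastaParseError(f"{path}: {exc}") from exc
    except ValueError as exc:  # Bio.SeqIO parse failures
        if isinstance(exc, FastaParseError):
            raise
        raise FastaParseError(f"{path}: malformed FASTA ({exc})") from exc
    if not clones:
        raise FastaParseError(f"{path}: no FASTA records")
    return CloneLibrary(strain_id or path.stem, clones, source=str(path))


def write_fasta(library: CloneLibrary, path: str | Path) -> None:
    """Write a clone library to FASTA, preserving counts in the headers."""
    with open(path, "w") as fh:
        for clone in library.clones:
            fh.write(f">{clone.clone_id} count={clone.count}\n{clone.sequence}\n")


def match_primer(
    sequence: str,
    primer: str,
    max_mismatch: int = 0,
    subject_n_wildcard: bool = False,
) -> list[int]:
    """All 0-based start positions where ``primer`` matches ``sequence``.

    A window matches when each position's subject base is in the IUPAC
    expansion of the primer base, allowing up to ``max_mismatch`` failures.
    Subject ``N`` matches nothing unless ``subject_n_wildcard`` is set
    (an uncalled base should not silently satisfy a primer site).
    """
    if len(primer) > len(sequence):
        raise ValueError("primer longer than sequence")
    allowed = [IUPAC_CODES[b] for b in primer]
    k = len(primer)
    hits: list[int] = []
    for start in range(len(sequence) - k + 1):
        mism = 0
        for off in range(k):
            base = sequence[start + off]
            if base == "N":
                if not subject_n_wildcard:
                    mism += 1
            elif base not in allowed[off]:
                mism += 1
            if mism > max_mismatch:
                break
        else:
            hits.append(start)
    return hits


def trim_to_amplicon(
    clone: str | Clone,
    scheme: PrimerScheme = DEFAULT_SCHEME,
    max_mismatch: int = 0,
    clone_id: str = "?",
) -> str:
    """Trim a clone to its barcoded-amplicon template (primers included).

    The template runs from the first base of the forward-primer core site
    through the last base of the reverse-primer core site on the deposited
    strand, i.e. the physical PCR product minus adapters and barcodes.
    Exactly one site per primer is required: silent resolution of multiple
    hits would corrupt every downstream size.
    """
    if isinstance(clone, Clone):
        clone_id, sequence = clone.clone_id, clone.sequence
    else:
        sequence = clone
    fwd = scheme.forward_core
    rev_site = reverse_complement(scheme.reverse_core)
    fwd_hits = match_primer(sequence, fwd, max_mismatch)
    rev_hits = match_primer(sequence, rev_site, max_mismatch)
    if len(fwd_hits) != 1:
        raise PrimerSiteError(
            f"clone {clone_id!r}: {len(fwd_hits)} forward-primer sites "
            f"(core {fwd!r}), need exactly 1"
        )
    if len(rev_hits) != 1:
        raise PrimerSiteError(
            f"clone {clone_id!r}: {len(rev_hits)} reverse-primer sites "
            f"(core revcomp {rev_site!r}), need exactly 1"
        )
    start, rstart = fwd_hits[0], rev_hits[0]
    if rstart <= start:
        raise PrimerSiteError(
            f"clone {clone_id!r}: reverse-primer site upstream of forward site"
        )
    return sequence[start: rstart + len(rev_site)]


def its1_length(clone_length: int, scheme: PrimerScheme = DEFAULT_SCHEME) -> int:
    """ITS1 region length implied by a full clone length.

    The clone amplicon is partial 18S + ITS1 + partial 5.8S with conserved
    flank sizes, so ITS1 = clone - flank_18S - flank_58S (637 -> 211 with
    the default 310 + 116 flanks).
    """
    its1 = clone_length - scheme.flank_18S_len - scheme.flank_58S_len
    if its1 <= 0:
        raise ValueError(
            f"clone length {clone_length} does not exceed the flanks "
            f"({scheme.flank_18S_len} + {scheme.flank_58S_len})"
        )
    return its1


def predict_amplicon_sizes(
    library: CloneLibrary, scheme: PrimerScheme = DEFAULT_SCHEME
) -> list[int]:
    """Predicted barcoded-amplicon sizes, one entry per clone instance.

    Sizes exclude adapters and barcodes (they are trimmed-template lengths);
    a clone with count k contributes k entries, so the multiset has
    ``library.n_clones`` elements.
    """
    sizes: list[int] = []
    for c in library.clones:
        n = len(trim_to_amplicon(c, scheme))
        sizes.extend([n] * c.count)
    return sizes
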