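"""Open-reference OTU calling on barcoded paired-end reads.

The caller follows the NG-Tax strategy: demultiplex on perfectly
matching paired barcodes, truncate both mates to a fixed read length,
dereplicate on the concatenated (forward, reverse) pair, keep unique
pairs above a minimum relative-abundance threshold as OTUs, discard
chimeric candidates whose two segments are each explained by a
sufficiently more abundant candidate, and finally rescue near-miss reads
by single-mismatch error correction into the most abundant compatible
OTU.  With the default 150-base reads and 1 allowed mismatch the
implied per-segment identity is 100 * 149/150 = 99.33%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .read_sim import ReadPair, ReadSet

__all__ = [
    "OTUCallerParams",
    "OTU",
    "OTUTable",
    "demultiplex",
    "call_otus",
    "remove_control_otus",
]


@dataclass(frozen=True)
class OTUCallerParams:
    read_length: int = 150
    min_abundance: float = 0.006
    chimera_ratio: float = 2.0
    max_mismatch: int = 1
    chimera_check: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_abundance < 1:
            raise ValueError("min_abundance must be in (0, 1)")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")

    @property
    def min_identity(self) -> float:
        """Percent identity implied by the per-segment mismatch allowance."""
        return 100.0 * (self.read_length - self.max_mismatch) / self.read_length


@dataclass
class OTU:
    otu_id: str
    fwd: str
    rev: str
    count: int
    rel_abundance: float


@dataclass
class OTUTable:
    """Per-sample OTUs; relative abundances are over all sample reads
    (assigned + unassigned), so they need not sum to 1."""

    sample_id: str
    otus: list[OTU]
    unassigned: int
    total: int

    def __post_init__(self) -> None:
        pairs = [(o.fwd, o.rev) for o in self.otus]
        if len(pairs) != len(set(pairs)):
            raise ValueError(f"sample {self.sample_id!r}: duplicate OTU sequences")

    @property
    def assigned(self) -> int:
        return sum(o.count for o in self.otus)


def demultiplex(
    reads: ReadSet, barcode_map: dict[str, str], barcode_length: int = 8
) -> dict[str, ReadSet]:
    """Split reads by sample barcode; only perfectly matching pairs survive.

    A pair is kept iff its forward and reverse barcodes are identical and
    present in ``barcode_map`` (barcode -> sample_id); the barcode is
    stripped from both mates.  Every sample in the map gets a (possibly
    empty) ReadSet.
    """
    out: dict[str, list[ReadPair]] = {s: [] for s in barcode_map.values()}
    for rec in reads:
        bf = rec.fwd[:barcode_length]
        br = rec.rev[:barcode_length]
        if bf != br or bf not in barcode_map:
            continue
        out[barcode_map[bf]].append(
            ReadPair(rec.read_id, rec.fwd[barcode_length:], rec.rev[barcode_length:])
        )
    return {s: ReadSet(recs, reads.quality_char) for s, recs in out.items()}


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def call_otus(
    sample_reads: ReadSet,
    params: OTUCallerParams = OTUCallerParams(),
    sample_id: str = "sample",
) -> OTUTable:
    """Call OTUs for one demultiplexed sample.

    Steps: truncate mates to ``read_length``; dereplicate on the
    (forward, reverse) pair; threshold unique pairs at ``min_abundance``
    of total sample reads (pre-correction abundance); remove chimeric
    candidates (both segments exactly matched by distinct candidates,
    each at >= ``chimera_ratio`` times the candidate's abundance); then
    error-correct remaining reads into the most abundant OTU within
    ``max_mismatch`` per segment.  Reads explained by no OTU are counted
    unassigned; relative abundances are recomputed over all reads.
    """
    total = len(sample_reads)
    if total == 0:
        warnings.warn(f"sample {sample_id!r}: no reads", stacklevel=2)
        return OTUTable(sample_id, [], 0, 0)

    derep: dict[tuple[str, str], int] = {}
    for rec in sample_reads:
        if len(rec.fwd) < params.read_length or len(rec.rev) < params.read_length:
            raise ValueError(
                f"sample {sample_id!r}: read {rec.read_id!r} shorter than "
                f"{params.read_length} after barcode stripping"
            )
        pair = (rec.fwd[: params.read_length], rec.rev[: params.read_length])
        derep[pair] = derep.get(pair, 0) + 1

    candidates = {
        pair: n for pair, n in derep.items() if n / total >= params.min_abundance
    }

    # chimera removal: a candidate is chimeric when one other candidate
    # matches its forward segment and a different one its reverse segment,
    # each at >= chimera_ratio times its abundance
    chimeric: set[tuple[str, str]] = set()
    if params.chimera_check:
        for pair, n in candidates.items():
            threshold = params.chimera_ratio * n
            fwd_parents = [
                p for p, m in candidates.items()
                if p != pair and p[0] == pair[0] and m >= threshold
            ]
            rev_parents = [
                p for p, m in candidates.items()
                if p != pair and p[1] == pair[1] and m >= threshold
            ]
            if any(fp != rp for fp in fwd_parents for rp in rev_parents):
                chimeric.add(pair)

    # OTUs ordered by decreasing pre-correction abundance, ties by sequence
    otu_pairs = sorted(
        (p for p in candidates if p not in chimeric),
        key=lambda p: (-candidates[p], p),
    )
    counts = {p: candidates[p] for p in otu_pairs}

    # error correction of non-OTU reads into the most abundant compatible OTU
    for pair, n in derep.items():
        if pair in counts:
            continue
        best = None
        for otu in otu_pairs:  # already in decreasing-abundance order
            if (
                _hamming(pair[0], otu[0]) <= params.max_mismatch
                and _hamming(pair[1], otu[1]) <= params.max_mismatch
            ):
                best = otu
                break
        if best is not None:
            counts[best] += n

    otus = [
        OTU(f"{sample_id}_otu{i}", p[0], p[1], counts[p], counts[p] / total)
        for i, p in enumerate(otu_pairs)
    ]
    return OTUTable(sample_id, otus, total - sum(counts[p] for p in otu_pairs), total)


def remove_control_otus(
    sample_tables: dict[str, OTUTable],
    control_tables: dict[str, OTUTable],
    multiple: float = 1.0,
) -> tuple[dict[str, OTUTable], list[tuple[str, str]]]:
    """Drop OTUs clearly associated with no-template controls.

    An OTU (matched across samples by exact sequence pair) is removed from
    every sample when its relative abundance in some control exceeds
    ``multiple`` times its maximum relative abundance across samples.
    Returns the filtered tables and a log of (sequence-pair repr, control)
    removals; removed reads are re-counted as unassigned.
    """
    max_in_samples: dict[tuple[str, str], float] = {}
    for table in sample_tables.values():
        for otu in table.otus:
            key = (otu.fwd, otu.rev)
            max_in_samples[key] = max(max_in_samples.get(key, 0.0), otu.rel_abundance)

    removed: set[tuple[str, str]] = set()
    log: list[tuple[str, str]] = []
    for control_id, table in control_tables.items():
        for otu in table.otus:
            key = (otu.fwd, otu.rev)
            if otu.rel_abundance > multiple * max_in_samples.get(key, 0.0):
                if key not in removed:
                    removed.add(key)
                    log.append((f"{otu.fwd[:12]}.../{otu.rev[:12]}...", control_id))

    filtered: dict[str, OTUTable] = {}
    for sample_id, table in sample_tables.items():
        kept = [o for o in table.otus if (o.fwd, o.rev) not in removed]
        dropped = sum(o.count for o in table.otus if (o.fwd, o.rev) in removed)
        filtered[sample_id] = OTUTable(
            sample_id, kept, table.unassigned + dropped, table.total
        )
    return filtered, log
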