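"""Theoretical barcoded paired-end read synthesis and PCR length-bias model.

Theoretical mock fastq files are idealized: each read pair is an exact
copy of a template's two ends, prefixed with the sample barcode, with a
flat quality string.  Composition is encoded purely in how many pairs
each clone template receives (largest-remainder apportionment of the
clone-level profile over the requested total).

The PCR bias model makes the "preferential amplification of smaller
amplicons" explanation operational: each template grows per cycle by a
length-dependent efficiency e(L) in [0, 1], either deterministically
(N -> N * (1 + e)^cycles) or stochastically (per-cycle binomial gains).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np

from .mock_design import CompositionProfile
from .reference_io import reverse_complement

__all__ = [
    "SimParams",
    "PCRBiasParams",
    "ReadPair",
    "ReadSet",
    "allocate_read_counts",
    "simulate_reads",
    "write_fastq_pair",
    "read_fastq_pair",
    "logistic_efficiency",
    "pcr_amplify",
]


@dataclass(frozen=True)
class SimParams:
    """Read-synthesis settings (defaults mirror the benchmark protocol)."""

    n_read_pairs: int = 200_000
    read_length: int = 150
    barcode: str = "ACGTACGT"
    quality_char: str = "I"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_read_pairs <= 0:
            raise ValueError("n_read_pairs must be positive")
        if len(self.barcode) != 8:
            raise ValueError("barcode must be 8 nucleotides")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    fwd: str
    rev: str


@dataclass
class ReadSet:
    """Barcoded paired-end reads with a shared flat quality character."""

    records: list[ReadPair]
    quality_char: str = "I"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReadPair]:
        return iter(self.records)


def allocate_read_counts(
    profile: CompositionProfile, n_read_pairs: int
) -> dict[str, int]:
    """Apportion ``n_read_pairs`` over clones by largest-remainder rounding.

    Counts sum exactly to ``n_read_pairs``.  Each clone first receives
    floor(abundance * n); remaining pairs go to the largest fractional
    remainders, ties broken by lexicographic clone key.
    """
    if n_read_pairs <= 0:
        raise ValueError("n_read_pairs must be positive")
    quotas = {k: ab * n_read_pairs for k, ab in profile.abundances.items()}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    remainder = n_read_pairs - sum(counts.values())
    by_fraction = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_fraction[:remainder]:
        counts[k] += 1
    return counts


def simulate_reads(
    templates: dict[str, str],
    counts: dict[str, int],
    params: SimParams,
) -> ReadSet:
    """Error-free barcoded read pairs from amplicon templates.

    The forward read is barcode + the first ``read_length`` template
    bases; the reverse read is barcode + the first ``read_length`` bases
    of the reverse complement, i.e. it covers the template's 3' end as in
    real paired-end chemistry.  Records are emitted in sorted clone-key
    order, so output is deterministic.
    """
    records: list[ReadPair] = []
    for key in sorted(counts):
        n = counts[key]
        if n == 0:
            continue
        template = templates[key]
        if len(template) < params.read_length:
            raise ValueError(
                f"template {key!r} ({len(template)} b) shorter than "
                f"read length {params.read_length}"
            )
        fwd = params.barcode + template[: params.read_length]
        rev = params.barcode + reverse_complement(template)[: params.read_length]
        for i in range(n):
            records.append(ReadPair(f"{key}.{i}", fwd, rev))
    return ReadSet(records, params.quality_char)


def _open_read(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def write_fastq_pair(reads: ReadSet, fwd_path: str | Path, rev_path: str | Path) -> None:
    """Write forward/reverse FASTQ files (gzipped when the path ends .gz).

    Gzip headers are written with a zero mtime so identical read sets
    produce byte-identical files (the reproducibility contract).
    """
    for path, attr in ((Path(fwd_path), "fwd"), (Path(rev_path), "rev")):
        text = "".join(
            f"@{rec.read_id}\n{seq}\n+\n{reads.quality_char * len(seq)}\n"
            for rec in reads.records
            for seq in (getattr(rec, attr),)
        )
        data = text.encode()
        if str(path).endswith(".gz"):
            with open(path, "wb") as raw:
                with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
                    gz.write(data)
        else:
            Path(path).write_bytes(data)


def read_fastq_pair(fwd_path: str | Path, rev_path: str | Path) -> ReadSet:
    """Read paired FASTQ files back into a :class:`ReadSet`."""
    from Bio import SeqIO

    quality_char = "I"
    with _open_read(Path(fwd_path)) as ff, _open_read(Path(rev_path)) as rf:
        fwd_records = list(SeqIO.parse(ff, "fastq"))
        rev_records = list(SeqIO.parse(rf, "fastq"))
    if len(fwd_records) != len(rev_records):
        raise ValueError("forward/reverse record counts differ")
    records = []
    for f, r in zip(fwd_records, rev_records):
        if f.id != r.id:
            raise ValueError(f"unpaired record ids {f.id!r} / {r.id!r}")
        records.append(ReadPair(f.id, str(f.seq), str(r.seq)))
    if fwd_records:
        q = fwd_records[0].letter_annotations["phred_quality"][0]
        quality_char = chr(q + 33)
    return ReadSet(records, quality_char)


@dataclass(frozen=True)
class PCRBiasParams:
    """Two-round PCR with a length-dependent per-cycle efficiency.

    The default cycle counts (40 target cycles then 5 barcoding cycles)
    match the benchmark's two-step amplification.  ``efficiency_fn`` maps
    template length to per-cycle duplication probability in [0, 1]; with
    no length dependence the model leaves composition unchanged.
    """

    cycles_round1: int = 40
    cycles_round2: int = 5
    efficiency_fn: Callable[[float], float] = lambda length: 0.9
    stochastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles_round1 < 0 or self.cycles_round2 < 0:
            raise ValueError("cycle counts must be non-negative")

    @property
    def total_cycles(self) -> int:
        return self.cycles_round1 + self.cycles_round2


def logistic_efficiency(
    e_max: float = 0.95,
    spread: float = 0.05,
    midpoint: float = 400.0,
    steepness: float = 0.03,
) -> Callable[[float], float]:
    """Length-monotone decreasing efficiency curve.

    e(L) = e_max - spread * sigmoid(steepness * (L - midpoint)): short
    templates amplify at close to ``e_max``, long ones at ``e_max -
    spread``.  ``spread`` is the bias strength; 0 disables the bias.  The
    default midpoint sits in the middle of the ARISA amplicon size range.
    """
    if not 0 <= e_max <= 1 or not 0 <= e_max - spread <= 1:
        raise ValueError("efficiencies must stay in [0, 1]")

    def efficiency(length: float) -> float:
        return e_max - spread / (1.0 + math.exp(-steepness * (length - midpoint)))

    return efficiency


def pcr_amplify(
    counts: dict[str, float],
    template_lengths: dict[str, float],
    params: PCRBiasParams,
) -> dict[str, float]:
    """Amplify per-template molecule counts over the configured cycles.

    Deterministic mode returns N_i * (1 + e(L_i))**cycles.  Stochastic
    mode simulates per-cycle binomial duplication with the seeded RNG
    (counts are rounded to integers first).
    """
    for key, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for {key!r}")
    effs = {}
    for key in counts:
        if key not in template_lengths:
            raise ValueError(f"no template length for {key!r}")
        e = params.efficiency_fn(template_lengths[key])
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"efficiency {e} for {key!r} outside [0, 1]")
        effs[key] = e
    if not params.stochastic:
        return {
            k: n * (1.0 + effs[k]) ** params.total_cycles for k, n in counts.items()
        }
    rng = np.random.default_rng(params.seed)
    out = {k: int(round(n)) for k, n in counts.items()}
    for _ in range(params.total_cycles):
        for k in sorted(out):
            out[k] += int(rng.binomial(out[k], effs[k]))
    return {k: float(v) for k, v in out.items()}
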