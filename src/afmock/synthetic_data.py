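"""Synthetic clone libraries, reference databases, and fixture studies.

The generator emulates the statistical structure of anaerobic-fungal
ITS1 clone libraries: five strains, 14-20 sequenced clones each with a
handful of unique sequence variants, clone amplicons of 625-705 bases
built from conserved genic flanks (partial 18S of 310 b, partial 5.8S of
116 b) around a strain-specific ITS1 of 192-282 bases.  Within a strain,
minor sequence variants differ from the dominant repeat by a few
substitutions/indels confined to ITS1 (rDNA repeat heterogeneity), up to
a configurable divergence cap (default 13%, the documented extreme);
optionally one minority clone is pushed near the cap and labeled with a
different genus to emulate a divergent paralog.

The nested sequencing primers sit inside the flanks so that the trimmed
barcoded amplicon is 130 b of 18S + ITS1 + 31 b of 5.8S (353-443 b,
the ARISA size range).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .mock_design import (
    CompositionProfile,
    MockDesign,
    clone_key,
    expand_to_clones,
    load_designs,
    mean_template_lengths,
    molar_composition,
)
from .read_sim import PCRBiasParams, SimParams, allocate_read_counts, pcr_amplify, \
    simulate_reads, write_fastq_pair
from .reference_io import (
    Clone,
    CloneLibrary,
    DEFAULT_SCHEME,
    PrimerScheme,
    match_primer,
    reverse_complement,
    trim_to_amplicon,
    write_fasta,
)
from .taxonomy import ReferenceDB, ReferenceRecord, Taxon

__all__ = [
    "SynthesisParams",
    "STRAIN_GENERA",
    "generate_clone_library",
    "generate_libraries",
    "generate_reference_db",
    "make_fixture_study",
    "FixtureStudy",
]

#: Amplicon portions of the conserved flanks retained by the nested primers.
AMPLICON_18S_PORTION = 130
AMPLICON_58S_PORTION = 31

#: Default strain ids and their genera (mirroring a five-genus design).
STRAIN_GENERA = {
    "RE1": "Neocallimastix",
    "SR2": "Orpinomyces",
    "CaDo16a": "Piromyces",
    "CaDo13a": "Caecomyces",
    "28xy": "Anaeromyces",
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthesisParams:
    """Knobs of the clone-library generator (defaults emulate the study)."""

    n_strains: int = 5
    clones_per_strain: tuple[int, int] = (14, 20)
    unique_per_strain: tuple[int, int] = (3, 10)
    its1_length_range: tuple[int, int] = (192, 282)
    within_strain_divergence: float = 0.13
    mean_minor_edits: float = 1.0  # extra Poisson edits beyond the first
    indel_fraction: float = 0.2  # 4:1 substitution:indel
    divergent_minority: bool = True
    scheme: PrimerScheme = DEFAULT_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.clones_per_strain, self.unique_per_strain,
                       self.its1_length_range):
            if lo > hi or lo < 1:
                raise ValueError("empty or invalid range")
        if not 0 <= self.within_strain_divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _primer_sites_ok(sequence: str, scheme: PrimerScheme) -> bool:
    fwd = scheme.forward_core
    rev = reverse_complement(scheme.reverse_core)
    return (
        len(match_primer(sequence, fwd)) == 1
        and len(match_primer(sequence, rev)) == 1
    )


def _make_flanks(rng: np.random.Generator, scheme: PrimerScheme) -> tuple[str, str]:
    """Conserved 18S / 5.8S flanks with exactly one primer site each.

    The forward core starts ``AMPLICON_18S_PORTION`` bases before the 18S
    flank's 3' end; the reverse site ends ``AMPLICON_58S_PORTION`` bases
    into the 5.8S flank.
    """
    fwd_core = scheme.forward_core
    rev_site = reverse_complement(scheme.reverse_core)
    f_len, r_len = scheme.flank_18S_len, scheme.flank_58S_len
    fwd_at = f_len - AMPLICON_18S_PORTION
    rev_end = AMPLICON_58S_PORTION
    if fwd_at < 0 or rev_end < len(rev_site):
        raise ValueError("flanks too short for the primer layout")
    for _ in range(100):
        flank_18s = (
            _random_seq(rng, fwd_at)
            + fwd_core
            + _random_seq(rng, f_len - fwd_at - len(fwd_core))
        )
        flank_58s = (
            _random_seq(rng, rev_end - len(rev_site))
            + rev_site
            + _random_seq(rng, r_len - rev_end)
        )
        if _primer_sites_ok(flank_18s + flank_58s, scheme):
            return flank_18s, flank_58s
    raise RuntimeError("could not place unique primer sites in flanks")


def _counts_for(rng: np.random.Generator, n_total: int, n_unique: int) -> list[int]:
    """Dominant-heavy multiplicities summing to n_total (each >= 1)."""
    weights = np.array([0.55 ** i for i in range(n_unique)])
    weights /= weights.sum()
    counts = np.maximum(1, np.floor(weights * n_total).astype(int))
    # repair the sum while keeping every count >= 1
    while counts.sum() > n_total:
        counts[np.argmax(counts)] -= 1
    counts[0] += n_total - counts.sum()
    return counts.tolist()


def _mutate_its1(
    rng: np.random.Generator,
    its1: str,
    n_edits: int,
    indel_fraction: float,
    length_range: tuple[int, int],
) -> str:
    seq = list(its1)
    for _ in range(n_edits):
        kind = "sub"
        if rng.random() < indel_fraction:
            kind = "ins" if rng.random() < 0.5 else "del"
            if kind == "ins" and len(seq) >= length_range[1]:
                kind = "sub"
            if kind == "del" and len(seq) <= length_range[0]:
                kind = "sub"
        pos = int(rng.integers(len(seq)))
        if kind == "sub":
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        elif kind == "ins":
            seq.insert(pos, str(rng.choice(_BASES)))
        else:
            del seq[pos]
    return "".join(seq)


def generate_clone_library(
    params: SynthesisParams,
    strain_id: str,
    genus: str | None = None,
    flanks: tuple[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CloneLibrary, dict[str, Taxon]]:
    """One strain's clone library plus ground-truth clone taxa.

    A single ancestral ITS1 is drawn; the dominant unique sequence is the
    ancestor and minor variants carry 1 + Poisson(``mean_minor_edits``)
    ITS1 edits (substitutions and, at ``indel_fraction``, indels), capped
    at ``within_strain_divergence`` of the ITS1 length.  Flanks are
    conserved and contain exactly one site per primer.  With
    ``divergent_minority`` the last minor variant is pushed to the
    divergence cap and labeled with a sister genus.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, zlib.crc32(strain_id.encode())])
        )
    genus = genus or STRAIN_GENERA.get(strain_id, f"Genus_{strain_id}")
    scheme = params.scheme
    if flanks is None:
        flanks = _make_flanks(rng, scheme)
    flank_18s, flank_58s = flanks

    lo, hi = params.its1_length_range
    n_total = int(rng.integers(params.clones_per_strain[0], params.clones_per_strain[1] + 1))
    n_unique = int(rng.integers(params.unique_per_strain[0], params.unique_per_strain[1] + 1))
    n_unique = min(n_unique, n_total)
    counts = _counts_for(rng, n_total, n_unique)

    for _ in range(200):
        its1_len = int(rng.integers(lo, hi + 1))
        ancestor = _random_seq(rng, its1_len)
        if _primer_sites_ok(flank_18s + ancestor + flank_58s, scheme):
            break
    else:
        raise RuntimeError("could not draw an ancestral ITS1 without primer hits")

    max_edits = max(1, int(params.within_strain_divergence * its1_len))
    variants = [ancestor]
    seen = {ancestor}
    for i in range(1, n_unique):
        for _ in range(200):
            if params.divergent_minority and i == n_unique - 1 and n_unique > 1:
                n_edits = max_edits
            else:
                n_edits = min(1 + int(rng.poisson(params.mean_minor_edits)), max_edits)
            var = _mutate_its1(rng, ancestor, n_edits, params.indel_fraction, (lo, hi))
            if var not in seen and _primer_sites_ok(flank_18s + var + flank_58s, scheme):
                seen.add(var)
                variants.append(var)
                break
        else:
            raise RuntimeError("could not draw a fresh ITS1 variant")

    clones = [
        Clone(f"{strain_id}_c{i:02d}", flank_18s + var + flank_58s, counts[i])
        for i, var in enumerate(variants)
    ]
    truth: dict[str, Taxon] = {}
    for i, clone in enumerate(clones):
        if params.divergent_minority and i == len(clones) - 1 and len(clones) > 1:
            truth[clone.clone_id] = Taxon(f"{genus}_sister", None)
        else:
            truth[clone.clone_id] = Taxon(genus, f"{genus}_1")
    return CloneLibrary(strain_id, clones, source="synthetic"), truth


def generate_libraries(
    params: SynthesisParams,
    strain_ids: list[str] | None = None,
) -> tuple[dict[str, CloneLibrary], dict[str, Taxon]]:
    """Libraries for all strains, sharing conserved flanks across strains.

    Returns (libraries by strain, truth by global clone key).
    """
    if strain_ids is None:
        strain_ids = list(STRAIN_GENERA)[: params.n_strains]
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    flanks = _make_flanks(rng, params.scheme)
    libraries: dict[str, CloneLibrary] = {}
    truth: dict[str, Taxon] = {}
    for strain_id in strain_ids:
        strain_rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 11, strain_ids.index(strain_id)])
        )
        lib, lib_truth = generate_clone_library(
            params, strain_id, flanks=flanks, rng=strain_rng
        )
        libraries[strain_id] = lib
        for cid, taxon in lib_truth.items():
            truth[clone_key(strain_id, cid)] = taxon
    return libraries, truth


def generate_reference_db(
    libraries: dict[str, CloneLibrary],
    truth: dict[str, Taxon],
    contamination: int = 0,
    seed: int = 0,
    scheme: PrimerScheme = DEFAULT_SCHEME,
) -> ReferenceDB:
    """Reference DB with one record per ground-truth taxon plus decoys.

    Each taxon's reference is the trimmed amplicon of its highest-count
    clone (tie: lexicographic clone id), which sits within a couple of
    percent of that taxon's other clones under the default edit model.
    Decoys are unrelated random sequences (no conserved flanks), far below
    any annotation cutoff.
    """
    best_by_taxon: dict[Taxon, tuple[int, str, str]] = {}
    for strain_id, lib in libraries.items():
        for clone in lib.clones:
            taxon = truth[clone_key(strain_id, clone.clone_id)]
            entry = (-clone.count, clone.clone_id, clone.sequence)
            if taxon not in best_by_taxon or entry < best_by_taxon[taxon]:
                best_by_taxon[taxon] = entry
    records = [
        ReferenceRecord(
            f"ref_{taxon.genus}_{taxon.clade or 'NA'}",
            trim_to_amplicon(seq, scheme, clone_id=cid),
            taxon,
        )
        for taxon, (_, cid, seq) in sorted(
            best_by_taxon.items(), key=lambda kv: kv[0].label
        )
    ]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    for i in range(contamination):
        length = int(rng.integers(350, 444))
        records.append(
            ReferenceRecord(f"decoy_{i:02d}", _random_seq(rng, length),
                            Taxon(f"Decoy_{i:02d}", None))
        )
    return ReferenceDB(records)


@dataclass
class FixtureStudy:
    """On-disk study layout produced by :func:`make_fixture_study`."""

    root: Path
    library_paths: dict[str, Path]
    reference_path: Path
    designs_path: Path
    fastq_paths: dict[str, tuple[Path, Path]]  # sample -> (R1, R2)
    barcodes: dict[str, str]  # sample -> barcode
    truth_path: Path


def _barcodes_for(samples: list[str], rng: np.random.Generator) -> dict[str, str]:
    used: set[str] = set()
    out: dict[str, str] = {}
    for sample in samples:
        while True:
            bc = _random_seq(rng, 8)
            if bc not in used:
                used.add(bc)
                out[sample] = bc
                break
    return out


def make_fixture_study(
    out_dir: str | Path,
    designs: dict[str, MockDesign] | None = None,
    params: SynthesisParams | None = None,
    bias: PCRBiasParams | None = None,
    n_read_pairs: int = 200_000,
    replicates: tuple[str, ...] = ("A1", "A2", "B", "C"),
    seed: int = 0,
) -> FixtureStudy:
    """Write a complete synthetic study an end-to-end run can consume.

    Defaults: the four packaged mock designs, four replicates per mock
    (duplicate A1/A2 plus B and C), 200,000 read pairs per sample, no PCR
    bias.  truth.json records the theoretical strain- and clone-level
    profiles, per-sample read allocations, and barcodes.
    """
    params = replace(params or SynthesisParams(), seed=seed)
    designs = designs or load_designs()
    out = Path(out_dir)
    (out / "libraries").mkdir(parents=True, exist_ok=True)
    (out / "fastq").mkdir(exist_ok=True)

    libraries, truth = generate_libraries(params)
    db = generate_reference_db(libraries, truth, seed=seed, scheme=params.scheme)

    library_paths = {}
    for strain_id, lib in libraries.items():
        path = out / "libraries" / f"{strain_id}.fasta"
        write_fasta(lib, path)
        library_paths[strain_id] = path
    reference_path = out / "reference.fasta"
    db.to_fasta(reference_path)
    designs_path = out / "designs.yaml"
    designs_path.write_text(
        yaml.safe_dump({n: d.masses for n, d in designs.items()}, sort_keys=False)
    )

    lengths = mean_template_lengths(libraries, params.scheme)
    templates = {
        clone_key(s, c.clone_id): trim_to_amplicon(c, params.scheme)
        for s, lib in libraries.items()
        for c in lib.clones
    }
    template_lengths = {k: float(len(v)) for k, v in templates.items()}

    samples = [f"{mock}_{rep}" for mock in designs for rep in replicates]
    barcode_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    barcodes = _barcodes_for(samples, barcode_rng)

    truth_record: dict = {"seed": seed, "barcodes": barcodes, "profiles": {},
                          "allocations": {}}
    fastq_paths: dict[str, tuple[Path, Path]] = {}
    for mock, design in designs.items():
        strain_profile = molar_composition(design, lengths)
        clone_profile = expand_to_clones(strain_profile, libraries)
        truth_record["profiles"][mock] = {
            "strain": strain_profile.abundances,
            "clone": clone_profile.abundances,
        }
        for r_i, rep in enumerate(replicates):
            sample = f"{mock}_{rep}"
            weights = dict(clone_profile.abundances)
            if bias is not None:
                rep_bias = replace(bias, seed=(seed * 1009 + r_i * 101) % 2**31)
                weights = pcr_amplify(weights, template_lengths, rep_bias)
                total = sum(weights.values())
                weights = {k: v / total for k, v in weights.items()}
            profile = CompositionProfile("clone", weights)
            counts = allocate_read_counts(profile, n_read_pairs)
            sim = SimParams(
                n_read_pairs=n_read_pairs, barcode=barcodes[sample],
                seed=(seed * 31 + r_i) % 2**31,
            )
            reads = simulate_reads(templates, counts, sim)
            r1 = out / "fastq" / f"{sample}_R1.fastq.gz"
            r2 = out / "fastq" / f"{sample}_R2.fastq.gz"
            write_fastq_pair(reads, r1, r2)
            fastq_paths[sample] = (r1, r2)
            truth_record["allocations"][sample] = counts

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth_record, indent=1, sort_keys=True))
    return FixtureStudy(out, library_paths, reference_path, designs_path,
                        fastq_paths, barcodes, truth_path)
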