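"""End-to-end benchmark orchestration: design -> simulate -> call -> score.

One :func:`run_benchmark` call reproduces the whole accuracy assessment
for a set of mock designs: theoretical composition from masses and mean
template lengths, idealized barcoded fastq synthesis (optionally after
length-biased PCR), demultiplexing and OTU calling, identity-based
annotation, and per-mock accuracy reports.  Everything is deterministic
under a fixed seed, and each stage works from explicit intermediate
objects so it can be re-run in isolation.

Taxon profiles on both the theoretical and observed side are built by
the same annotator on the same kind of evidence (the 150-base forward
and reverse read segments), so a taxon label means the same thing in
both profiles.  Observed abundances are measured over all demultiplexed
reads of a sample; read mass the caller could not assign stays in an
explicit "Unassigned" key rather than being renormalized away.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .evaluate import (
    UNASSIGNED,
    AccuracyReport,
    build_taxon_tree,
    pearson_accuracy,
    percentage_deviation,
    weighted_unifrac,
)
from .mock_design import (
    CompositionProfile,
    MockDesign,
    clone_key,
    expand_to_clones,
    load_designs,
    mean_template_lengths,
    molar_composition,
)
from .otu_caller import OTUCallerParams, OTUTable, call_otus, demultiplex
from .read_sim import (
    PCRBiasParams,
    SimParams,
    allocate_read_counts,
    pcr_amplify,
    simulate_reads,
)
from .reference_io import (
    CloneLibrary,
    DEFAULT_SCHEME,
    PrimerScheme,
    reverse_complement,
    trim_to_amplicon,
)
from .taxonomy import AnnotationParams, ReferenceDB, Taxon, annotate_read_pair

logger = logging.getLogger("afmock")

__all__ = ["RunConfig", "MockResult", "run_benchmark", "theoretical_taxon_profile",
           "observed_taxon_profile"]


@dataclass
class RunConfig:
    """All inputs and parameters of one benchmark run."""

    libraries: dict[str, CloneLibrary]
    reference: ReferenceDB
    designs: dict[str, MockDesign] = field(default_factory=load_designs)
    scheme: PrimerScheme = DEFAULT_SCHEME
    n_read_pairs: int = 20_000
    read_length: int = 150
    caller: OTUCallerParams = field(default_factory=OTUCallerParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    bias: PCRBiasParams | None = None
    replicates: tuple[str, ...] = ("A1", "A2", "B", "C")
    length_basis: str = "amplicon"
    seed: int = 0
    out_dir: Path | None = None


@dataclass
class MockResult:
    mock_name: str
    theoretical: CompositionProfile  # taxon level
    observed: dict[str, CompositionProfile]  # replicate -> taxon level
    otu_tables: dict[str, OTUTable]
    report: AccuracyReport


def _segments(template: str, read_length: int) -> tuple[str, str]:
    """Forward/reverse read segments a template yields (reverse as read)."""
    return template[:read_length], reverse_complement(template)[:read_length]


def theoretical_taxon_profile(
    clone_profile: CompositionProfile,
    templates: dict[str, str],
    db: ReferenceDB,
    annotation: AnnotationParams,
    read_length: int,
) -> tuple[CompositionProfile, dict[str, Taxon]]:
    """Taxon-level expectation: annotate each clone's read segments.

    Using the read segments (not the full amplicon) keeps theoretical and
    observed taxon labels on identical footing: an error-free OTU derived
    from a clone annotates exactly as the clone itself does here.
    """
    sums: dict[str, float] = {}
    taxa: dict[str, Taxon] = {}
    cache: dict[tuple[str, str], Taxon] = {}
    for key, ab in clone_profile.abundances.items():
        segs = _segments(templates[key], read_length)
        if segs not in cache:
            cache[segs], _, _ = annotate_read_pair(segs[0], segs[1], db, annotation)
        taxon = cache[segs]
        taxa[key] = taxon
        sums[taxon.label] = sums.get(taxon.label, 0.0) + ab
    return CompositionProfile("taxon", sums), taxa


def observed_taxon_profile(
    table: OTUTable,
    db: ReferenceDB,
    annotation: AnnotationParams,
) -> tuple[CompositionProfile, dict[str, tuple[Taxon, float, str]]]:
    """Taxon-level observation from an OTU table.

    Abundance mass is measured over all sample reads; the unassigned
    remainder is kept under the "Unassigned" key so the profile still
    sums to 1.
    """
    if table.total == 0:
        raise ValueError(f"sample {table.sample_id!r} has no reads")
    sums: dict[str, float] = {}
    annotations: dict[str, tuple[Taxon, float, str]] = {}
    for otu in table.otus:
        taxon, identity, ref_id = annotate_read_pair(otu.fwd, otu.rev, db, annotation)
        annotations[otu.otu_id] = (taxon, identity, ref_id)
        sums[taxon.label] = sums.get(taxon.label, 0.0) + otu.rel_abundance
    unassigned_mass = 1.0 - sum(sums.values())
    if unassigned_mass > 1e-12:
        sums[UNASSIGNED] = unassigned_mass
    return CompositionProfile("taxon", sums), annotations


def _representatives(
    theoretical_taxa: dict[str, Taxon],
    clone_profile: CompositionProfile,
    templates: dict[str, str],
    observed_annotations: dict[str, dict[str, tuple[Taxon, float, str]]],
    otu_tables: dict[str, OTUTable],
) -> dict[str, str]:
    """One representative sequence per taxon label for tree building.

    The highest-abundance clone amplicon annotated to a taxon represents
    it; taxa seen only among OTUs (unexpected detections) fall back to
    the concatenated segments of their most abundant OTU.
    """
    best: dict[str, tuple[float, str]] = {}
    for key, taxon in theoretical_taxa.items():
        ab = clone_profile.abundances[key]
        cand = (ab, templates[key])
        if taxon.label not in best or cand > best[taxon.label]:
            best[taxon.label] = cand
    for rep, table in otu_tables.items():
        for otu in table.otus:
            taxon = observed_annotations[rep][otu.otu_id][0]
            if taxon.label in best:
                continue
            seq = otu.fwd + reverse_complement(otu.rev)
            cand = (otu.rel_abundance, seq)
            if taxon.label not in best or cand > best[taxon.label]:
                best[taxon.label] = cand
    return {label: seq for label, (_, seq) in best.items()}


def _renormalized(profile: CompositionProfile) -> CompositionProfile:
    mass = {k: v for k, v in profile.abundances.items() if k != UNASSIGNED and v > 0}
    return CompositionProfile.from_weights("taxon", mass)


def run_mock(
    config: RunConfig,
    design: MockDesign,
    templates: dict[str, str],
    clone_profile: CompositionProfile,
    barcodes: dict[str, str],
) -> tuple[dict[str, OTUTable], dict[str, CompositionProfile],
           dict[str, dict[str, tuple[Taxon, float, str]]]]:
    """Simulate, call and annotate all replicates of one mock."""
    template_lengths = {k: float(len(v)) for k, v in templates.items()}
    tables: dict[str, OTUTable] = {}
    observed: dict[str, CompositionProfile] = {}
    annotations: dict[str, dict[str, tuple[Taxon, float, str]]] = {}
    for r_i, rep in enumerate(config.replicates):
        weights = dict(clone_profile.abundances)
        if config.bias is not None:
            rep_bias = replace(config.bias,
                               seed=(config.seed * 1009 + r_i * 101) % 2**31)
            weights = pcr_amplify(weights, template_lengths, rep_bias)
            total = sum(weights.values())
            weights = {k: v / total for k, v in weights.items()}
        profile = CompositionProfile("clone", weights)
        counts = allocate_read_counts(profile, config.n_read_pairs)
        sim = SimParams(
            n_read_pairs=config.n_read_pairs,
            read_length=config.read_length,
            barcode=barcodes[rep],
            seed=(config.seed * 31 + r_i) % 2**31,
        )
        reads = simulate_reads(templates, counts, sim)
        demuxed = demultiplex(reads, {barcodes[rep]: rep})
        table = call_otus(demuxed[rep], config.caller, sample_id=f"{design.name}_{rep}")
        tables[rep] = table
        observed[rep], annotations[rep] = observed_taxon_profile(
            table, config.reference, config.annotation
        )
        logger.info(
            "%s %s: %d reads, %d OTUs, %d unassigned",
            design.name, rep, table.total, len(table.otus), table.unassigned,
        )
    return tables, observed, annotations


def run_benchmark(config: RunConfig) -> dict[str, MockResult]:
    """Run the full accuracy assessment for every design in the config."""
    lengths = mean_template_lengths(config.libraries, config.scheme,
                                    basis=config.length_basis)
    templates = {
        clone_key(s, c.clone_id): trim_to_amplicon(c, config.scheme)
        for s, lib in config.libraries.items()
        for c in lib.clones
    }

    # deterministic per-sample barcodes
    import numpy as np

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    all_barcodes: dict[tuple[str, str], str] = {}
    used: set[str] = set()
    for mock in config.designs:
        for rep in config.replicates:
            while True:
                bc = "".join(rng.choice(list("ACGT"), size=8))
                if bc not in used:
                    used.add(bc)
                    all_barcodes[(mock, rep)] = bc
                    break

    results: dict[str, MockResult] = {}
    for mock, design in config.designs.items():
        strain_profile = molar_composition(design, lengths)
        clone_profile = expand_to_clones(strain_profile, config.libraries)
        theoretical, theo_taxa = theoretical_taxon_profile(
            clone_profile, templates, config.reference, config.annotation,
            config.read_length,
        )
        barcodes = {rep: all_barcodes[(mock, rep)] for rep in config.replicates}
        tables, observed, annotations = run_mock(
            config, design, templates, clone_profile, barcodes
        )

        reps = _representatives(theo_taxa, clone_profile, templates,
                                annotations, tables)
        tree = build_taxon_tree(reps, config.annotation) if len(reps) > 1 else None
        deviations: dict[str, list] = {}
        pearson: dict[str, float | None] = {}
        unifrac: dict[str, float] = {}
        for rep, obs in observed.items():
            for taxon, entry in percentage_deviation(obs, theoretical).items():
                deviations.setdefault(taxon, []).append(entry)
            pearson[rep] = pearson_accuracy(obs, theoretical)
            if tree is not None:
                unifrac[rep] = weighted_unifrac(
                    _renormalized(obs), _renormalized(theoretical), tree
                )
        report = AccuracyReport(mock, deviations, pearson, unifrac)
        results[mock] = MockResult(mock, theoretical, observed, tables, report)

    if config.out_dir is not None:
        _write_artifacts(config, results)
    return results


def _write_artifacts(config: RunConfig, results: dict[str, MockResult]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "n_read_pairs": config.n_read_pairs,
        "read_length": config.read_length,
        "replicates": list(config.replicates),
        "length_basis": config.length_basis,
        "min_abundance": config.caller.min_abundance,
        "chimera_ratio": config.caller.chimera_ratio,
        "max_mismatch": config.caller.max_mismatch,
        "clade_cutoff": config.annotation.clade_cutoff,
        "genus_cutoff": config.annotation.genus_cutoff,
        "bias": None if config.bias is None else {
            "cycles_round1": config.bias.cycles_round1,
            "cycles_round2": config.bias.cycles_round2,
            "stochastic": config.bias.stochastic,
        },
        "designs": {n: d.masses for n, d in config.designs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for mock, res in results.items():
        rows = ["taxon\ttheoretical\tmean_deviation_or_flag\tsd"]
        summary = res.report.deviation_summary()
        for taxon, (dev, sd) in sorted(summary.items()):
            theor = res.theoretical.abundances.get(taxon, 0.0)
            dev_s = dev if isinstance(dev, str) else f"{dev:.3f}"
            rows.append(f"{taxon}\t{theor:.6f}\t{dev_s}\t{sd:.3f}")
        (out / f"{mock}_report.tsv").write_text("\n".join(rows) + "\n")
        metrics = {
            "pearson_r": res.report.pearson_r,
            "weighted_unifrac": res.report.unifrac,
        }
        (out / f"{mock}_metrics.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True)
        )
        for rep, table in res.otu_tables.items():
            rows = ["otu_id\tcount\trel_abundance\tfwd\trev"]
            for otu in table.otus:
                rows.append(
                    f"{otu.otu_id}\t{otu.count}\t{otu.rel_abundance:.6f}"
                    f"\t{otu.fwd}\t{otu.rev}"
                )
            rows.append(f"unassigned\t{table.unassigned}\t"
                        f"{table.unassigned / table.total:.6f}\t.\t.")
            (out / f"{mock}_{rep}_otus.tsv").write_text("\n".join(rows) + "\n")
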