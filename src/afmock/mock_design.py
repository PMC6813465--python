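"""Theoretical mock-community composition from per-strain DNA masses.

Mock communities are prepared by mixing per-strain PCR amplicons by mass
(ng).  Because the strains' amplicons differ in length, equal masses do
not mean equal molecule counts: the theoretical relative abundance of a
strain is its molar share, mass divided by mean template length,
normalized across strains (the molecular-weight constant cancels).
Strain-level profiles expand to clone level via within-strain clone
counts, and aggregate to taxon level via a clone -> taxon annotation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .reference_io import CloneLibrary, PrimerScheme, DEFAULT_SCHEME, trim_to_amplicon
from .taxonomy import Taxon

__all__ = [
    "MockDesign",
    "CompositionProfile",
    "clone_key",
    "molar_composition",
    "expand_to_clones",
    "taxon_composition",
    "mean_template_lengths",
    "load_designs",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MockDesign:
    """Named recipe: per-strain amplicon DNA mass in ng."""

    name: str
    masses: dict[str, float]

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.masses.values()):
            raise ValueError(f"design {self.name!r}: negative mass")
        if not any(m > 0 for m in self.masses.values()):
            raise ValueError(f"design {self.name!r}: no strain with mass > 0")

    @property
    def total_mass(self) -> float:
        return sum(self.masses.values())


@dataclass
class CompositionProfile:
    """Relative abundances at strain, clone, or taxon level (sum to 1)."""

    level: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if self.level not in ("strain", "clone", "taxon"):
            raise ValueError(f"unknown level {self.level!r}")
        total = sum(self.abundances.values())
        if self.abundances and abs(total - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.level} profile sums to {total!r}, expected 1"
            )

    @classmethod
    def from_weights(cls, level: str, weights: dict[str, float]) -> "CompositionProfile":
        """Normalize non-negative weights into a profile."""
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("weights sum to zero")
        return cls(level, {k: v / total for k, v in weights.items()})

    def __getitem__(self, key: str) -> float:
        return self.abundances[key]


def clone_key(strain_id: str, clone_id: str) -> str:
    """Globally unique clone key (clone_ids are only unique within strain)."""
    return f"{strain_id}/{clone_id}"


def mean_template_lengths(
    libraries: dict[str, CloneLibrary],
    scheme: PrimerScheme = DEFAULT_SCHEME,
    basis: str = "amplicon",
) -> dict[str, float]:
    """Count-weighted mean template length per strain.

    ``basis="amplicon"`` (default) uses trimmed barcoded-amplicon lengths;
    ``basis="clone"`` uses full clone lengths.  Both conventions are
    supported because the molarity calculation's length basis is a design
    choice; the default follows the template actually amplified.
    """
    if basis not in ("amplicon", "clone"):
        raise ValueError(f"unknown length basis {basis!r}")
    out: dict[str, float] = {}
    for strain_id, lib in libraries.items():
        total_len = 0
        for c in lib.clones:
            n = len(trim_to_amplicon(c, scheme)) if basis == "amplicon" else len(c)
            total_len += n * c.count
        out[strain_id] = total_len / lib.n_clones
    return out


def molar_composition(
    design: MockDesign, mean_template_length: dict[str, float]
) -> CompositionProfile:
    """Strain-level theoretical composition from masses and mean lengths.

    abundance_i = (m_i / L_i) / sum_j (m_j / L_j); strains with zero mass
    are kept at abundance 0.
    """
    weights: dict[str, float] = {}
    for strain, mass in design.masses.items():
        if mass == 0:
            weights[strain] = 0.0
            continue
        if strain not in mean_template_length:
            raise ValueError(f"design {design.name!r}: no mean length for {strain!r}")
        length = mean_template_length[strain]
        if length <= 0:
            raise ValueError(f"design {design.name!r}: non-positive length for {strain!r}")
        weights[strain] = mass / length
    return CompositionProfile.from_weights("strain", weights)


def expand_to_clones(
    strain_profile: CompositionProfile,
    libraries: dict[str, CloneLibrary],
) -> CompositionProfile:
    """Clone-level profile: within each strain, mass follows clone counts."""
    if strain_profile.level != "strain":
        raise ValueError("expected a strain-level profile")
    abundances: dict[str, float] = {}
    for strain, ab in strain_profile.abundances.items():
        if strain not in libraries:
            raise ValueError(f"no clone library for strain {strain!r}")
        lib = libraries[strain]
        if not lib.clones:
            raise ValueError(f"empty clone library for strain {strain!r}")
        total = lib.n_clones
        for c in lib.clones:
            abundances[clone_key(strain, c.clone_id)] = ab * c.count / total
    return CompositionProfile("clone", abundances)


def taxon_composition(
    clone_profile: CompositionProfile,
    annotation: dict[str, Taxon],
) -> CompositionProfile:
    """Aggregate a clone-level profile over (genus, clade) annotations.

    No thresholding happens here: arbitrarily small taxa are retained.
    """
    if clone_profile.level != "clone":
        raise ValueError("expected a clone-level profile")
    sums: dict[str, float] = {}
    for key, ab in clone_profile.abundances.items():
        if key not in annotation:
            raise ValueError(f"clone {key!r} has no annotation")
        label = annotation[key].label
        sums[label] = sums.get(label, 0.0) + ab
    return CompositionProfile("taxon", sums)


def load_designs(path: str | Path | None = None) -> dict[str, MockDesign]:
    """Load mock designs from YAML (``name -> strain -> ng``).

    With no path, returns the packaged presets Mock_1..Mock_4: the two- and
    five-strain equal-mass designs, the staggered design, and the
    low-abundance design (strains at 1, 0.1 and 0.01% of total mass).
    """
    if path is None:
        text = (
            importlib.resources.files("afmock") / "data" / "designs.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: MockDesign(name, {s: float(m) for s, m in masses.items()})
            for name, masses in raw.items()}
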