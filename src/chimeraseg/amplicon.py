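"""Per-sample PCR clone-library simulation, including chimera formation.

A chimera arises when a prematurely terminated amplicon re-anneals to a
different template — feasible only where the two templates are locally
near-identical, i.e. within the conserved regions of the 16S gene — and
is extended to full length in later cycles.  Clones therefore come in
two kinds: faithful copies of one template, and two-parent hybrids whose
crossover points (breakpoints) sit inside conserved regions.  Every
simulated clone carries its true parental provenance so that detector
calls can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .community import Community, RegionMap, SymbiontRef


@dataclass(frozen=True)
class SampleConfig:
    """Template composition of one aphid sample's PCR."""

    sample_id: str
    complement: tuple[tuple[str, float], ...]  # (taxon, relative abundance)
    n_clones: int = 20
    chimera_rate: float = 0.0
    max_breakpoints: int = 2

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.max_breakpoints < 1:
            raise ValueError("max_breakpoints must be >= 1")
        if not self.complement:
            raise ValueError("complement must be non-empty")
        abund = [a for _, a in self.complement]
        if any(a <= 0 for a in abund):
            raise ValueError("abundances must be positive")
        if abs(sum(abund) - 1.0) > 1e-6:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class CloneRead:
    """One cloned amplicon with (in simulation) its true provenance.

    ``provenance`` is an ordered tuple of ``(start, end, parent_taxon)``
    half-open segments that partition the whole sequence; adjacent
    segments have different parents.  Real-data clones carry an empty
    provenance.
    """

    clone_id: str
    sample_id: str
    sequence: str
    provenance: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.provenance:
            return
        pos = 0
        prev_parent = None
        for start, end, parent in self.provenance:
            if start != pos or end <= start:
                raise ValueError("provenance segments must tile the sequence")
            if parent == prev_parent:
                raise ValueError("adjacent provenance segments share a parent")
            pos = end
            prev_parent = parent
        if pos != len(self.sequence):
            raise ValueError("provenance does not cover the full sequence")

    @property
    def is_chimera(self) -> bool:
        return len(self.provenance) > 1

    @property
    def true_breakpoints(self) -> tuple[int, ...]:
        """Start positions of every segment after the first."""
        return tuple(start for start, _, _ in self.provenance[1:])


def form_chimera(
    parents: Sequence[SymbiontRef],
    region_map: RegionMap,
    n_breakpoints: int,
    seed: int | np.random.Generator = 0,
    clone_id: str = "chimera",
    sample_id: str = "sim",
    include_terminal_regions: bool = False,
    allow_multiparent: bool = False,
) -> CloneRead:
    """Build a chimeric clone by splicing parent sequences at conserved regions.

    Breakpoints are drawn uniformly within distinct conserved intervals;
    a breakpoint is the first column of the slice contributed by the next
    parent.  By default only the internal conserved regions are eligible:
    a crossover inside a terminal, primer-flanking conserved region would
    yield a (near-)full-length single-parent amplicon rather than an
    observable hybrid.  Parents alternate, so a two-parent chimera with
    two breakpoints has the structure A|B|A.
    """
    parents = list(parents)
    if len(parents) < 2:
        raise ValueError("need at least two parents")
    if len(parents) > 2 and not allow_multiparent:
        raise ValueError("more than two parents requires allow_multiparent=True")
    taxa = [p.taxon for p in parents]
    if len(set(taxa)) != len(taxa):
        raise ValueError("parents must be distinct taxa")

    intervals = list(region_map.conserved)
    if not include_terminal_regions and len(intervals) > 2:
        intervals = intervals[1:-1]
    if n_breakpoints < 1:
        raise ValueError("n_breakpoints must be >= 1")
    if n_breakpoints > len(intervals):
        raise ValueError(
            f"{n_breakpoints} breakpoints requested but only "
            f"{len(intervals)} eligible conserved intervals"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(intervals), size=n_breakpoints, replace=False))
    breakpoints = []
    for k in chosen:
        start, end = intervals[k]
        lo = max(start, 1)  # an empty leading segment is not a chimera
        breakpoints.append(int(rng.integers(lo, end)))

    bounds = [0, *breakpoints, region_map.total_length]
    pieces = []
    provenance = []
    for i in range(len(bounds) - 1):
        parent = parents[i % len(parents)]
        start, end = bounds[i], bounds[i + 1]
        pieces.append(parent.sequence[start:end])
        provenance.append((start, end, parent.taxon))
    return CloneRead(
        clone_id=clone_id,
        sample_id=sample_id,
        sequence="".join(pieces),
        provenance=tuple(provenance),
    )


def simulate_clone_library(
    config: SampleConfig,
    community: Community,
    seed: int | np.random.Generator = 0,
) -> list[CloneRead]:
    """Simulate one sample's clone library.

    Each clone is, with probability ``chimera_rate``, a two-parent
    chimera (parents sampled without replacement, weighted by template
    abundance; breakpoint count uniform on ``{1..max_breakpoints}``);
    otherwise an error-free copy of one template sampled by abundance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    taxa = [t for t, _ in config.complement]
    weights = np.array([a for _, a in config.complement])
    refs = {t: community.get(t) for t in taxa}  # raises KeyError on unknown taxon

    clones: list[CloneRead] = []
    for i in range(config.n_clones):
        clone_id = f"{config.sample_id}_c{i:03d}"
        is_chimera = len(taxa) >= 2 and rng.random() < config.chimera_rate
        if is_chimera:
            pick = rng.choice(len(taxa), size=2, replace=False, p=weights)
            parents = [refs[taxa[j]] for j in pick]
            n_bp = int(rng.integers(1, config.max_breakpoints + 1))
            clones.append(
                form_chimera(
                    parents,
                    community.region_map,
                    n_breakpoints=n_bp,
                    seed=rng,
                    clone_id=clone_id,
                    sample_id=config.sample_id,
                )
            )
        else:
            taxon = taxa[int(rng.choice(len(taxa), p=weights))]
            ref = refs[taxon]
            clones.append(
                CloneRead(
                    clone_id=clone_id,
                    sample_id=config.sample_id,
                    sequence=ref.sequence,
                    provenance=((0, community.region_map.total_length, taxon),),
                )
            )
    return clones


def simulate_direct_sequencing(
    config: SampleConfig, dominance_threshold: float = 0.9
) -> bool:
    """Whether direct (uncloned) Sanger sequencing of the PCR product works.

    A chromatogram shows a single peak at every position only when one
    template dominates the product; with several abundant templates the
    trace shows miscellaneous peaks and is unusable.  Returns True iff
    the most abundant template's relative abundance reaches
    *dominance_threshold*.
    """
    if not 0.5 < dominance_threshold <= 1.0:
        raise ValueError("dominance_threshold must be in (0.5, 1]")
    return max(a for _, a in config.complement) >= dominance_threshold
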