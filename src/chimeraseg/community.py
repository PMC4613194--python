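"""Simulation of an aligned multi-symbiont 16S reference community.

The community consists of a primary endosymbiont (*Buchnera*-like, "BA")
that co-diversifies with its aphid hosts along a host tree, plus a set of
facultative secondary symbionts ("oe" = other endosymbiont) placed on
independent branches off the primary's ancestral sequence.  Sequences
evolve under Jukes–Cantor (JC69) with a two-rate site model: roughly ten
conserved regions — the stretches of the 16S gene that stay nearly
identical even between phylogenetically remote bacteria, and the sites
where PCR chimeras re-anneal — mutate at a strongly reduced rate, all
other (variable) columns at rate 1.

Branch lengths are calibrated against target uncorrected p-distances by
inverting the JC69 expected-difference formula, so that the simulated
community reproduces the divergence structure observed in real aphid
clone libraries: within-primary p-distances up to ~12.8% and secondary
symbionts at ~12–26% from the primary.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from dendropy.simulate import treesim
from scipy.optimize import brentq

NUCLEOTIDES = "ACGT"
_NUC_TO_IDX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: Default divergence targets (uncorrected p-distance to the primary's
#: ancestral sequence) for the four secondary-symbiont analogs.
DEFAULT_SECONDARY_SPEC: tuple[tuple[str, float], ...] = (
    ("Serratia-like", 0.142),
    ("Sodalis-like", 0.124),
    ("Arsenophonus-like", 0.150),
    ("Wolbachia-like", 0.260),
)

#: Default relative substitution rate of conserved columns.
DEFAULT_CONSERVED_RATE = 0.02

#: Default maximum pairwise p-distance among primary-symbiont sequences.
DEFAULT_MAX_PRIMARY_P = 0.128

#: Group label shared by all primary-symbiont references.
PRIMARY_GROUP = "BA"


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionMap:
    """Conserved/variable architecture of the aligned 16S gene.

    Parameters
    ----------
    total_length
        Number of alignment columns.
    conserved
        Sorted, non-overlapping 0-based half-open intervals of the
        conserved regions.  Their complement is the variable-region set.
    """

    total_length: int
    conserved: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ValueError("total_length must be positive")
        prev_end = 0
        for start, end in self.conserved:
            if not (0 <= start < end <= self.total_length):
                raise ValueError(f"interval ({start}, {end}) out of bounds")
            if start < prev_end:
                raise ValueError("conserved intervals must be sorted and disjoint")
            prev_end = end

    @property
    def n_conserved(self) -> int:
        return len(self.conserved)

    def conserved_mask(self) -> np.ndarray:
        """Boolean mask over columns, True at conserved positions."""
        mask = np.zeros(self.total_length, dtype=bool)
        for start, end in self.conserved:
            mask[start:end] = True
        return mask

    def variable_intervals(self) -> tuple[tuple[int, int], ...]:
        """Complement of the conserved intervals, as sorted intervals."""
        out = []
        pos = 0
        for start, end in self.conserved:
            if start > pos:
                out.append((pos, start))
            pos = end
        if pos < self.total_length:
            out.append((pos, self.total_length))
        return tuple(out)

    def interval_of(self, position: int) -> int | None:
        """Index (0-based) of the conserved interval containing *position*."""
        for i, (start, end) in enumerate(self.conserved):
            if start <= position < end:
                return i
        return None

    def site_rates(self, conserved_rate: float = DEFAULT_CONSERVED_RATE) -> np.ndarray:
        """Per-column rate multipliers: 1.0 variable, *conserved_rate* conserved."""
        rates = np.ones(self.total_length)
        rates[self.conserved_mask()] = conserved_rate
        return rates

    def to_tsv(self, path) -> None:
        """Write the conserved intervals as BED-like TSV (name, start, end)."""
        with open(path, "w") as fh:
            fh.write(f"# total_length={self.total_length}\n")
            for i, (start, end) in enumerate(self.conserved, start=1):
                fh.write(f"C{i}\t{start}\t{end}\n")

    @classmethod
    def from_tsv(cls, path) -> "RegionMap":
        total = None
        intervals = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "total_length=" in line:
                        total = int(line.split("total_length=")[1])
                    continue
                _, start, end = line.split("\t")
                intervals.append((int(start), int(end)))
        if total is None:
            raise ValueError("missing total_length header")
        return cls(total_length=total, conserved=tuple(intervals))


def build_region_map(
    total_length: int = 1500,
    n_conserved: int = 10,
    conserved_len: int = 50,
    seed: int = 0,
) -> RegionMap:
    """Lay out *n_conserved* equal-length conserved regions along the gene.

    The layout is deterministic: regions are evenly spaced, and for
    ``n_conserved >= 2`` the first and last regions abut the sequence
    ends (the primer-binding sites of universal 16S primers sit in
    conserved sequence).  *seed* is accepted for interface uniformity but
    the layout does not depend on it.
    """
    del seed
    if total_length <= 0 or conserved_len < 0 or n_conserved < 0:
        raise ValueError("lengths and counts must be non-negative (length positive)")
    if n_conserved * conserved_len > total_length:
        raise ValueError(
            f"cannot pack {n_conserved} x {conserved_len} conserved columns "
            f"into {total_length} positions"
        )
    if n_conserved == 0 or conserved_len == 0:
        return RegionMap(total_length=total_length, conserved=())
    if n_conserved == 1:
        start = (total_length - conserved_len) // 2
        return RegionMap(total_length, ((start, start + conserved_len),))
    span = total_length - conserved_len
    starts = [round(i * span / (n_conserved - 1)) for i in range(n_conserved)]
    intervals = tuple((s, s + conserved_len) for s in starts)
    return RegionMap(total_length=total_length, conserved=intervals)


# ---------------------------------------------------------------------------
# JC69 machinery
# ---------------------------------------------------------------------------


def seq_to_indices(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as uint8 indices; raises on other symbols."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, idx in _NUC_TO_IDX.items():
        out[arr == ord(base)] = idx
    if (out == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(out == 255)[0][:5]})
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
    return out


def indices_to_seq(indices: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] for i in indices)


def jc69_expected_diff(t: float) -> float:
    """Expected fraction of differing sites after branch length *t* (JC69)."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))


def expected_p_two_rate(
    t: float, variable_fraction: float, conserved_rate: float
) -> float:
    """Expected whole-sequence p-distance across a path of length *t*.

    Mixes the JC69 expected difference over the variable columns (rate 1)
    and the conserved columns (rate *conserved_rate*); *t* is in expected
    substitutions per variable-region site.
    """
    fc = 1.0 - variable_fraction
    return variable_fraction * jc69_expected_diff(t) + fc * jc69_expected_diff(
        conserved_rate * t
    )


def solve_branch_length(
    target_p: float,
    variable_fraction: float,
    conserved_rate: float = DEFAULT_CONSERVED_RATE,
    t_max: float = 100.0,
) -> float:
    """Invert the two-rate JC69 expected difference for a branch length.

    Raises ``ValueError`` if *target_p* is not attainable given the
    conserved-column fraction (the expected difference saturates below
    0.75 on any finite branch when most columns barely evolve).
    """
    if not 0.0 < target_p < 0.75:
        raise ValueError("target p-distance must be in (0, 0.75)")
    f = lambda t: expected_p_two_rate(t, variable_fraction, conserved_rate) - target_p
    if f(t_max) < 0:
        raise ValueError(
            f"target p-distance {target_p} unreachable with variable fraction "
            f"{variable_fraction:.3f} and conserved rate {conserved_rate}"
        )
    return float(brentq(f, 0.0, t_max))


def evolve_jc69(
    seq: str,
    t: float,
    site_rates: Sequence[float] | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve *seq* along a branch of length *t* under JC69.

    Each column *i* mutates independently with effective branch length
    ``t * site_rates[i]``; on a substitution event the new base is drawn
    uniformly from the three alternatives (the JC69 transition kernel).
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    rates = np.asarray(site_rates, dtype=float)
    idx = seq_to_indices(seq)
    if rates.shape[0] != idx.shape[0]:
        raise ValueError("site_rates length must equal sequence length")
    if t == 0:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t * rates / 3.0))
    hit = rng.random(idx.shape[0]) < p_change
    # uniform over the three non-identical bases
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out = idx.copy()
    out[hit] = (out[hit] + shift) % 4
    return indices_to_seq(out)


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymbiontRef:
    """One aligned reference sequence of a community member."""

    taxon: str
    role: str  # "primary" | "secondary"
    sequence: str

    def __post_init__(self) -> None:
        if self.role not in ("primary", "secondary"):
            raise ValueError(f"unknown role {self.role!r}")
        seq_to_indices(self.sequence)  # alphabet validation


@dataclass
class Community:
    """A simulated symbiont community sharing one alignment coordinate system."""

    region_map: RegionMap
    refs: list[SymbiontRef]
    root_sequence: str
    host_tree: dendropy.Tree | None = None
    conserved_rate: float = DEFAULT_CONSERVED_RATE

    def __post_init__(self) -> None:
        for ref in self.refs:
            if len(ref.sequence) != self.region_map.total_length:
                raise ValueError(f"{ref.taxon}: sequence length mismatch")

    @property
    def primary(self) -> list[SymbiontRef]:
        return [r for r in self.refs if r.role == "primary"]

    @property
    def secondary(self) -> list[SymbiontRef]:
        return [r for r in self.refs if r.role == "secondary"]

    def get(self, taxon: str) -> SymbiontRef:
        for ref in self.refs:
            if ref.taxon == taxon:
                return ref
        raise KeyError(f"unknown taxon {taxon!r}")

    def groups(self) -> dict[str, str]:
        """Taxon -> group map: primaries collapse to one group, secondaries
        keep their own label (they are phylogenetically distinct genera)."""
        out = {}
        for ref in self.refs:
            out[ref.taxon] = PRIMARY_GROUP if ref.role == "primary" else ref.taxon
        return out


def default_host_tree(
    n_hosts: int = 12, seed: int = 0, taxon_namespace: dendropy.TaxonNamespace | None = None
) -> dendropy.Tree:
    """A pure-birth host tree with *n_hosts* leaves (host taxa)."""
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_hosts,
        rng=rng,
        taxon_namespace=taxon_namespace,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"host{i:02d}"
    return tree


def _max_pairwise_path(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    best = 0.0
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            best = max(best, pdm.patristic_distance(a, b))
    return best


def simulate_references(
    host_tree: dendropy.Tree | None = None,
    region_map: RegionMap | None = None,
    secondary_spec: Iterable[tuple[str, float]] | None = None,
    seed: int = 0,
    conserved_rate: float = DEFAULT_CONSERVED_RATE,
    max_primary_p: float = DEFAULT_MAX_PRIMARY_P,
    root_sequence: str | None = None,
) -> Community:
    """Simulate the aligned reference community.

    One primary reference per host-tree leaf (labelled ``BA_<host>``),
    one reference per secondary symbiont.  The host tree is rescaled so
    that the expected p-distance between its two most distant leaves is
    *max_primary_p*; each secondary's branch off the primary ancestral
    (root) sequence is solved so its expected p-distance to that root
    sequence matches its target.
    """
    region_map = region_map or build_region_map()
    if secondary_spec is None:
        secondary_spec = DEFAULT_SECONDARY_SPEC
    secondary_spec = list(secondary_spec)
    for name, target in secondary_spec:
        if not 0.0 < target < 0.75:
            raise ValueError(f"secondary target for {name!r} must be in (0, 0.75)")

    rng = np.random.default_rng(int(seed))
    if host_tree is None:
        host_tree = default_host_tree(n_hosts=12, seed=int(seed))
    host_tree = host_tree.clone(depth=1)

    mask = region_map.conserved_mask()
    variable_fraction = 1.0 - mask.mean()
    rates = region_map.site_rates(conserved_rate)

    # rescale host tree: deepest leaf pair hits the target max p-distance
    max_path = _max_pairwise_path(host_tree)
    if max_path <= 0:
        raise ValueError("host tree must have positive depth")
    t_target = solve_branch_length(max_primary_p, variable_fraction, conserved_rate)
    scale = t_target / max_path
    for edge in host_tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale

    if root_sequence is None:
        root_sequence = indices_to_seq(
            rng.integers(0, 4, size=region_map.total_length, dtype=np.uint8)
        )
    elif len(root_sequence) != region_map.total_length:
        raise ValueError("root_sequence length must match region map")

    # evolve primaries down the host tree
    refs: list[SymbiontRef] = []
    seqs: dict[int, str] = {id(host_tree.seed_node): root_sequence}
    for node in host_tree.preorder_node_iter():
        if node is host_tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        t = node.edge.length or 0.0
        seqs[id(node)] = evolve_jc69(parent_seq, t, rates, rng)
    for leaf in host_tree.leaf_node_iter():
        refs.append(
            SymbiontRef(
                taxon=f"BA_{leaf.taxon.label}", role="primary", sequence=seqs[id(leaf)]
            )
        )

    # secondaries: independent branches off the primary root sequence
    for name, target in secondary_spec:
        t = solve_branch_length(target, variable_fraction, conserved_rate)
        seq = evolve_jc69(root_sequence, t, rates, rng)
        refs.append(SymbiontRef(taxon=name, role="secondary", sequence=seq))

    return Community(
        region_map=region_map,
        refs=refs,
        root_sequence=root_sequence,
        host_tree=host_tree,
        conserved_rate=conserved_rate,
    )
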