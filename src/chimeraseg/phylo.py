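"""Phylogenetic impact of chimeric clones: the dataset I vs II contrast.

Dataset I is the chimera-free alignment (normal primary-symbiont
sequences plus an outgroup); dataset II is the same alignment with some
species' normal sequences replaced by their chimeric clones.  A tree is
inferred from each by neighbor joining on JC69-corrected distances, and
the two topologies are compared with a Shimodaira–Hasegawa (SH) test
using RELL resampling of per-site JC69 log-likelihoods, evaluated on the
chimera-containing alignment.  Robinson–Foulds distances quantify how
far the chimeras drag the topology.

Deliberate scale choices: tree inference is distance-based (NJ + JC69)
rather than a full maximum-likelihood search, and branch lengths are not
re-optimised per topology inside the SH test — a conservative,
deterministic protocol adequate for alignments of tens of taxa.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from dendropy.calculate import treecompare

from .stats import p_distance

# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A labelled nucleotide alignment with optional outgroup flags."""

    seqs: dict[str, str]
    outgroup: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        unknown = self.outgroup - set(self.seqs)
        if unknown:
            raise ValueError(f"outgroup taxa not in alignment: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.seqs)

    @property
    def n_taxa(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) uint8 matrix: 0..3 for ACGT, 255 missing."""
        raw = np.frombuffer(
            "".join(self.seqs.values()).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)
        out = np.full(raw.shape, 255, dtype=np.uint8)
        for code, char in enumerate(b"ACGT"):
            out[raw == char] = code
        return out

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="") for name, s in self.seqs.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, outgroup: Sequence[str] = ()) -> "Alignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs=seqs, outgroup=frozenset(outgroup))


@dataclass(frozen=True)
class SHResult:
    """Shimodaira–Hasegawa test outcome for a best/alternative tree pair."""

    delta_lnL: float
    p_value: float
    n_replicates: int
    seed: int


def build_datasets(
    normal: Mapping[str, str],
    chimeras: Mapping[str, str],
    outgroup: Mapping[str, str],
) -> tuple[Alignment, Alignment]:
    """Assemble the chimera-free and chimera-substituted alignments.

    *normal* maps species to their normal sequences, *chimeras* maps a
    subset of those species to the chimeric clone that replaces them in
    dataset II, *outgroup* adds the outgroup sequences to both datasets.
    Both alignments share one taxon label set.
    """
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    unmapped = set(chimeras) - set(normal)
    if unmapped:
        raise ValueError(f"chimeras for unknown species: {sorted(unmapped)}")
    collisions = set(normal) & set(outgroup)
    if collisions:
        raise ValueError(f"label collision between ingroup and outgroup: {sorted(collisions)}")
    og = frozenset(outgroup)
    seqs_i = {**dict(normal), **dict(outgroup)}
    seqs_ii = {
        name: (chimeras[name] if name in chimeras else seq)
        for name, seq in seqs_i.items()
    }
    return Alignment(seqs_i, og), Alignment(seqs_ii, og)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------


def jc69_correct(p: float) -> float:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= 0.75:
        raise ValueError(f"p-distance {p} is saturated under JC69 (>= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def alignment_distance_matrix(
    aln: Alignment, correction: str = "jc69"
) -> tuple[list[str], np.ndarray]:
    """Pairwise distance matrix from an alignment (p or JC69-corrected)."""
    labels = aln.names
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.seqs[labels[i]], aln.seqs[labels[j]])
            d[i, j] = d[j, i] = jc69_correct(p) if correction == "jc69" else p
    return labels, d


def neighbor_joining(
    labels: Sequence[str],
    dist: np.ndarray,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with non-negative branch lengths.

    A negative branch-length estimate at a join is clamped to zero and
    the deficit moved to the sibling branch, preserving the pair's
    summed length.  Ties in the Q criterion break on the smallest index
    pair, making the agglomeration deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    ns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for label in labels:
        taxon = ns.get_taxon(label) or ns.new_taxon(label)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)

    d = dist.copy()
    active = list(range(n))

    def _join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:  # clamp to zero, move the deficit to the sibling
            li, lj = 0.0, max(dij, 0.0)
        elif lj < 0.0:
            li, lj = max(dij, 0.0), 0.0
        parent = _join(i, j, li, lj)
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # final three-point join
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Likelihood and the SH test
# ---------------------------------------------------------------------------


#: Minimum branch length used in likelihood evaluation.  Distance-based
#: estimates can clamp to exactly zero, which would assign zero
#: likelihood to any conflicting site pattern; the conventional floor
#: keeps the likelihood proper without affecting resolvable branches.
MIN_BRANCH_LENGTH = 1e-6


def _jc69_transition(t: float) -> tuple[float, float]:
    """(p_same, p_diff) JC69 transition probabilities for branch length t."""
    e = np.exp(-4.0 * max(t, MIN_BRANCH_LENGTH) / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def pruning_loglik(tree: dendropy.Tree, aln: Alignment) -> np.ndarray:
    """Per-site log-likelihood vector under JC69 via Felsenstein pruning.

    Uniform base frequencies; gaps and ambiguity codes are treated as
    missing data (partial likelihood 1 for every state).  The total
    alignment log-likelihood is the sum of the returned vector.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if leaf_labels != set(aln.names):
        raise ValueError("tree leaves and alignment taxa differ")

    mat = aln.matrix()
    row_of = {name: i for i, name in enumerate(aln.names)}
    patterns, inverse = np.unique(mat, axis=1, return_inverse=True)
    n_pat = patterns.shape[1]

    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            codes = patterns[row_of[node.taxon.label]]
            pl = np.ones((n_pat, 4))
            known = codes != 255
            pl[known, :] = 0.0
            pl[known, codes[known]] = 1.0
            partials[id(node)] = pl
        else:
            pl = np.ones((n_pat, 4))
            for child in node.child_nodes():
                p_same, p_diff = _jc69_transition(child.edge.length or 0.0)
                child_pl = partials.pop(id(child))
                total = child_pl.sum(axis=1, keepdims=True)
                message = p_diff * total + (p_same - p_diff) * child_pl
                pl *= message
            partials[id(node)] = pl
    root_pl = partials[id(tree.seed_node)]
    site_lik = 0.25 * root_pl.sum(axis=1)
    return np.log(site_lik)[inverse]


def sh_test(
    best: dendropy.Tree,
    alt: dendropy.Tree,
    aln: Alignment,
    n_rell: int = 1000,
    seed: int = 0,
) -> SHResult:
    """Shimodaira–Hasegawa test of two topologies by RELL resampling.

    Per-site log-likelihoods are computed for both trees on *aln*
    (branch lengths as given, not re-optimised).  RELL replicates
    resample sites with replacement; each topology's replicate score is
    centred on its own replicate mean, and the p-value is the fraction
    of replicates whose centred score difference reaches the observed
    difference ``delta_lnL = lnL(best) - lnL(alt)``.
    """
    if n_rell < 100:
        raise ValueError("n_rell must be >= 100")
    lb = pruning_loglik(best, aln)
    la = pruning_loglik(alt, aln)
    delta = float(lb.sum() - la.sum())
    rng = np.random.default_rng(seed)
    n_sites = lb.shape[0]
    idx = rng.integers(0, n_sites, size=(n_rell, n_sites))
    rb = lb[idx].sum(axis=1)
    ra = la[idx].sum(axis=1)
    centered = (rb - rb.mean()) - (ra - ra.mean())
    p = float(np.mean(centered >= delta))
    return SHResult(delta_lnL=delta, p_value=p, n_replicates=n_rell, seed=seed)


# ---------------------------------------------------------------------------
# Topology comparison
# ---------------------------------------------------------------------------


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance between two unrooted trees.

    Symmetric-difference count of non-trivial bipartitions; the trees
    must share a leaf set.
    """
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(
        data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    b = dendropy.Tree.get(
        data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    for t in (a, b):
        t.is_rooted = False
        t.update_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def read_newick(path_or_string) -> dendropy.Tree:
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        return dendropy.Tree.get(data=path_or_string, schema="newick")
    return dendropy.Tree.get(path=str(path_or_string), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


# ---------------------------------------------------------------------------
# The dataset I vs II experiment
# ---------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Everything the chimera-substitution experiment produces."""

    dataset_i: Alignment
    dataset_ii: Alignment
    tree_i: dendropy.Tree
    tree_ii: dendropy.Tree
    sh: SHResult
    rf: int
    substituted: tuple[str, ...]


def chimera_contrast(
    community,
    chimeras: Mapping[str, str] | None = None,
    n_substituted: int = 6,
    n_rell: int = 1000,
    seed: int = 0,
    n_breakpoints: int = 1,
) -> ContrastResult:
    """Run the chimera-free vs chimera-substituted tree contrast.

    Dataset I holds the community's primary references plus its
    secondary symbionts as outgroup-eligible taxa (the most Buchnera-like
    secondary, Serratia, is the conventional outgroup).  Dataset II
    replaces primary species' sequences with chimeric clones: either the
    *chimeras* mapping supplied by the caller (e.g. authentic chimeras
    detected in simulated clone libraries; may be empty, giving a null
    contrast), or — when none is given — freshly formed two-parent
    chimeras of *n_substituted* species with a divergent secondary.
    NJ/JC69 trees are inferred from both alignments, and the SH test
    compares the two topologies on the chimera-containing alignment.
    """
    from .amplicon import form_chimera  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    primaries = community.primary
    secondaries = community.secondary
    if n_substituted > len(primaries):
        raise ValueError("cannot substitute more species than there are primaries")
    if not secondaries:
        raise ValueError("community has no secondary symbionts")

    normal = {r.taxon: r.sequence for r in primaries}
    outgroup = {secondaries[0].taxon: secondaries[0].sequence}

    if chimeras is None:
        chosen = rng.choice(len(primaries), size=n_substituted, replace=False)
        chimeras = {}
        for k, idx in enumerate(sorted(chosen)):
            primary = primaries[idx]
            partner = secondaries[k % len(secondaries)]
            clone = form_chimera(
                (primary, partner),
                community.region_map,
                n_breakpoints=n_breakpoints,
                seed=rng,
                clone_id=f"chimera_{primary.taxon}",
            )
            chimeras[primary.taxon] = clone.sequence
    else:
        chimeras = dict(chimeras)

    ds_i, ds_ii = build_datasets(normal, chimeras, outgroup)
    labels_i, d_i = alignment_distance_matrix(ds_i)
    labels_ii, d_ii = alignment_distance_matrix(ds_ii)
    tree_i = neighbor_joining(labels_i, d_i)
    tree_ii = neighbor_joining(labels_ii, d_ii)

    # evaluate both topologies on the chimera-containing alignment;
    # the tree inferred from that alignment is the "best" candidate
    sh = sh_test(tree_ii, tree_i, ds_ii, n_rell=n_rell, seed=int(rng.integers(2**31)))
    rf = rf_distance(tree_i, tree_ii)
    return ContrastResult(
        dataset_i=ds_i,
        dataset_ii=ds_ii,
        tree_i=tree_i,
        tree_ii=tree_ii,
        sh=sh,
        rf=rf,
        substituted=tuple(sorted(chimeras)),
    )
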