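"""Divergence and clone-library composition statistics.

"Genetic distance" is implemented throughout as the uncorrected
p-distance with pairwise deletion: mismatching columns divided by
compared columns, excluding any column where either sequence carries a
non-A/C/G/T symbol (gaps, ambiguity codes).  The multiple-hit-corrected
JC69 distance lives in :mod:`chimeraseg.phylo`, where it feeds tree
inference.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_ACGT = frozenset(b"ACGT")

CHIMERA_CATEGORY = "chimera"


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _valid_mask(codes: np.ndarray) -> np.ndarray:
    mask = np.zeros(codes.shape, dtype=bool)
    for b in _ACGT:
        mask |= codes == b
    return mask


def p_distance(a: str, b: str) -> float:
    """Uncorrected pairwise distance with pairwise deletion.

    Raises on unequal lengths or when no column is comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ca, cb = _codes(a), _codes(b)
    valid = _valid_mask(ca) & _valid_mask(cb)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable columns (all gapped/ambiguous)")
    mismatches = int(((ca != cb) & valid).sum())
    return mismatches / n


def distance_matrix(seqs: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs p-distance matrix over a labelled set of aligned sequences."""
    labels = list(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(seqs[labels[i]], seqs[labels[j]])
    return labels, d


def group_divergence(
    seqs: Mapping[str, str], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Within/between-group p-distance summaries.

    One row per group (within) and per unordered group pair (between)
    with columns ``n_pairs, min, max, mean``.  Within-group statistics
    for singleton groups are reported as empty (``n_pairs`` 0, NaNs).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two taxa")
    missing = set(seqs) - set(groups)
    if missing:
        raise ValueError(f"taxa without group assignment: {sorted(missing)}")
    labels, d = distance_matrix(seqs)
    pairs: dict[tuple[str, str, str], list[float]] = {}
    group_names = sorted({groups[t] for t in labels})
    for g in group_names:
        pairs[(g, g, "within")] = []
    for i, a in enumerate(group_names):
        for b in group_names[i + 1 :]:
            pairs[(a, b, "between")] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ga, gb = sorted((groups[labels[i]], groups[labels[j]]))
            kind = "within" if ga == gb else "between"
            pairs[(ga, gb, kind)].append(d[i, j])
    rows = []
    for (ga, gb, kind), values in pairs.items():
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "kind": kind,
                "n_pairs": len(values),
                "min": min(values) if values else np.nan,
                "max": max(values) if values else np.nan,
                "mean": float(np.mean(values)) if values else np.nan,
            }
        )
    return pd.DataFrame(rows)


def otu_distinct(d: float, threshold: float = 0.03) -> bool:
    """Whether a 16S divergence marks two lineages as distinct OTUs.

    Strictly more than *threshold* (conventionally 3%) divergence.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError("p-distance must be in [0, 1)")
    return d > threshold


@dataclass(frozen=True)
class CloneLibrarySummary:
    """Per-category clone counts and the chimera occurrence frequency."""

    counts: tuple[tuple[str, int], ...]

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def n_chimeras(self) -> int:
        return dict(self.counts).get(CHIMERA_CATEGORY, 0)

    @property
    def chimera_frequency(self) -> float:
        """Chimera occurrence frequency in percent, 2 decimals."""
        return round(100.0 * self.n_chimeras / self.total, 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=["category", "count"])


def summarize_library(categories: Iterable[str]) -> CloneLibrarySummary:
    """Tally clone categories (pure-taxon labels plus ``"chimera"``).

    Raises on an empty/missing category; category order follows first
    appearance.
    """
    counter: Counter[str] = Counter()
    order: list[str] = []
    n = 0
    for cat in categories:
        if not cat:
            raise ValueError("uncategorized clone")
        if cat not in counter:
            order.append(cat)
        counter[cat] += 1
        n += 1
    if n == 0:
        raise ValueError("no clones to summarize")
    return CloneLibrarySummary(counts=tuple((c, counter[c]) for c in order))


def categorize_calls(calls: Sequence) -> list[str]:
    """Map detector calls to library categories.

    A detected chimera is ``"chimera"``; a pure clone is labelled by the
    group of its single confident block (falling back to the best
    assignment's group); an undetermined call is ``"undetermined"``.
    """
    out = []
    for call in calls:
        if getattr(call, "undetermined", False):
            out.append("undetermined")
        elif call.is_chimera:
            out.append(CHIMERA_CATEGORY)
        elif call.blocks:
            out.append(call.blocks[0][2])
        else:
            confident = [a for a in call.assignments if a.confident]
            pool = confident or list(call.assignments)
            groups = [a.best_group for a in pool if a.best_group]
            out.append(Counter(groups).most_common(1)[0][0] if groups else "undetermined")
    return out


def direct_seq_rate(flags: Sequence[bool]) -> float:
    """Percentage of samples with an effective direct sequence, 1 decimal."""
    if len(flags) == 0:
        raise ValueError("no samples")
    return round(100.0 * sum(bool(f) for f in flags) / len(flags), 1)
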