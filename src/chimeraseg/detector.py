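"""Reference-based chimera detection by conserved-region segmentation.

The detector implements the remedy of splitting a query 16S sequence at
the conserved regions of the gene and matching each portion separately
against a panel of confirmed pure reference sequences.  A full-length
similarity search hides chimeras, because the within-primary divergence
of *Buchnera* (up to ~12.8%) is of the same order as the divergence
between the primary and the secondary symbionts (~12–26%); portion-wise
assignment makes the two parents visible individually.

Algorithm:

1. **Anchor** — locate the conserved regions in the query by comparing
   it to the panel consensus (few mismatches allowed per region).
2. **Segment** — cut the query at the midpoints of consecutive anchors;
   segments tile the query, each centred on one variable region.
3. **Assign** — for each segment, the best-matching panel taxon by
   column-wise fractional identity; an assignment is confident when the
   identity and the identity margin over the nearest other taxon group
   clear configurable thresholds.
4. **Call** — merge adjacent segments assigned to the same taxon group;
   two or more merged blocks = chimera.  Breakpoints are reported at the
   midpoint of the separating conserved region, the finest resolution at
   which a crossover inside near-identical sequence is identifiable.

Detected chimeras are classified into the structural types observed in
clone libraries — ``BA+oe``, ``oe+BA`` and ``BA+oe+BA``, where BA is the
primary symbiont and oe an "other endosymbiont" — plus ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .amplicon import CloneRead
from .community import (
    PRIMARY_GROUP,
    Community,
    RegionMap,
    SymbiontRef,
)

STRUCTURE_LABELS = ("BA+oe", "oe+BA", "BA+oe+BA", "other", "none")

_A_ORD = np.frombuffer(b"ACGT", dtype=np.uint8)


class AnchoringError(ValueError):
    """Raised when fewer than two conserved regions can be anchored."""


@dataclass(frozen=True)
class SegmentAssignment:
    """Best-taxon assignment for one query segment."""

    interval: tuple[int, int]
    best_taxon: str
    best_group: str
    identity: float
    margin: float
    confident: bool


@dataclass(frozen=True)
class ChimeraCall:
    """Detector verdict for one clone."""

    clone_id: str
    is_chimera: bool
    assignments: tuple[SegmentAssignment, ...]
    blocks: tuple[tuple[int, int, str], ...]  # (start, end, group) merged blocks
    breakpoints: tuple[int, ...]
    structure: str
    undetermined: bool = False

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure label {self.structure!r}")
        if self.is_chimera == (self.structure == "none"):
            raise ValueError("structure must be 'none' exactly for non-chimeras")


def _encode(seq: str) -> np.ndarray:
    """uint8 codes 0..3 for ACGT, 255 for anything else (missing)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(raw.shape, 255, dtype=np.uint8)
    for code, char in enumerate(_A_ORD):
        out[raw == char] = code
    return out


def segment_intervals(
    anchors: Sequence[tuple[int, int]],
    total_length: int,
    variable_mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Cut ``[0, total_length)`` at the midpoints of consecutive anchors.

    With k anchors there are at most k cut points, giving up to k+1
    candidate segments; a leading or trailing piece that contains no
    variable column (it lies wholly inside a terminal anchor) is merged
    into its neighbour, so the default ten-anchor architecture yields
    nine informative segments.  The returned segments always tile
    ``[0, total_length)``.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two anchors to segment")
    mids = [(s + e) // 2 for s, e in sorted(anchors)]
    bounds = sorted({0, *mids, total_length})
    segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    if variable_mask is not None:
        while len(segs) > 1 and not variable_mask[segs[0][0] : segs[0][1]].any():
            first = segs.pop(0)
            segs[0] = (first[0], segs[0][1])
        while len(segs) > 1 and not variable_mask[segs[-1][0] : segs[-1][1]].any():
            last = segs.pop()
            segs[-1] = (segs[-1][0], last[1])
    return segs


class ChimeraDetector:
    """Segment-and-assign chimera detector over a pure-reference panel.

    Parameters
    ----------
    panel
        Pure reference sequences (a :class:`~chimeraseg.community.Community`
        or a sequence of :class:`SymbiontRef`), aligned to shared
        coordinates.
    region_map
        Conserved-region architecture of the alignment.  Defaults to the
        community's map when *panel* is a Community.
    groups
        Taxon -> group labels.  Assignment margins and block merging
        operate at group level, so that the many near-identical primary
        references never compete with each other; defaults to the
        community's grouping (all primaries collapse to ``BA``).
    identity_min, margin_min
        Confidence thresholds for a segment assignment.  Defaults (0.80,
        0.02) are chosen so that within-primary variation (<= ~13%) never
        splits a pure clone while primary/secondary gaps (>= ~12%) do.
    anchor_mismatch_limit
        Maximum mismatches against the panel consensus per conserved
        region for it to anchor (default 3 per 50-bp region).
    """

    def __init__(
        self,
        panel: Community | Sequence[SymbiontRef],
        region_map: RegionMap | None = None,
        groups: Mapping[str, str] | None = None,
        identity_min: float = 0.80,
        margin_min: float = 0.02,
        anchor_mismatch_limit: int = 3,
        primary_group: str = PRIMARY_GROUP,
    ) -> None:
        if isinstance(panel, Community):
            refs = list(panel.refs)
            region_map = region_map or panel.region_map
            groups = groups if groups is not None else panel.groups()
        else:
            refs = list(panel)
        if region_map is None:
            raise ValueError("region_map is required with a bare reference panel")
        if not refs:
            raise ValueError("panel must be non-empty")
        self.refs = refs
        self.region_map = region_map
        self.taxa = [r.taxon for r in refs]
        if groups is None:
            groups = {t: t for t in self.taxa}
        self.groups = {t: groups.get(t, t) for t in self.taxa}
        self.identity_min = float(identity_min)
        self.margin_min = float(margin_min)
        self.anchor_mismatch_limit = int(anchor_mismatch_limit)
        self.primary_group = primary_group

        self._matrix = np.stack([_encode(r.sequence) for r in refs])
        if self._matrix.shape[1] != region_map.total_length:
            raise ValueError("panel sequences do not match region map length")
        self._consensus = self._majority_consensus(self._matrix)

    @staticmethod
    def _majority_consensus(matrix: np.ndarray) -> np.ndarray:
        counts = np.stack([(matrix == b).sum(axis=0) for b in range(4)])
        return counts.argmax(axis=0).astype(np.uint8)

    # -- step 1: anchoring ------------------------------------------------

    def anchor_conserved(self, query: str) -> list[tuple[int, int]]:
        """Conserved intervals where the query matches the panel consensus.

        A region anchors when the query disagrees with the consensus in
        at most ``anchor_mismatch_limit`` columns (non-ACGT query symbols
        count as mismatches).  Raises :class:`AnchoringError` when fewer
        than two regions anchor — the query cannot be segmented.
        """
        q = _encode(query)
        if q.shape[0] != self.region_map.total_length:
            raise ValueError("query length does not match the panel alignment")
        anchors = []
        for start, end in self.region_map.conserved:
            mismatches = int((q[start:end] != self._consensus[start:end]).sum())
            if mismatches <= self.anchor_mismatch_limit:
                anchors.append((start, end))
        if len(anchors) < 2:
            raise AnchoringError(
                f"only {len(anchors)} conserved regions anchored; need >= 2"
            )
        return anchors

    # -- step 2: segmentation ---------------------------------------------

    def segment_query(self, anchors: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        """Cut the alignment at consecutive anchor midpoints.

        Segments tile ``[0, total_length)``; leading/trailing pieces
        without any variable column are merged into their neighbours.
        """
        variable_mask = ~self.region_map.conserved_mask()
        return segment_intervals(
            anchors, self.region_map.total_length, variable_mask=variable_mask
        )

    # -- step 3: assignment -----------------------------------------------

    def assign_segment(self, query: str, interval: tuple[int, int]) -> SegmentAssignment:
        """Best panel taxon for one segment by fractional identity.

        Identity is matches / compared columns, comparing only columns
        where both query and reference are A/C/G/T.  The margin is the
        identity gap to the best taxon of a *different group*; ties at
        the top are broken lexicographically and marked non-confident
        (margin 0).
        """
        start, end = interval
        if end <= start:
            raise ValueError("zero-length segment")
        q = _encode(query)[start:end]
        sub = self._matrix[:, start:end]
        valid = (q != 255) & (sub != 255)
        compared = valid.sum(axis=1)
        matches = ((sub == q) & valid).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            identities = np.where(compared > 0, matches / np.maximum(compared, 1), np.nan)

        if np.all(np.isnan(identities)):
            return SegmentAssignment(interval, "", "", float("nan"), 0.0, False)

        order = sorted(
            range(len(self.taxa)),
            key=lambda i: (-(identities[i] if not np.isnan(identities[i]) else -1.0), self.taxa[i]),
        )
        best = order[0]
        best_id = float(identities[best])
        best_group = self.groups[self.taxa[best]]
        # margin against the nearest competitor outside the best group
        rival_ids = [
            identities[i]
            for i in order[1:]
            if self.groups[self.taxa[i]] != best_group and not np.isnan(identities[i])
        ]
        margin = best_id - float(rival_ids[0]) if rival_ids else 0.0
        # exact tie with a different group: ambiguous, non-confident
        tied = any(
            identities[i] == best_id and self.groups[self.taxa[i]] != best_group
            for i in order[1:]
        )
        if tied:
            margin = 0.0
        confident = (
            not np.isnan(best_id)
            and best_id >= self.identity_min
            and margin >= self.margin_min
        )
        return SegmentAssignment(
            interval=interval,
            best_taxon=self.taxa[best],
            best_group=best_group,
            identity=best_id,
            margin=float(margin),
            confident=confident,
        )

    # -- step 4: calling ---------------------------------------------------

    def call(self, query: CloneRead | str, clone_id: str | None = None) -> ChimeraCall:
        """Full segment-and-assign chimera call for one clone."""
        if isinstance(query, CloneRead):
            seq = query.sequence
            clone_id = clone_id or query.clone_id
        else:
            seq = query
            clone_id = clone_id or "query"

        try:
            anchors = self.anchor_conserved(seq)
        except AnchoringError:
            return ChimeraCall(
                clone_id=clone_id,
                is_chimera=False,
                assignments=(),
                blocks=(),
                breakpoints=(),
                structure="none",
                undetermined=True,
            )

        segments = self.segment_query(anchors)
        assignments = tuple(self.assign_segment(seq, iv) for iv in segments)

        # merge consecutive confident assignments with the same group;
        # non-confident segments are uninformative and do not break a block
        blocks: list[list] = []  # [start, end, group]
        for a in assignments:
            if not a.confident:
                continue
            if blocks and blocks[-1][2] == a.best_group:
                blocks[-1][1] = a.interval[1]
            else:
                blocks.append([a.interval[0], a.interval[1], a.best_group])

        is_chimera = len(blocks) >= 2
        breakpoints = tuple(b[0] for b in blocks[1:]) if is_chimera else ()
        structure = (
            _structure_of([g for _, _, g in blocks], self.primary_group)
            if is_chimera
            else "none"
        )
        return ChimeraCall(
            clone_id=clone_id,
            is_chimera=is_chimera,
            assignments=assignments,
            blocks=tuple((s, e, g) for s, e, g in blocks),
            breakpoints=breakpoints,
            structure=structure,
        )

    def call_many(self, clones: Iterable[CloneRead | str]) -> list[ChimeraCall]:
        return [self.call(c) for c in clones]


def _structure_of(block_groups: Sequence[str], primary_taxon: str) -> str:
    labels = ["BA" if g == primary_taxon else "oe" for g in block_groups]
    if labels == ["BA", "oe"]:
        return "BA+oe"
    if labels == ["oe", "BA"]:
        return "oe+BA"
    if labels == ["BA", "oe", "BA"]:
        return "BA+oe+BA"
    return "other"


def classify_structure(call: ChimeraCall, primary_taxon: str = PRIMARY_GROUP) -> str:
    """Structural type of a detected chimera.

    Two blocks (primary, other) -> ``BA+oe``; (other, primary) ->
    ``oe+BA``; three blocks (primary, other, primary) -> ``BA+oe+BA``;
    any other arrangement -> ``other``.
    """
    if not call.is_chimera:
        raise ValueError("classify_structure requires a chimera call")
    return _structure_of([g for _, _, g in call.blocks], primary_taxon)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def anchor_conserved(
    query: str,
    panel: Community | Sequence[SymbiontRef],
    region_map: RegionMap | None = None,
    **kwargs,
) -> list[tuple[int, int]]:
    return ChimeraDetector(panel, region_map=region_map, **kwargs).anchor_conserved(query)


def segment_query(
    anchors: Sequence[tuple[int, int]], total_length: int
) -> list[tuple[int, int]]:
    """Segment an alignment of *total_length* at the given anchor midpoints.

    The anchors themselves are taken as the conserved set when deciding
    whether an end piece carries any variable column.
    """
    mask = np.ones(total_length, dtype=bool)
    for start, end in anchors:
        mask[start:end] = False
    return segment_intervals(anchors, total_length, variable_mask=mask)


def assign_segment(
    query: str,
    interval: tuple[int, int],
    panel: Community | Sequence[SymbiontRef],
    region_map: RegionMap | None = None,
    **kwargs,
) -> SegmentAssignment:
    return ChimeraDetector(panel, region_map=region_map, **kwargs).assign_segment(
        query, interval
    )


def call_chimera(
    query: CloneRead | str,
    panel: Community | Sequence[SymbiontRef],
    region_map: RegionMap | None = None,
    **kwargs,
) -> ChimeraCall:
    return ChimeraDetector(panel, region_map=region_map, **kwargs).call(query)
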