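"""Reference-based artifact screening.

When the copies of a camo set are not perfectly identical in the
reference, pooling their reads onto the representative turns every
reference-divergence site into an apparent variant.  These positions
are derived *from the reference alone*: each non-representative copy is
locally aligned back to the representative (match=1, mismatch=-3, gap
open=-5, gap extend=-2) and every mismatch or gap column is converted
to a representative-coordinate artifact position.  Variants called at
these positions are filtered during rescue.

Sets repeated more than ``max_repeat`` times (default 5) are excluded
from screening but still rescued.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .alignment import Alignment, ScoringScheme, align, percent_identity
from .camo import CamoSet, Interval
from .formats import GenomeSequence

__all__ = [
    "ScoringScheme",
    "ArtifactPosition",
    "local_align",
    "derive_artifact_positions",
    "screen_artifacts",
    "artifact_position_set",
]


@dataclass(frozen=True)
class ArtifactPosition:
    contig: str
    pos: int  # representative coordinates, left anchor for gaps
    ref: str  # representative allele
    alt: str  # divergent allele seen in the copy
    source_copy_index: int
    set_id: str = ""


def local_align(
    a: str, b: str, scoring: ScoringScheme = ScoringScheme()
) -> Alignment:
    """Optimal affine-gap local alignment (open on the first gap column,
    extend on each subsequent one)."""
    return align(a, b, scoring, mode="local")


def derive_artifact_positions(
    camo_set: CamoSet,
    genome: GenomeSequence,
    scoring: ScoringScheme = ScoringScheme(),
    max_repeat: int = 5,
    min_hit_identity: float = 98.0,
) -> Optional[list[ArtifactPosition]]:
    """Artifact positions for one camo set, or None when it is skipped.

    Each non-representative copy is locally aligned to the
    representative; mismatch columns become substitution artifacts at
    ``rep_start + query_offset``; a gap run becomes a single
    left-anchored record at the column preceding the gap.  Copies whose
    alignment falls below ``min_hit_identity`` are not qualifying hits.
    """
    if camo_set.repeat_count > max_repeat:
        return None
    rep_contig, rep_start, rep_end = camo_set.representative
    rep_seq = genome.fetch(rep_contig, rep_start, rep_end)
    out: list[ArtifactPosition] = []
    for ci, (contig, start, end) in enumerate(camo_set.regions[1:], start=1):
        copy_seq = genome.fetch(contig, start, end)
        aln = align(rep_seq, copy_seq, scoring, mode="local")
        if aln.n_columns == 0 or percent_identity(aln) < min_hit_identity:
            continue
        out.extend(_columns_to_artifacts(aln, rep_contig, rep_start, ci, camo_set.set_id))
    out.sort(key=lambda a: a.pos)
    return out


def _columns_to_artifacts(
    aln: Alignment, contig: str, rep_start: int, copy_index: int, set_id: str
) -> list[ArtifactPosition]:
    cols = aln.columns
    out: list[ArtifactPosition] = []
    i = 0
    last_q: Optional[int] = None
    while i < len(cols):
        q, s = cols[i]
        if q is not None and s is not None:
            if aln.query[q] != aln.subject[s]:
                out.append(
                    ArtifactPosition(contig, rep_start + q, aln.query[q], aln.subject[s], copy_index, set_id)
                )
            last_q = q
            i += 1
            continue
        # gap run: collect all consecutive gap columns of the same kind
        kind_query_gap = q is None
        j = i
        run_q: list[int] = []
        run_s: list[int] = []
        while j < len(cols) and ((cols[j][0] is None) == kind_query_gap) and (
            cols[j][0] is None or cols[j][1] is None
        ):
            if cols[j][0] is not None:
                run_q.append(cols[j][0])
            if cols[j][1] is not None:
                run_s.append(cols[j][1])
            j += 1
        anchor_q = last_q if last_q is not None else 0
        if kind_query_gap:
            # copy has extra sequence (insertion relative to representative)
            inserted = "".join(aln.subject[s] for s in run_s)
            ref = aln.query[anchor_q]
            out.append(
                ArtifactPosition(contig, rep_start + anchor_q, ref, ref + inserted, copy_index, set_id)
            )
        else:
            # copy lacks representative bases (deletion in the copy)
            ref = aln.query[anchor_q] + "".join(aln.query[qq] for qq in run_q)
            out.append(
                ArtifactPosition(contig, rep_start + anchor_q, ref, aln.query[anchor_q], copy_index, set_id)
            )
            last_q = run_q[-1]
        i = j
    return out


def screen_artifacts(
    sets: Sequence[CamoSet],
    genome: GenomeSequence,
    scoring: ScoringScheme = ScoringScheme(),
    max_repeat: int = 5,
    min_hit_identity: float = 98.0,
) -> tuple[list[ArtifactPosition], list[str]]:
    """Screen every set; returns (positions, skipped set ids)."""
    positions: list[ArtifactPosition] = []
    skipped: list[str] = []
    for s in sets:
        res = derive_artifact_positions(s, genome, scoring, max_repeat, min_hit_identity)
        if res is None:
            skipped.append(s.set_id)
        else:
            positions.extend(res)
    return positions, skipped


def artifact_position_set(
    positions: Iterable[ArtifactPosition],
) -> set[tuple[str, int]]:
    """(contig, pos) pairs covering every reference base each artifact spans."""
    out: set[tuple[str, int]] = set()
    for a in positions:
        for p in range(a.pos, a.pos + len(a.ref)):
            out.add((a.contig, p))
    return out
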