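"""Adaptive immune receptor (AIR) transcript analysis.

Per cell: extract reads from the receptor loci (IGH, IGK, IGL, TRA, TRB),
keep reads with a high-quality V-segment match, build one consensus per
locus (per isotype for IGH), assign V/(D)/J/constant segments by local
alignment against user-supplied IMGT-style references, and pair heavy with
light chains (IG) or alpha with beta chains (TCR).

Segment assignment uses plain Smith–Waterman local alignment (match 2,
mismatch −2, gap open −4, gap extend −1); candidate segments are ranked by
a fast infix edit-distance prefilter before the full alignment of the
winner.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pysam
from Bio import Align

from .io import BedInterval, ReadRecord, revcomp

IGH_ISOTYPES = ("IGHM", "IGHD", "IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2")
LOCUS_NAMES = ("IGH", "IGK", "IGL", "TRA", "TRB")
REQUIRES_D = {"IGH": True, "IGK": False, "IGL": False, "TRA": False, "TRB": True}


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    intervals: tuple[BedInterval, ...]
    requires_d: bool

    @classmethod
    def from_bed(cls, intervals: list[BedInterval]) -> dict[str, "LocusDefinition"]:
        """Group BED records by their name column into locus definitions."""
        by_name: dict[str, list[BedInterval]] = defaultdict(list)
        for iv in intervals:
            if iv.name not in REQUIRES_D:
                raise ValueError(f"unknown locus name in BED: {iv.name!r}")
            by_name[iv.name].append(iv)
        return {
            name: cls(name, tuple(ivs), REQUIRES_D[name]) for name, ivs in by_name.items()
        }


@dataclass(frozen=True)
class SegmentReference:
    segment_class: str  # V | D | J | C
    locus: str
    segment_id: str
    sequence: str
    isotype: str = "n/a"
    form: str = "n/a"  # membrane | secreted | n/a

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.segment_id}: empty sequence")


@dataclass(frozen=True)
class VFilterParams:
    min_identity: float = 0.80
    min_aligned_length: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class SegmentCall:
    segment_id: str
    identity: float  # identities / aligned columns (incl. internal gaps)
    score: float
    start: int  # position on the consensus/read
    end: int
    matched: int = 0  # gapless aligned columns (identities + mismatches)


@dataclass
class AIRConsensus:
    cell_id: str
    locus: str
    isotype: str  # "n/a" outside IGH
    sequence: str
    support: int
    calls: dict[str, SegmentCall] = field(default_factory=dict)
    annotated: bool = False
    reason: str = ""
    dropped_calls: list[str] = field(default_factory=list)


@dataclass
class PairedReceptor:
    cell_id: str
    receptor_type: str  # IG | TCR
    chain_a: AIRConsensus  # IGH or TRB
    chain_b: AIRConsensus  # IGK/IGL or TRA
    v_consistent_across_isotypes: bool | None = None


def make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=2,
        mismatch_score=-2,
        open_gap_score=-4,
        extend_gap_score=-1,
    )


def _edlib_rank(seq: str, ref: str) -> int:
    """Infix edit distance of ref within seq (large when no fit)."""
    res = edlib.align(ref, seq, mode="HW", k=max(1, int(0.45 * len(ref))))
    d = res["editDistance"]
    return d if d != -1 else 10 ** 9


def _best_local(seq: str, refs: list[SegmentReference]) -> tuple[SegmentReference, str, int] | None:
    """Best reference over both strands by infix edit distance.

    Returns (ref, oriented_seq, distance); None if nothing fits.
    """
    best = None
    for oriented in (seq, revcomp(seq)):
        for ref in refs:
            d = _edlib_rank(oriented, ref.sequence)
            if d >= 10 ** 9:
                continue
            key = (d, -len(ref.sequence), ref.segment_id)
            if best is None or key < best[0]:
                best = (key, ref, oriented)
    if best is None:
        return None
    return best[1], best[2], best[0][0]


def _alignment_stats(aligner: Align.PairwiseAligner, seq: str, ref: str) -> SegmentCall | None:
    alignments = aligner.align(seq, ref)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    matched = counts.identities + counts.mismatches
    columns = matched + counts.gaps  # local alignment: gaps are internal
    if columns == 0:
        return None
    identity = counts.identities / columns
    blocks = aln.aligned[0]
    return SegmentCall(
        "", identity, float(aln.score), int(blocks[0][0]), int(blocks[-1][1]), matched
    )


# ---------------------------------------------------------------------------
# Locus read extraction from alignments
# ---------------------------------------------------------------------------

def extract_locus_reads(
    sam_paths: dict[str, str | Path] | str | Path,
    loci: dict[str, LocusDefinition],
    cell_tag: str = "CB",
) -> dict[str, dict[str, list[ReadRecord]]]:
    """Select reads whose primary alignment overlaps a receptor locus.

    ``sam_paths`` is either one SAM with per-read cell tags (``cell_tag``)
    or a mapping cell_id → SAM path (one file per cell).  A read is
    selected for a locus iff its primary alignment overlaps any interval
    of the locus by at least one base; unmapped, secondary and
    supplementary records are ignored.
    """
    if isinstance(sam_paths, (str, Path)):
        items = [(None, Path(sam_paths))]
    else:
        items = [(cell, Path(p)) for cell, p in sorted(sam_paths.items())]
    out: dict[str, dict[str, list[ReadRecord]]] = {}
    for fixed_cell, path in items:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if fixed_cell is not None:
                    cell = fixed_cell
                elif rec.has_tag(cell_tag):
                    cell = rec.get_tag(cell_tag)
                else:
                    raise ValueError(
                        f"{path}: record {rec.query_name} lacks the {cell_tag} tag and no "
                        "per-cell file mapping was given"
                    )
                chrom = rec.reference_name
                start, end = rec.reference_start, rec.reference_end
                seq = rec.query_sequence or ""
                if not seq:
                    continue
                if rec.is_reverse:
                    seq = revcomp(seq)  # restore original read orientation
                for locus in loci.values():
                    if any(iv.overlaps(chrom, start, end) for iv in locus.intervals):
                        out.setdefault(cell, {}).setdefault(locus.name, []).append(
                            ReadRecord(rec.query_name, seq)
                        )
                        break
    return out


# ---------------------------------------------------------------------------
# Filtering, consensus, annotation
# ---------------------------------------------------------------------------

def v_filter(
    reads: list[ReadRecord],
    v_references: list[SegmentReference],
    params: VFilterParams | None = None,
) -> list[tuple[ReadRecord, SegmentCall]]:
    """Keep reads with a high-quality local-alignment match to a V segment.

    Reads are reoriented to the V-coding strand; the best V and its
    identity/score are attached.
    """
    params = params or VFilterParams()
    if not v_references:
        raise ValueError("no V references")
    aligner = make_aligner()
    kept = []
    for read in reads:
        hit = _best_local(read.sequence, v_references)
        if hit is None:
            continue
        ref, oriented, _ = hit
        call = _alignment_stats(aligner, oriented, ref.sequence)
        if call is None:
            continue
        if call.identity >= params.min_identity and call.matched >= params.min_aligned_length:
            call.segment_id = ref.segment_id
            kept.append((ReadRecord(read.read_id, oriented, subread_count=read.subread_count), call))
    return kept


def split_igh_by_isotype(
    reads: list[ReadRecord],
    c_references: list[SegmentReference],
    min_matched: int = 50,
    min_identity: float = 0.75,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign IGH reads to the isotype (and membrane/secreted form when the
    references distinguish forms) of their best constant-region match."""
    aligner = make_aligner()
    groups: dict[str, list[ReadRecord]] = defaultdict(list)
    unassigned = []
    for read in reads:
        hit = _best_local(read.sequence, c_references)
        call = None
        if hit is not None:
            ref, oriented, _ = hit
            call = _alignment_stats(aligner, oriented, ref.sequence)
        if (
            call is None
            or call.matched < min_matched
            or call.identity < min_identity
        ):
            unassigned.append(read)
            continue
        label = ref.isotype if ref.form == "n/a" else f"{ref.isotype}_{ref.form}"
        groups[label].append(read)
    return dict(groups), unassigned


def build_consensus(reads: list[ReadRecord]) -> tuple[str, int]:
    """Medoid-scaffold consensus of a read set.

    The medoid (minimal summed edit distance to all members, ties by read
    id) anchors a column space; every member is globally aligned to it and
    votes per column for a base, a deletion, or an insertion.  Majority
    wins; insertions need support from more than half the members.
    Deterministic and independent of input order.
    """
    if not reads:
        raise ValueError("no reads to build a consensus from")
    members = sorted(reads, key=lambda r: r.read_id)
    if len(members) == 1:
        return members[0].sequence, 1
    n = len(members)
    seqs = [m.sequence for m in members]
    sums = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j])["editDistance"]
            sums[i] += d
            sums[j] += d
    medoid_idx = min(range(n), key=lambda i: (sums[i], members[i].read_id))
    medoid = seqs[medoid_idx]

    base_votes: list[Counter] = [Counter() for _ in medoid]
    insert_votes: dict[int, Counter] = defaultdict(Counter)
    for seq in seqs:
        res = edlib.align(seq, medoid, mode="NW", task="path")
        qpos = tpos = 0
        for length, op in _iter_cigar(res["cigar"]):
            if op in "=X":
                for k in range(length):
                    base_votes[tpos + k][seq[qpos + k]] += 1
                qpos += length
                tpos += length
            elif op == "I":  # present in member, absent in medoid
                insert_votes[tpos][seq[qpos : qpos + length]] += 1
                qpos += length
            elif op == "D":  # absent in member
                for k in range(length):
                    base_votes[tpos + k]["-"] += 1
                tpos += length
    out: list[str] = []
    half = n / 2
    for pos in range(len(medoid) + 1):
        ins = insert_votes.get(pos)
        if ins and sum(ins.values()) > half:
            out.append(min(ins.items(), key=lambda kv: (-kv[1], kv[0]))[0])
        if pos < len(medoid):
            base, _ = min(base_votes[pos].items(), key=lambda kv: (-kv[1], kv[0]))
            if base != "-":
                out.append(base)
    return "".join(out), n


def _iter_cigar(cigar: str):
    length = 0
    for ch in cigar:
        if ch.isdigit():
            length = length * 10 + ord(ch) - 48
        else:
            yield length, ch
            length = 0


_CLASS_ORDER = ("V", "D", "J", "C")


def assign_vdj(
    consensus: str,
    references: dict[str, list[SegmentReference]],
    params: VFilterParams | None = None,
) -> tuple[dict[str, SegmentCall], str, bool, list[str], str]:
    """Call the best V/(D)/J/C segment on a consensus sequence.

    Returns (calls, oriented_sequence, annotated, dropped_classes, reason).
    Calls must appear in V→(D)→J→C order along the consensus; a call that
    violates the order is dropped and flagged.  A consensus without both a
    V and a J call is unannotated.
    """
    params = params or VFilterParams()
    if not references.get("V") or not references.get("J"):
        raise ValueError("V and J references are required")
    aligner = make_aligner()
    v_hit = _best_local(consensus, references["V"])
    oriented = v_hit[1] if v_hit is not None else consensus
    calls: dict[str, SegmentCall] = {}
    for cls in _CLASS_ORDER:
        refs = references.get(cls)
        if not refs:
            continue
        ranked = sorted(
            refs, key=lambda r: (_edlib_rank(oriented, r.sequence), r.segment_id)
        )
        best = ranked[0]
        if _edlib_rank(oriented, best.sequence) >= 10 ** 9:
            continue
        call = _alignment_stats(aligner, oriented, best.sequence)
        if call is None:
            continue
        min_len = min(params.min_aligned_length, max(10, int(0.5 * len(best.sequence))))
        if call.identity < params.min_identity or call.matched < min_len:
            continue
        call.segment_id = best.segment_id
        calls[cls] = call
    dropped = []
    last_start = -1
    for cls in _CLASS_ORDER:
        if cls not in calls:
            continue
        if calls[cls].start < last_start:
            dropped.append(cls)
            del calls[cls]
        else:
            last_start = calls[cls].start
    if "V" not in calls or "J" not in calls:
        missing = [c for c in ("V", "J") if c not in calls]
        return calls, oriented, False, dropped, f"missing {'/'.join(missing)} call"
    return calls, oriented, True, dropped, ""


# ---------------------------------------------------------------------------
# Per-cell analysis and pairing
# ---------------------------------------------------------------------------

def route_reads_by_v_match(
    reads: list[ReadRecord],
    references: dict[str, dict[str, list[SegmentReference]]],
    params: VFilterParams | None = None,
) -> dict[str, list[tuple[ReadRecord, SegmentCall]]]:
    """Assign each read to the receptor locus whose V references it best
    matches (alignment-free entry point when no genome alignments exist).

    Reads failing the V filter for every locus are dropped.
    """
    params = params or VFilterParams()
    best: dict[str, tuple[float, str, ReadRecord, SegmentCall]] = {}
    for locus in sorted(references):
        v_refs = references[locus].get("V", [])
        if not v_refs:
            continue
        for read, call in v_filter(reads, v_refs, params):
            prev = best.get(read.read_id)
            if prev is None or call.score > prev[0]:
                best[read.read_id] = (call.score, locus, read, call)
    routed: dict[str, list[tuple[ReadRecord, SegmentCall]]] = defaultdict(list)
    for read_id in sorted(best):
        score, locus, read, call = best[read_id]
        routed[locus].append((read, call))
    return dict(routed)


def analyze_cell(
    cell_id: str,
    reads_by_locus: dict[str, list[ReadRecord]],
    references: dict[str, dict[str, list[SegmentReference]]],
    params: VFilterParams | None = None,
    prefiltered: bool = False,
) -> list[AIRConsensus]:
    """Consensus + segment assignment for one cell.

    IGH reads are first split by isotype so alternative splicing products
    of the same rearrangement yield separate consensuses.  When
    ``prefiltered`` is true the reads already passed the V filter.
    """
    params = params or VFilterParams()
    out = []
    for locus in sorted(reads_by_locus):
        reads = reads_by_locus[locus]
        if not prefiltered:
            reads = [r for r, _ in v_filter(reads, references[locus]["V"], params)]
        if not reads:
            continue
        if locus == "IGH":
            groups, _ = split_igh_by_isotype(reads, references[locus]["C"])
            labelled = sorted(groups.items())
        else:
            labelled = [("n/a", reads)]
        for isotype, group in labelled:
            seq, support = build_consensus(group)
            calls, oriented, annotated, dropped, reason = assign_vdj(
                seq, references[locus], params
            )
            out.append(
                AIRConsensus(
                    cell_id=cell_id,
                    locus=locus,
                    isotype=isotype,
                    sequence=oriented,
                    support=support,
                    calls=calls,
                    annotated=annotated,
                    reason=reason,
                    dropped_calls=dropped,
                )
            )
    return out


def pair_receptors(
    consensuses: list[AIRConsensus],
) -> tuple[list[PairedReceptor], list[dict]]:
    """Pair annotated heavy/light (IG) and alpha/beta (TCR) chains per cell.

    IG: annotated IGH + annotated IGK-or-IGL (higher read support wins when
    both exist).  For cells with several IGH isotype consensuses,
    ``v_consistent_across_isotypes`` records whether all share one V call.
    Returns the pairs and a per-cell summary of detected chains.
    """
    by_cell: dict[str, list[AIRConsensus]] = defaultdict(list)
    for cons in consensuses:
        by_cell[cons.cell_id].append(cons)
    pairs: list[PairedReceptor] = []
    summary: list[dict] = []
    for cell in sorted(by_cell):
        chains = by_cell[cell]
        annotated = [c for c in chains if c.annotated]
        per_locus: dict[str, list[AIRConsensus]] = defaultdict(list)
        for c in annotated:
            per_locus[c.locus].append(c)
        detected = sorted({c.locus for c in chains})
        row = {
            "cell_id": cell,
            "detected_loci": ",".join(detected),
            "paired_ig": False,
            "paired_tcr": False,
            "v_consistent_across_isotypes": None,
        }
        igh_list = per_locus.get("IGH", [])
        v_consistent = None
        if len(igh_list) > 1:
            v_ids = {c.calls["V"].segment_id for c in igh_list}
            v_consistent = len(v_ids) == 1
        row["v_consistent_across_isotypes"] = v_consistent
        if igh_list:
            lights = per_locus.get("IGK", []) + per_locus.get("IGL", [])
            if lights:
                heavy = max(igh_list, key=lambda c: (c.support, c.isotype))
                light = max(lights, key=lambda c: (c.support, -ord(c.locus[2]), c.cell_id))
                pairs.append(PairedReceptor(cell, "IG", heavy, light, v_consistent))
                row["paired_ig"] = True
        if per_locus.get("TRA") and per_locus.get("TRB"):
            tra = max(per_locus["TRA"], key=lambda c: c.support)
            trb = max(per_locus["TRB"], key=lambda c: c.support)
            pairs.append(PairedReceptor(cell, "TCR", trb, tra, None))
            row["paired_tcr"] = True
        summary.append(row)
    return pairs, summary


def load_segment_fastas(
    paths: dict[str, dict[str, str | Path]],
) -> dict[str, dict[str, list[SegmentReference]]]:
    """Load {locus: {class: fasta_path}} into segment references.

    FASTA headers become segment ids; for IGH constant regions the id
    prefix up to the first '_' is taken as the isotype and an optional
    '_membrane'/'_secreted' suffix as the form.
    """
    from Bio import SeqIO

    refs: dict[str, dict[str, list[SegmentReference]]] = {}
    for locus, classes in paths.items():
        refs[locus] = {}
        for cls, path in classes.items():
            segs = []
            for rec in SeqIO.parse(str(path), "fasta"):
                isotype, form = "n/a", "n/a"
                if cls == "C":
                    name = rec.id
                    for suffix in ("membrane", "secreted"):
                        if name.endswith("_" + suffix):
                            form = suffix
                            name = name[: -len(suffix) - 1]
                    isotype = name
                segs.append(
                    SegmentReference(cls, locus, rec.id, str(rec.seq), isotype, form)
                )
            refs[locus][cls] = segs
    return refs
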