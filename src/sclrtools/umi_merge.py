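"""Molecule-level read merging via splint- and 10X-UMIs.

Reads from the same circularization event share a splint-UMI; reads from
the same RNA molecule share a 10X-UMI.  Merging happens in two sequential
steps (splint first, then 10X) by single-linkage grouping of UMIs within a
small edit distance.  Groups whose members carry different cell
assignments are discarded afterwards.  An exact-match dedup mirroring
short-read processing is provided for cross-platform comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import edlib
import pandas as pd

from .io import ReadRecord, revcomp
from .simulate import ChemistryConfig


@dataclass(frozen=True)
class UmiMergeParams:
    """``umi_max_edits`` quantifies "similar UMIs": single-linkage merge
    radius in Levenshtein distance.  At 10 nt and ~98% read accuracy most
    UMI errors are single events, hence the default of 1."""

    umi_max_edits: int = 1

    def __post_init__(self) -> None:
        if self.umi_max_edits < 0:
            raise ValueError("umi_max_edits must be ≥ 0")


@dataclass(frozen=True)
class IlluminaDedupParams:
    min_raw_coverage: int = 3

    def __post_init__(self) -> None:
        if self.min_raw_coverage < 0:
            raise ValueError("min_raw_coverage must be ≥ 0")


@dataclass
class MergedRead:
    representative: ReadRecord
    member_ids: list[str]
    stage: str  # "splint" | "tenx"
    cell_assignments: list[str] = field(default_factory=list)

    @property
    def member_count(self) -> int:
        return len(self.member_ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def extract_splint_umi(
    read: ReadRecord | str,
    chemistry: ChemistryConfig,
    params: UmiMergeParams | None = None,
) -> str | None:
    """Locate both splint flanks by infix alignment and return the bases
    between them; None when a flank is missing or the insert length
    deviates from the expected UMI length by more than ``umi_max_edits``."""
    params = params or UmiMergeParams()
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if chemistry.splint_umi_len <= 0:
        return None
    left, right = chemistry.splint_umi_flanks
    budgets = (max(1, math.ceil(0.2 * len(left))), max(1, math.ceil(0.2 * len(right))))
    best = None
    for oriented in (seq, revcomp(seq)):
        res_l = edlib.align(left, oriented, mode="HW", task="locations", k=budgets[0])
        if res_l["editDistance"] == -1:
            continue
        l_end = res_l["locations"][0][1]
        res_r = edlib.align(right, oriented, mode="HW", task="locations", k=budgets[1])
        if res_r["editDistance"] == -1:
            continue
        # first right-flank hit starting after the left flank
        starts = [loc[0] for loc in res_r["locations"] if loc[0] > l_end]
        if not starts:
            continue
        umi = oriented[l_end + 1 : starts[0]]
        dist = res_l["editDistance"] + res_r["editDistance"]
        if best is None or dist < best[0]:
            best = (dist, umi)
    if best is None:
        return None
    umi = best[1]
    if abs(len(umi) - chemistry.splint_umi_len) > params.umi_max_edits:
        return None
    return umi


def _representative(members: list[ReadRecord]) -> ReadRecord:
    # highest subread count, then longest sequence, then smallest read id
    return min(members, key=lambda r: (-r.subread_count, -len(r.sequence), r.read_id))


def merge_by_umi(
    reads: list[ReadRecord],
    umi_accessor: Callable[[ReadRecord], str | None],
    params: UmiMergeParams | None = None,
    stage: str = "splint",
    cell_of: Callable[[ReadRecord], str] | None = None,
) -> list[MergedRead]:
    """Single-linkage grouping of reads whose UMIs are within
    ``umi_max_edits``; reads without an extractable UMI pass through as
    singletons.  Group membership is independent of input order."""
    params = params or UmiMergeParams()
    ordered = sorted(reads, key=lambda r: r.read_id)
    umis = [umi_accessor(r) for r in ordered]
    with_umi = [i for i, u in enumerate(umis) if u is not None]

    # distinct UMI strings; identical UMIs collapse immediately
    distinct: dict[str, list[int]] = {}
    for i in with_umi:
        distinct.setdefault(umis[i], []).append(i)
    keys = sorted(distinct)
    uf = _UnionFind(len(keys))
    k = params.umi_max_edits
    if k > 0:
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                if abs(len(keys[a]) - len(keys[b])) > k:
                    continue
                if edlib.align(keys[a], keys[b], k=k)["editDistance"] != -1:
                    uf.union(a, b)

    groups: dict[int, list[int]] = {}
    for ki, key in enumerate(keys):
        groups.setdefault(uf.find(ki), []).extend(distinct[key])

    merged = []
    for root in sorted(groups):
        members = [ordered[i] for i in sorted(groups[root])]
        merged.append(_make_merged(members, stage, cell_of))
    for i, u in enumerate(umis):
        if u is None:
            merged.append(_make_merged([ordered[i]], stage, cell_of))
    return merged


def _make_merged(members: list[ReadRecord], stage: str, cell_of) -> MergedRead:
    rep = _representative(members)
    cells = sorted({cell_of(m) for m in members}) if cell_of else []
    return MergedRead(rep, [m.read_id for m in members], stage, cells)


def sequential_merge(
    per_cell_reads: dict[str, list[ReadRecord]],
    chemistry: ChemistryConfig,
    params: UmiMergeParams | None = None,
    tenx_umi_of: dict[str, str] | None = None,
) -> tuple[list[MergedRead], dict]:
    """Two-stage merge within each cell-assignment group: first by
    splint-UMI, then the stage-1 representatives by 10X-UMI.

    ``tenx_umi_of`` maps read_id → observed 10X-UMI (from the
    demultiplexing report); reads absent from it pass stage 2 unmerged.
    The report gives per-stage read counts and merged fractions in the
    style of a run-statistics table.
    """
    params = params or UmiMergeParams()
    tenx_umi_of = tenx_umi_of or {}
    final: list[MergedRead] = []
    n_input = sum(len(v) for v in per_cell_reads.values())
    n_stage1 = 0
    for cell in sorted(per_cell_reads):
        reads = per_cell_reads[cell]
        stage1 = merge_by_umi(
            reads,
            lambda r: extract_splint_umi(r, chemistry, params),
            params,
            stage="splint",
            cell_of=lambda r, c=cell: c,
        )
        n_stage1 += len(stage1)
        reps = {g.representative.read_id: g for g in stage1}
        stage2 = merge_by_umi(
            [g.representative for g in stage1],
            lambda r: tenx_umi_of.get(r.read_id),
            params,
            stage="tenx",
        )
        for g2 in stage2:
            member_ids = sorted(
                mid for rep_id in g2.member_ids for mid in reps[rep_id].member_ids
            )
            final.append(MergedRead(g2.representative, member_ids, "tenx", [cell]))
    report = {
        "input_reads": n_input,
        "after_splint_merge": n_stage1,
        "after_tenx_merge": len(final),
        "splint_merged_fraction": 1 - n_stage1 / n_input if n_input else 0.0,
        "tenx_merged_fraction": 1 - len(final) / n_stage1 if n_stage1 else 0.0,
    }
    return final, report


def discard_cross_cell_merges(
    merged: list[MergedRead],
    cell_of: dict[str, str] | None = None,
) -> tuple[list[MergedRead], list[MergedRead]]:
    """Remove any merged read whose members were assigned to >1 cell."""
    kept, discarded = [], []
    for g in merged:
        cells = set(g.cell_assignments)
        if cell_of is not None:
            cells |= {cell_of[mid] for mid in g.member_ids if mid in cell_of}
        (discarded if len(cells) > 1 else kept).append(g)
    return kept, discarded


def illumina_style_dedup(
    records: Iterable[tuple[str, str]],
    params: IlluminaDedupParams | None = None,
) -> pd.DataFrame:
    """Exact-match dedup of (cell barcode, UMI) pairs, keeping molecules
    with raw read coverage strictly above ``min_raw_coverage``."""
    params = params or IlluminaDedupParams()
    df = pd.DataFrame(list(records), columns=["barcode", "umi"])
    if df.empty:
        return pd.DataFrame(columns=["barcode", "umi", "coverage"])
    table = df.groupby(["barcode", "umi"], as_index=False).size()
    table = table.rename(columns={"size": "coverage"})
    table = table[table["coverage"] > params.min_raw_coverage].reset_index(drop=True)
    return table


def compare_umi_sets(
    cell_umis_a: dict[str, set[str]],
    cell_umis_b: dict[str, set[str]],
) -> tuple[pd.DataFrame, float]:
    """Per-cell UMI set intersection between two platforms plus the
    aggregate shared fraction (shared / |A| over all cells)."""
    rows = []
    for cell in sorted(set(cell_umis_a) | set(cell_umis_b)):
        a = cell_umis_a.get(cell, set())
        b = cell_umis_b.get(cell, set())
        rows.append((cell, len(a & b), len(a - b), len(b - a)))
    df = pd.DataFrame(rows, columns=["cell", "shared", "a_only", "b_only"])
    total_a = int(df["shared"].sum() + df["a_only"].sum())
    shared_fraction = df["shared"].sum() / total_a if total_a else 0.0
    return df, float(shared_fraction)
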