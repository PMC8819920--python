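"""Cell-barcode whitelist construction and read demultiplexing.

A whitelist of the most frequent barcodes is built by exact counting; each
read's observed barcode is then compared to the whitelist by Levenshtein
distance and assigned to the nearest entry iff

    L1 < 3   and   L1 < L2 - 1

where L1 and L2 are the distances to the most and second-most similar
whitelist entries.  A tie at L1 between two entries makes L2 = L1, so the
second rule fails and the read is ambiguous.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import edlib
import pandas as pd

from .io import ReadRecord, revcomp
from .simulate import ChemistryConfig

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
TOO_DISTANT = "too_distant"
NO_ADAPTER = "no_adapter"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b)["editDistance"]


@dataclass(frozen=True)
class WhitelistParams:
    """Whitelist construction settings; the default cell count matches a
    typical droplet run loading ~1500 cells."""

    expected_cells: int = 1500
    adapter_max_edits: int | None = None  # None → 20% of adapter length

    def __post_init__(self) -> None:
        if self.expected_cells < 1:
            raise ValueError("expected_cells must be ≥ 1")


@dataclass
class BarcodeAssignment:
    read_id: str
    observed_barcode: str | None
    assigned_barcode: str | None
    L1: float
    L2: float
    status: str
    orientation: str | None = None
    observed_umi: str | None = None


@dataclass(frozen=True)
class Extraction:
    status: str  # "ok" | "no_adapter" | "ambiguous_adapter"
    barcode: str | None = None
    umi: str | None = None
    orientation: str | None = None


def _adapter_budget(chemistry: ChemistryConfig, max_edits: int | None) -> int:
    if max_edits is not None:
        return max_edits
    return max(1, int(0.2 * len(chemistry.adapter_seq)))


def locate_and_extract_barcode(
    read: ReadRecord | str,
    chemistry: ChemistryConfig,
    adapter_max_edits: int | None = None,
) -> Extraction:
    """Find the priming-site adapter on either strand and slice out the
    barcode/UMI immediately 3' of it, reported in whitelist orientation."""
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if not seq:
        return Extraction(NO_ADAPTER)
    budget = _adapter_budget(chemistry, adapter_max_edits)
    hits = []
    for orientation, oriented in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(chemistry.adapter_seq, oriented, mode="HW", task="locations", k=budget)
        if res["editDistance"] != -1:
            hits.append((res["editDistance"], orientation, oriented, res["locations"][0]))
    if not hits:
        return Extraction(NO_ADAPTER)
    if len(hits) == 2 and hits[0][0] == hits[1][0]:
        return Extraction("ambiguous_adapter")
    dist, orientation, oriented, (start, end) = min(hits, key=lambda h: h[0])
    bc_start = end + 1
    umi_end = bc_start + chemistry.barcode_len + chemistry.umi_len
    if umi_end > len(oriented):
        return Extraction(NO_ADAPTER)
    barcode = oriented[bc_start : bc_start + chemistry.barcode_len]
    umi = oriented[bc_start + chemistry.barcode_len : umi_end]
    return Extraction("ok", barcode, umi, orientation)


def build_whitelist(
    reads: list[ReadRecord],
    chemistry: ChemistryConfig,
    params: WhitelistParams,
) -> tuple[list[str], pd.DataFrame, bool]:
    """Count exact observed barcodes and keep the ``expected_cells`` most
    frequent (ties broken lexicographically).

    Returns (whitelist, full count table, truncated_warning) where the
    warning flags that fewer distinct barcodes existed than requested.
    """
    counts: Counter[str] = Counter()
    for read in reads:
        ext = locate_and_extract_barcode(read, chemistry, params.adapter_max_edits)
        if ext.status == "ok":
            counts[ext.barcode] += 1
    if not counts:
        raise ValueError("no read with a locatable adapter")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(ranked, columns=["barcode", "count"])
    warning = len(ranked) < params.expected_cells
    whitelist = [bc for bc, _ in ranked[: params.expected_cells]]
    return whitelist, table, warning


def assign_barcode(observed: str, whitelist: list[str]) -> BarcodeAssignment:
    """Apply the two-rule Levenshtein assignment against the whitelist."""
    if not whitelist:
        raise ValueError("whitelist is empty")
    best_bc, l1, l2 = None, math.inf, math.inf
    for bc in whitelist:
        d = levenshtein(observed, bc)
        if d < l1:
            best_bc, l2, l1 = bc, l1, d
        elif d < l2:
            l2 = d
    if l1 < 3 and l1 < l2 - 1:
        return BarcodeAssignment("", observed, best_bc, l1, l2, ASSIGNED)
    status = TOO_DISTANT if l1 >= 3 else AMBIGUOUS
    return BarcodeAssignment("", observed, None, l1, l2, status)


def demultiplex(
    reads: list[ReadRecord],
    whitelist: list[str],
    chemistry: ChemistryConfig,
    adapter_max_edits: int | None = None,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame, dict]:
    """Assign every read to exactly one cell or the unassigned pool.

    Returns (per-cell read sets, per-read assignment report, summary).
    The report carries the observed UMI so downstream molecule merging can
    reuse it without re-locating the adapter.
    """
    cells: dict[str, list[ReadRecord]] = {}
    rows = []
    status_counts: Counter[str] = Counter()
    cache: dict[str, BarcodeAssignment] = {}
    for read in reads:
        ext = locate_and_extract_barcode(read, chemistry, adapter_max_edits)
        if ext.status != "ok":
            status_counts[NO_ADAPTER] += 1
            rows.append((read.read_id, None, None, math.nan, math.nan, NO_ADAPTER, None, None))
            continue
        hit = cache.get(ext.barcode)
        if hit is None:
            hit = assign_barcode(ext.barcode, whitelist)
            cache[ext.barcode] = hit
        status_counts[hit.status] += 1
        if hit.status == ASSIGNED:
            cells.setdefault(hit.assigned_barcode, []).append(read)
        rows.append(
            (
                read.read_id,
                ext.barcode,
                hit.assigned_barcode,
                hit.L1,
                hit.L2,
                hit.status,
                ext.orientation,
                ext.umi,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=["read_id", "observed", "assigned", "L1", "L2", "status", "orientation", "umi"],
    )
    total = len(reads)
    summary = {
        "total": total,
        **{s: status_counts.get(s, 0) for s in (ASSIGNED, AMBIGUOUS, TOO_DISTANT, NO_ADAPTER)},
        "assigned_fraction": status_counts.get(ASSIGNED, 0) / total if total else 0.0,
    }
    return cells, report, summary
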