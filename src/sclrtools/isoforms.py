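"""Isoform-model merging, diversity statistics and differential usage.

Transcript models enter as 21-column PSL (0-based half-open coordinates).
Two models merge when they use all the same splice sites — a site a single
base pair off counts as the same site if it is much less abundant than its
partner — and their start and end sites lie within a small genomic window
(default 10 nt).  Grouping is single-linkage, so members of one group may
individually differ by more than the window if connected through a third
isoform.  Differential isoform usage between cell types is tested per gene
with a Pearson chi-square contingency test over isoform × cell-type
counts, followed by multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class IsoformModel:
    """A transcript model: exon structure on a chromosome strand.

    ``splice_chain`` is the ordered tuple of intron (donor, acceptor)
    genomic coordinates; identical chains define the same splicing
    structure.  ``support`` is a read count (or cell count after merging).
    """

    isoform_id: str
    source: str
    chrom: str
    strand: str
    start: int
    end: int
    splice_chain: tuple[tuple[int, int], ...]
    support: int = 1
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.splice_chain = tuple(tuple(x) for x in self.splice_chain)
        flat = [c for pair in self.splice_chain for c in pair]
        if any(b <= a for a, b in zip(flat, flat[1:])):
            raise ValueError(f"{self.isoform_id}: splice chain not strictly increasing")
        if flat and (flat[0] <= self.start or flat[-1] >= self.end):
            raise ValueError(f"{self.isoform_id}: splice chain outside start/end")
        if self.support < 1:
            raise ValueError(f"{self.isoform_id}: support must be ≥ 1")

    @property
    def exon_blocks(self) -> list[tuple[int, int]]:
        bounds = [self.start] + [c for pair in self.splice_chain for c in pair] + [self.end]
        return [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]


@dataclass(frozen=True)
class MergeParams:
    """Merging tolerances: start/end sites similar within ``end_window``
    nt; splice sites 1 bp apart equivalent when the minority site's
    support times ``abundance_ratio`` does not exceed the majority's."""

    end_window: int = 10
    splice_slop: int = 1
    abundance_ratio: float = 5.0

    def __post_init__(self) -> None:
        if self.end_window < 0:
            raise ValueError("end_window must be ≥ 0")
        if self.splice_slop not in (0, 1):
            raise ValueError("splice_slop must be 0 or 1")


@dataclass(frozen=True)
class DiffUsageParams:
    alpha: float = 0.01
    min_cell_types: int = 2
    correction: str = "fdr_bh"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class GeneUsageResult:
    gene_id: str
    table: pd.DataFrame  # isoforms × cell types
    chi2: float
    df: int
    p_value: float
    corrected_p: float = np.nan
    significant: bool = False


class DegenerateTableError(ValueError):
    """Contingency table reduces to a single row or column."""


# ---------------------------------------------------------------------------
# PSL reading / writing
# ---------------------------------------------------------------------------

def _chain_from_blocks(t_starts: list[int], sizes: list[int]) -> tuple[tuple[int, int], ...]:
    return tuple(
        (t_starts[i] + sizes[i], t_starts[i + 1]) for i in range(len(t_starts) - 1)
    )


def read_psl(path: str | Path, source: str | None = None) -> list[IsoformModel]:
    """Parse a 21-column PSL file into isoform models.

    ``source`` labels the originating cell or pool; default: file stem.
    """
    path = Path(path)
    src = source if source is not None else path.stem
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            fields = line.split("\t")
            if len(fields) != 21:
                raise ValueError(f"{path}:{lineno}: expected 21 PSL columns, got {len(fields)}")
            try:
                strand = fields[8]
                q_name = fields[9]
                t_name = fields[13]
                t_start, t_end = int(fields[15]), int(fields[16])
                block_count = int(fields[17])
                sizes = [int(x) for x in fields[18].rstrip(",").split(",")]
                t_starts = [int(x) for x in fields[20].rstrip(",").split(",")]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PSL line ({exc})") from None
            if len(sizes) != block_count or len(t_starts) != block_count:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            if t_starts[0] != t_start or t_starts[-1] + sizes[-1] != t_end:
                raise ValueError(f"{path}:{lineno}: blocks inconsistent with tStart/tEnd")
            models.append(
                IsoformModel(
                    isoform_id=q_name,
                    source=src,
                    chrom=t_name,
                    strand=strand,
                    start=t_start,
                    end=t_end,
                    splice_chain=_chain_from_blocks(t_starts, sizes),
                )
            )
    return models


def write_psl(models: list[IsoformModel], path: str | Path) -> None:
    """Write models as canonical 21-column PSL (coordinates bit-exact)."""
    with open(path, "w") as fh:
        for m in models:
            blocks = m.exon_blocks
            sizes = [e - s for s, e in blocks]
            q_size = sum(sizes)
            line = [
                str(q_size), "0", "0", "0", "0", "0", "0", "0",
                m.strand,
                m.isoform_id,
                str(q_size), "0", str(q_size),
                m.chrom,
                str(m.end),
                str(m.start), str(m.end),
                str(len(blocks)),
                ",".join(str(s) for s in sizes) + ",",
                ",".join(str(s) for s in np.cumsum([0] + sizes[:-1])) + ",",
                ",".join(str(s) for s, _ in blocks) + ",",
            ]
            fh.write("\t".join(line) + "\n")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def collect_site_support(models: list[IsoformModel]) -> dict[tuple[str, str, int], int]:
    """Total support observed at each splice-site coordinate."""
    support: dict[tuple[str, str, int], int] = {}
    for m in models:
        for pair in m.splice_chain:
            for pos in pair:
                key = (m.chrom, m.strand, pos)
                support[key] = support.get(key, 0) + m.support
    return support


def splice_sites_equivalent(
    chain_a: tuple[tuple[int, int], ...],
    chain_b: tuple[tuple[int, int], ...],
    site_support: dict[int, int],
    params: MergeParams | None = None,
) -> bool:
    """True iff the chains use all the same splice sites.

    Corresponding sites must be identical, or exactly 1 bp apart with the
    minority site much less abundant (support ratio ≥ ``abundance_ratio``)
    than the majority site.  ``site_support`` maps site coordinate →
    support within one chromosome/strand context.
    """
    params = params or MergeParams()
    if len(chain_a) != len(chain_b):
        return False
    flat_a = [c for pair in chain_a for c in pair]
    flat_b = [c for pair in chain_b for c in pair]
    for sa, sb in zip(flat_a, flat_b):
        if sa == sb:
            continue
        if params.splice_slop == 0 or abs(sa - sb) != 1:
            return False
        sup_a = site_support.get(sa, 0)
        sup_b = site_support.get(sb, 0)
        minority, majority = min(sup_a, sup_b), max(sup_a, sup_b)
        if minority * params.abundance_ratio > majority:
            return False
    return True


@dataclass
class IsoformGroup:
    representative: IsoformModel
    members: list[IsoformModel]
    cell_count: int
    total_support: int

    @property
    def gene_id(self) -> str | None:
        return self.representative.gene_id


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


def _linkable(a: IsoformModel, b: IsoformModel, site_support, params: MergeParams) -> bool:
    return (
        abs(a.start - b.start) <= params.end_window
        and abs(a.end - b.end) <= params.end_window
        and splice_sites_equivalent(a.splice_chain, b.splice_chain, site_support, params)
    )


def merge_isoforms(
    models: list[IsoformModel],
    params: MergeParams | None = None,
) -> list[IsoformGroup]:
    """Single-linkage merge of isoform models across cells.

    Two models link iff their splice chains are equivalent and both the
    start and end sites lie within ``end_window`` nt; linkage is iterative,
    so chained members may individually be further apart.  The result is a
    partition of the input, independent of input order.
    """
    params = params or MergeParams()
    ordered = sorted(models, key=lambda m: (m.chrom, m.strand, m.start, m.end, m.isoform_id))
    all_support = collect_site_support(ordered)

    uf = _UnionFind(len(ordered))
    by_context: dict[tuple[str, str], list[int]] = {}
    for i, m in enumerate(ordered):
        by_context.setdefault((m.chrom, m.strand), []).append(i)
    for (chrom, strand), idxs in by_context.items():
        ctx_support = {
            pos: sup for (c, s, pos), sup in all_support.items() if c == chrom and s == strand
        }
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1 :]:
                # sorted by start: stop once starts drift past the window
                if ordered[j].start - ordered[i].start > params.end_window:
                    break
                if _linkable(ordered[i], ordered[j], ctx_support, params):
                    uf.union(i, j)

    groups: dict[int, list[IsoformModel]] = {}
    for i, m in enumerate(ordered):
        groups.setdefault(uf.find(i), []).append(m)
    out = []
    for root in sorted(groups):
        members = groups[root]
        rep = min(members, key=lambda m: (-m.support, -(m.end - m.start), m.isoform_id))
        out.append(
            IsoformGroup(
                representative=rep,
                members=members,
                cell_count=len({m.source for m in members}),
                total_support=sum(m.support for m in members),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Diversity and differential usage
# ---------------------------------------------------------------------------

def diversity_stats(
    groups: list[IsoformGroup],
    bulk_isoforms_per_gene: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene isoform-diversity table.

    ``cells_expressing`` counts distinct source cells over all models of a
    gene; ``unique_merged_isoforms`` counts merged groups; the log10 ratio
    to the bulk isoform count is NaN (flagged) for genes absent from bulk.
    """
    bulk = bulk_isoforms_per_gene or {}
    per_gene: dict[str, dict] = {}
    for g in groups:
        gene = g.gene_id or "NA"
        entry = per_gene.setdefault(gene, {"cells": set(), "groups": 0})
        entry["cells"].update(m.source for m in g.members)
        entry["groups"] += 1
    rows = []
    for gene in sorted(per_gene):
        entry = per_gene[gene]
        n_bulk = bulk.get(gene)
        defined = n_bulk is not None and n_bulk > 0 and entry["groups"] > 0
        ratio = np.log10(entry["groups"] / n_bulk) if defined else np.nan
        rows.append((gene, len(entry["cells"]), entry["groups"], n_bulk, ratio, not defined))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "cells_expressing",
            "unique_merged_isoforms",
            "bulk_isoforms",
            "log10_ratio",
            "ratio_undefined",
        ],
    )


def quantify_by_group(
    supports: pd.DataFrame,
    cell_types: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Sum per-cell isoform supports into a gene × isoform × cell-type table.

    ``supports`` needs columns (gene_id, isoform_id, cell_id, support);
    ``cell_types`` needs (cell_id, cell_type).  Cells missing from the
    mapping are dropped; their number is returned alongside the table,
    which is indexed by (gene_id, isoform_id) with one column per cell type.
    """
    required = {"gene_id", "isoform_id", "cell_id", "support"}
    if not required.issubset(supports.columns):
        raise ValueError(f"supports table needs columns {sorted(required)}")
    mapping = dict(zip(cell_types["cell_id"], cell_types["cell_type"]))
    known = supports["cell_id"].isin(mapping)
    dropped = int((~known).sum())
    kept = supports[known].copy()
    kept["cell_type"] = kept["cell_id"].map(mapping)
    tensor = (
        kept.pivot_table(
            index=["gene_id", "isoform_id"],
            columns="cell_type",
            values="support",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index()
    )
    tensor.columns.name = None
    return tensor, dropped


def chi2_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts matrix.

    All-zero rows/columns are dropped first; a table left with fewer than
    two rows or columns raises :class:`DegenerateTableError`.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError("not_testable: table has <2 rows or columns")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


def diff_isoform_usage(
    tensor: pd.DataFrame,
    params: DiffUsageParams | None = None,
) -> list[GeneUsageResult]:
    """Per-gene differential isoform usage across cell types.

    Genes expressed in fewer than ``min_cell_types`` cell types, or with
    fewer than two expressed isoforms, are skipped.  P-values are
    corrected across all tested genes; a gene is significant when its
    corrected p is below ``alpha``.  Both raw and corrected p are reported.
    """
    params = params or DiffUsageParams()
    results: list[GeneUsageResult] = []
    for gene in tensor.index.get_level_values("gene_id").unique():
        sub = tensor.loc[gene]
        sub = sub.loc[:, sub.sum(axis=0) > 0]
        if sub.shape[1] < params.min_cell_types:
            continue
        sub = sub.loc[sub.sum(axis=1) > 0]
        if sub.shape[0] < 2:
            continue
        try:
            chi2, dof, p = chi2_contingency(sub.to_numpy())
        except DegenerateTableError:
            continue
        results.append(GeneUsageResult(gene, sub, chi2, dof, p))
    if results:
        _, corrected, _, _ = multipletests(
            [r.p_value for r in results], method=params.correction
        )
        for r, cp in zip(results, corrected):
            r.corrected_p = float(cp)
            r.significant = bool(cp < params.alpha)
    return results


def usage_results_frame(results: list[GeneUsageResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.chi2, r.df, r.p_value, r.corrected_p, r.significant)
            for r in results
        ],
        columns=["gene_id", "chi2", "df", "p", "corrected_p", "significant"],
    )
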