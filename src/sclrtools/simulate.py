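"""Synthetic read, isoform and immune-receptor simulators with ground truth.

The generator reproduces the structure the processing stages rely on: each
read is a full-length cDNA consensus laid out as

    [adapter][16nt cell barcode][10nt UMI][poly(T)][transcript, revcomp][splint backbone]

where the splint backbone carries its own molecular identifier (the
circularization-event UMI) between two fixed anchor sequences.  Reads are
emitted on a random strand, duplicated at two independent levels — extra
reads of the same RNA molecule (shared 10X-UMI) and extra reads of the same
circularization event (shared splint-UMI) — and corrupted last with
independent per-base substitution/insertion/deletion errors.  Every read is
recorded in a ground-truth table linking it to its cell, molecule,
circularization event, transcript and (for immune-receptor transcripts)
gene segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .air import SegmentReference, IGH_ISOTYPES
from .io import ReadRecord, revcomp
from .isoforms import IsoformModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

TRUTH_COLUMNS = [
    "read_id",
    "cell_barcode",
    "molecule_id",
    "splint_event_id",
    "transcript_id",
    "locus",
    "v_id",
    "d_id",
    "j_id",
    "c_id",
    "strand",
]


@dataclass(frozen=True)
class ChemistryConfig:
    """Read-layout constants of the droplet 3' chemistry.

    ``adapter_seq`` is the constant PCR priming site directly 5' of the cell
    barcode; barcode and UMI sit adjacent to each other and to the oligo(dT)
    stretch.  The splint-UMI is anchored between two constant flanks at the
    read end (the backbone of the circularization splint).
    """

    adapter_seq: str = "CTACACGACGCTCTTCCGATCT"
    barcode_len: int = 16
    umi_len: int = 10
    polya_len: int = 20
    splint_umi_len: int = 10
    splint_umi_flanks: tuple[str, str] = ("CTGACTGGAGTTCAGACG", "ATCTCGTATGCCGTCTTC")

    def __post_init__(self) -> None:
        if self.barcode_len <= 0 or self.umi_len <= 0:
            raise ValueError("barcode_len and umi_len must be positive")
        if not self.adapter_seq:
            raise ValueError("adapter_seq must be non-empty")
        if self.splint_umi_len > 0 and not all(self.splint_umi_flanks):
            raise ValueError("splint flanks must be non-empty when splint_umi_len > 0")


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base error process (substitution / insertion / deletion)."""

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(not (0 <= r < 1) for r in rates):
            raise ValueError("error rates must be in [0, 1)")
        if sum(rates) >= 1:
            raise ValueError("total error rate must be < 1")

    @property
    def is_zero(self) -> bool:
        return self.sub_rate == self.ins_rate == self.del_rate == 0


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def corrupt_sequence(seq: str, model: ErrorModel, rng: np.random.Generator | None = None) -> str:
    """Apply the error model to one sequence.

    Each base is independently deleted (``del_rate``) or substituted
    (``sub_rate``, always to a different base); independently, a random base
    is inserted before each position with probability ``ins_rate``.
    """
    if not seq:
        raise ValueError("cannot corrupt an empty sequence")
    if model.is_zero:
        return seq
    if rng is None:
        rng = np.random.default_rng(model.seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    r = rng.random(n)
    del_mask = r < model.del_rate
    sub_mask = (~del_mask) & (r < model.del_rate + model.sub_rate)
    if sub_mask.any():
        idx = _BASE_INDEX[arr[sub_mask]].astype(np.int64)
        shift = rng.integers(1, 4, idx.size)
        new_idx = np.where(idx >= 0, (idx + shift) % 4, rng.integers(0, 4, idx.size))
        arr[sub_mask] = _BASES[new_idx]
    ins_mask = rng.random(n) < model.ins_rate
    ins_pos = np.flatnonzero(ins_mask)
    if ins_pos.size:
        ins_bases = _BASES[rng.integers(0, 4, ins_pos.size)]
        arr = np.insert(arr, ins_pos, ins_bases)
        keep = np.insert(~del_mask, ins_pos, True)
    else:
        keep = ~del_mask
    out = arr[keep]
    if out.size == 0:
        # pathological draw on a very short sequence; keep one random base
        return random_sequence(1, rng)
    return out.tobytes().decode()


def make_barcode_whitelist(
    n: int,
    length: int = 16,
    min_dist: int = 5,
    seed: int = 0,
    max_attempts: int | None = None,
) -> list[str]:
    """Draw ``n`` distinct barcodes with pairwise Levenshtein distance ≥ ``min_dist``."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if 4 ** length < 4 * n:
        raise ValueError("barcode space too small for the requested whitelist")
    rng = np.random.default_rng(seed)
    limit = max_attempts if max_attempts is not None else max(2000, 200 * n)
    chosen: list[str] = []
    k = min_dist - 1
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > limit:
            raise RuntimeError(
                f"could not place {n} barcodes at min_dist={min_dist} in {limit} attempts"
            )
        cand = random_sequence(length, rng)
        if min_dist <= 1:
            if cand not in chosen:
                chosen.append(cand)
            continue
        if all(edlib.align(cand, b, k=k)["editDistance"] == -1 for b in chosen):
            chosen.append(cand)
    return chosen


def make_transcripts(n: int, length: int = 500, seed: int = 0, prefix: str = "tx") -> list[tuple[str, str]]:
    """Random transcript bodies for read simulation."""
    rng = np.random.default_rng(seed)
    return [(f"{prefix}{i:04d}", random_sequence(length, rng)) for i in range(n)]


def _edit1_neighborhood(u: str) -> set[str]:
    """All strings within Levenshtein distance 1 of ``u``."""
    out = {u}
    for i in range(len(u) + 1):
        for b in "ACGT":
            out.add(u[:i] + b + u[i:])  # insertions
        if i < len(u):
            out.add(u[:i] + u[i + 1 :])  # deletion
            for b in "ACGT":
                out.add(u[:i] + b + u[i + 1 :])  # substitution
    return out


def _draw_umi(
    length: int,
    rng: np.random.Generator,
    taken: set[str],
    cell_forbidden: set[str],
) -> str:
    """Globally unique UMI, kept at edit distance ≥2 from the cell's other
    UMIs so that merging at the default radius recovers molecules exactly;
    UMI collisions are exercised by dedicated fixtures instead.

    ``cell_forbidden`` accumulates the distance-1 neighborhoods of the
    cell's accepted UMIs, making the separation test a set lookup.
    """
    while True:
        u = random_sequence(length, rng)
        if u in taken or u in cell_forbidden:
            continue
        taken.add(u)
        cell_forbidden |= _edit1_neighborhood(u)
        return u


def simulate_reads(
    whitelist: list[str],
    transcripts: list[tuple[str, str]],
    cells: int | None = None,
    molecules_per_cell: int = 20,
    splint_dup_rate: float = 0.0,
    tenx_dup_rate: float = 0.0,
    chemistry: ChemistryConfig | None = None,
    errors: ErrorModel | None = None,
    transcripts_by_cell: dict[str, list[str]] | None = None,
    molecules_per_transcript: int | None = None,
    transcript_annotations: dict[str, dict] | None = None,
    seed: int | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a demultiplexable read set with full ground truth.

    Molecules are assigned unique 10X-UMIs; with probability
    ``tenx_dup_rate`` a molecule emits one extra read (a PCR duplicate, new
    circularization event) and with probability ``splint_dup_rate`` each
    read emits one extra copy sharing its splint event.  When
    ``transcripts_by_cell`` and ``molecules_per_transcript`` are given,
    every listed transcript of a cell gets exactly that many molecules
    (used for receptor simulations); otherwise each cell draws
    ``molecules_per_cell`` molecules from the shared transcript pool.
    """
    if not whitelist:
        raise ValueError("whitelist is empty")
    if not transcripts:
        raise ValueError("transcript set is empty")
    chem = chemistry or ChemistryConfig()
    err = errors or ErrorModel()
    rng = np.random.default_rng(err.seed if seed is None else seed)
    tx_by_id = dict(transcripts)
    use_cells = whitelist if cells is None else whitelist[:cells]

    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    umi_taken: set[str] = set()
    splint_taken: set[str] = set()
    mol_counter = 0
    event_counter = 0
    read_counter = 0

    for barcode in use_cells:
        cell_umis: set[str] = set()
        cell_splints: set[str] = set()
        if transcripts_by_cell is not None and molecules_per_transcript is not None:
            mol_tx = [
                tid
                for tid in transcripts_by_cell.get(barcode, [])
                for _ in range(molecules_per_transcript)
            ]
        elif transcripts_by_cell is not None:
            pool = transcripts_by_cell.get(barcode, [])
            mol_tx = [pool[i] for i in rng.integers(0, len(pool), molecules_per_cell)] if pool else []
        else:
            mol_tx = [transcripts[i][0] for i in rng.integers(0, len(transcripts), molecules_per_cell)]
        for tid in mol_tx:
            mol_id = f"mol{mol_counter:07d}"
            mol_counter += 1
            umi = _draw_umi(chem.umi_len, rng, umi_taken, cell_umis)
            n_events = 1 + (1 if rng.random() < tenx_dup_rate else 0)
            for _ in range(n_events):
                event_id = f"ev{event_counter:07d}"
                event_counter += 1
                splint_umi = (
                    _draw_umi(chem.splint_umi_len, rng, splint_taken, cell_splints)
                    if chem.splint_umi_len > 0
                    else ""
                )
                n_copies = 1 + (1 if rng.random() < splint_dup_rate else 0)
                for _ in range(n_copies):
                    core = (
                        chem.adapter_seq
                        + barcode
                        + umi
                        + "T" * chem.polya_len
                        + revcomp(tx_by_id[tid])
                    )
                    if chem.splint_umi_len > 0:
                        core += chem.splint_umi_flanks[0] + splint_umi + chem.splint_umi_flanks[1]
                    strand = "+" if rng.random() < 0.5 else "-"
                    seq = core if strand == "+" else revcomp(core)
                    seq = corrupt_sequence(seq, err, rng) if not err.is_zero else seq
                    read_id = f"read{read_counter:07d}"
                    read_counter += 1
                    reads.append(ReadRecord(read_id, seq))
                    ann = (transcript_annotations or {}).get(tid, {})
                    rows.append(
                        (
                            read_id,
                            barcode,
                            mol_id,
                            event_id,
                            tid,
                            ann.get("locus"),
                            ann.get("v_id"),
                            ann.get("d_id"),
                            ann.get("j_id"),
                            ann.get("c_id"),
                            strand,
                        )
                    )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# Immune-receptor simulation
# ---------------------------------------------------------------------------

_LOCUS_CLASSES = {
    "IGH": ("V", "D", "J", "C"),
    "IGK": ("V", "J", "C"),
    "IGL": ("V", "J", "C"),
    "TRA": ("V", "J", "C"),
    "TRB": ("V", "D", "J", "C"),
}


def make_segment_references(
    seed: int = 0,
    n_v: int = 8,
    n_d: int = 4,
    n_j: int = 4,
    v_len: int = 300,
    d_len: int = 20,
    j_len: int = 50,
    c_len: int = 350,
    loci: tuple[str, ...] = ("IGH", "IGK", "IGL", "TRA", "TRB"),
) -> dict[str, dict[str, list[SegmentReference]]]:
    """Synthetic IMGT-style V/(D)/J/C references for each receptor locus.

    Sequences are random and therefore mutually distinguishable; IGH gets
    one constant region per isotype.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, dict[str, list[SegmentReference]]] = {}
    for locus in loci:
        refs[locus] = {}
        classes = _LOCUS_CLASSES[locus]
        refs[locus]["V"] = [
            SegmentReference("V", locus, f"{locus}V{i+1}", random_sequence(v_len, rng))
            for i in range(n_v)
        ]
        if "D" in classes:
            refs[locus]["D"] = [
                SegmentReference("D", locus, f"{locus}D{i+1}", random_sequence(d_len, rng))
                for i in range(n_d)
            ]
        refs[locus]["J"] = [
            SegmentReference("J", locus, f"{locus}J{i+1}", random_sequence(j_len, rng))
            for i in range(n_j)
        ]
        if locus == "IGH":
            refs[locus]["C"] = [
                SegmentReference("C", locus, iso, random_sequence(c_len, rng), isotype=iso)
                for iso in IGH_ISOTYPES
            ]
        else:
            iso = f"{locus}C"
            refs[locus]["C"] = [
                SegmentReference("C", locus, iso, random_sequence(c_len, rng), isotype=iso)
            ]
    return refs


def simulate_air_repertoire(
    references: dict[str, dict[str, list[SegmentReference]]],
    n_bcells: int,
    n_tcells: int,
    seed: int = 0,
    junction_max: int = 8,
    kappa_fraction: float = 0.6,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Recombine V(–D)–J–C transcripts for a mixed B/T repertoire.

    Each B cell expresses one IGH transcript (random isotype) and one light
    chain (IGK or IGL); each T cell expresses one TRA and one TRB.  Segment
    junctions receive 0–``junction_max`` random inserted nucleotides.
    Returns the transcripts and a truth table of segment choices.
    """
    for locus, classes in _LOCUS_CLASSES.items():
        if locus not in references:
            continue
        for cls in classes:
            if not references[locus].get(cls):
                raise ValueError(f"locus {locus} is missing {cls} references")
    rng = np.random.default_rng(seed)
    transcripts: list[tuple[str, str]] = []
    rows = []

    def _recombine(cell_id: str, locus: str) -> None:
        refs = references[locus]
        v = refs["V"][rng.integers(0, len(refs["V"]))]
        d = refs["D"][rng.integers(0, len(refs["D"]))] if "D" in refs else None
        j = refs["J"][rng.integers(0, len(refs["J"]))]
        c = refs["C"][rng.integers(0, len(refs["C"]))]
        parts = [v.sequence, random_sequence(int(rng.integers(0, junction_max + 1)), rng)]
        if d is not None:
            parts += [d.sequence, random_sequence(int(rng.integers(0, junction_max + 1)), rng)]
        parts += [j.sequence, c.sequence]
        tid = f"{cell_id}_{locus}"
        transcripts.append((tid, "".join(parts)))
        rows.append(
            {
                "cell_id": cell_id,
                "locus": locus,
                "transcript_id": tid,
                "v_id": v.segment_id,
                "d_id": d.segment_id if d is not None else None,
                "j_id": j.segment_id,
                "c_id": c.segment_id,
            }
        )

    for i in range(n_bcells):
        cell = f"B{i:03d}"
        _recombine(cell, "IGH")
        _recombine(cell, "IGK" if rng.random() < kappa_fraction else "IGL")
    for i in range(n_tcells):
        cell = f"T{i:03d}"
        _recombine(cell, "TRA")
        _recombine(cell, "TRB")
    truth = pd.DataFrame(rows)
    return transcripts, truth


def simulate_air_dataset(
    n_bcells: int,
    n_tcells: int,
    reads_per_chain: int = 10,
    chemistry: ChemistryConfig | None = None,
    errors: ErrorModel | None = None,
    seed: int = 0,
    references: dict[str, dict[str, list[SegmentReference]]] | None = None,
):
    """End-to-end receptor simulation: repertoire → barcoded, errored reads.

    Returns ``(reads, truth, references, cell_map)`` where ``cell_map``
    maps simulator cell ids (B000, T000, …) to their assigned barcodes and
    ``truth`` is the per-read table with segment annotations filled in.
    """
    refs = references or make_segment_references(seed=seed)
    transcripts, rep_truth = simulate_air_repertoire(refs, n_bcells, n_tcells, seed=seed)
    n_cells = n_bcells + n_tcells
    whitelist = make_barcode_whitelist(n_cells, min_dist=5, seed=seed + 1)
    cell_ids = sorted(rep_truth["cell_id"].unique())
    cell_map = dict(zip(cell_ids, whitelist))
    tx_by_cell = {
        cell_map[cid]: sorted(rep_truth.loc[rep_truth.cell_id == cid, "transcript_id"])
        for cid in cell_ids
    }
    annotations = {
        row.transcript_id: {
            "locus": row.locus,
            "v_id": row.v_id,
            "d_id": row.d_id,
            "j_id": row.j_id,
            "c_id": row.c_id,
        }
        for row in rep_truth.itertuples()
    }
    reads, truth = simulate_reads(
        whitelist,
        transcripts,
        chemistry=chemistry,
        errors=errors or ErrorModel(),
        transcripts_by_cell=tx_by_cell,
        molecules_per_transcript=reads_per_chain,
        transcript_annotations=annotations,
        seed=seed + 2,
    )
    return reads, truth, refs, cell_map


# ---------------------------------------------------------------------------
# Isoform-population simulation (diversity / differential-usage fixtures)
# ---------------------------------------------------------------------------

def simulate_cell_isoforms(
    gene_id: str,
    n_cells: int,
    n_chains: int,
    seed: int = 0,
    chrom: str = "chr1",
    strand: str = "+",
    gene_start: int = 10_000,
    exon_len: int = 150,
    intron_len: int = 800,
    n_introns: int = 4,
    end_jitter: int = 4,
) -> list[IsoformModel]:
    """Per-cell isoform models for one gene with a controlled diversity level.

    ``n_chains`` distinct splice chains are created by shifting one donor
    site in steps of 20 nt (never mergeable under the 1 bp splice rule);
    each cell expresses one chain with start/end positions jittered within
    ``end_jitter`` nt, so same-chain isoforms merge under the default 10 nt
    end window.  A low-diversity gene is ``n_chains=1``; a maximally
    diverse gene is ``n_chains=n_cells``.
    """
    if not 1 <= n_chains <= max(n_cells, 1):
        raise ValueError("need 1 ≤ n_chains ≤ n_cells")
    rng = np.random.default_rng(seed)
    base_chain = []
    pos = gene_start
    for _ in range(n_introns):
        pos += exon_len
        base_chain.append((pos, pos + intron_len))
        pos += intron_len
    gene_end = pos + exon_len

    # distinct chains: move donor sites down in 20 nt steps, mixed-radix over
    # introns so coordinates stay strictly increasing within each exon
    per_intron = exon_len // 20 - 1
    if n_chains > (per_intron + 1) ** n_introns:
        raise ValueError("too many chains for this gene structure")
    chains = []
    for k in range(n_chains):
        digits, kk = [], k
        for _ in range(n_introns):
            digits.append(kk % (per_intron + 1))
            kk //= per_intron + 1
        chains.append(
            tuple(
                (donor - 20 * digit, acceptor)
                for (donor, acceptor), digit in zip(base_chain, digits)
            )
        )

    models = []
    for c in range(n_cells):
        chain = chains[c % n_chains]
        start = gene_start - int(rng.integers(0, end_jitter + 1))
        end = gene_end + int(rng.integers(0, end_jitter + 1))
        models.append(
            IsoformModel(
                isoform_id=f"{gene_id}_cell{c:04d}_iso0",
                source=f"cell{c:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                splice_chain=chain,
                support=1,
                gene_id=gene_id,
            )
        )
    return models
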