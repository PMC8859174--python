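"""From structured reads to UMI-corrected clonotype counts.

Reads follow the library layout adapter + 10 bp UMI + spacer + insert, where
the insert is the TCR-beta junction.  Processing is: UMI/insert extraction
(adapter and spacer located with at most one mismatch), reference-anchored
CDR3 calling against the generative model's V/J flanks, and directional
UMI collapsing within each clonotype (merge a smaller UMI group into a
larger one when the UMIs are within Hamming distance 1 and
count_large >= 2*count_small - 1 — the standard directional-adjacency error
model).  Rejections are data, not exceptions: every read is either assigned
or tallied under a rejection reason, and totals are conserved.

Only single-end logic is implemented (synthetic reads present the whole
insert in one sequence) and base qualities are ignored; the error model is
positional substitution only.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

from .core import ClonotypeKey, ClonotypeRecord, RepertoireSample
from .vdj import GenerativeModel

# layout of the template-switch oligo: adapter, 10 random bases, riboG spacer
DEFAULT_ADAPTER = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
DEFAULT_SPACER = "ACATGGG"

NO_ADAPTER = "no_adapter"
NO_SPACER = "no_spacer"
TOO_SHORT = "too_short"
NO_V = "no_v"
NO_J = "no_j"
FRAME = "frame"
ASSIGNED = "assigned"

REJECTION_REASONS = (NO_ADAPTER, NO_SPACER, TOO_SHORT, NO_V, NO_J, FRAME)


@dataclass(frozen=True)
class ReadStructure:
    adapter: str = DEFAULT_ADAPTER
    umi_length: int = 10
    spacer: str = DEFAULT_SPACER

    def __post_init__(self) -> None:
        if self.umi_length <= 0:
            raise ValueError("umi_length must be positive")
        if not self.adapter or not self.spacer:
            raise ValueError("adapter and spacer must be non-empty")


@dataclass
class UmiGroup:
    umi: str
    read_count: int
    consensus_insert: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass
class Extraction:
    umi: str | None
    insert: str | None
    rejection: str | None

    @property
    def ok(self) -> bool:
        return self.rejection is None


def _hamming(a: str, b: str, limit: int = 10**9) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def extract_umi(read: str, structure: ReadStructure = ReadStructure()) -> Extraction:
    """Locate adapter (<=1 mismatch), read the UMI, require the spacer.

    Returns an :class:`Extraction` whose ``rejection`` is one of
    {no_adapter, no_spacer, too_short} on failure.
    """
    la, lu, ls = len(structure.adapter), structure.umi_length, len(structure.spacer)
    pos = None
    for i in range(0, len(read) - la + 1):
        if _hamming(read[i : i + la], structure.adapter, limit=1) <= 1:
            pos = i
            break
    if pos is None:
        return Extraction(None, None, NO_ADAPTER)
    if len(read) < pos + la + lu + ls + 1:
        return Extraction(None, None, TOO_SHORT)
    umi = read[pos + la : pos + la + lu]
    spacer = read[pos + la + lu : pos + la + lu + ls]
    if _hamming(spacer, structure.spacer, limit=1) > 1:
        return Extraction(None, None, NO_SPACER)
    insert = read[pos + la + lu + ls :]
    return Extraction(umi, insert, None)


def collapse_umis(groups: list[UmiGroup]) -> list[UmiGroup]:
    """Directional collapse of UMI groups sharing one clonotype context.

    Groups are processed in descending read count (ties lexicographic by
    UMI); each group merges into the first retained group within Hamming
    distance 1 whose count satisfies the 2n-1 rule, making the result
    independent of input order.
    """
    if not groups:
        return []
    lengths = {len(g.umi) for g in groups}
    if len(lengths) != 1:
        raise ValueError(f"UMIs of unequal length: {sorted(lengths)}")
    ordered = sorted(groups, key=lambda g: (-g.read_count, g.umi))
    retained: list[UmiGroup] = []
    for g in ordered:
        merged = False
        for root in retained:
            if root.read_count >= 2 * g.read_count - 1 and _hamming(root.umi, g.umi, 1) <= 1:
                root.read_count += g.read_count
                merged = True
                break
        if not merged:
            retained.append(UmiGroup(g.umi, g.read_count, g.consensus_insert))
    return retained


def _best_flank_match(seqs: list[str], text: str, from_right: bool) -> tuple[int, int, int]:
    """Best (index, length, mismatches) anchor match; index -1 if none.

    Acceptance: matched length >= 6 with at most 1 mismatch; score is
    length - 2*mismatches, ties broken by segment-list order.
    """
    best = (-1, 0, 0)
    best_score = -1
    for idx, flank in enumerate(seqs):
        lmax = min(len(flank), len(text))
        # mismatches of the length-l anchor, cumulatively
        mm = 0
        cand = None
        for l in range(1, lmax + 1):
            if from_right:
                if text[len(text) - l] != flank[len(flank) - l]:
                    mm += 1
            else:
                if text[l - 1] != flank[l - 1]:
                    mm += 1
            if mm <= 1 and l >= 6:
                cand = (l, mm)
        if cand is None:
            continue
        l, m = cand
        score = l - 2 * m
        if score > best_score:
            best_score = score
            best = (idx, l, m)
    return best


def call_cdr3(
    insert: str, gen: GenerativeModel
) -> tuple[ClonotypeKey, str] | str:
    """Anchor the junction against V/J reference flanks and call the clone.

    The insert is expected to span the conserved-C codon through the
    conserved-F codon.  Returns (key, cdr3_nt) or a rejection reason in
    {no_v, no_j, frame}.
    """
    v_idx, _, _ = _best_flank_match(gen.v_seqs, insert, from_right=False)
    if v_idx < 0:
        return NO_V
    j_idx, _, _ = _best_flank_match(gen.j_seqs, insert, from_right=True)
    if j_idx < 0:
        return NO_J
    if len(insert) % 3 != 0:
        return FRAME
    aa = str(Seq(insert).translate())
    if "*" in aa:
        return FRAME
    key = ClonotypeKey(gen.v_names[v_idx], gen.j_names[j_idx], aa)
    return key, insert


@dataclass
class QcReport:
    """Per-reason read tallies for one sample's read-to-clonotype run."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def assigned(self) -> int:
        return self.counts.get(ASSIGNED, 0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.counts, indent=1, sort_keys=True))


def _iter_reads(reads) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        for rec in SeqIO.parse(str(reads), "fastq"):
            yield str(rec.seq)
    else:
        for r in reads:
            yield str(r.seq) if hasattr(r, "seq") else str(r)


def build_clonotype_table(
    reads,
    structure: ReadStructure,
    gen: GenerativeModel,
    subject_id: str = "S",
    timepoint_months: int = 0,
    subset: str = "CD4_RO",
) -> tuple[RepertoireSample, QcReport]:
    """Run extract -> call -> group -> collapse over a FASTQ read stream.

    ``reads`` may be a FASTQ path or an iterable of sequences.  Per
    nucleotide clonotype, ``umi_count`` is the number of collapsed UMI
    groups and ``read_count`` the total assigned reads; the QC report
    conserves totals (assigned + rejected = input).
    """
    qc: dict[str, int] = defaultdict(int)
    by_clone: dict[tuple[ClonotypeKey, str], dict[str, int]] = defaultdict(
        lambda: defaultdict(int)
    )
    for seq in _iter_reads(reads):
        ext = extract_umi(seq, structure)
        if not ext.ok:
            qc[ext.rejection] += 1
            continue
        called = call_cdr3(ext.insert, gen)
        if isinstance(called, str):
            qc[called] += 1
            continue
        key, nt = called
        by_clone[(key, nt)][ext.umi] += 1
        qc[ASSIGNED] += 1

    sample = RepertoireSample(subject_id, timepoint_months, subset)
    for (key, nt), umi_counts in sorted(
        by_clone.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        groups = [UmiGroup(u, c, nt) for u, c in umi_counts.items()]
        collapsed = collapse_umis(groups)
        reads_total = sum(g.read_count for g in collapsed)
        sample.records.append(
            ClonotypeRecord(key, nt, read_count=reads_total, umi_count=len(collapsed))
        )
    return sample, QcReport(dict(qc))
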