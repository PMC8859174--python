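"""Domain types and tab-separated interchange I/O for TCR-beta clonotype data.

A *clonotype* is identified at the amino-acid level by the triple
(V gene, J gene, CDR3 amino-acid sequence); the same clonotype may be carried
by several nucleotide sequences (convergent recombination).  The junction
convention is IMGT-style: the CDR3 string runs from the conserved cysteine
codon through the conserved phenylalanine codon inclusive.

The interchange format is an AIRR-Rearrangement-flavoured TSV with columns
``subject_id, timepoint_months, cell_subset, v_call, j_call, junction,
junction_aa, duplicate_count, umi_count`` (UTF-8, tab-delimited).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio.Seq import Seq

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
NT_ALPHABET = set("ACGT")

CLONOTYPE_COLUMNS = [
    "subject_id",
    "timepoint_months",
    "cell_subset",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
    "umi_count",
]

SUBJECT_COLUMNS = ["subject_id", "hla_alleles", "treatment_group"]


class FormatError(ValueError):
    """Raised when an interchange file violates the documented schema."""


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string to amino acids ('*' for stops)."""
    if len(nt) % 3 != 0:
        raise ValidationError(f"nucleotide length {len(nt)} not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True, order=True)
class ClonotypeKey:
    """Amino-acid level clone identity: (V gene, J gene, CDR3 AA sequence).

    Equality and hashing use this triple and nothing else; nucleotide
    encodings live on :class:`ClonotypeRecord`.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValidationError("cdr3_aa must be non-empty")
        if not self.cdr3_aa.isupper():
            raise ValidationError(f"cdr3_aa must be uppercase: {self.cdr3_aa!r}")
        bad = set(self.cdr3_aa) - AA_ALPHABET
        if bad:
            raise ValidationError(f"cdr3_aa has non amino-acid letters {bad!r}")


@dataclass
class ClonotypeRecord:
    """One nucleotide clonotype with read and UMI abundances."""

    key: ClonotypeKey
    cdr3_nt: str
    read_count: int
    umi_count: int = 0

    def __post_init__(self) -> None:
        if set(self.cdr3_nt) - NT_ALPHABET:
            raise ValidationError(f"cdr3_nt has non-ACGT letters: {self.cdr3_nt!r}")
        if len(self.cdr3_nt) != 3 * len(self.key.cdr3_aa):
            raise ValidationError(
                f"cdr3_nt length {len(self.cdr3_nt)} != 3 x |cdr3_aa| "
                f"({len(self.key.cdr3_aa)})"
            )
        if translate_nt(self.cdr3_nt) != self.key.cdr3_aa:
            raise ValidationError(
                f"junction {self.cdr3_nt} does not translate to {self.key.cdr3_aa}"
            )
        if self.read_count < 0 or self.umi_count < 0:
            raise ValidationError("counts must be non-negative")
        if self.umi_count and self.read_count < self.umi_count:
            raise ValidationError("read_count must be >= umi_count")

    @property
    def abundance(self) -> int:
        """UMI count when present, read count otherwise (tracking default)."""
        return self.umi_count if self.umi_count > 0 else self.read_count


class AAProfile(NamedTuple):
    """Amino-acid level aggregate of one clonotype within one sample."""

    total_reads: int
    total_umis: int
    nt_variants: frozenset[str]


SUBSETS = ("CD4_RA", "CD4_RO", "CD8_RA", "CD8_RO")


@dataclass
class RepertoireSample:
    """All clonotype records for one (subject, timepoint, cell subset)."""

    subject_id: str
    timepoint_months: int
    subset: str
    records: list[ClonotypeRecord] = field(default_factory=list)

    def aggregate_nt(self) -> None:
        """Merge duplicate (key, cdr3_nt) rows by summing their counts."""
        merged: dict[tuple[ClonotypeKey, str], ClonotypeRecord] = {}
        for rec in self.records:
            k = (rec.key, rec.cdr3_nt)
            if k in merged:
                merged[k].read_count += rec.read_count
                merged[k].umi_count += rec.umi_count
            else:
                merged[k] = ClonotypeRecord(
                    rec.key, rec.cdr3_nt, rec.read_count, rec.umi_count
                )
        self.records = list(merged.values())

    @property
    def label(self) -> tuple[str, int, str]:
        return (self.subject_id, self.timepoint_months, self.subset)


def normalize_allele(allele: str) -> str:
    """Normalize an HLA allele string to LOCUS*GG:PP form (uppercase, no spaces)."""
    a = allele.strip().upper().replace(" ", "")
    if a.startswith("HLA-"):
        a = a[4:]
    if "*" not in a:
        raise ValidationError(f"malformed HLA allele {allele!r} (missing '*')")
    return a


@dataclass
class SubjectMeta:
    subject_id: str
    hla_alleles: frozenset[str] = frozenset()
    treatment_group: str = "AHSCT"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "hla_alleles", frozenset(normalize_allele(a) for a in self.hla_alleles)
        )
        if self.treatment_group not in ("AHSCT", "comparator"):
            raise ValidationError(
                f"treatment_group must be AHSCT or comparator: {self.treatment_group!r}"
            )


@dataclass
class CohortDataset:
    """A cohort: repertoire samples plus per-subject metadata."""

    samples: list[RepertoireSample] = field(default_factory=list)
    subjects: list[SubjectMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {s.subject_id for s in self.subjects}
        missing = {s.subject_id for s in self.samples} - known
        if missing:
            raise ValidationError(f"samples reference unknown subjects: {sorted(missing)}")
        labels = [s.label for s in self.samples]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate (subject, timepoint, subset) samples")

    def subject(self, subject_id: str) -> SubjectMeta:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def get_sample(
        self, subject_id: str, timepoint_months: int, subset: str
    ) -> RepertoireSample | None:
        for s in self.samples:
            if s.label == (subject_id, timepoint_months, subset):
                return s
        return None

    def samples_at(self, timepoint_months: int, subset: str) -> list[RepertoireSample]:
        return [
            s
            for s in self.samples
            if s.timepoint_months == timepoint_months and s.subset == subset
        ]


# ---------------------------------------------------------------------------
# Interchange I/O


def read_clonotype_table(path: str | Path, metadata_path: str | Path | None = None) -> CohortDataset:
    """Read an AIRR-flavoured clonotype TSV into a :class:`CohortDataset`.

    Rows sharing (subject, timepoint, subset, v_call, j_call, junction) have
    their counts summed.  When ``metadata_path`` is given it must be a subject
    TSV written by :func:`write_clonotype_table`; otherwise subjects are
    created with empty HLA metadata.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clonotype table missing required column(s): {missing}")

    samples: dict[tuple[str, int, str], RepertoireSample] = {}
    counts: dict[tuple, list[int]] = {}
    rowmeta: dict[tuple, tuple] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nt, aa = row.junction, row.junction_aa
        try:
            if translate_nt(nt) != aa:
                raise ValidationError(f"junction does not translate to junction_aa ({nt} vs {aa})")
        except ValidationError as e:
            raise ValidationError(f"line {i}: {e}") from None
        label = (row.subject_id, int(row.timepoint_months), row.cell_subset)
        k = label + (row.v_call, row.j_call, nt)
        c = counts.setdefault(k, [0, 0])
        c[0] += int(row.duplicate_count)
        c[1] += int(row.umi_count)
        rowmeta[k] = (aa,)

    for k, (reads, umis) in counts.items():
        subject_id, tp, subset, v, j, nt = k
        (aa,) = rowmeta[k]
        label = (subject_id, tp, subset)
        sample = samples.setdefault(label, RepertoireSample(subject_id, tp, subset))
        sample.records.append(
            ClonotypeRecord(ClonotypeKey(v, j, aa), nt, reads, umis)
        )

    if metadata_path is not None:
        subjects = read_subject_table(metadata_path)
    else:
        subjects = [
            SubjectMeta(sid) for sid in sorted({s.subject_id for s in samples.values()})
        ]
    return CohortDataset(samples=list(samples.values()), subjects=subjects)


def read_subject_table(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subject table missing required column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        alleles = frozenset(a for a in row.hla_alleles.split(";") if a)
        out.append(SubjectMeta(row.subject_id, alleles, row.treatment_group))
    return out


def write_clonotype_table(
    cohort: CohortDataset,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a cohort to the interchange TSV; round-trips through the reader."""
    rows = []
    for sample in cohort.samples:
        for rec in sample.records:
            rows.append(
                {
                    "subject_id": sample.subject_id,
                    "timepoint_months": sample.timepoint_months,
                    "cell_subset": sample.subset,
                    "v_call": rec.key.v_gene,
                    "j_call": rec.key.j_gene,
                    "junction": rec.cdr3_nt,
                    "junction_aa": rec.key.cdr3_aa,
                    "duplicate_count": rec.read_count,
                    "umi_count": rec.umi_count,
                }
            )
    df = pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")

    if metadata_path is not None:
        mrows = [
            {
                "subject_id": s.subject_id,
                "hla_alleles": ";".join(sorted(s.hla_alleles)),
                "treatment_group": s.treatment_group,
            }
            for s in cohort.subjects
        ]
        pd.DataFrame(mrows, columns=SUBJECT_COLUMNS).to_csv(
            metadata_path, sep="\t", index=False, encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# Aggregation and frequencies


def aggregate_to_aa(sample: RepertoireSample) -> dict[ClonotypeKey, AAProfile]:
    """Collapse nucleotide variants to amino-acid clonotypes.

    Reads and UMIs are summed over nucleotide variants; the set of distinct
    nucleotide encodings per key is retained (convergent-recombination count).
    Total read and UMI counts are conserved.
    """
    reads: dict[ClonotypeKey, int] = defaultdict(int)
    umis: dict[ClonotypeKey, int] = defaultdict(int)
    variants: dict[ClonotypeKey, set[str]] = defaultdict(set)
    for rec in sample.records:
        reads[rec.key] += rec.read_count
        umis[rec.key] += rec.umi_count
        variants[rec.key].add(rec.cdr3_nt)
    return {
        k: AAProfile(reads[k], umis[k], frozenset(variants[k])) for k in reads
    }


def frequencies(
    sample: RepertoireSample,
    level: str = "aa",
    weight: str = "auto",
):
    """Clone frequencies for one sample.

    Parameters
    ----------
    level : 'aa' or 'nt'
        Amino-acid clonotypes (:class:`ClonotypeKey` keys) or nucleotide
        clonotypes ((key, cdr3_nt) keys).
    weight : 'reads', 'umis' or 'auto'
        'auto' uses UMIs when any record carries them, reads otherwise.

    Returns an insertion-ordered dict of fractions summing to 1; ordering is
    deterministic (descending weight, then lexicographic key).
    """
    if level not in ("aa", "nt"):
        raise ValueError(f"level must be 'aa' or 'nt', got {level!r}")
    if weight not in ("reads", "umis", "auto"):
        raise ValueError(f"weight must be 'reads', 'umis' or 'auto', got {weight!r}")
    if not sample.records:
        raise ValidationError("empty repertoire")
    if weight == "auto":
        weight = "umis" if any(r.umi_count > 0 for r in sample.records) else "reads"

    acc: dict = defaultdict(int)
    for rec in sample.records:
        w = rec.read_count if weight == "reads" else rec.umi_count
        clone = rec.key if level == "aa" else (rec.key, rec.cdr3_nt)
        acc[clone] += w
    total = sum(acc.values())
    if total <= 0:
        raise ValidationError(f"empty repertoire (total {weight} weight is 0)")
    ordered = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))
    return {clone: w / total for clone, w in ordered}
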