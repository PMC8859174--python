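"""Antigen-specificity annotation against a VDJdb-style table.

A clonotype is annotated when a database entry matches its V gene, J gene
and CDR3 amino-acid sequence exactly AND the entry's HLA restriction is
carried by the subject.  HLA matching is by prefix at the resolution
recorded in the database entry (low-resolution class I typing matches
4-digit entries and vice versa).  The database is treated as pre-filtered;
no confidence-score cutoff is applied.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    ClonotypeKey,
    RepertoireSample,
    SubjectMeta,
    aggregate_to_aa,
    normalize_allele,
)

DB_COLUMNS = ["v_gene", "j_gene", "cdr3_aa", "epitope", "antigen_species", "hla_restriction"]


@dataclass(frozen=True)
class AntigenDbEntry:
    v_gene: str
    j_gene: str
    cdr3_aa: str
    epitope: str
    antigen_species: str
    hla_restriction: str

    def __post_init__(self) -> None:
        for f in ("v_gene", "j_gene", "cdr3_aa", "epitope", "antigen_species", "hla_restriction"):
            if not getattr(self, f):
                raise ValueError(f"antigen db entry field {f} must be non-empty")
        object.__setattr__(self, "hla_restriction", normalize_allele(self.hla_restriction))


def read_antigen_db(path: str | Path) -> list[AntigenDbEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in DB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"antigen db missing required column(s): {missing}")
    return [AntigenDbEntry(*[getattr(r, c) for c in DB_COLUMNS]) for r in df.itertuples(index=False)]


def write_antigen_db(entries: Sequence[AntigenDbEntry], path: str | Path) -> None:
    pd.DataFrame([vars(e) | {} for e in [e for e in entries]], columns=DB_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def _hla_match(entry_allele: str, subject_alleles) -> bool:
    # prefix matching at the coarser of the two resolutions
    for a in subject_alleles:
        if a == entry_allele or a.startswith(entry_allele + ":") or entry_allele.startswith(a + ":"):
            return True
    return False


def annotate_repertoire(
    sample: RepertoireSample,
    db: Sequence[AntigenDbEntry],
    subject: SubjectMeta,
) -> dict[ClonotypeKey, list[AntigenDbEntry]]:
    """Match clonotypes to database entries under the HLA restriction rule."""
    index: dict[tuple[str, str, str], list[AntigenDbEntry]] = defaultdict(list)
    for e in db:
        if _hla_match(e.hla_restriction, subject.hla_alleles):
            index[(e.v_gene, e.j_gene, e.cdr3_aa)].append(e)
    out: dict[ClonotypeKey, list[AntigenDbEntry]] = {}
    for key in aggregate_to_aa(sample):
        hits = index.get((key.v_gene, key.j_gene, key.cdr3_aa))
        if hits:
            out[key] = list(hits)
    return out


def annotated_fraction(
    sample: RepertoireSample,
    annotations: Mapping[ClonotypeKey, Sequence[AntigenDbEntry]],
    by: str = "reads",
) -> dict[str, float]:
    """Fraction of the repertoire annotated, per antigen species.

    ``by='reads'`` weights by abundance (UMIs when present), ``by='clonotypes'``
    counts clones.  A clonotype annotated to several species contributes to
    each, so the per-species fractions can sum to more than the overall
    annotated fraction but never exceed 1 individually.
    """
    if by not in ("reads", "clonotypes"):
        raise ValueError("by must be 'reads' or 'clonotypes'")
    agg = aggregate_to_aa(sample)
    use_umis = any(p.total_umis > 0 for p in agg.values())

    def weight(key: ClonotypeKey) -> float:
        p = agg[key]
        return float(p.total_umis if use_umis else p.total_reads) if by == "reads" else 1.0

    total = sum(weight(k) for k in agg)
    out: dict[str, float] = defaultdict(float)
    for key, hits in annotations.items():
        if key not in agg:
            continue
        for species in {h.antigen_species for h in hits}:
            out[species] += weight(key) / total
    return dict(out)
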