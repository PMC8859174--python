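"""Synthetic longitudinal TCR-beta cohorts with complete ground truth.

The generator emulates the structure of a longitudinal transplant study:
multiple subjects sampled at months 0, 6, 12, 24 and 36 in four sorted
T-cell subsets (CD4/CD8 x naive/memory), with

* clonotypes drawn from the V(D)J generative model (optionally reweighted by
  a planted selection model),
* rank-frequency clone sizes following a Zipf law with subset-specific
  exponents (memory subsets skewed and growing more skewed over time, naive
  subsets near-flat),
* per-interval survival of clones: baseline-dominant (top-100) clones
  persist with one probability, background clones with another, and lost
  clones are replaced by newly generated ones (a few of which expand into
  the dominant ranks, emulating lymphopenia-induced proliferation),
* public clonotypes injected across designated subjects with a configured
  number of distinct synonymous nucleotide encodings (convergent
  recombination), and
* structured reads (adapter + UMI + spacer + junction) with positional
  substitution errors for the UMI-pipeline stage.

Every emitted quantity has a ground-truth record, and everything is
reproducible from the configuration seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .core import (
    ClonotypeKey,
    ClonotypeRecord,
    CohortDataset,
    RepertoireSample,
    SubjectMeta,
)
from .selection import SelectionModel, featurize
from .umi import ReadStructure
from .vdj import NT, GenerativeModel, ModelError, is_productive, pgen_nt, sample_rearrangements, toy_model

CODON_SYNONYMS: dict[str, tuple[str, ...]] = {}


def _synonyms(codon: str) -> tuple[str, ...]:
    from .vdj import CODONS_FOR_AA

    if codon not in CODON_SYNONYMS:
        aa = str(Seq(codon).translate())
        CODON_SYNONYMS[codon] = tuple(c for c in CODONS_FOR_AA[aa] if c != codon)
    return CODON_SYNONYMS[codon]


@dataclass
class PublicSpec:
    """How many public clones to inject, into how many subjects, with how
    many synonymous nucleotide encodings (distribution over 1..5)."""

    n_public: int = 60
    subjects_range: tuple[int, int] = (2, 3)
    encoding_probs: tuple[float, ...] = (0.88, 0.06, 0.03, 0.02, 0.01)
    subset: str = "CD4_RO"

    def __post_init__(self) -> None:
        if abs(sum(self.encoding_probs) - 1.0) > 1e-9:
            raise ValueError("encoding_probs must sum to 1")


Survival = float | tuple[float, ...]


def survival_at(s: Survival, interval_index: int) -> float:
    """Per-interval survival; a tuple schedule repeats its last entry."""
    if isinstance(s, (int, float)):
        return float(s)
    return float(s[min(interval_index, len(s) - 1)])


@dataclass
class SubsetProfile:
    """Clone-size and survival kinetics for one sorted subset.

    Survival values may be a single per-interval probability or a schedule
    (one entry per interval, last entry repeated), which lets memory pools
    show the two-phase pattern of immuno-ablation: a large first-interval
    loss followed by slower attrition.
    """

    alpha: float  # Zipf rank-frequency exponent at baseline
    dominant_survival: Survival  # per-interval persistence of baseline top-100
    background_survival: Survival
    skew_growth: float = 0.0  # relative alpha increase per interval

    def __post_init__(self) -> None:
        for field_name in ("dominant_survival", "background_survival"):
            v = getattr(self, field_name)
            if isinstance(v, list):
                setattr(self, field_name, tuple(v))


DEFAULT_PROFILES = {
    # memory pools: skewed, progressively more clonal; ablation removes most
    # dominant clones in the first interval, attrition continues thereafter
    "CD4_RO": SubsetProfile(alpha=1.0, dominant_survival=(0.41, 0.78),
                            background_survival=(0.15, 0.55), skew_growth=0.10),
    "CD8_RO": SubsetProfile(alpha=1.1, dominant_survival=(0.33, 0.74),
                            background_survival=(0.15, 0.55), skew_growth=0.12),
    # naive pools: near-flat sizes, high turnover
    "CD4_RA": SubsetProfile(alpha=0.4, dominant_survival=0.15, background_survival=0.05, skew_growth=0.0),
    "CD8_RA": SubsetProfile(alpha=0.4, dominant_survival=0.15, background_survival=0.05, skew_growth=0.0),
}


@dataclass
class SimulationConfig:
    n_subjects: int = 13
    timepoints: tuple[int, ...] = (0, 6, 12, 24, 36)
    subsets: tuple[str, ...] = ("CD4_RA", "CD4_RO", "CD8_RA", "CD8_RO")
    clones_per_sample: int = 400
    size_alpha: float | None = None  # overrides every subset's alpha when set
    umis_per_sample: int = 20_000
    reads_per_umi: float = 4.0
    dominant_survival: float | None = None  # overrides every subset when set
    background_survival: float | None = None
    top_n_dominant: int = 100
    public: PublicSpec = field(default_factory=PublicSpec)
    selection: SelectionModel | None = None
    error_rate: float = 0.001
    seed: int = 0
    subset_profiles: dict[str, SubsetProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    n_new_expansions: int = 40  # new clones entering the dominant ranks per interval
    risk_allele: str = "DRB1*15:01"
    n_risk_carriers: int = 5
    n_comparators: int = 0
    comparator_survival: float = 0.86

    def __post_init__(self) -> None:
        if isinstance(self.public, dict):
            self.public = PublicSpec(**self.public)
        self.subset_profiles = {
            k: (SubsetProfile(**v) if isinstance(v, dict) else v)
            for k, v in self.subset_profiles.items()
        }
        self.timepoints = tuple(self.timepoints)
        self.subsets = tuple(self.subsets)
        tps = tuple(self.timepoints)
        if tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        for name, p in (
            ("dominant_survival", self.dominant_survival),
            ("background_survival", self.background_survival),
        ):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    def profile(self, subset: str) -> SubsetProfile:
        prof = self.subset_profiles.get(subset, SubsetProfile(1.0, 0.5, 0.2))
        return SubsetProfile(
            alpha=self.size_alpha if self.size_alpha is not None else prof.alpha,
            dominant_survival=(
                self.dominant_survival
                if self.dominant_survival is not None
                else prof.dominant_survival
            ),
            background_survival=(
                self.background_survival
                if self.background_survival is not None
                else prof.background_survival
            ),
            skew_growth=prof.skew_growth,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d.pop("selection", None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "public" in d and isinstance(d["public"], dict):
            pub = d["public"]
            pub["subjects_range"] = tuple(pub.get("subjects_range", (2, 3)))
            pub["encoding_probs"] = tuple(pub.get("encoding_probs", PublicSpec().encoding_probs))
            d["public"] = PublicSpec(**pub)
        if "subset_profiles" in d:
            d["subset_profiles"] = {
                k: SubsetProfile(**v) for k, v in d["subset_profiles"].items()
            }
        for key in ("timepoints", "subsets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PublicCloneTruth:
    key: ClonotypeKey
    subjects: tuple[str, ...]
    encodings: tuple[str, ...]
    subset: str


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream estimators must recover."""

    freqs: dict = field(default_factory=dict)  # label -> {key: frequency}
    presence: dict = field(default_factory=dict)  # (subject, subset) -> {key: set(tp)}
    baseline_dominant: dict = field(default_factory=dict)  # (subject, subset) -> [keys]
    public_registry: list[PublicCloneTruth] = field(default_factory=list)
    config: SimulationConfig | None = None


def synonymous_variants(
    gen: GenerativeModel,
    cdr3_nt: str,
    n_variants: int,
    rng: np.random.Generator,
    max_tries: int = 400,
) -> list[str]:
    """Distinct generatable nucleotide encodings of one junction.

    Returns ``n_variants`` strings (the input first) that all translate to
    the same amino-acid sequence and all have nonzero generation
    probability; raises :class:`ModelError` after bounded retries.
    """
    out = [cdr3_nt]
    tries = 0
    n_codons = len(cdr3_nt) // 3
    while len(out) < n_variants:
        tries += 1
        if tries > max_tries:
            raise ModelError(
                f"could not find {n_variants} generatable encodings of {cdr3_nt}"
            )
        variant = list(cdr3_nt)
        for pos in rng.choice(n_codons, size=min(2, n_codons), replace=False):
            syns = _synonyms(cdr3_nt[3 * pos : 3 * pos + 3])
            if syns:
                variant[3 * pos : 3 * pos + 3] = syns[rng.integers(len(syns))]
        v = "".join(variant)
        if v not in out and pgen_nt(gen, v) > 0:
            out.append(v)
    return out


def _sample_distinct_keys(
    gen: GenerativeModel,
    n: int,
    rng: np.random.Generator,
    exclude: set[ClonotypeKey],
    selection: SelectionModel | None,
) -> list[tuple[ClonotypeKey, str]]:
    """Distinct productive clonotypes (key, nt), optionally selection-biased."""
    target = n if selection is None else max(4 * n, 1024)
    cands: list[tuple[ClonotypeKey, str]] = []
    seen = set(exclude)
    while len(cands) < target:
        batch = sample_rearrangements(gen, max(512, 2 * (target - len(cands))), rng)
        for nt, sc in batch:
            if not is_productive(nt):
                continue
            key = ClonotypeKey(
                gen.v_names[sc.v_choice], gen.j_names[sc.j_choice], str(Seq(nt).translate())
            )
            if key in seen:
                continue
            seen.add(key)
            cands.append((key, nt))
    if selection is None:
        return cands[:n]
    # exponential-weights sampling without replacement (Gumbel top-n)
    scores = np.array([selection.score(k) for k, _ in cands], dtype=float)
    noisy = scores + rng.gumbel(size=len(cands))
    idx = np.argsort(-noisy)[:n]
    return [cands[i] for i in idx]


def _zipf_weights(n: int, alpha: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-alpha)
    return w / w.sum()


def _subject_meta(config: SimulationConfig) -> list[SubjectMeta]:
    filler = ("A*02:01", "B*07:02", "DRB1*04:01")
    subjects = []
    for i in range(config.n_subjects):
        alleles = set(filler[: 1 + i % 3])
        if i < config.n_risk_carriers:
            alleles.add(config.risk_allele)
        subjects.append(SubjectMeta(f"HSCT{i + 1:02d}", frozenset(alleles), "AHSCT"))
    for i in range(config.n_comparators):
        alleles = set(filler[: 1 + i % 3])
        subjects.append(SubjectMeta(f"NTZ{i + 1:02d}", frozenset(alleles), "comparator"))
    return subjects


def simulate_cohort(
    config: SimulationConfig, gen: GenerativeModel | None = None
) -> tuple[CohortDataset, GroundTruth]:
    """Generate a longitudinal cohort and its ground truth (seed-reproducible)."""
    gen = gen if gen is not None else toy_model()
    rng = np.random.default_rng(config.seed)
    subjects = _subject_meta(config)
    truth = GroundTruth(config=config)

    # --- public-clone registry: shared keys with synonymous encodings
    pub = config.public
    registry: list[PublicCloneTruth] = []
    if pub.n_public > 0 and pub.subset in config.subsets and config.n_subjects >= 2:
        pool = _sample_distinct_keys(gen, pub.n_public, rng, set(), None)
        ahsct_ids = [s.subject_id for s in subjects if s.treatment_group == "AHSCT"]
        for key, nt in pool:
            n_enc = 1 + int(
                rng.choice(len(pub.encoding_probs), p=np.array(pub.encoding_probs))
            )
            n_subj = int(rng.integers(pub.subjects_range[0], pub.subjects_range[1] + 1))
            n_subj = min(n_subj, len(ahsct_ids))
            chosen = tuple(
                sorted(rng.choice(ahsct_ids, size=n_subj, replace=False).tolist())
            )
            encodings = tuple(synonymous_variants(gen, nt, n_enc, rng))
            registry.append(PublicCloneTruth(key, chosen, encodings, pub.subset))
    truth.public_registry = registry
    injected: dict[tuple[str, str], list[PublicCloneTruth]] = {}
    for pc in registry:
        for sid in pc.subjects:
            injected.setdefault((sid, pc.subset), []).append(pc)

    samples: list[RepertoireSample] = []
    for subj in subjects:
        comparator = subj.treatment_group == "comparator"
        for subset in config.subsets:
            prof = config.profile(subset)
            dom_s = config.comparator_survival if comparator else prof.dominant_survival
            bg_s = (
                min(1.0, config.comparator_survival * 0.5)
                if comparator
                else prof.background_survival
            )
            k = config.clones_per_sample
            used: set[ClonotypeKey] = set()
            pubs_here = injected.get((subj.subject_id, subset), [])
            pub_keys = {pc.key: pc for pc in pubs_here}
            used |= set(pub_keys)
            baseline = _sample_distinct_keys(
                gen, k - len(pubs_here), rng, used, config.selection
            )
            used |= {key for key, _ in baseline}
            # splice public clones into mid ranks so they are clearly detected
            order: list[tuple[ClonotypeKey, str]] = list(baseline)
            for pc in pubs_here:
                lo = min(40, len(order))
                pos = int(rng.integers(lo, len(order) + 1))
                order.insert(pos, (pc.key, pc.encodings[0]))

            nt_of = {key: nt for key, nt in order}
            dominant = [key for key, _ in order[: config.top_n_dominant]]
            truth.baseline_dominant[(subj.subject_id, subset)] = dominant
            presence = truth.presence.setdefault((subj.subject_id, subset), {})

            current = [key for key, _ in order]
            for t_idx, tp in enumerate(config.timepoints):
                alpha_t = prof.alpha * (1.0 + prof.skew_growth * t_idx)
                if t_idx > 0:
                    dom_set = set(dominant)
                    dom_p = survival_at(dom_s, t_idx - 1)
                    bg_p = survival_at(bg_s, t_idx - 1)
                    survive_p = np.array(
                        [dom_p if key in dom_set else bg_p for key in current]
                    )
                    alive = rng.random(len(current)) < survive_p
                    survivors = [key for key, a in zip(current, alive) if a]
                    n_new = k - len(survivors)
                    new = _sample_distinct_keys(gen, n_new, rng, used, config.selection)
                    used |= {key for key, _ in new}
                    nt_of.update(new)
                    current = survivors + [key for key, _ in new]
                    # a few new clones expand into the dominant ranks
                    n_exp = min(config.n_new_expansions, n_new)
                    for idx in range(n_exp):
                        src = len(survivors) + idx
                        dst = int(rng.integers(0, min(config.top_n_dominant, len(current))))
                        clone = current.pop(src)
                        current.insert(dst, clone)

                w = _zipf_weights(len(current), alpha_t)
                label = (subj.subject_id, tp, subset)
                truth.freqs[label] = dict(zip(current, w))
                for key in current:
                    presence.setdefault(key, set()).add(tp)

                # every present clone receives at least one molecule so that
                # the emitted repertoire is exactly the alive clone list
                n_umis = config.umis_per_sample
                if n_umis >= len(current):
                    umis = 1 + rng.multinomial(n_umis - len(current), w)
                else:
                    umis = rng.multinomial(n_umis, w)
                sample = RepertoireSample(subj.subject_id, tp, subset)
                for key, u in zip(current, umis):
                    pc = pub_keys.get(key)
                    encodings = pc.encodings if pc is not None else (nt_of[key],)
                    if pc is not None:
                        u = max(int(u), 2 * len(encodings))
                    if u == 0:
                        continue
                    per_enc = np.ones(len(encodings), dtype=int)
                    if u > len(encodings):
                        per_enc += rng.multinomial(
                            u - len(encodings), np.full(len(encodings), 1 / len(encodings))
                        )
                    for nt, u_enc in zip(encodings, per_enc):
                        if u_enc == 0:
                            continue
                        reads = int(u_enc + rng.poisson((config.reads_per_umi - 1.0) * u_enc))
                        reads = max(reads, u_enc)
                        sample.records.append(
                            ClonotypeRecord(key, nt, read_count=reads, umi_count=int(u_enc))
                        )
                samples.append(sample)

    cohort = CohortDataset(samples=samples, subjects=subjects)
    return cohort, truth


# ---------------------------------------------------------------------------
# Read-level simulation


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, size=length))


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    s = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        alternatives = [c for c in NT if c != s[pos]]
        s[pos] = alternatives[rng.integers(3)]
    return "".join(s)


def simulate_reads(
    sample: RepertoireSample,
    structure: ReadStructure,
    rng: int | np.random.Generator,
    error_rate: float = 0.001,
) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs for one sample's molecules.

    Each record contributes ``umi_count`` molecules carrying distinct UMIs
    (pairwise Hamming distance >= 2 within a clonotype, the regime in which
    directional collapse is exact) and ``read_count`` reads in total, each
    read being adapter + UMI + spacer + junction with i.i.d. substitution
    errors at ``error_rate`` per base.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    i = 0
    for rec in sample.records:
        m = rec.umi_count if rec.umi_count > 0 else 1
        umis: list[str] = []
        while len(umis) < m:
            u = _random_umi(rng, structure.umi_length)
            if all(_dist_ge2(u, prev) for prev in umis):
                umis.append(u)
        n_reads = max(rec.read_count, m)
        per_mol = np.ones(m, dtype=int)
        if n_reads > m:
            per_mol += rng.multinomial(n_reads - m, np.full(m, 1 / m))
        for umi, nr in zip(umis, per_mol):
            template = structure.adapter + umi + structure.spacer + rec.cdr3_nt
            for _ in range(int(nr)):
                i += 1
                yield (
                    f"{sample.subject_id}:{sample.timepoint_months}:{sample.subset}:r{i}",
                    _mutate(template, rng, error_rate),
                )


def _dist_ge2(a: str, b: str) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d >= 2:
                return True
    return False


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
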