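"""Pipeline orchestration: run analysis stages from a YAML configuration.

Stages (dependency order): simulate | clonotype | track | diversity |
public | annotate | motifs | selection.  Every stage reads the cohort
produced by an earlier stage (or supplied under ``input:``) and writes tidy
TSV/JSON outputs into the report directory; each output is stamped with the
configuration hash and seed (comment line in TSVs, fields in JSON) and a
``manifest.json`` records the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annot
from . import diversity as div
from . import motifs as mot
from . import publics as pub
from . import selection as sel
from . import simulate as sim
from . import tracking as trk
from .core import CohortDataset, read_clonotype_table, write_clonotype_table
from .stats import bonferroni, wilcoxon_paired
from .umi import ReadStructure, build_clonotype_table
from .vdj import GenerativeModel, toy_model

log = logging.getLogger("tcrtrack")

STAGE_ORDER = [
    "simulate",
    "clonotype",
    "track",
    "diversity",
    "public",
    "annotate",
    "motifs",
    "selection",
]


class ConfigError(ValueError):
    """Raised on schema violations in the pipeline configuration."""


class DependencyError(RuntimeError):
    """Raised when a stage's upstream output is missing."""


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


class _Run:
    def __init__(self, config: dict, out_dir: Path, seed: int):
        self.config = config
        self.out = out_dir
        self.seed = seed
        self.stamp = f"# tcrtrack config={_config_hash(config)} seed={seed}\n"
        self.cohort: CohortDataset | None = None
        self.gen: GenerativeModel = toy_model()
        self.truth: sim.GroundTruth | None = None
        self.outputs: list[str] = []

    def write_tsv(self, df: pd.DataFrame, name: str) -> None:
        path = self.out / name
        with open(path, "w") as fh:
            fh.write(self.stamp)
            df.to_csv(fh, sep="\t", index=False)
        self.outputs.append(name)

    def write_json(self, obj: dict, name: str) -> None:
        obj = {"config": _config_hash(self.config), "seed": self.seed, **obj}
        (self.out / name).write_text(json.dumps(obj, indent=1, default=str))
        self.outputs.append(name)

    def require_cohort(self, stage: str) -> CohortDataset:
        if self.cohort is None:
            raise DependencyError(
                f"stage '{stage}' needs clonotype tables; run 'simulate' or "
                "'clonotype' first, or provide input.clonotypes"
            )
        return self.cohort


def _validate(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    stages = config.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("field 'stages' must be a non-empty list")
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; valid: {STAGE_ORDER}")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ConfigError("field 'seed' must be an integer")


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> Path:
    """Execute the configured stages in dependency order; returns report dir."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    _validate(config)
    seed = seed if seed is not None else int(config.get("seed", 0))
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "report"))
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out, seed)

    inp = config.get("input", {})
    if "clonotypes" in inp:
        run.cohort = read_clonotype_table(inp["clonotypes"], inp.get("subjects"))
    if "model" in inp:
        run.gen = GenerativeModel.from_yaml(inp["model"])

    stages = sorted(set(config["stages"]), key=STAGE_ORDER.index)
    for stage in stages:
        log.info("stage %s", stage)
        _STAGES[stage](run, config.get(stage) or {})

    (out / "manifest.json").write_text(
        json.dumps(
            {
                "config_hash": _config_hash(config),
                "seed": seed,
                "stages": stages,
                "outputs": sorted(run.outputs),
            },
            indent=1,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(run: _Run, opts: dict) -> None:
    cfg = sim.SimulationConfig(**{**opts, "seed": run.seed})
    cohort, truth = sim.simulate_cohort(cfg, run.gen)
    run.cohort, run.truth = cohort, truth
    write_clonotype_table(cohort, run.out / "clonotypes.tsv", run.out / "subjects.tsv")
    run.outputs += ["clonotypes.tsv", "subjects.tsv"]
    run.write_json(
        {
            "n_samples": len(cohort.samples),
            "n_subjects": len(cohort.subjects),
            "n_public_injected": len(truth.public_registry),
        },
        "simulate_summary.json",
    )


def _stage_clonotype(run: _Run, opts: dict) -> None:
    runs = opts.get("runs")
    if not runs:
        raise ConfigError("clonotype stage requires 'runs': list of {fastq, subject_id, timepoint_months, subset}")
    structure = ReadStructure(**opts.get("read_structure", {}))
    samples, subjects = [], []
    qc_all = {}
    for r in runs:
        sample, qc = build_clonotype_table(
            r["fastq"], structure, run.gen, r["subject_id"], int(r["timepoint_months"]), r["subset"]
        )
        samples.append(sample)
        qc_all["%s:%s:%s" % sample.label] = qc.counts
    from .core import SubjectMeta

    cohort = CohortDataset(
        samples=samples,
        subjects=[SubjectMeta(s) for s in sorted({x.subject_id for x in samples})],
    )
    run.cohort = cohort
    write_clonotype_table(cohort, run.out / "clonotypes.tsv", run.out / "subjects.tsv")
    run.outputs += ["clonotypes.tsv", "subjects.tsv"]
    run.write_json({"qc": qc_all}, "clonotype_qc.json")


def _memory_subsets(cohort: CohortDataset) -> list[str]:
    subsets = sorted({s.subset for s in cohort.samples})
    mem = [s for s in subsets if s.endswith("RO")]
    return mem or subsets


def _stage_track(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("track")
    top_n = int(opts.get("top_n", 100))
    min_reads = int(opts.get("min_reads", 1))
    rows = []
    for subset in opts.get("subsets") or _memory_subsets(cohort):
        for subj in cohort.subjects:
            base = cohort.get_sample(subj.subject_id, 0, subset)
            if base is None:
                continue
            dominant = trk.top_n_clones(base, top_n)
            for s in cohort.samples:
                if s.subject_id != subj.subject_id or s.subset != subset or s.timepoint_months == 0:
                    continue
                pf = trk.persistence_fraction(dominant, s, min_reads)
                persistent, new = trk.partition_new_persistent(base, s)
                shared, jac = trk.repertoire_overlap(base, s)
                rows += [
                    dict(subject_id=subj.subject_id, subset=subset,
                         timepoint_months=s.timepoint_months, metric=m, value=v)
                    for m, v in [
                        ("top%d_persistence" % top_n, pf),
                        ("persistent_mass_fraction", persistent),
                        ("new_mass_fraction", new),
                        ("shared_clones", shared),
                        ("jaccard", jac),
                    ]
                ]
    df = pd.DataFrame(rows)
    run.write_tsv(df, "tracking.tsv")

    # cohort means and paired tests of persistence vs the first follow-up
    summary = []
    if not df.empty:
        pers = df[df.metric.str.endswith("persistence")]
        for (subset, tp), grp in pers.groupby(["subset", "timepoint_months"]):
            summary.append(
                dict(subset=subset, timepoint_months=tp,
                     mean_persistence=grp.value.mean(), n=len(grp))
            )
    run.write_tsv(pd.DataFrame(summary), "tracking_summary.tsv")


def _stage_diversity(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("diversity")
    rows = [
        dict(
            subject_id=s.subject_id,
            subset=s.subset,
            timepoint_months=s.timepoint_months,
            entropy=div.sample_entropy(s),
            entropy_normalized=div.sample_entropy(s, normalized=True),
        )
        for s in cohort.samples
        if s.records
    ]
    df = pd.DataFrame(rows)
    run.write_tsv(df, "diversity.tsv")
    trends = []
    for subset, grp in df.groupby("subset"):
        series = list(zip(grp.timepoint_months, grp.entropy))
        if len(series) >= 3 and grp.timepoint_months.nunique() >= 2:
            slope, r2, p = div.entropy_trend(series)
            trends.append(dict(subset=subset, slope=slope, adjusted_r2=r2, p_value=p))
    run.write_tsv(pd.DataFrame(trends), "diversity_trends.tsv")


def _stage_public(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("public")
    subset = opts.get("subset", "CD4_RO")
    timepoints = opts.get("timepoints", [0])
    min_reads = int(opts.get("min_reads", 2))
    min_subjects = int(opts.get("min_subjects", 2))
    rows, sharing_rows, conv_rows = [], [], []
    for tp in timepoints:
        public = pub.identify_public(cohort, subset, tp, min_reads, min_subjects)
        for key, subs in public.items():
            rows.append(
                dict(timepoint_months=tp, v_call=key.v_gene, j_call=key.j_gene,
                     junction_aa=key.cdr3_aa, n_subjects=len(subs),
                     subjects=";".join(sorted(subs)))
            )
        for combo, count in pub.sharing_distribution(public).items():
            sharing_rows.append(
                dict(timepoint_months=tp, subjects=";".join(sorted(combo)), n_clonotypes=count)
            )
        for s in cohort.samples_at(tp, subset):
            keys_here = [k for k, subs in public.items() if s.subject_id in subs]
            conv = pub.convergence_counts(s, keys_here)
            for key, n_nt in conv.items():
                conv_rows.append(
                    dict(timepoint_months=tp, subject_id=s.subject_id,
                         junction_aa=key.cdr3_aa, v_call=key.v_gene,
                         j_call=key.j_gene, n_nt_encodings=n_nt)
                )
    run.write_tsv(pd.DataFrame(rows), "public_clones.tsv")
    run.write_tsv(pd.DataFrame(sharing_rows), "public_sharing.tsv")
    run.write_tsv(pd.DataFrame(conv_rows), "public_convergence.tsv")
    allele = opts.get("hla_allele")
    if allele:
        carriers, others = pub.stratify_by_hla(cohort, allele)
        run.write_json(
            {
                "allele": allele,
                "carriers": [s.subject_id for s in carriers.subjects],
                "non_carriers": [s.subject_id for s in others.subjects],
            },
            "public_hla_strata.json",
        )


def _stage_annotate(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("annotate")
    db_path = opts.get("db")
    if not db_path:
        raise ConfigError("annotate stage requires 'db': path to antigen TSV")
    db = annot.read_antigen_db(db_path)
    rows = []
    for s in cohort.samples:
        if not s.records:
            continue
        subject = cohort.subject(s.subject_id)
        hits = annot.annotate_repertoire(s, db, subject)
        fr = annot.annotated_fraction(s, hits, by="reads")
        fc = annot.annotated_fraction(s, hits, by="clonotypes")
        for species in sorted(set(fr) | set(fc)):
            rows.append(
                dict(subject_id=s.subject_id, subset=s.subset,
                     timepoint_months=s.timepoint_months, antigen_species=species,
                     read_fraction=fr.get(species, 0.0),
                     clonotype_fraction=fc.get(species, 0.0),
                     n_annotated=len(hits))
            )
    run.write_tsv(pd.DataFrame(rows), "annotation.tsv")


def _stage_motifs(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("motifs")
    subset = opts.get("subset", "CD4_RO")
    timepoint = int(opts.get("timepoint", 6))
    alpha = float(opts.get("alpha_fisher", 1e-3))
    # pooled-baseline reference: baseline clonotypes of all subjects
    reference = [
        key
        for s in cohort.samples_at(0, subset)
        for key in trk.top_n_clones(s, len(s.records) + 1)
    ]
    if not reference:
        raise DependencyError("motifs stage needs baseline samples for the reference")
    v_usage = mot.reference_v_usage(reference)
    rows, summary = [], []
    for s in cohort.samples_at(timepoint, subset):
        sample_keys = list(trk.top_n_clones(s, len(s.records) + 1))
        clusters = mot.motif_fisher(sample_keys, reference, alpha_fisher=alpha)
        for cl in clusters:
            mot.v_bias_score(cl, v_usage)
            rows.append(
                dict(subject_id=s.subject_id, motif=cl.motif, k=len(cl.motif),
                     fisher_p=cl.fisher_p, v_bias_p=cl.v_bias_p, v_biased=cl.v_biased,
                     sample_count=cl.sample_count, reference_count=cl.reference_count,
                     sample_total=cl.sample_total, reference_total=cl.reference_total,
                     members=";".join(sorted(k.cdr3_aa for k in cl.member_keys)))
            )
        reads_frac, clone_frac = mot.enriched_motif_summary(clusters, s)
        summary.append(
            dict(subject_id=s.subject_id, subset=subset, timepoint_months=timepoint,
                 n_clusters=len(clusters), enriched_read_fraction=reads_frac,
                 enriched_clonotype_fraction=clone_frac)
        )
    run.write_tsv(pd.DataFrame(rows), "motif_clusters.tsv")
    run.write_tsv(pd.DataFrame(summary), "motif_summary.tsv")


def _stage_selection(run: _Run, opts: dict) -> None:
    cohort = run.require_cohort("selection")
    subset = opts.get("subset", "CD4_RO")
    timepoint = int(opts.get("timepoint", 0))
    baseline_size = int(opts.get("baseline_size", 20_000))
    l2 = float(opts.get("l2", 0.02))
    n_annotate = int(opts.get("n_annotate", 300))

    observed = [
        key
        for s in cohort.samples_at(timepoint, subset)
        for key in trk.top_n_clones(s, len(s.records) + 1)
    ]
    if not observed:
        raise DependencyError("selection stage found no observed clonotypes")
    model = sel.fit_selection(run.gen, observed, baseline_size, l2=l2, rng_seed=run.seed)
    model.to_json(run.out / "selection_model.json")
    run.outputs.append("selection_model.json")

    uniq = sorted(set(observed))[:n_annotate]
    rows = []
    for key in uniq:
        a = sel.ppost(model, run.gen, key)
        rows.append(
            dict(v_call=key.v_gene, j_call=key.j_gene, junction_aa=key.cdr3_aa,
                 pgen=a.pgen, ppost=a.ppost, q_ratio=a.q_ratio, bin=a.bin,
                 escapee=a.escapee, low_ppost=a.low_ppost)
        )
    run.write_tsv(pd.DataFrame(rows), "selection_annotations.tsv")


_STAGES = {
    "simulate": _stage_simulate,
    "clonotype": _stage_clonotype,
    "track": _stage_track,
    "diversity": _stage_diversity,
    "public": _stage_public,
    "annotate": _stage_annotate,
    "motifs": _stage_motifs,
    "selection": _stage_selection,
}
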