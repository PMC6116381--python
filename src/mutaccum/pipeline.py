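"""End-to-end orchestration: inputs -> classified calls -> rates,
comparisons, Monte Carlo null and metabolic tables.

A run consumes either a synthetic-experiment spec or user-supplied
FASTA/GFF/VCF files plus colony-count and assay tables, and emits
tab-separated report tables plus a JSON run log. Fully deterministic
given the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io_formats, mc_null, metabolic, rates, spectrum, stats_compare
from . import synthetic_data as synth
from .io_formats import AnnotatedGenome, MutationCall
from .metabolic import MetabolicAssay
from .rates import LineGenerationRecord

RATE_CATEGORIES = [
    "mutations_total", "bps_total", *spectrum.SIX_TYPES,
    "transitions", "transversions", "coding", "noncoding",
    "synonymous", "nonsynonymous", "conservative", "non_conservative",
    "indels_total", "gains", "losses", "ins1_AT", "ins1_GC",
    "del1_AT", "del1_GC", "indels_in_runs",
]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``synthetic`` (a dict of synthetic-experiment
    parameters) or ``inputs`` (paths to reference/annotation/VCFs plus
    line metadata tables) must be provided.
    """

    output_dir: str = "mutaccum_out"
    synthetic: dict | None = None
    inputs: dict | None = None
    min_depth: int = 20
    keep_missing_depth: bool = False
    denominator: str = "genome_length"      # or a number of callable sites
    mc_trials: int = 1000
    mc_composition_blind: bool = False
    alpha: float = 0.05
    test_flavor: str = "welch"              # or "pooled"
    direction: str = "increasing"
    run_min_len: int = 3
    seed: int = 0
    group_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'synthetic' or 'inputs'")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_flavor not in ("welch", "pooled"):
            raise ValueError("test_flavor must be 'welch' or 'pooled'")
        if self.mc_trials < 1:
            raise ValueError("mc_trials must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_synthetic(cfg: RunConfig):
    params = dict(cfg.synthetic or {})
    gs_kwargs = params.get("genome", {})
    genome_spec = synth.GenomeSpec(seed=cfg.seed, **gs_kwargs)
    genome = synth.generate_genome(genome_spec)

    design_kwargs = params.get("design", {})
    if "groups" in design_kwargs:
        design_kwargs["groups"] = {
            name: synth.GroupDesign(**g) for name, g in design_kwargs["groups"].items()
        }
    design = synth.ExperimentDesign(seed=cfg.seed + 1, **design_kwargs)

    rate_specs = synth.default_rate_specs()
    if "rates" in params:
        rate_specs = {
            name: synth.RateSpec(**r) for name, r in params["rates"].items()
        }
    exp = synth.simulate_ma_lines(genome, rate_specs, design, run_min_len=cfg.run_min_len)
    assays = synth.simulate_assays(
        design,
        our_truth=params.get("our_truth"),
        noise_cv=params.get("assay_noise_cv", 0.08),
    )
    all_calls = [c for line in exp.calls.values() for c in line]
    return genome, all_calls, exp.records, exp.line_groups, assays, design


def _load_real(cfg: RunConfig):
    paths = cfg.inputs or {}
    genome = io_formats.parse_reference(paths["fasta"], paths["gff"])
    line_groups: dict[str, str] = {}
    all_calls: list[MutationCall] = []
    ancestor: list[MutationCall] = []
    if paths.get("ancestor_vcf"):
        ancestor, _ = io_formats.parse_calls(paths["ancestor_vcf"], "ancestor")
    for line_id, entry in paths["lines"].items():
        line_groups[line_id] = entry["group"]
        calls, _skipped = io_formats.parse_calls(entry["vcf"], line_id)
        if ancestor:
            calls, _n = io_formats.subtract_ancestor(calls, ancestor)
        all_calls.extend(calls)
    colony = pd.read_csv(paths["colony_counts"], sep="\t")
    records = {}
    for line_id, sub in colony.groupby("line_id"):
        records[line_id] = LineGenerationRecord(
            str(line_id),
            dict(zip(sub["bottleneck"].astype(int), sub["colony_cells"].astype(float))),
            n_bottlenecks=int(paths.get("n_bottlenecks", 30)),
        )
    assays = read_assay_table(paths["assays"]) if paths.get("assays") else []
    return genome, all_calls, records, line_groups, assays, None


def read_assay_table(path: str | Path) -> list[MetabolicAssay]:
    df = pd.read_csv(path, sep="\t")
    return [
        MetabolicAssay(
            assay_id=str(r.assay_id), group=str(r.group),
            o2_fraction_before=float(r.o2_fraction_before),
            o2_fraction_after=float(r.o2_fraction_after),
            gas_volume_l=float(r.gas_volume_l), temperature_k=float(r.temperature_k),
            pressure_atm=float(r.pressure_atm), colony_count=int(r.colony_count),
            cells_per_colony=float(r.cells_per_colony),
            qc_discard=bool(r.qc_discard),
        )
        for r in df.itertuples()
    ]


def write_assay_table(assays: list[MetabolicAssay], path: str | Path) -> None:
    pd.DataFrame([a.__dict__ for a in assays]).to_csv(path, sep="\t", index=False)


def write_colony_table(
    records: dict[str, LineGenerationRecord], line_groups: dict[str, str], path: str | Path
) -> None:
    rows = [
        dict(line_id=lid, group=line_groups.get(lid, ""), bottleneck=b, colony_cells=c)
        for lid, rec in sorted(records.items())
        for b, c in sorted(rec.colony_cells.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_calls(
    calls: list[MutationCall], genome: AnnotatedGenome, run_min_len: int = 3
) -> list[tuple[MutationCall, spectrum.BPSClass | spectrum.IndelClass]]:
    out = []
    for c in calls:
        if c.kind == "SNV":
            out.append((c, spectrum.classify_bps(c, genome)))
        else:
            out.append((c, spectrum.classify_indel(c, genome, run_min_len=run_min_len)))
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full analysis and write the report bundle.

    Emits classified_mutations.tsv, spectrum_counts.tsv, rates.tsv,
    rate_summary.tsv, comparisons.tsv, letters.tsv, mc_null.tsv,
    metabolic.tsv, filter_report.tsv and run_log.json in the output
    directory, and returns the main tables in memory.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic is not None:
        genome, all_calls, records, line_groups, assays, _design = _load_synthetic(cfg)
    else:
        genome, all_calls, records, line_groups, assays, _design = _load_real(cfg)

    kept, filt = io_formats.filter_by_depth(
        all_calls, min_depth=cfg.min_depth, keep_missing=cfg.keep_missing_depth
    )
    (out / "filter_report.tsv").write_text(filt.to_table())

    classified = classify_calls(kept, genome, run_min_len=cfg.run_min_len)
    spectrum.classified_table(classified).to_csv(
        out / "classified_mutations.tsv", sep="\t", index=False
    )
    counts = spectrum.tabulate_spectrum(classified, line_groups)
    counts.per_line.to_csv(out / "spectrum_counts.tsv", sep="\t")

    if cfg.denominator == "genome_length":
        sites = float(len(genome))
    else:
        sites = float(cfg.denominator)
    generations = {lid: rec.total_generations for lid, rec in records.items()}
    rate_table = rates.per_line_rate_table(
        counts.per_line, line_groups, generations, sites, categories=RATE_CATEGORIES
    )
    rate_table.to_csv(out / "rates.tsv", sep="\t", index=False)
    summary = rates.summarize_rates(rate_table)
    summary.to_csv(out / "rate_summary.tsv", sep="\t", index=False)

    group_order = cfg.group_order or sorted(set(line_groups.values()))
    cmp_data = rate_table.rename(columns={"rate": "value"})[["group", "category", "value"]]
    comparison = stats_compare.compare_groups(
        cmp_data, group_order=group_order, alpha=cfg.alpha,
        direction=cfg.direction, pooled=cfg.test_flavor == "pooled",
    )
    comparison.contrasts.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    comparison.letters.to_csv(out / "letters.tsv", sep="\t", index=False)

    mc_rows = []
    per_group = counts.per_group
    for gi, group in enumerate(group_order):
        if group not in per_group.index:
            continue
        row = per_group.loc[group]
        six_counts = {t: int(row[t]) for t in spectrum.SIX_TYPES}
        if sum(six_counts.values()) == 0:
            continue
        spec = mc_null.MCNullSpec(
            counts=six_counts, n_trials=cfg.mc_trials, seed=cfg.seed + 100 + gi,
            composition_blind=cfg.mc_composition_blind,
        )
        observed = {k: int(row[k]) for k in (
            "coding", "noncoding", "synonymous", "nonsynonymous",
            "conservative", "non_conservative")}
        res = mc_null.simulate_null_spectrum(genome, spec, observed=observed)
        for _, r in res.tests.iterrows():
            mc_rows.append(dict(group=group, **r.to_dict()))
    mc_df = pd.DataFrame(mc_rows)
    mc_df.to_csv(out / "mc_null.tsv", sep="\t", index=False)

    met_rows = []
    our_by_group = metabolic.summarize_our(assays) if assays else {}
    mu_total = summary[summary["category"] == "mutations_total"].set_index("group")
    for group, est in our_by_group.items():
        mu = float(mu_total.loc[group, "mean"]) if group in mu_total.index else float("nan")
        met_rows.append(dict(
            group=group, n_assays=est.n, our_mean=est.mean, our_sem=est.sem,
            our_cl95=est.cl_halfwidth, mu_mean=mu,
            mutations_per_mol_o2=metabolic.mutation_per_energy(mu, est.mean),
        ))
    met_df = pd.DataFrame(met_rows)
    met_df.to_csv(out / "metabolic.tsv", sep="\t", index=False)

    log = dict(
        version=__version__, seed=cfg.seed, genome_id=genome.id,
        genome_length=len(genome), coding_fraction=genome.coding_fraction,
        gc_fraction=genome.gc_fraction, n_lines=len(line_groups),
        n_calls_total=len(all_calls), n_calls_kept=len(kept),
        removed_low_depth=sum(filt.removed_low_depth.values()),
        removed_missing_depth=sum(filt.removed_missing_depth.values()),
        min_depth=cfg.min_depth, denominator_sites=sites,
        mc_trials=cfg.mc_trials, alpha=cfg.alpha, test_flavor=cfg.test_flavor,
    )
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")

    return dict(
        genome=genome, counts=counts, rate_table=rate_table, rate_summary=summary,
        comparison=comparison, mc_null=mc_df, metabolic=met_df, run_log=log,
    )
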