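"""Regenerate the small bundled fixture dataset (synthetic, 20 kb, 6 lines).

Run from the repository root:  python scripts/make_fixture.py
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from mutaccum import io_formats, pipeline, synthetic_data as synth

OUT = Path(__file__).resolve().parents[1] / "src" / "mutaccum" / "data" / "fixture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = synth.generate_genome(synth.GenomeSpec(
        length=20_000, coding_fraction_target=0.85, gc_target=0.5077,
        n_genes=14, homopolymer_spec=(("A", 6, 6), ("G", 5, 6)), seed=42,
    ))
    design = synth.ExperimentDesign(
        groups={
            "25C": synth.GroupDesign(2, 72.0, 25.0, 4),
            "28C": synth.GroupDesign(2, 48.0, 28.0, 4),
            "37C": synth.GroupDesign(2, 24.0, 37.0, 4),
        },
        seed=43,
    )
    # per-nt rates scaled up so a 20 kb genome accumulates workable counts
    scale = 250.0
    rates = {
        name: dataclasses.replace(
            spec,
            six_type={c: r * scale for c, r in spec.six_type.items()},
            indel={c: r * scale for c, r in spec.indel.items()},
        )
        for name, spec in synth.default_rate_specs().items()
    }
    exp = synth.simulate_ma_lines(genome, rates, design)
    assays = synth.simulate_assays(design, noise_cv=0.08)

    io_formats.write_reference(genome, OUT / "genome.fasta", OUT / "genome.gff3")
    for lid, calls in exp.calls.items():
        io_formats.write_calls(calls, genome, OUT / f"{lid}.vcf")
    pipeline.write_colony_table(exp.records, exp.line_groups, OUT / "colony_counts.tsv")
    pipeline.write_assay_table(assays, OUT / "assays.tsv")
    n_calls = sum(len(v) for v in exp.calls.values())
    print(f"fixture written to {OUT} ({len(exp.calls)} lines, {n_calls} calls)")


if __name__ == "__main__":
    main()
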