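"""mutaccum: mutation-accumulation sequencing analysis.

Estimate per-site per-generation mutation rates from bottlenecked MA
lines, classify the full molecular spectrum of substitutions and small
indels, test spectrum ratios against a Monte Carlo placement null,
compare temperature groups, and normalize mutation rate by metabolic
rate (oxygen uptake per cell division).
"""

__version__ = "0.1.0"

from pathlib import Path


def fixture_dir() -> Path:
    """Directory of the bundled 20 kb synthetic fixture dataset."""
    return Path(__file__).parent / "data" / "fixture"


from .io_formats import AnnotatedGenome, Gene, MutationCall, parse_calls, parse_reference
from .metabolic import MetabolicAssay, mutation_per_energy, oxygen_uptake_rate
from .rates import (
    LineGenerationRecord,
    RateEstimate,
    generations_per_passage,
    growth_rate,
    mutation_rate,
    rate_summary,
    total_generations,
)
from .spectrum import BPSClass, IndelClass, classify_bps, classify_indel, six_type_of

__all__ = [
    "AnnotatedGenome", "Gene", "MutationCall", "parse_calls", "parse_reference",
    "MetabolicAssay", "mutation_per_energy", "oxygen_uptake_rate",
    "LineGenerationRecord", "RateEstimate", "generations_per_passage",
    "growth_rate", "mutation_rate", "rate_summary", "total_generations",
    "BPSClass", "IndelClass", "classify_bps", "classify_indel", "six_type_of",
    "fixture_dir", "__version__",
]
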