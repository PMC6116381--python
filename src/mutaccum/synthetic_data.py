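"""Synthetic annotated genomes, MA experiments and physiological assays.

The generator emulates the statistical structure of a bacterial MA +
whole-genome-sequencing study: an annotated genome (default 50.77% GC,
majority coding), lines propagated through single-colony bottlenecks
(default 30, with ~2^27 cells per colony so ~27 generations per
passage), Poisson mutation supply per six-type substitution class plus
1-4 bp indels with homopolymer hotspots, and airtight-container oxygen
assays with multiplicative measurement noise. Every operation is a pure
function of its inputs and a seed.

Default rates are synthetic but sized like a mismatch-repair-deficient
(mutS) mutator strain: total rate ~8e-9 per nt per generation at 37 C,
scaled down at cooler temperatures, transition-dominated spectra and an
indel rate about one fifth of the BPS rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotatedGenome, Gene, MutationCall
from .metabolic import R_L_ATM_PER_K_MOL, MetabolicAssay
from .rates import LineGenerationRecord
from .spectrum import SIX_TYPES

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic annotated genome."""

    length: int = 100_000
    coding_fraction_target: float = 0.85
    gc_target: float = 0.5077
    n_genes: int = 80
    homopolymer_spec: tuple[tuple[str, int, int], ...] = ()   # (base, run_len, count)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not 0 <= self.coding_fraction_target <= 1:
            raise ValueError("coding_fraction_target must be in [0, 1]")
        if not 0 <= self.gc_target <= 1:
            raise ValueError("gc_target must be in [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for base, run_len, count in self.homopolymer_spec:
            if base not in _BASES or run_len < 1 or count < 1:
                raise ValueError(f"bad homopolymer spec entry {(base, run_len, count)}")


@dataclass(frozen=True)
class RateSpec:
    """Mutation supply per nucleotide per generation.

    ``six_type`` rates are per eligible site (a site whose strand-
    collapsed pair matches the class source pair); ``indel`` rates are
    per site, keyed by (size 1-4, "gain"/"loss"). ``in_run_multiplier``
    scales indel rates inside homopolymer runs; ``coding_bias`` scales
    substitution rates at coding sites (1 = unbiased placement).
    """

    six_type: dict[str, float] = field(default_factory=dict)
    indel: dict[tuple[int, str], float] = field(default_factory=dict)
    in_run_multiplier: float = 1.0
    coding_bias: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.six_type) - set(SIX_TYPES)
        if unknown:
            raise ValueError(f"unknown six-type class(es): {sorted(unknown)}")
        if any(r < 0 for r in self.six_type.values()):
            raise ValueError("substitution rates must be >= 0")
        for (size, direction), r in self.indel.items():
            if not 1 <= size <= 4 or direction not in ("gain", "loss") or r < 0:
                raise ValueError(f"bad indel rate entry {(size, direction)}: {r}")
        if self.in_run_multiplier < 1:
            raise ValueError("in_run_multiplier must be >= 1")
        if self.coding_bias < 0:
            raise ValueError("coding_bias must be >= 0")


@dataclass(frozen=True)
class GroupDesign:
    """One temperature group of the experiment."""

    n_lines: int = 20
    incubation_hours: float = 24.0
    temperature_c: float = 37.0
    n_assays: int = 12


@dataclass(frozen=True)
class ExperimentDesign:
    """The bottleneck design shared by all groups."""

    groups: dict[str, GroupDesign] = field(default_factory=lambda: {
        "25C": GroupDesign(20, 72.0, 25.0, 14),
        "28C": GroupDesign(20, 48.0, 28.0, 11),
        "37C": GroupDesign(20, 24.0, 37.0, 12),
    })
    n_bottlenecks: int = 30
    colony_cells_mean: float = float(2 ** 27)
    colony_cells_cv: float = 0.1
    measurement_bottlenecks: tuple[int, ...] = (1, 11, 21)
    depth_mean: float = 163.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bottlenecks < 1:
            raise ValueError("n_bottlenecks must be >= 1")
        if self.colony_cells_mean < 2:
            raise ValueError("colony_cells_mean must be >= 2")
        if self.colony_cells_cv < 0:
            raise ValueError("colony_cells_cv must be >= 0")
        for m in self.measurement_bottlenecks:
            if not 1 <= m <= self.n_bottlenecks:
                raise ValueError("measurement bottlenecks must lie within the design")


def default_rate_specs() -> dict[str, RateSpec]:
    """Per-temperature default rates (synthetic, mutator-strain sized).

    Total rate at 37 C is ~8.1e-9 per nt per generation, with 25 and
    28 C at 0.63x and 0.62x; transitions make up 87% of BPSs at 25 C and
    96% at 28/37 C; indels run at ~1/5 of the BPS rate with gains more
    frequent than losses.
    """
    def spec(total_mu: float, ts_fraction: float) -> RateSpec:
        bps_mu = total_mu * 5 / 6
        indel_mu = total_mu / 6
        # per-eligible-site class rates: total BPS mu = sum(class rates)/2
        # for a balanced-composition genome
        ts_sum = 2 * bps_mu * ts_fraction
        tv_sum = 2 * bps_mu * (1 - ts_fraction)
        six = {
            "G:C>A:T": 0.55 * ts_sum, "A:T>G:C": 0.45 * ts_sum,
            "A:T>C:G": tv_sum / 4, "G:C>T:A": tv_sum / 4,
            "A:T>T:A": tv_sum / 4, "G:C>C:G": tv_sum / 4,
        }
        split = {(1, "gain"): 0.45, (1, "loss"): 0.30,
                 (2, "gain"): 0.08, (2, "loss"): 0.07,
                 (3, "gain"): 0.03, (3, "loss"): 0.03,
                 (4, "gain"): 0.02, (4, "loss"): 0.02}
        # normalize base rates so the total indel supply, including the
        # in-run multiplier, stays near indel_mu on a random iid genome:
        # 15.625% of such a sequence lies in runs >= 3, so the effective
        # site count is inflated by 1 + (8 - 1) * 0.15625
        run_inflation = 1 + (8.0 - 1.0) * 0.15625
        indel = {k: f * indel_mu / run_inflation for k, f in split.items()}
        return RateSpec(six_type=six, indel=indel, in_run_multiplier=8.0)

    mu_37 = 8.1e-9
    return {
        "25C": spec(0.63 * mu_37, 0.87),
        "28C": spec(0.62 * mu_37, 0.96),
        "37C": spec(mu_37, 0.96),
    }


#: synthetic per-group OUR truths (mol O2 per cell division), sized so the
#: mutation-per-energy ratio is ~1e6 mutations per nt per mol O2
DEFAULT_OUR_TRUTH = {"25C": 4.80e-15, "28C": 4.95e-15, "37C": 7.50e-15}


# ---------------------------------------------------------------------------
# genome generation

def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Generate an annotated genome matching the spec.

    Genes are tiled non-overlapping with alternating strands, each a
    valid CDS (start codon, stop codon, no internal stops, length
    divisible by 3); requested homopolymer runs are planted in
    intergenic sequence. Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    gc = spec.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    p_coding = _stop_compensated_probs(gc)

    seq = rng.choice(np.frombuffer(_BASES.encode(), dtype=np.uint8), size=L, p=p)

    genes: list[Gene] = []
    if spec.n_genes > 0:
        coding_total = int(round(spec.coding_fraction_target * L))
        gene_len = max(6, (coding_total // spec.n_genes) // 3 * 3)
        intergenic = L - gene_len * spec.n_genes
        if intergenic < spec.n_genes + 1:
            raise ValueError(
                "infeasible genome spec: cannot tile "
                f"{spec.n_genes} genes of {gene_len} bp into {L} bp "
                "with intergenic gaps"
            )
        gap_sizes = _split_evenly(intergenic, spec.n_genes + 1)
        pos = 0
        for i in range(spec.n_genes):
            pos += gap_sizes[i]
            start = pos + 1                      # 1-based
            end = pos + gene_len
            strand = "+" if i % 2 == 0 else "-"
            cds = _random_cds(rng, gene_len, p_coding)
            if strand == "-":
                cds = _revcomp_bytes(cds)
            seq[pos : pos + gene_len] = cds
            genes.append(Gene(f"gene_{i + 1:04d}", start, end, strand))
            pos = end

    sequence = seq.tobytes().decode()
    sequence = _plant_homopolymers(rng, sequence, genes, spec.homopolymer_spec)
    return AnnotatedGenome(id=f"synthetic_{spec.seed}", sequence=sequence, genes=genes)


def _stop_compensated_probs(gc_target: float) -> np.ndarray:
    """Per-base probabilities whose stop-codon-rejected codons hit the GC
    target.

    Stop codons (TAA/TAG/TGA) are AT-rich, so rejecting internal stops
    enriches coding sequence in GC; the pre-rejection composition is
    solved so the conditional GC equals the target.
    """
    from scipy.optimize import brentq

    def conditional_gc(g: float) -> float:
        pa = pt = (1 - g) / 2
        pg = g / 2
        p_stop = pt * pa * (pa + 2 * pg)
        gc_in_stops = 2 * pt * pa * pg       # TAG and TGA carry one G each
        return (3 * g - gc_in_stops) / (3 * (1 - p_stop))

    if gc_target in (0.0, 1.0):
        g = gc_target
    else:
        g = brentq(lambda x: conditional_gc(x) - gc_target, 1e-9, 1 - 1e-9)
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _random_cds(rng: np.random.Generator, length: int, p: np.ndarray) -> np.ndarray:
    """Sense-strand CDS bytes: start codon, stop-free body, stop codon."""
    n_codons = length // 3
    body = rng.choice(np.frombuffer(_BASES.encode(), dtype=np.uint8),
                      size=(n_codons, 3), p=p)
    stop_bytes = [np.frombuffer(s.encode(), dtype=np.uint8) for s in _STOPS]
    is_stop = np.zeros(n_codons, dtype=bool)
    for sb in stop_bytes:
        is_stop |= (body == sb).all(axis=1)
    while is_stop[1:-1].any():                   # resample internal stops
        idx = np.flatnonzero(is_stop)
        idx = idx[(idx > 0) & (idx < n_codons - 1)]
        body[idx] = rng.choice(np.frombuffer(_BASES.encode(), dtype=np.uint8),
                               size=(idx.size, 3), p=p)
        is_stop = np.zeros(n_codons, dtype=bool)
        for sb in stop_bytes:
            is_stop |= (body == sb).all(axis=1)
    body[0] = np.frombuffer(b"ATG", dtype=np.uint8)
    body[-1] = stop_bytes[rng.integers(len(_STOPS))]
    return body.reshape(-1)


_COMP_BYTES = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_BYTES[_a] = _b


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return _COMP_BYTES[arr][::-1]


def _plant_homopolymers(
    rng: np.random.Generator,
    sequence: str,
    genes: list[Gene],
    homopolymer_spec: tuple[tuple[str, int, int], ...],
) -> str:
    if not homopolymer_spec:
        return sequence
    L = len(sequence)
    # intergenic intervals (0-based half-open)
    free: list[tuple[int, int]] = []
    pos = 0
    for g in genes:
        if g.start - 1 > pos:
            free.append((pos, g.start - 1))
        pos = g.end
    if pos < L:
        free.append((pos, L))
    seq = bytearray(sequence.encode())
    used: list[tuple[int, int]] = []
    for base, run_len, count in homopolymer_spec:
        placed = 0
        candidates = [iv for iv in free if iv[1] - iv[0] >= run_len]
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 1000 * count or not candidates:
                raise ValueError(
                    f"cannot place {count} homopolymer run(s) of {base}x{run_len}: "
                    "insufficient intergenic space"
                )
            lo, hi = candidates[int(rng.integers(len(candidates)))]
            start = int(rng.integers(lo, hi - run_len + 1))
            span = (start, start + run_len)
            if any(not (span[1] <= a or span[0] >= b) for a, b in used):
                continue
            seq[span[0] : span[1]] = base.encode() * run_len
            used.append(span)
            placed += 1
    return seq.decode()


# ---------------------------------------------------------------------------
# MA-line simulation

@dataclass
class SimulatedExperiment:
    """Per-line calls, generation records and group membership."""

    calls: dict[str, list[MutationCall]]
    records: dict[str, LineGenerationRecord]
    line_groups: dict[str, str]
    true_generations: dict[str, float]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _run_mask(sequence: str, run_min_len: int = 3) -> np.ndarray:
    """True at sites inside homopolymer runs of >= run_min_len."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    mask = np.zeros(arr.size, dtype=bool)
    if arr.size == 0:
        return mask
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    for s, e in zip(starts, ends):
        if e - s >= run_min_len:
            mask[s:e] = True
    return mask


def _weighted_sample(
    rng: np.random.Generator, pool: np.ndarray, weights: np.ndarray | None, k: int
) -> np.ndarray:
    """k distinct pool members; Gumbel top-k when weights are non-uniform."""
    if k == 0:
        return pool[:0]
    if k > pool.size:
        raise ValueError("cannot place more mutations than eligible sites")
    if weights is None:
        if k < pool.size // 50:
            idx = rng.integers(0, pool.size, size=int(k * 1.2) + 8)
            uniq = np.unique(idx)
            while uniq.size < k:
                uniq = np.unique(np.concatenate([uniq, rng.integers(0, pool.size, size=k)]))
            rng.shuffle(uniq)
            return pool[uniq[:k]]
        return rng.choice(pool, size=k, replace=False)
    keys = np.log(weights) + rng.gumbel(size=pool.size)
    return pool[np.argpartition(-keys, k - 1)[:k]]


def simulate_ma_lines(
    genome: AnnotatedGenome,
    rates: RateSpec | dict[str, RateSpec],
    design: ExperimentDesign,
    run_min_len: int = 3,
) -> SimulatedExperiment:
    """Simulate neutral mutation accumulation for every line.

    Per line: colony sizes are drawn lognormally at each measurement
    bottleneck; the true generation count is the window-weighted sum of
    log2(cells) (identical to the estimator, so recovery checks are
    self-consistent); each six-type class contributes a Poisson count
    with mean rate x effective eligible sites x generations and is
    placed uniformly (weighted by ``coding_bias``) without replacement
    within the line; indels are placed with ``in_run_multiplier``
    weighting inside homopolymer runs. Read depths are Poisson around
    the design's mean depth. No selection is modeled.
    """
    rng = np.random.default_rng(design.seed)
    seq = genome.sequence
    L = len(genome)
    base_of = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_of[ord(b)] = i
    ref_idx = base_of[np.frombuffer(seq.encode(), dtype=np.uint8)]
    coding = genome.coding_mask
    runs = _run_mask(seq, run_min_len)

    pools = {
        "AT": np.flatnonzero((ref_idx == 0) | (ref_idx == 3)),
        "GC": np.flatnonzero((ref_idx == 1) | (ref_idx == 2)),
    }
    from .mc_null import _ALT_OF, _CLASS_PAIR

    calls: dict[str, list[MutationCall]] = {}
    records: dict[str, LineGenerationRecord] = {}
    line_groups: dict[str, str] = {}
    true_G: dict[str, float] = {}

    for group_name, gd in design.groups.items():
        gspec = rates[group_name] if isinstance(rates, dict) else rates
        # per-class effective weights
        sub_pools: dict[str, tuple[np.ndarray, np.ndarray | None, float]] = {}
        for cls, rate in gspec.six_type.items():
            pool = pools[_CLASS_PAIR[cls]]
            if rate > 0 and pool.size == 0:
                raise ValueError(f"class {cls} has positive rate but no eligible sites")
            if gspec.coding_bias == 1.0:
                w, eff = None, float(pool.size)
            else:
                w = np.where(coding[pool], gspec.coding_bias, 1.0)
                eff = float(w.sum())
            sub_pools[cls] = (pool, w, eff)
        indel_pool = np.arange(L)
        if gspec.in_run_multiplier == 1.0:
            indel_w, indel_eff = None, float(L)
        else:
            indel_w = np.where(runs, gspec.in_run_multiplier, 1.0)
            indel_eff = float(indel_w.sum())

        for i in range(gd.n_lines):
            lid = f"{group_name}_line{i + 1:02d}"
            line_groups[lid] = group_name
            cells = _lognormal(rng, design.colony_cells_mean, design.colony_cells_cv,
                               len(design.measurement_bottlenecks))
            colony_cells = dict(zip(design.measurement_bottlenecks, map(float, cells)))
            rec = LineGenerationRecord(lid, colony_cells, design.n_bottlenecks)
            records[lid] = rec
            G = rec.total_generations
            true_G[lid] = G

            line_calls: list[MutationCall] = []
            taken: set[int] = set()

            for cls, rate in gspec.six_type.items():
                pool, w, eff = sub_pools[cls]
                n = int(rng.poisson(rate * eff * G))
                if n == 0:
                    continue
                placed = _weighted_sample(rng, pool, w, n)
                for p0 in placed:
                    p0 = int(p0)
                    if p0 in taken:
                        continue        # recurrent hits are vanishingly rare
                    taken.add(p0)
                    ref = seq[p0]
                    alt = _BASES[_ALT_OF[cls][base_of[ord(ref)]]]
                    line_calls.append(MutationCall(
                        lid, p0 + 1, ref, alt,
                        depth=int(rng.poisson(design.depth_mean)),
                    ))

            for (size, direction), rate in gspec.indel.items():
                n = int(rng.poisson(rate * indel_eff * G))
                if n == 0:
                    continue
                placed = _weighted_sample(rng, indel_pool, indel_w, n)
                for p0 in placed:
                    p0 = int(p0)
                    if p0 in taken or p0 < 1 or p0 + size > L:
                        continue
                    taken.add(p0)
                    depth = int(rng.poisson(design.depth_mean))
                    if direction == "loss":
                        line_calls.append(MutationCall(
                            lid, p0 + 1, seq[p0 : p0 + size], "", depth=depth))
                    else:
                        if runs[p0]:
                            ins = seq[p0] * size   # extend the run
                        else:
                            ins = "".join(
                                _BASES[j] for j in rng.integers(0, 4, size=size))
                        line_calls.append(MutationCall(lid, p0 + 1, "", ins, depth=depth))

            line_calls.sort(key=lambda c: c.position)
            calls[lid] = line_calls

    return SimulatedExperiment(calls=calls, records=records,
                               line_groups=line_groups, true_generations=true_G)


# ---------------------------------------------------------------------------
# physiological assays

#: fixed assay-rig parameters: headspace volume, starting O2 fraction,
#: pressure, and the colony census per plate
ASSAY_GAS_VOLUME_L = 0.5
ASSAY_O2_BEFORE = 0.2095
ASSAY_PRESSURE_ATM = 1.0
ASSAY_COLONIES_PER_PLATE = 150.0


def simulate_assays(
    design: ExperimentDesign,
    our_truth: dict[str, float] | None = None,
    noise_cv: float = 0.08,
    seed: int | None = None,
) -> list[MetabolicAssay]:
    """Simulate oxygen-uptake assays for every group.

    Each assay grows a plate of colonies, consumes ``our_truth`` mol O2
    per cell division perturbed by multiplicative lognormal noise of the
    stated CV, and reports headspace O2 fractions consistent with the
    ideal-gas contract of the metabolic module (a noiseless simulation
    inverts exactly to the truth).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    truth = our_truth or DEFAULT_OUR_TRUTH
    for g, v in truth.items():
        if v <= 0:
            raise ValueError(f"our_truth for {g} must be > 0")
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    assays: list[MetabolicAssay] = []
    for group_name, gd in design.groups.items():
        temp_k = gd.temperature_c + 273.15
        for i in range(gd.n_assays):
            colonies = max(1, int(rng.poisson(ASSAY_COLONIES_PER_PLATE)))
            cells = float(_lognormal(rng, design.colony_cells_mean,
                                     design.colony_cells_cv, 1)[0])
            divisions = colonies * (cells - 1)
            noise = float(_lognormal(rng, 1.0, noise_cv, 1)[0]) if noise_cv else 1.0
            mol = truth[group_name] * divisions * noise
            delta = mol * R_L_ATM_PER_K_MOL * temp_k / (
                ASSAY_PRESSURE_ATM * ASSAY_GAS_VOLUME_L)
            after = ASSAY_O2_BEFORE - delta
            if after < 0:
                raise ValueError("simulated O2 consumption exceeds the headspace supply")
            assays.append(MetabolicAssay(
                assay_id=f"{group_name}_assay{i + 1:02d}", group=group_name,
                o2_fraction_before=ASSAY_O2_BEFORE, o2_fraction_after=after,
                gas_volume_l=ASSAY_GAS_VOLUME_L, temperature_k=temp_k,
                pressure_atm=ASSAY_PRESSURE_ATM, colony_count=colonies,
                cells_per_colony=cells, qc_discard=False,
            ))
    return assays
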