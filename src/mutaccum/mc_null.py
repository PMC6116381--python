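"""Monte Carlo null model for the placement of base-pair substitutions.

With the total number of BPSs fixed at the observed counts and the
six-type composition fixed at the observed values, mutations are placed
uniformly at random on eligible sites (sites whose strand-collapsed base
pair matches the class's source pair), classified, and tallied over many
trials. The trial means are the expected spectrum ratios under random
placement; observed ratios are compared with a Pearson chi-squared test
and with the empirical Monte Carlo tail probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotatedGenome
from .spectrum import (
    SITE_NONSYN_CONSERVATIVE,
    SITE_NONSYN_NONCONSERVATIVE,
    SITE_SYNONYMOUS,
    SIX_TYPES,
    site_effect_table,
)

# per class: source-pair ('AT' or 'GC') and genomic ref-base -> alt-base index
# over the ACGT alphabet (A=0, C=1, G=2, T=3)
_CLASS_PAIR = {
    "A:T>G:C": "AT", "A:T>C:G": "AT", "A:T>T:A": "AT",
    "G:C>A:T": "GC", "G:C>T:A": "GC", "G:C>C:G": "GC",
}
_ALT_OF = {
    # ref base index -> alt base index, strand-collapsed
    "A:T>G:C": {0: 2, 3: 1},  # A->G, T->C
    "A:T>C:G": {0: 1, 3: 2},  # A->C, T->G
    "A:T>T:A": {0: 3, 3: 0},  # A->T, T->A
    "G:C>A:T": {2: 0, 1: 3},  # G->A, C->T
    "G:C>T:A": {2: 3, 1: 0},  # G->T, C->A
    "G:C>C:G": {2: 1, 1: 2},  # G->C, C->G
}


@dataclass(frozen=True)
class MCNullSpec:
    """Observed six-type counts to be randomly re-placed."""

    counts: dict[str, int]
    n_trials: int = 1000
    seed: int = 0
    composition_blind: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(SIX_TYPES)
        if unknown:
            raise ValueError(f"unknown six-type class(es): {sorted(unknown)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class MCNullResult:
    """Per-trial tallies, expected ratios and observed-vs-expected tests."""

    trials: pd.DataFrame                # one row per trial
    expected: dict[str, float]          # trial-mean proportions
    observed: dict[str, int] | None
    tests: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_table(self) -> pd.DataFrame:
        rows = [dict(quantity=k, expected=v) for k, v in self.expected.items()]
        return pd.DataFrame(rows)


def _sample_without_replacement(rng: np.random.Generator, pool: np.ndarray, k: int) -> np.ndarray:
    """k distinct elements of pool; rejection sampling when k << |pool|."""
    n = pool.size
    if k > n:
        raise ValueError("cannot sample more sites than the pool holds")
    if k == 0:
        return pool[:0]
    if k < n // 50:
        idx = rng.integers(0, n, size=int(k * 1.2) + 8)
        uniq = pd.unique(idx)
        while uniq.size < k:
            extra = rng.integers(0, n, size=k)
            uniq = pd.unique(np.concatenate([uniq, extra]))
        return pool[uniq[:k]]
    return rng.choice(pool, size=k, replace=False)


def simulate_null_spectrum(
    genome: AnnotatedGenome,
    spec: MCNullSpec,
    observed: dict[str, int] | None = None,
) -> MCNullResult:
    """Place the observed BPS counts at random and tally consequences.

    Each trial places every class's count uniformly without replacement
    on that class's eligible sites (A/T sites for A:T>*, G/C sites for
    G:C>*) and classifies every placement as coding/noncoding and, for
    coding sites, synonymous/nonsynonymous and conservative/
    non-conservative. ``observed`` may carry the observed category counts
    (keys among coding, noncoding, synonymous, nonsynonymous,
    conservative, non_conservative) to be tested against the expectation.

    In ``composition_blind`` mode sites are drawn from the whole genome
    regardless of base identity, as a sensitivity analysis; only the
    coding/noncoding contrast is defined there since the alt base is
    unconstrained on non-matching sites.
    """
    rng = np.random.default_rng(spec.seed)
    seq_idx = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    base_of = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        base_of[ord(b)] = i
    ref_idx = base_of[seq_idx]
    coding = genome.coding_mask
    effect = None if spec.composition_blind else site_effect_table(genome)

    pools = {
        "AT": np.flatnonzero((ref_idx == 0) | (ref_idx == 3)),
        "GC": np.flatnonzero((ref_idx == 1) | (ref_idx == 2)),
    }
    all_sites = np.arange(len(genome))

    active = [(c, n) for c, n in spec.counts.items() if n > 0]
    if not spec.composition_blind:
        for cls, n in active:
            if pools[_CLASS_PAIR[cls]].size < n:
                raise ValueError(
                    f"class {cls}: {n} mutations requested but only "
                    f"{pools[_CLASS_PAIR[cls]].size} eligible sites"
                )
    elif spec.total > len(genome):
        raise ValueError("more mutations than genome sites")

    cols = ["coding", "noncoding", "synonymous", "nonsynonymous",
            "conservative", "non_conservative"]
    tallies = np.zeros((spec.n_trials, len(cols)), dtype=np.int64)

    if spec.composition_blind:
        for t in range(spec.n_trials):
            sites = _sample_without_replacement(rng, all_sites, spec.total)
            c = int(coding[sites].sum())
            tallies[t, 0] = c
            tallies[t, 1] = spec.total - c
    else:
        by_pair: dict[str, list[tuple[str, int]]] = {"AT": [], "GC": []}
        for cls, n in active:
            by_pair[_CLASS_PAIR[cls]].append((cls, n))
        for t in range(spec.n_trials):
            for pair, classes in by_pair.items():
                total_pair = sum(n for _, n in classes)
                if total_pair == 0:
                    continue
                sites = _sample_without_replacement(rng, pools[pair], total_pair)
                start = 0
                for cls, n in classes:
                    placed = sites[start : start + n]
                    start += n
                    refs = ref_idx[placed]
                    alts = np.empty_like(refs)
                    for rb, ab in _ALT_OF[cls].items():
                        alts[refs == rb] = ab
                    codes = effect[placed, alts]
                    c = int((codes > 0).sum())
                    tallies[t, 0] += c
                    tallies[t, 2] += int((codes == SITE_SYNONYMOUS).sum())
                    tallies[t, 3] += int(
                        ((codes == SITE_NONSYN_CONSERVATIVE)
                         | (codes == SITE_NONSYN_NONCONSERVATIVE)).sum()
                    )
                    tallies[t, 4] += int((codes == SITE_NONSYN_CONSERVATIVE).sum())
                    tallies[t, 5] += int((codes == SITE_NONSYN_NONCONSERVATIVE).sum())
            tallies[t, 1] = spec.total - tallies[t, 0]

    trials = pd.DataFrame(tallies, columns=cols)
    trials.index.name = "trial"

    total = spec.total
    expected = {
        "coding_fraction": float(trials["coding"].mean() / total) if total else 0.0,
        "synonymous_fraction_of_coding": _safe_frac(trials, "synonymous", "coding"),
        "conservative_fraction_of_nonsyn": _safe_frac(trials, "conservative", "nonsynonymous"),
    }

    result = MCNullResult(trials=trials, expected=expected, observed=observed)
    if observed:
        result.tests = _obs_vs_exp_tests(trials, expected, observed, total)
    return result


def _safe_frac(trials: pd.DataFrame, num: str, den: str) -> float:
    d = trials[den].sum()
    return float(trials[num].sum() / d) if d else float("nan")


def _obs_vs_exp_tests(
    trials: pd.DataFrame,
    expected: dict[str, float],
    observed: dict[str, int],
    total: int,
) -> pd.DataFrame:
    rows = []
    contrasts = [
        ("coding_vs_noncoding", ("coding", "noncoding"), expected["coding_fraction"]),
        ("nonsyn_vs_syn", ("nonsynonymous", "synonymous"),
         1.0 - expected["synonymous_fraction_of_coding"]),
        ("noncons_vs_cons", ("non_conservative", "conservative"),
         1.0 - expected["conservative_fraction_of_nonsyn"]),
    ]
    for name, (cat_a, cat_b), p_a in contrasts:
        if cat_a not in observed or cat_b not in observed:
            continue
        oa, ob = observed[cat_a], observed[cat_b]
        n = oa + ob
        if n == 0 or not np.isfinite(p_a) or p_a in (0.0, 1.0):
            continue
        stat, df, p = chi_squared_obs_vs_exp([oa, ob], [p_a, 1.0 - p_a])
        # one-tailed empirical probability of a trial at least as extreme
        # (as large a cat_a fraction) as observed
        trial_frac = trials[cat_a] / (trials[cat_a] + trials[cat_b]).replace(0, np.nan)
        emp = float((trial_frac >= oa / n).mean())
        rows.append(dict(
            contrast=name, observed_a=oa, observed_b=ob,
            expected_fraction_a=p_a, observed_fraction_a=oa / n,
            chi2=stat, df=df, p=p, empirical_p_upper=emp,
        ))
    return pd.DataFrame(rows)


def chi_squared_obs_vs_exp(observed_counts, expected_proportions) -> tuple[float, int, float]:
    """Pearson chi-squared of observed counts against expected proportions.

    Returns (statistic, df, p) with df = categories - 1; expected
    proportions must sum to 1 and be strictly positive.
    """
    obs = np.asarray(list(observed_counts), dtype=float)
    props = np.asarray(list(expected_proportions), dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected must have the same length")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    if np.any(props <= 0):
        raise ValueError("every expected proportion must be > 0")
    exp = props * obs.sum()
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p
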