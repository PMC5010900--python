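"""Multispecies HSBs (msHSBs) and their length statistics.

msHSBs for a clade set are the reference-chromosome regions free of any
EBR assigned to a branch visible to that clade and of any *uncertain*
breakpoint involving a clade species.  Block lengths are tested for
goodness-of-fit to an exponential distribution (the null expected when
breakpoints fall uniformly at random) with a one-sample Kolmogorov–Smirnov
test, and individual blocks longer than the expected maximum of n iid
exponential draws are flagged.

Note the KS p-value is conservative because the rate is estimated from the
same data (Lilliefors effect); a seeded parametric-bootstrap p-value is
available for a calibrated alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .breakpoints import BRGroup
from .formats import GenomicInterval
from .phylo import ClassificationResult, Phylogeny

CLADE_SET_NAMES = (
    "avian",
    "archosaurian",
    "archosaurian_testudines",
    "sauropsid",
    "amniote",
)


@dataclass(frozen=True)
class MsHSB:
    clade_set: str
    ref: GenomicInterval

    @property
    def length(self) -> int:
        return self.ref.length


@dataclass
class ExpFitResult:
    n: int
    lambda_hat: float
    ks_statistic: float
    p_value: float
    flagged_long: list[int] = field(default_factory=list)  # indices into the input
    p_value_bootstrap: float | None = None


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def compute_mshsbs(
    groups: Sequence[BRGroup],
    results: Sequence[ClassificationResult],
    clade_species: set[str],
    chrom_sizes: Mapping[str, int],
    phylo: Phylogeny,
    reference: str,
    clade_name: str = "custom",
) -> list[MsHSB]:
    """Complement of clade-relevant EBRs and uncertain BRs within chromosomes.

    An EBR is relevant iff its branch's predicted observation set
    intersects the clade species; an uncertain group is relevant iff any
    clade species observes it as present.
    """
    if not clade_species:
        raise ValueError("empty clade species set")
    by_id = {r.group_id: r for r in results}

    excised: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for group in groups:
        res = by_id.get(group.group_id)
        if res is None:
            continue
        if res.is_ebr:
            pattern = phylo.expected_pattern(res.best_branch, reference)
            observers = {leaf for leaf, v in pattern.items() if v}
            relevant = bool(observers & clade_species)
        else:
            relevant = any(
                group.pattern.get(sp) == "present" for sp in clade_species
            )
        if relevant and group.ref.seq_id in excised:
            excised[group.ref.seq_id].append((group.ref.start, group.ref.end))

    blocks: list[MsHSB] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = 0
        for lo, hi in _merge_intervals(excised[chrom]):
            lo, hi = max(lo, 0), min(hi, size)
            if lo > pos:
                blocks.append(MsHSB(clade_name, GenomicInterval(chrom, pos, lo)))
            pos = max(pos, hi)
        if pos < size:
            blocks.append(MsHSB(clade_name, GenomicInterval(chrom, pos, size)))
    return blocks


def ks_exponential(
    lengths: Sequence[float],
    bootstrap: bool = False,
    n_boot: int = 999,
    seed: int | None = None,
) -> ExpFitResult:
    """One-sample KS goodness-of-fit of block lengths to Exp(1/mean)."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 lengths, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    mean = float(x.mean())
    lam = 1.0 / mean
    res = stats.kstest(x, "expon", args=(0, mean), method="asymp")
    out = ExpFitResult(
        n=int(x.size),
        lambda_hat=lam,
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
    if bootstrap:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_boot):
            sim = rng.exponential(scale=mean, size=x.size)
            d = stats.kstest(sim, "expon", args=(0, sim.mean()), method="asymp").statistic
            if d >= out.ks_statistic:
                count += 1
        out.p_value_bootstrap = (count + 1) / (n_boot + 1)
    return out


def max_length_threshold(n: int, mean: float, alpha: float = 0.05) -> float:
    """Length x* with P(max of n iid Exp(1/mean) >= x*) = alpha (closed form)."""
    if n < 1 or mean <= 0 or not (0 < alpha < 1):
        raise ValueError("need n >= 1, mean > 0, 0 < alpha < 1")
    return -math.log(1.0 - (1.0 - alpha) ** (1.0 / n)) * mean


def flag_long_blocks(lengths: Sequence[float], alpha: float = 0.05) -> list[int]:
    """Indices of blocks longer than expected by chance under the Exp null.

    Block x is flagged iff P(max of n iid Exp(lambda_hat) >= x) < alpha,
    i.e. 1 - (1 - exp(-lambda_hat * x))**n < alpha.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 lengths, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("lengths must be positive")
    lam = 1.0 / float(x.mean())
    tail = 1.0 - (1.0 - np.exp(-lam * x)) ** x.size
    return [int(i) for i in np.nonzero(tail < alpha)[0]]


def fit_lengths(
    lengths: Sequence[float],
    alpha: float = 0.05,
    bootstrap: bool = False,
    seed: int | None = None,
) -> ExpFitResult:
    """KS fit plus long-block flags in one result object."""
    out = ks_exponential(lengths, bootstrap=bootstrap, seed=seed)
    out.flagged_long = flag_long_blocks(lengths, alpha=alpha)
    return out
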