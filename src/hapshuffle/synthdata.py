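"""Self-contained generators of labeled haplotype-matrix datasets.

Two regimes are emulated, both desk-scale:

* a *classification* regime — neutral windows versus stylized selective
  sweeps of increasing strength (analogous to selection-coefficient tiers),
  where sweeps homogenize haplotypes and thin segregating sites; and
* a *regression* regime — windows simulated under a three-epoch
  piecewise-constant demographic history whose five parameters
  (N0, N1, N2, T1, T2) are the regression targets.

The neutral engine is a Kingman coalescent without recombination under
piecewise-constant population sizes, with Poisson infinite-sites mutations
dropped on branches.  Times are in units of 2*N_ref generations; epoch
sizes are scalars relative to N_ref; theta = 4*N_ref*mu*L is the scaled
mutation rate of the whole window, so under constant size s the expected
number of segregating sites is theta*s*a1(n) and the expected nucleotide
diversity is theta*s.

Sweeps are *stylized distortions*, not structured-coalescent simulations:
a fraction of haplotypes is replaced by copies of one core haplotype
(elevating haplotype homozygosity) and a fraction of sites is thinned
(reducing the minor-allele load), which are the separating features the
evaluation harness needs with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._seeding import child_seed, rng_for
from .dataset import LabeledDataset
from .matrix import HaplotypeMatrix, pad_to_width

__all__ = [
    "DemographyParams",
    "SweepParams",
    "SimSettings",
    "simulate_neutral",
    "apply_sweep_distortion",
    "make_classification_dataset",
    "make_regression_dataset",
    "DEFAULT_TIERS",
    "DEFAULT_PRIORS",
]

_POSITION_SCALE = 1_000_000  # uniform [0,1) positions stored as bp on a 1 Mb window


@dataclass(frozen=True)
class DemographyParams:
    """Piecewise-constant demography, most recent epoch first.

    sizes[j] is the population size of epoch j in units of a reference
    size N_ref; times[j] is the (coalescent-scaled, units of 2*N_ref
    generations) boundary between epoch j and epoch j+1.  theta is
    4*N_ref*mu*L for the simulated window.
    """

    sizes: tuple[float, ...] = (1.0,)
    times: tuple[float, ...] = ()
    theta: float = 5.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("epoch sizes must be strictly positive")
        if len(self.times) != len(self.sizes) - 1:
            raise ValueError("need exactly one fewer epoch boundary than sizes")
        if any(b <= a for a, b in zip((0.0,) + tuple(self.times), self.times)):
            raise ValueError("epoch boundary times must be strictly increasing")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass(frozen=True)
class SweepParams:
    """Stylized sweep distortion strength.

    core_fraction f: fraction of haplotypes replaced by copies of one core
    haplotype.  site_thinning: fraction of segregating sites deleted.
    tier: class label; the neutral tier is exactly f = thinning = 0.
    """

    core_fraction: float = 0.0
    site_thinning: float = 0.0
    tier: str = "neutral"

    def __post_init__(self) -> None:
        if not (0 <= self.core_fraction <= 1 and 0 <= self.site_thinning <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        neutral = self.core_fraction == 0 and self.site_thinning == 0
        if (self.tier == "neutral") != neutral:
            raise ValueError("tier 'neutral' iff core_fraction = site_thinning = 0")


@dataclass(frozen=True)
class SimSettings:
    """Shared matrix geometry for a generated dataset."""

    n_hap: int = 32
    width: int = 64


# Class tiers: a neutral baseline and two sweep strengths, mirroring the
# usual weak/strong selection-coefficient tiers of sweep classifiers.
DEFAULT_TIERS: tuple[SweepParams, ...] = (
    SweepParams(0.0, 0.0, "neutral"),
    SweepParams(0.5, 0.3, "moderate"),
    SweepParams(0.8, 0.6, "strong"),
)

# Log-uniform priors for the three epoch sizes (spanning 10x) and uniform,
# disjoint priors for the two epoch-boundary times.
DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "N0": (0.3, 3.0),
    "N1": (0.3, 3.0),
    "N2": (0.3, 3.0),
    "T1": (0.05, 0.45),
    "T2": (0.5, 1.5),
}


def _coalescent_branches(
    n_hap: int, demography: DemographyParams, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Simulate one genealogy; return (leaf bitmask, branch length) pairs.

    The exponential clock is run per-epoch: with k lineages in an epoch of
    size s the coalescence rate is C(k,2)/s; a waiting time overshooting
    the epoch boundary is discarded and redrawn from the boundary
    (memorylessness makes this exact).
    """
    k = n_hap
    t = 0.0
    epoch = 0
    masks = [1 << i for i in range(n_hap)]
    births = [0.0] * n_hap
    branches: list[tuple[int, float]] = []
    while k > 1:
        rate = k * (k - 1) / 2 / demography.sizes[epoch]
        wait = rng.exponential(1.0 / rate)
        boundary = (
            demography.times[epoch] if epoch < len(demography.times) else math.inf
        )
        if t + wait > boundary:
            t = boundary
            epoch += 1
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        branches.append((masks[i], t - births[i]))
        branches.append((masks[j], t - births[j]))
        merged = masks[i] | masks[j]
        masks[i] = merged
        births[i] = t
        del masks[j], births[j]
        k -= 1
    return branches


def simulate_neutral(
    n_hap: int,
    demography: DemographyParams,
    width: int,
    seed: int,
) -> HaplotypeMatrix:
    """One neutral haplotype matrix: coalescent genealogy + infinite sites.

    Mutations fall on branches as a Poisson process with rate theta/2 per
    unit branch length; each mutation creates one column marking its
    carrier leaves with 1 (derived coding).  Columns are ordered by seeded
    uniform positions; if more than ``width`` sites arise, the first
    ``width`` by position are kept; otherwise the matrix is zero-padded.
    """
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    rng = rng_for(seed)
    branches = _coalescent_branches(n_hap, demography, rng)
    lengths = np.array([l for _, l in branches])
    total = float(lengths.sum())
    n_mut = int(rng.poisson(demography.theta / 2 * total)) if demography.theta > 0 else 0
    if n_mut == 0:
        data = np.zeros((n_hap, width), dtype=np.uint8)
        return HaplotypeMatrix(
            data=data, n_seg=0, positions=np.empty(0, dtype=np.int64),
            allele_coding="derived",
        )
    which = rng.choice(len(branches), size=n_mut, p=lengths / total)
    u = np.sort(rng.random(n_mut))
    cols = np.zeros((n_hap, n_mut), dtype=np.uint8)
    for m, b in enumerate(which):
        mask = branches[int(b)][0]
        for h in range(n_hap):
            if mask >> h & 1:
                cols[h, m] = 1
    n_seg = min(n_mut, width)
    positions = np.floor(u[:n_seg] * _POSITION_SCALE).astype(np.int64)
    matrix = HaplotypeMatrix(
        data=cols[:, :n_seg], n_seg=n_seg, positions=positions, allele_coding="derived"
    )
    return pad_to_width(matrix, width)


def apply_sweep_distortion(
    matrix: HaplotypeMatrix, sweep: SweepParams, seed: int
) -> HaplotypeMatrix:
    """Impose a stylized hard-sweep signature on a neutral matrix.

    A seeded core haplotype is chosen; ceil(f * n_hap) - 1 other rows are
    replaced by copies of it (f = 0 replaces none); then a seeded
    ``site_thinning`` fraction of columns is deleted and the matrix is
    re-padded to its original width.
    """
    rng = rng_for(seed)
    out = matrix.copy()
    n = out.n_hap
    if sweep.core_fraction > 0:
        core = int(rng.integers(n))
        n_rep = max(math.ceil(sweep.core_fraction * n) - 1, 0)
        others = np.array([h for h in range(n) if h != core])
        chosen = rng.choice(others, size=min(n_rep, len(others)), replace=False)
        for h in chosen:
            out.data[int(h), : out.n_seg] = out.data[core, : out.n_seg]
    if sweep.site_thinning > 0 and out.n_seg > 0:
        n_del = int(round(sweep.site_thinning * out.n_seg))
        keep = np.ones(out.n_seg, dtype=bool)
        if n_del > 0:
            keep[rng.choice(out.n_seg, size=n_del, replace=False)] = False
        kept_idx = np.flatnonzero(keep)
        positions = out.positions[kept_idx] if out.positions is not None else None
        thinned = HaplotypeMatrix(
            data=out.data[:, kept_idx],
            n_seg=len(kept_idx),
            positions=positions,
            allele_coding=out.allele_coding,
        )
        out = pad_to_width(thinned, matrix.width)
    return out


def make_classification_dataset(
    n_per_class: int,
    tiers: Sequence[SweepParams] = DEFAULT_TIERS,
    settings: SimSettings = SimSettings(),
    demography: DemographyParams = DemographyParams(theta=12.0),
    seed: int = 0,
) -> LabeledDataset:
    """Balanced neutral-vs-sweep dataset; per-matrix seeds from (seed, class, index)."""
    if len(tiers) < 2:
        raise ValueError("need at least 2 tiers")
    matrices, labels = [], []
    for c, tier in enumerate(tiers):
        for i in range(n_per_class):
            s = child_seed(seed, c, i)
            m = simulate_neutral(settings.n_hap, demography, settings.width, child_seed(s, 0))
            m = apply_sweep_distortion(m, tier, child_seed(s, 1))
            matrices.append(m)
            labels.append(tier.tier)
    meta = {
        "generator": "hapshuffle.synthdata.make_classification_dataset",
        "seed": int(seed),
        "n_per_class": int(n_per_class),
        "n_hap": settings.n_hap,
        "width": settings.width,
        "theta": demography.theta,
        "tiers": [
            {"tier": t.tier, "core_fraction": t.core_fraction, "site_thinning": t.site_thinning}
            for t in tiers
        ],
    }
    return LabeledDataset(
        matrices=matrices,
        labels=labels,
        label_names=[t.tier for t in tiers],
        task="classification",
        meta=meta,
    )


def make_regression_dataset(
    n: int,
    priors: dict[str, tuple[float, float]] = DEFAULT_PRIORS,
    settings: SimSettings = SimSettings(n_hap=20, width=96),
    theta_ref: float = 8.0,
    seed: int = 0,
) -> LabeledDataset:
    """Three-epoch demography dataset; labels are (N0, N1, N2, T1, T2).

    Sizes are drawn log-uniform and times uniform from ``priors``; each
    matrix is simulated under its own drawn history with the shared
    reference theta.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    names = ["N0", "N1", "N2", "T1", "T2"]
    for k in names:
        lo, hi = priors[k]
        if not (0 < lo <= hi):
            raise ValueError(f"invalid prior range for {k}")
    matrices, labels = [], []
    for i in range(n):
        rng = rng_for(child_seed(seed, i), 0)
        sizes = tuple(
            float(np.exp(rng.uniform(np.log(priors[k][0]), np.log(priors[k][1]))))
            for k in ("N0", "N1", "N2")
        )
        t1 = float(rng.uniform(*priors["T1"]))
        t2 = float(rng.uniform(*priors["T2"]))
        if t2 <= t1:  # possible only with overlapping prior ranges
            t1, t2 = min(t1, t2), max(t1, t2) + 1e-9
        demog = DemographyParams(sizes=sizes, times=(t1, t2), theta=theta_ref)
        matrices.append(
            simulate_neutral(settings.n_hap, demog, settings.width, child_seed(seed, i, 1))
        )
        labels.append(np.array(sizes + (t1, t2)))
    meta = {
        "generator": "hapshuffle.synthdata.make_regression_dataset",
        "seed": int(seed),
        "n": int(n),
        "n_hap": settings.n_hap,
        "width": settings.width,
        "theta_ref": float(theta_ref),
        "priors": {k: [float(v[0]), float(v[1])] for k, v in priors.items()},
    }
    return LabeledDataset(
        matrices=matrices, labels=labels, label_names=names, task="regression", meta=meta
    )
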