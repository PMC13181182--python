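"""Ground-truth WGBS simulation and graded-noise replicates.

The generator emulates the block structure of real methylomes: a
chromosome of CpG sites with geometric inter-site gaps is partitioned into
segments; each segment carries one methylation rate per sample, drawn from
a bimodal Beta(0.3, 0.3) like real beta-value distributions; per-cell read
depth is Poisson and methylated counts are binomial at the segment rate.

Noise is injected per site/sample cell by mixing the true rate with an
independent Uniform(0, 1) draw: at amplitude ``eta`` percent the generative
rate becomes ``clip((1 - w) * p + w * e, 0, 1)`` with ``w = eta / 100``, and
the methylated counts are re-drawn binomially at unchanged depth.  At
``eta = 100`` the cell rates are pure noise; above 100 the (negative)
signal weight pushes rates further toward the clipped extremes, so the
segmentation signal is fully destroyed -- matching the regime where noise
exceeds signal at every CpG.

Replicate collections derive one deterministic seed per (eta, k) pair from
a single master seed, so a collection is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .core_model import MethylationCountSet

__all__ = [
    "GroundTruth",
    "NoisyDatasetCollection",
    "simulate_baseline",
    "inject_noise",
    "build_collection",
    "write_truth",
    "read_truth",
    "DEFAULT_ETA_GRID",
]

#: Noise amplitude grid in percent: 5, 10, ..., 120.
DEFAULT_ETA_GRID: tuple[float, ...] = tuple(range(5, 125, 5))


@dataclass
class GroundTruth:
    """True segmentation behind a simulated baseline dataset.

    ``breakpoints`` maps chromosome -> sorted local site-index boundaries
    (boundary ``b`` separates sites ``b-1`` and ``b``; chromosome ends are
    not listed).  ``true_rates`` is (segments x samples), segments in
    genomic order.  ``site_rates`` expands the rates to (sites x samples).
    """

    breakpoints: dict[str, np.ndarray]
    true_rates: np.ndarray
    positions: np.ndarray
    depths: np.ndarray
    site_rates: np.ndarray

    def n_breakpoints(self) -> int:
        return int(sum(len(b) for b in self.breakpoints.values()))


@dataclass
class NoisyDatasetCollection:
    """A baseline dataset plus noisy replicates over an amplitude grid."""

    baseline: MethylationCountSet
    truth: GroundTruth
    replicates: dict[tuple[float, int], MethylationCountSet] = field(default_factory=dict)
    master_seed: int | None = None
    eta_grid: tuple[float, ...] = ()
    n_replicates: int = 0


def _default_rate_sampler(rng: np.random.Generator, size) -> np.ndarray:
    # bimodal like real methylomes: mass near 0 and 1
    return rng.beta(0.3, 0.3, size=size)


def _default_gap_sampler(rng: np.random.Generator, size) -> np.ndarray:
    # inter-CpG gaps: geometric with mean 100 bp, minimum 2 bp
    return 1 + rng.geometric(1.0 / 99.0, size=size)


def _draw_boundaries(
    rng: np.random.Generator, n_sites: int, n_segments: int, min_segment_sites: int
) -> np.ndarray:
    if n_segments == 1:
        return np.array([], dtype=int)
    for _ in range(1000):
        bps = np.sort(rng.choice(np.arange(1, n_sites), n_segments - 1, replace=False))
        sizes = np.diff(np.r_[0, bps, n_sites])
        if (sizes >= min_segment_sites).all():
            return bps
    raise ValueError(
        "could not place segment boundaries with the requested minimum size"
    )


def simulate_baseline(
    n_sites: int = 2000,
    n_samples: int = 5,
    n_segments: int = 10,
    depth_mean: float = 30.0,
    rate_sampler: Callable | None = None,
    gap_sampler: Callable | None = None,
    seed: int | None = None,
    chrom: str = "chr1",
    min_segment_sites: int = 20,
    min_neighbor_rate_diff: float = 0.0,
) -> tuple[MethylationCountSet, GroundTruth]:
    """Simulate a noise-free piecewise-constant baseline dataset.

    Defaults are the desk-scale profile: 2000 CpGs, 10 segments of at least
    20 sites, 5 samples, Poisson depth with mean 30.
    ``min_neighbor_rate_diff`` forces each sample's rate to differ by at
    least that much between adjacent segments (rejection sampling), which
    guarantees a detectable change at every true boundary.
    """
    if n_segments > n_sites:
        raise ValueError("n_segments cannot exceed n_sites")
    if n_segments < 1 or n_sites < 1 or n_samples < 1:
        raise ValueError("n_sites, n_samples, n_segments must be >= 1")
    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    rng = np.random.default_rng(seed)
    rate_sampler = rate_sampler or _default_rate_sampler
    gap_sampler = gap_sampler or _default_gap_sampler

    bps = _draw_boundaries(rng, n_sites, n_segments, min(min_segment_sites, n_sites // n_segments))
    rates = np.empty((n_segments, n_samples))
    rates[0] = rate_sampler(rng, n_samples)
    for s in range(1, n_segments):
        draw = rate_sampler(rng, n_samples)
        if min_neighbor_rate_diff > 0:
            for _ in range(10000):
                bad = np.abs(draw - rates[s - 1]) < min_neighbor_rate_diff
                if not bad.any():
                    break
                draw[bad] = rate_sampler(rng, int(bad.sum()))
            else:
                raise ValueError("could not satisfy min_neighbor_rate_diff")
        rates[s] = draw
    np.clip(rates, 0.0, 1.0, out=rates)

    gaps = gap_sampler(rng, n_sites)
    positions = np.cumsum(gaps).astype(np.int64)
    seg_of_site = np.searchsorted(bps, np.arange(n_sites), side="right")
    site_rates = rates[seg_of_site]  # (m, n)
    depths = rng.poisson(depth_mean, size=(n_sites, n_samples))
    meth = rng.binomial(depths, site_rates)
    unmeth = depths - meth

    data = MethylationCountSet(
        meth, unmeth, positions, np.full(n_sites, chrom, dtype=object),
        [f"sample_{j + 1}" for j in range(n_samples)],
    )
    truth = GroundTruth(
        breakpoints={chrom: bps},
        true_rates=rates,
        positions=positions,
        depths=depths,
        site_rates=site_rates,
    )
    return data, truth


def inject_noise(
    baseline: MethylationCountSet,
    truth: GroundTruth,
    eta_percent: float,
    seed: int | None = None,
) -> MethylationCountSet:
    """Re-draw methylated counts at noise-mixed rates, depths unchanged.

    Per cell: ``p' = clip((1 - w) * p_true + w * e, 0, 1)`` with
    ``w = eta_percent / 100`` and ``e ~ Uniform(0, 1)`` iid; methylated
    counts are then Binomial(depth, p').
    """
    if eta_percent < 0:
        raise ValueError("eta_percent must be non-negative")
    rng = np.random.default_rng(seed)
    w = eta_percent / 100.0
    depths = baseline.total_counts()
    if w == 0.0:
        p = truth.site_rates
    else:
        eps = rng.uniform(size=depths.shape)
        p = np.clip((1.0 - w) * truth.site_rates + w * eps, 0.0, 1.0)
    meth = rng.binomial(depths, p)
    return MethylationCountSet(
        meth, depths - meth, baseline.positions.copy(),
        baseline.chroms.copy(), list(baseline.sample_ids),
    )


def replicate_seed(master_seed: int, eta_percent: float, k: int) -> np.random.SeedSequence:
    """Deterministic, collision-free seed for replicate (eta, k)."""
    return np.random.SeedSequence(
        entropy=(int(master_seed), int(round(eta_percent * 1000)), int(k))
    )


def build_collection(
    baseline: MethylationCountSet,
    truth: GroundTruth,
    eta_grid: tuple[float, ...] = DEFAULT_ETA_GRID,
    n_replicates: int = 20,
    master_seed: int = 0,
) -> NoisyDatasetCollection:
    """Generate ``n_replicates`` noisy datasets at every amplitude in the grid."""
    if not eta_grid:
        raise ValueError("eta_grid must be non-empty")
    coll = NoisyDatasetCollection(
        baseline=baseline,
        truth=truth,
        master_seed=master_seed,
        eta_grid=tuple(eta_grid),
        n_replicates=n_replicates,
    )
    for eta in eta_grid:
        for k in range(1, n_replicates + 1):
            ss = replicate_seed(master_seed, eta, k)
            coll.replicates[(float(eta), k)] = inject_noise(
                baseline, truth, eta, seed=ss
            )
    return coll


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist breakpoints and segment rates as a TSV (one section each)."""
    with open(path, "w") as fh:
        fh.write("#breakpoints\tchrom\tsite_index\tposition\n")
        for chrom, bps in truth.breakpoints.items():
            for b in bps:
                fh.write(f"BP\t{chrom}\t{b}\t{truth.positions[b]}\n")
        fh.write("#rates\tsegment\t" + "\t".join(
            f"sample_{j + 1}" for j in range(truth.true_rates.shape[1])) + "\n")
        for s, row in enumerate(truth.true_rates):
            fh.write(
                "RATE\t" + str(s) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def read_truth(path: str | Path) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read back a truth TSV: (breakpoints per chromosome, segment rates)."""
    bps: dict[str, list[int]] = {}
    rates: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "BP":
                bps.setdefault(parts[1], []).append(int(parts[2]))
            elif parts[0] == "RATE":
                rates.append([float(v) for v in parts[2:]])
    return (
        {ch: np.array(sorted(v), dtype=int) for ch, v in bps.items()},
        np.array(rates),
    )
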