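"""Degree-matched resampling null model for seed-neighborhood statistics.

Observed level-1 / level-2 / bridging counts are compared against random
gene sets of the same size drawn from the same node-degree strata as the
observed set ("degree-matched"), which controls for the hub bias of both
the seed and GWAS-reported genes. For each statistic the null distribution
is the vector of counts over ``n_samples`` resampled sets (default 1000);
significance is the add-one empirical upper-tail p-value

    p = (1 + #{null >= observed}) / (1 + n_samples),

which is never zero and counts ties toward the tail (conservative), and
effect size is the fold change observed / mean(null).

Degree matching is exact by default (stratum = degree, with a nearest-bin
fallback when a stratum runs out of candidates) or by log2 degree bins for
sparse degree spectra.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .neighborhood import STATISTICS, SeedNeighborhoodIndex, compute_neighborhood
from .network_io import InteractionNetwork

log = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NullResult",
    "MatchedSetSampler",
    "degree_bins",
    "sample_matched_set",
    "run_null_test",
    "results_to_json",
    "results_to_tsv",
]

MATCHING_SCHEMES = ("exact", "log2")


@dataclass(frozen=True)
class NullConfig:
    """Parameters of the resampling null.

    n_samples : number of random degree-matched sets (default 1000).
    alpha : significance level for downstream study flagging.
    degree_matching : ``exact`` (stratum = degree) or ``log2``
        (stratum = floor(log2 degree)).
    rng_seed : root seed; every random draw in a run descends from it.
    """

    n_samples: int = 1000
    alpha: float = 0.05
    degree_matching: str = "exact"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.degree_matching not in MATCHING_SCHEMES:
            raise ValueError(f"unknown matching scheme {self.degree_matching!r}")


@dataclass
class NullResult:
    """Null sample vector, fold change and empirical p for one statistic.

    ``fold_change`` is observed / mean(null); when the null mean is zero it
    degenerates to 1.0 if the observed count is also zero and to NaN (an
    undefined sentinel, flagged by ``fold_defined``) otherwise — no
    infinities are fabricated.
    """

    statistic: str
    observed: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def mean_null(self) -> float:
        return float(self.samples.mean())

    @property
    def sd_null(self) -> float:
        return float(self.samples.std(ddof=1)) if self.samples.size > 1 else 0.0

    @property
    def p_value(self) -> float:
        tail = int(np.count_nonzero(self.samples >= self.observed))
        return (1 + tail) / (1 + self.n_samples)

    @property
    def fold_change(self) -> float:
        mean = self.mean_null
        if mean > 0:
            return self.observed / mean
        return 1.0 if self.observed == 0 else math.nan

    @property
    def fold_defined(self) -> bool:
        return not math.isnan(self.fold_change)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "mean_null": self.mean_null,
            "sd_null": self.sd_null,
            "fold_change": None if not self.fold_defined else self.fold_change,
            "p_value": self.p_value,
            "n_samples": self.n_samples,
        }


def degree_bins(network: InteractionNetwork, scheme: str = "exact") -> dict[str, int]:
    """Assign every node a degree-stratum label.

    ``exact``: label = degree. ``log2``: label = floor(log2(degree)), with
    degree-0 nodes in their own bin (label -1).
    """
    if scheme not in MATCHING_SCHEMES:
        raise ValueError(f"unknown matching scheme {scheme!r}")
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    bins: dict[str, int] = {}
    for node, deg in network.graph.degree():
        if scheme == "exact":
            bins[node] = deg
        else:
            bins[node] = -1 if deg == 0 else int(math.floor(math.log2(deg)))
    return bins


class MatchedSetSampler:
    """Draw degree-matched random node sets, excluding the seed.

    Strata are precomputed once; ``sample`` then draws, for each template
    member, one node uniformly without replacement from that member's
    stratum. A stratum with too few candidates falls back to the nearest
    non-empty stratum by label distance (logged); if the whole network is
    exhausted a ``ValueError`` is raised.
    """

    def __init__(
        self,
        network: InteractionNetwork,
        seed: str,
        scheme: str = "exact",
        bins: Mapping[str, int] | None = None,
    ):
        self.seed = seed
        self.scheme = scheme
        self.bins = dict(bins) if bins is not None else degree_bins(network, scheme)
        by_bin: dict[int, list[str]] = {}
        for node, label in self.bins.items():
            if node == seed:
                continue
            by_bin.setdefault(label, []).append(node)
        # sorted node arrays make draws reproducible across runs
        self.bin_nodes: dict[int, np.ndarray] = {
            label: np.array(sorted(nodes), dtype=object)
            for label, nodes in by_bin.items()
        }
        self.bin_labels = sorted(self.bin_nodes)
        self.n_candidates = sum(arr.size for arr in self.bin_nodes.values())

    def sample(self, template: Iterable[str], rng: np.random.Generator) -> set[str]:
        """One degree-matched set of ``|template|`` distinct non-seed nodes."""
        template = set(template)
        if self.seed in template:
            raise ValueError("template must not contain the seed")
        if len(template) > self.n_candidates:
            raise ValueError(
                f"template size {len(template)} exceeds the {self.n_candidates} "
                "available candidate nodes"
            )
        needed = Counter(self.bins[v] for v in template)
        chosen: set[str] = set()
        deficits: list[tuple[int, int]] = []
        for label in sorted(needed):
            k = needed[label]
            arr = self.bin_nodes.get(label)
            if arr is None or arr.size == 0:
                deficits.append((label, k))
                continue
            if k <= arr.size:
                picks = rng.choice(arr, size=k, replace=False)
                chosen.update(picks.tolist())
            else:
                chosen.update(arr.tolist())
                deficits.append((label, k - arr.size))
        for label, k in deficits:
            self._fill_from_nearest(label, k, chosen, rng)
        return chosen

    def _fill_from_nearest(
        self, label: int, k: int, chosen: set[str], rng: np.random.Generator
    ) -> None:
        log.debug(
            "degree stratum %s exhausted: relaxing %d draw(s) to nearest strata",
            label, k,
        )
        for other in sorted(self.bin_labels, key=lambda b: (abs(b - label), b)):
            if k == 0:
                return
            pool = [n for n in self.bin_nodes[other].tolist() if n not in chosen]
            if not pool:
                continue
            take = min(k, len(pool))
            picks = rng.choice(np.array(pool, dtype=object), size=take, replace=False)
            chosen.update(picks.tolist())
            k -= take
        if k > 0:
            raise ValueError("network exhausted while drawing a matched set")


def sample_matched_set(
    network: InteractionNetwork,
    template: Iterable[str],
    seed: str,
    scheme: str = "exact",
    rng: np.random.Generator | None = None,
    bins: Mapping[str, int] | None = None,
) -> set[str]:
    """Convenience wrapper: one matched draw without keeping the sampler."""
    if rng is None:
        rng = np.random.default_rng()
    sampler = MatchedSetSampler(network, seed, scheme=scheme, bins=bins)
    return sampler.sample(template, rng)


def run_null_test(
    network: InteractionNetwork,
    seed: str,
    gene_set: Iterable[str],
    config: NullConfig,
    seed_sequence: np.random.SeedSequence | None = None,
    _index: SeedNeighborhoodIndex | None = None,
    _sampler: MatchedSetSampler | None = None,
) -> dict[str, NullResult]:
    """Observed statistics plus their degree-matched null distributions.

    Draws ``config.n_samples`` matched sets, recomputes all three statistics
    on each, and returns one :class:`NullResult` per statistic. Randomness
    descends from ``config.rng_seed`` (or an explicit ``seed_sequence``,
    which callers use to key per-study sub-streams); per-sample child
    streams are spawned deterministically, so identical inputs give
    bit-identical sample vectors.
    """
    config.validate()
    gene_set = set(gene_set)
    observed = compute_neighborhood(network, seed, gene_set)
    index = _index if _index is not None else SeedNeighborhoodIndex(network, seed)
    sampler = (
        _sampler
        if _sampler is not None
        else MatchedSetSampler(network, seed, scheme=config.degree_matching)
    )
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(config.rng_seed)
    children = seed_sequence.spawn(config.n_samples)
    counts = np.empty((config.n_samples, 3), dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        null_set = sampler.sample(gene_set, rng)
        counts[i, :] = index.counts(null_set)
    obs = observed.counts()
    return {
        stat: NullResult(statistic=stat, observed=obs[stat], samples=counts[:, j])
        for j, stat in enumerate(STATISTICS)
    }


def results_to_json(results: Mapping[str, NullResult], rng_seed: int | None = None) -> str:
    """Serialize per-statistic null results to a JSON string."""
    import json

    payload = {stat: res.to_dict() for stat, res in results.items()}
    if rng_seed is not None:
        for entry in payload.values():
            entry["rng_seed"] = rng_seed
    return json.dumps(payload, indent=2, sort_keys=True)


def results_to_tsv(results: Mapping[str, NullResult]) -> str:
    """One row per statistic: observed, null moments, fold change, p."""
    lines = ["statistic\tobserved\tmean_null\tsd_null\tfold_change\tp_value\tn_samples"]
    for stat in STATISTICS:
        res = results[stat]
        fold = f"{res.fold_change:.4g}" if res.fold_defined else "NA"
        lines.append(
            f"{res.statistic}\t{res.observed}\t{res.mean_null:.4g}\t"
            f"{res.sd_null:.4g}\t{fold}\t{res.p_value:.4g}\t{res.n_samples}"
        )
    return "\n".join(lines) + "\n"
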