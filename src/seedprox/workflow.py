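"""Multi-study workflow: per-study significance, then re-analysis of the union.

Each GWAS study's gene set is mapped onto the network, its level-1 /
level-2 / bridging statistics computed, and each compared to the
degree-matched null. A study is flagged significant when at least one of
the three statistics has p below alpha (no cross-study correction by
default; an optional Benjamini–Hochberg flag is available). The union of
the significant studies' gene sets is then re-analyzed as a single set,
with fresh null draws, and its level-1 interactors are attributed back to
the contributing studies.

Each study row consumes an independent random sub-stream keyed by
(rng_seed, study name), so adding or removing a study never perturbs the
other rows' p-values.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .neighborhood import STATISTICS, SeedNeighborhoodIndex, compute_neighborhood
from .network_io import GeneSetCollection, InteractionNetwork, map_gene_set
from .null_model import MatchedSetSampler, NullConfig, run_null_test

log = logging.getLogger(__name__)

__all__ = [
    "StatRow",
    "StudyRow",
    "StudyReport",
    "analyze_studies",
    "analyze_union",
    "union_of_significant",
]

UNION_LABEL = "UNION"


@dataclass(frozen=True)
class StatRow:
    """Summary for one statistic in one study row."""

    observed: int
    fold_change: float  # NaN = undefined (zero null mean, non-zero observed)
    p_value: float


@dataclass
class StudyRow:
    study: str
    n_genes: int
    n_mapped: int
    stats: dict[str, StatRow]
    significant: bool
    note: str = ""

    def min_p(self) -> float:
        return min(s.p_value for s in self.stats.values())


@dataclass
class StudyReport:
    """One row per study plus, when any study is significant, the union row."""

    rows: list[StudyRow]
    union_row: StudyRow | None = None
    union_members: list[tuple[str, list[str]]] = field(default_factory=list)
    alpha: float = 0.05
    rng_seed: int = 0

    def significant_studies(self) -> list[str]:
        return [row.study for row in self.rows if row.significant]


def _study_seed_sequence(rng_seed: int, study: str) -> np.random.SeedSequence:
    """Deterministic sub-stream key for one study, stable across study order."""
    digest = hashlib.sha256(study.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.SeedSequence([rng_seed, key])


def _zero_row(study: str, n_genes: int, note: str) -> StudyRow:
    stats = {stat: StatRow(observed=0, fold_change=1.0, p_value=1.0) for stat in STATISTICS}
    return StudyRow(
        study=study, n_genes=n_genes, n_mapped=0, stats=stats,
        significant=False, note=note,
    )


def _row_from_results(
    study: str, n_genes: int, n_mapped: int, results, alpha: float
) -> StudyRow:
    stats = {
        stat: StatRow(
            observed=res.observed,
            fold_change=res.fold_change,
            p_value=res.p_value,
        )
        for stat, res in results.items()
    }
    significant = min(s.p_value for s in stats.values()) < alpha
    return StudyRow(
        study=study, n_genes=n_genes, n_mapped=n_mapped,
        stats=stats, significant=significant,
    )


def analyze_studies(
    network: InteractionNetwork,
    seed: str,
    collection: GeneSetCollection,
    config: NullConfig,
    id_map: Mapping[str, str] | None = None,
    bh_correct: bool = False,
) -> StudyReport:
    """Run the per-study analysis and, if any study is significant, the union.

    A study whose gene set maps to zero network nodes yields a row with
    zero counts, p = 1 and a warning note rather than an error. With
    ``bh_correct`` the per-statistic p-values are Benjamini–Hochberg
    adjusted across studies before flagging (off by default).
    """
    if len(collection) == 0:
        raise ValueError("gene-set collection is empty")
    config.validate()
    index = SeedNeighborhoodIndex(network, seed)
    sampler = MatchedSetSampler(network, seed, scheme=config.degree_matching)
    rows: list[StudyRow] = []
    mapped_sets: dict[str, set[str]] = {}
    for study in collection:
        genes = collection[study]
        mapped, unmapped = map_gene_set(network, genes, seed, id_map=id_map)
        mapped_sets[study] = mapped
        if not mapped:
            log.warning("study %s: no genes mapped to the network", study)
            rows.append(_zero_row(study, len(genes), note="no genes mapped"))
            continue
        if unmapped:
            log.info("study %s: %d of %d symbols unmapped", study, len(unmapped), len(genes))
        results = run_null_test(
            network, seed, mapped, config,
            seed_sequence=_study_seed_sequence(config.rng_seed, study),
            _index=index, _sampler=sampler,
        )
        rows.append(_row_from_results(study, len(genes), len(mapped), results, config.alpha))
    if bh_correct:
        _apply_bh(rows, config.alpha)
    report = StudyReport(rows=rows, alpha=config.alpha, rng_seed=config.rng_seed)
    union_genes = union_of_significant(report, collection)
    if union_genes:
        union_row, members = analyze_union(
            network, seed, union_genes, config,
            mapped_sets={s: mapped_sets[s] for s in report.significant_studies()},
            id_map=id_map, _index=index, _sampler=sampler,
        )
        report.union_row = union_row
        report.union_members = members
    return report


def _apply_bh(rows: list[StudyRow], alpha: float) -> None:
    """Benjamini–Hochberg across studies, per statistic; re-flags rows in place."""
    from statsmodels.stats.multitest import multipletests

    rejected = {row.study: False for row in rows}
    for stat in STATISTICS:
        pvals = [row.stats[stat].p_value for row in rows]
        reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        for row, rej in zip(rows, reject):
            rejected[row.study] |= bool(rej)
    for row in rows:
        row.significant = rejected[row.study] and row.n_mapped > 0


def union_of_significant(
    report: StudyReport, collection: GeneSetCollection
) -> frozenset[str]:
    """Union of the gene sets of all significant studies (raw symbols).

    Invariant to study order; empty when no study is significant.
    """
    union: set[str] = set()
    for row in report.rows:
        if row.significant:
            union.update(collection[row.study])
    return frozenset(union)


def analyze_union(
    network: InteractionNetwork,
    seed: str,
    union_genes: Iterable[str],
    config: NullConfig,
    mapped_sets: Mapping[str, set[str]] | None = None,
    id_map: Mapping[str, str] | None = None,
    _index: SeedNeighborhoodIndex | None = None,
    _sampler: MatchedSetSampler | None = None,
) -> tuple[StudyRow | None, list[tuple[str, list[str]]]]:
    """Re-run the pipeline on the union gene set; attribute level-1 members.

    Returns ``(union_row, members)`` where ``members`` lists every level-1
    interactor of the union together with the contributing studies (those
    of ``mapped_sets`` that contain it). The union analysis draws fresh null
    samples from its own sub-stream. An empty union yields ``(None, [])``.
    """
    union_genes = set(union_genes)
    if not union_genes:
        return None, []
    mapped, _ = map_gene_set(network, union_genes, seed, id_map=id_map)
    if not mapped:
        return _zero_row(UNION_LABEL, len(union_genes), note="no genes mapped"), []
    results = run_null_test(
        network, seed, mapped, config,
        seed_sequence=_study_seed_sequence(config.rng_seed, UNION_LABEL),
        _index=_index, _sampler=_sampler,
    )
    row = _row_from_results(UNION_LABEL, len(union_genes), len(mapped), results, config.alpha)
    observed = compute_neighborhood(network, seed, mapped)
    members: list[tuple[str, list[str]]] = []
    for node in sorted(observed.level1):
        sources = (
            sorted(s for s, genes in mapped_sets.items() if node in genes)
            if mapped_sets
            else []
        )
        members.append((node, sources))
    return row, members
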