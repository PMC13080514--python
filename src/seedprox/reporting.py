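"""Tabular rendering of study reports (TSV for eyes, JSON for round trips)."""

from __future__ import annotations

import json
import math
from pathlib import Path

from .neighborhood import STATISTICS
from .workflow import StatRow, StudyReport, StudyRow

__all__ = [
    "render_report_tsv",
    "render_report_json",
    "report_from_json",
    "render_members_tsv",
]

_COLUMNS = ["study", "n_genes", "n_mapped"] + [
    f"{stat}_{field}" for stat in STATISTICS for field in ("obs", "fold", "p")
] + ["significant", "note"]


def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.4g}"


def _row_cells(row: StudyRow) -> list[str]:
    cells = [row.study, str(row.n_genes), str(row.n_mapped)]
    for stat in STATISTICS:
        s = row.stats[stat]
        cells += [str(s.observed), _fmt(s.fold_change), _fmt(s.p_value)]
    cells += ["true" if row.significant else "false", row.note]
    return cells


def render_report_tsv(report: StudyReport) -> str:
    """Stable-column TSV, one row per study; the union row (if any) comes last."""
    lines = ["\t".join(_COLUMNS)]
    for row in report.rows:
        lines.append("\t".join(_row_cells(row)))
    if report.union_row is not None:
        lines.append("\t".join(_row_cells(report.union_row)))
    return "\n".join(lines) + "\n"


def _row_dict(row: StudyRow) -> dict:
    return {
        "study": row.study,
        "n_genes": row.n_genes,
        "n_mapped": row.n_mapped,
        "stats": {
            stat: {
                "observed": row.stats[stat].observed,
                "fold_change": None
                if math.isnan(row.stats[stat].fold_change)
                else row.stats[stat].fold_change,
                "p_value": row.stats[stat].p_value,
            }
            for stat in STATISTICS
        },
        "significant": row.significant,
        "note": row.note,
    }


def render_report_json(report: StudyReport) -> str:
    payload = {
        "alpha": report.alpha,
        "rng_seed": report.rng_seed,
        "rows": [_row_dict(r) for r in report.rows],
        "union_row": _row_dict(report.union_row) if report.union_row else None,
        "union_members": [[node, sources] for node, sources in report.union_members],
    }
    return json.dumps(payload, indent=2)


def _row_from_dict(data: dict) -> StudyRow:
    stats = {
        stat: StatRow(
            observed=entry["observed"],
            fold_change=math.nan if entry["fold_change"] is None else entry["fold_change"],
            p_value=entry["p_value"],
        )
        for stat, entry in data["stats"].items()
    }
    return StudyRow(
        study=data["study"],
        n_genes=data["n_genes"],
        n_mapped=data["n_mapped"],
        stats=stats,
        significant=data["significant"],
        note=data.get("note", ""),
    )


def report_from_json(text: str) -> StudyReport:
    """Inverse of :func:`render_report_json`; round-trips to an equal report."""
    payload = json.loads(text)
    return StudyReport(
        rows=[_row_from_dict(d) for d in payload["rows"]],
        union_row=_row_from_dict(payload["union_row"]) if payload["union_row"] else None,
        union_members=[(node, list(src)) for node, src in payload["union_members"]],
        alpha=payload["alpha"],
        rng_seed=payload["rng_seed"],
    )


def render_members_tsv(report: StudyReport) -> str:
    """Level-1 interactors of the union with their contributing studies."""
    lines = ["interactor\tsource_studies"]
    for node, sources in report.union_members:
        lines.append(f"{node}\t{','.join(sources)}")
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, outdir: str | Path, stem: str = "study_report") -> None:
    outdir = Path(outdir)
    (outdir / f"{stem}.tsv").write_text(render_report_tsv(report))
    (outdir / f"{stem}.json").write_text(render_report_json(report))
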