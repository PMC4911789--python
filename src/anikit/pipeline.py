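"""End-to-end run: read genomes, predict CDSs, align, filter, ANI, tree.

This is the library face of the command-line workflow: one query genome is
compared against a set of reference genomes (a directory of FASTA files
standing in for a hosted genome database), and a report bundle is written —
ranked best-match table, symmetrized matrix (TSV + PHYLIP), Newick tree
when at least three genomes are present, and a machine-readable JSON of
every directed comparison. All outputs are deterministic functions of the
inputs; reruns with the same configuration produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from anikit._version import __version__ as _version
from anikit.aligner import ScoringScheme
from anikit.ani import ANIMatrix, FilterParams, build_matrix
from anikit.genome_io import FastaFormatError, Genome, read_fasta
from anikit.orf_finder import OrfParams
from anikit.phylo import ani_to_distance, ascii_tree, neighbor_joining

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_NO_VALID_COMPARISON = 3


class InputError(ValueError):
    """Unreadable or inconsistent inputs (exit code 2 in the CLI)."""


class NoValidComparisonError(RuntimeError):
    """Every comparison was filtered out by the 50% coverage rule."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    message: str


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    query_path: str | Path
    reference_paths: Sequence[str | Path] = ()
    reference_dir: str | Path | None = None
    output_dir: str | Path = "anikit_out"
    filter_params: FilterParams = field(default_factory=FilterParams)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    orf_params: OrfParams = field(default_factory=OrfParams)
    weighted: bool = False
    log_level: str = "INFO"
    seed: int = 0  # reserved for determinism audits; the pipeline is seed-free

    def resolved_reference_paths(self) -> list[Path]:
        paths = [Path(p) for p in self.reference_paths]
        if self.reference_dir is not None:
            exts = {".fa", ".fasta", ".fna"}
            paths.extend(
                sorted(
                    p
                    for p in Path(self.reference_dir).iterdir()
                    if p.suffix.lower() in exts
                )
            )
        return paths


@dataclass
class ReportBundle:
    """Paths and in-memory results of one completed run."""

    matrix: ANIMatrix
    ranked: list[dict]
    newick: str | None
    output_dir: Path
    files: dict[str, Path]


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Check inputs and parameter ranges without starting compute."""
    diags: list[Diagnostic] = []
    qp = Path(config.query_path)
    if not qp.exists():
        diags.append(Diagnostic("error", f"query FASTA not found: {qp}"))
    refs = []
    try:
        refs = config.resolved_reference_paths()
    except FileNotFoundError:
        diags.append(
            Diagnostic("error", f"reference dir not found: {config.reference_dir}")
        )
    if not refs:
        diags.append(Diagnostic("error", "no references found"))
    seen: dict[str, Path] = {}
    for p in [qp] + list(refs):
        if not p.exists():
            diags.append(Diagnostic("error", f"reference FASTA not found: {p}"))
            continue
        try:
            g = read_fasta(p)
        except FastaFormatError as exc:
            diags.append(Diagnostic("error", str(exc)))
            continue
        if g.genome_id in seen:
            diags.append(
                Diagnostic(
                    "error",
                    f"duplicate genome id {g.genome_id!r}: {seen[g.genome_id]} "
                    f"and {p}",
                )
            )
        else:
            seen[g.genome_id] = p
    try:
        _ = config.filter_params, config.scoring, config.orf_params
    except ValueError as exc:  # dataclass validation
        diags.append(Diagnostic("error", str(exc)))
    return diags


def _rank_table(matrix: ANIMatrix, query_id: str) -> list[dict]:
    rows = []
    for tid in matrix.genome_ids:
        if tid == query_id:
            continue
        fwd = matrix.results[(query_id, tid)]
        rev = matrix.results[(tid, query_id)]
        vals = [r.ani_pct for r in (fwd, rev) if r.valid and r.ani_pct is not None]
        sym = sum(vals) / len(vals) if vals else None
        rows.append(
            {
                "target": tid,
                "symmetrized_ani_pct": sym,
                "ani_query_to_target": fwd.ani_pct,
                "ani_target_to_query": rev.ani_pct,
                "n_cds_kept": fwd.n_cds_kept,
                "alignable_fraction": round(fwd.alignable_fraction, 6),
                "valid_query_to_target": fwd.valid,
                "valid_target_to_query": rev.valid,
            }
        )
    # descending ANI; undefined last; genome id breaks ties deterministically
    rows.sort(
        key=lambda r: (
            r["symmetrized_ani_pct"] is None,
            -(r["symmetrized_ani_pct"] or 0.0),
            r["target"],
        )
    )
    return rows


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute read -> predict -> align -> filter -> ANI -> matrix -> tree.

    Raises InputError for unreadable inputs and NoValidComparisonError when
    the 50% rule filters out every query-reference comparison.
    """
    diags = validate_inputs(config)
    errors = [d for d in diags if d.level == "error"]
    if errors:
        raise InputError("; ".join(d.message for d in errors))
    query = read_fasta(config.query_path)
    refs = [read_fasta(p) for p in config.resolved_reference_paths()]
    genomes = [query] + refs
    logger.info(
        "comparing query %s against %d reference(s)", query.genome_id, len(refs)
    )
    matrix = build_matrix(
        genomes,
        params=config.filter_params,
        scoring=config.scoring,
        orf_params=config.orf_params,
        weighted=config.weighted,
    )
    ranked = _rank_table(matrix, query.genome_id)
    query_rows = [
        matrix.results[(query.genome_id, r.genome_id)] for r in refs
    ] + [matrix.results[(r.genome_id, query.genome_id)] for r in refs]
    if not any(r.valid for r in query_rows):
        raise NoValidComparisonError(
            "every query-reference comparison was filtered out by the "
            "coverage rule",
            [r.to_dict() for r in query_rows],
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["ranked_tsv"] = out / "best_matches.tsv"
    with open(files["ranked_tsv"], "w") as fh:
        cols = [
            "target",
            "symmetrized_ani_pct",
            "ani_query_to_target",
            "ani_target_to_query",
            "n_cds_kept",
            "alignable_fraction",
            "valid_query_to_target",
            "valid_target_to_query",
        ]
        fh.write("\t".join(cols) + "\n")
        for row in ranked:
            fh.write(
                "\t".join(
                    "NA" if row[c] is None else
                    (f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c]))
                    for c in cols
                )
                + "\n"
            )

    files["matrix_tsv"] = out / "ani_matrix.tsv"
    matrix.to_tsv(files["matrix_tsv"])
    files["matrix_phylip"] = out / "ani_matrix.phylip"
    matrix.to_phylip(files["matrix_phylip"])

    newick: str | None = None
    if len(genomes) >= 3:
        tree = neighbor_joining(ani_to_distance(matrix))
        newick = tree.newick
        files["tree_newick"] = out / "tree.nwk"
        files["tree_newick"].write_text(newick + "\n")
        files["tree_ascii"] = out / "tree.txt"
        files["tree_ascii"].write_text(ascii_tree(tree))

    files["report_json"] = out / "report.json"
    report = {
        "anikit_version": _version,
        "query": query.genome_id,
        "references": [r.genome_id for r in refs],
        "parameters": {
            "filter": asdict(config.filter_params),
            "scoring": asdict(config.scoring),
            "orf": {
                "min_length": config.orf_params.min_length,
                "max_overlap": config.orf_params.max_overlap,
                "start_codons": sorted(config.orf_params.start_codons),
                "stop_codons": sorted(config.orf_params.stop_codons),
            },
            "weighted": config.weighted,
        },
        "comparisons": [
            matrix.results[key].to_dict() for key in sorted(matrix.results)
        ],
        "ranked_best_matches": ranked,
        "newick": newick,
    }
    files["report_json"].write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    files["run_log"] = out / "run_log.txt"
    files["run_log"].write_text(
        f"anikit {_version}\nquery: {config.query_path}\n"
        + "".join(f"reference: {p}\n" for p in config.resolved_reference_paths())
        + f"parameters: {json.dumps(report['parameters'], sort_keys=True)}\n"
    )
    return ReportBundle(
        matrix=matrix, ranked=ranked, newick=newick, output_dir=out, files=files
    )
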