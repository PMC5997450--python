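"""End-to-end orchestration: load or generate, annotate, measure, report.

A run consumes either annotation tables or a synthetic genotype model,
applies geometry (when traces are present) and the annotation rules, and
writes one JSON report per analysis (specificity, redundancy, dominance,
sibling exclusivity, mixed-terminal fraction, branch counts) plus a
GraphML wiring diagram per specimen and a manifest sufficient to
reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .annotation import AnnotationConfig, annotate
from .geometry import GeometryConfig, compute_all_contacts
from .model import (NeuromastConnectome, load_annotation_tables, validate,
                    write_connectome_graph, write_connectome_tables)
from .stats import (branch_count_stats, dominance_stats,
                    mixed_terminal_fraction, redundancy_stats,
                    sibling_exclusivity, significance_stars,
                    specificity_stats, two_tailed_t)
from .synthetic import GenotypeModel, generate_connectome

log = logging.getLogger("neuromast.pipeline")

REPORT_NAMES = ("specificity", "redundancy", "dominance", "sibling",
                "mixed_fraction", "branch_counts")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mode: str = "synthetic"                     # "synthetic" or "tables"
    outdir: str | Path = "neuromast-run"
    seed: int | None = None                     # required in synthetic mode
    genotype: str = "wild-type"
    n_specimens: int = 1
    grouping: str | None = None                 # default by genotype
    model_overrides: dict[str, Any] = field(default_factory=dict)
    table_dirs: list[str] = field(default_factory=list)   # tables mode
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if self.mode == "tables" and not self.table_dirs:
            raise ValueError("tables mode requires table_dirs")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        geo = GeometryConfig(**raw.pop("geometry", {}))
        ann = AnnotationConfig(**raw.pop("annotation", {}))
        return cls(geometry=geo, annotation=ann, **raw)

    def effective_grouping(self) -> str:
        if self.grouping:
            return self.grouping
        return "polarity" if self.genotype == "wild-type" else "ap_position"

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        d["versions"] = {"neuromast": __version__,
                         "python": platform.python_version(),
                         "numpy": np.__version__}
        return d


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                               default=_json_default) + "\n")


def _text_table(report: Mapping[str, Any]) -> str:
    lines = []

    def walk(prefix: str, obj: Any) -> None:
        if isinstance(obj, Mapping):
            for k in sorted(obj, key=str):
                walk(f"{prefix}{k}.", obj[k])
        elif isinstance(obj, (list, tuple)):
            lines.append(f"{prefix[:-1]}\t" + "\t".join(str(v) for v in obj))
        else:
            lines.append(f"{prefix[:-1]}\t{obj}")

    walk("", report)
    return "\n".join(lines) + "\n"


def _per_specimen_metrics(conns: Sequence[NeuromastConnectome],
                          grouping: str) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for conn in conns:
        spec = specificity_stats([conn], grouping=grouping)
        mixed = mixed_terminal_fraction([conn])
        sib = sibling_exclusivity([conn])
        branches = branch_count_stats([conn])
        out[conn.specimen_id] = {
            "ribbon_specificity": spec.ribbon_specificity,
            "contact_specificity": spec.contact_specificity_all,
            "mixed_fraction": mixed["mixed_fraction"],
            "sibling_shared_fraction": sib["shared_fraction"],
            "branch_count": float(branches["counts"][0]),
        }
    return out


def run(config: RunConfig) -> dict:
    """Execute a full analysis run; returns the report bundle (also on disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    conns: list[NeuromastConnectome] = []
    if config.mode == "synthetic":
        try:
            model = GenotypeModel(genotype=config.genotype,
                                  **config.model_overrides)
            seeds = np.random.SeedSequence(config.seed).generate_state(
                config.n_specimens) % (2 ** 31)
            for s in seeds:
                conn, ledger = generate_connectome(model, int(s))
                conns.append(conn)
                tdir = outdir / "tables" / conn.specimen_id
                write_connectome_tables(conn, tdir)
                ledger.to_json(tdir / "ledger.json")
        except (ValueError, KeyError) as exc:
            raise PipelineError("generate", str(exc)) from exc
    else:
        for tdir in config.table_dirs:
            try:
                conns.append(load_annotation_tables(tdir))
            except Exception as exc:
                raise PipelineError("load", f"{tdir}: {exc}") from exc

    for conn in conns:
        try:
            if conn.traces and conn.contacts is None:
                compute_all_contacts(conn, config.geometry)
            if conn.contacts is None:
                raise ValueError("no traces and no planted contacts")
            annotate(conn, config.annotation)
        except Exception as exc:
            raise PipelineError("annotate", f"{conn.specimen_id}: {exc}") from exc
        problems = validate(conn)
        if problems:
            raise PipelineError(
                "validate", f"{conn.specimen_id}: {problems[0]}"
                f" (+{len(problems) - 1} more)" if len(problems) > 1
                else f"{conn.specimen_id}: {problems[0]}")

    grouping = config.effective_grouping()
    try:
        bundle: dict[str, Any] = {
            "specificity": specificity_stats(conns, grouping=grouping).to_dict(),
            "redundancy": redundancy_stats(conns),
            "dominance": dominance_stats(conns, grouping=grouping).to_dict(),
            "sibling": sibling_exclusivity(conns),
            "mixed_fraction": mixed_terminal_fraction(conns),
            "branch_counts": branch_count_stats(conns),
        }
    except Exception as exc:
        raise PipelineError("statistics", str(exc)) from exc
    bundle["per_specimen_metrics"] = _per_specimen_metrics(conns, grouping)

    for conn in conns:
        try:
            write_connectome_graph(conn, outdir / "graphs" /
                                   f"{conn.specimen_id}.graphml")
        except Exception as exc:
            raise PipelineError("graph", f"{conn.specimen_id}: {exc}") from exc

    reports_dir = outdir / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    for name in REPORT_NAMES:
        _write_json(reports_dir / f"{name}.json", bundle[name])
        (reports_dir / f"{name}.txt").write_text(_text_table(bundle[name]))
    _write_json(reports_dir / "per_specimen_metrics.json",
                bundle["per_specimen_metrics"])
    _write_json(outdir / "manifest.json", config.to_manifest())
    return bundle


def compare_runs(bundle_a: Mapping[str, Any], bundle_b: Mapping[str, Any]) -> dict:
    """Per-metric two-tailed t comparison of two report bundles.

    Uses the per-specimen metric tables; each side needs at least two
    specimens, and the two bundles must share at least one metric.
    """
    ma = bundle_a.get("per_specimen_metrics", {})
    mb = bundle_b.get("per_specimen_metrics", {})
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("compare_runs needs >= 2 specimens per group")
    metrics_a = {m for d in ma.values() for m in d}
    metrics_b = {m for d in mb.values() for m in d}
    shared = sorted(metrics_a & metrics_b)
    if not shared:
        raise ValueError("no shared metrics between the two bundles")
    out = {}
    for metric in shared:
        va = [d[metric] for d in ma.values() if not np.isnan(d[metric])]
        vb = [d[metric] for d in mb.values() if not np.isnan(d[metric])]
        if len(va) < 2 or len(vb) < 2:
            continue
        t, p, (sa, sb) = two_tailed_t(va, vb)
        out[metric] = {"mean_a": float(np.mean(va)), "mean_b": float(np.mean(vb)),
                       "sem_a": sa, "sem_b": sb, "t": t, "p": p,
                       "stars": significance_stars(p),
                       "n_a": len(va), "n_b": len(vb)}
    if not out:
        raise ValueError("no metric had >= 2 non-NaN values per group")
    return out
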