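"""End-to-end run orchestration: purge -> classify -> align -> trees -> RF.

A run writes one fresh directory per invocation (never overwritten) with
machine-readable artifacts for each stage and a manifest recording the
seed, parameters and sha256 of every output, so identical configurations
reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .core_io import PrecursorRecord, read_fasta, write_fasta
from .dnalm import PRESETS, progressive_align
from .families import classify_family, classify_gnrh_lineage
from .phylo import nj_tree, normalized_rf, p_distance_matrix, robinson_foulds
from .purge import convertase_screen, dibasic_screen, run_purge, structural_screen
from .stats import retention_rate, summarize_pipeline
from .synth import SyntheticConfig, generate_precursors

log = logging.getLogger("nppcur")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str
    in_fasta: Optional[str] = None  # mutually exclusive with synth
    synth: Optional[dict] = None
    presets: tuple = ("dnalm", "default")
    max_align: int = 40  # sequences entering the alignment stage
    allowlist: tuple = ()
    denylist: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.in_fasta is None) == (self.synth is None):
            raise ValueError("config needs exactly one of in_fasta or synth")
        for p in self.presets:
            if p not in PRESETS:
                raise ValueError(f"unknown alignment preset {p!r}")
        if self.max_align < 4:
            raise ValueError("max_align must be >= 4")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(raw)
        for key in ("presets", "allowlist", "denylist"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure raises with a stage-tagged message; artifacts
    written before the failure are retained for inspection.
    """
    out = Path(config.out_dir)
    if out.exists():
        raise FileExistsError(f"run directory {out} already exists")
    out.mkdir(parents=True)
    artifacts: list[Path] = []

    def stage(name):
        log.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("input"):
        if config.synth is not None:
            syn_cfg = SyntheticConfig(**{**config.synth, "seed": config.seed})
            records, truth = generate_precursors(syn_cfg)
            truth_path = out / "truth.tsv"
            with truth_path.open("w") as fh:
                fh.write("record_id\tis_valid\tfamily\tcopy_count\tcorruption\n")
                for t in truth:
                    fh.write(
                        f"{t.record_id}\t{int(t.is_valid)}\t{t.family}"
                        f"\t{t.copy_count}\t{t.corruption or ''}\n"
                    )
            artifacts.append(truth_path)
            input_path = out / "input.fasta"
            write_fasta(records, input_path)
            artifacts.append(input_path)
        else:
            records = read_fasta(config.in_fasta)

    with stage("purge"):
        retained, counts = run_purge(records, config.allowlist, config.denylist)
        purge_path = out / "purge.tsv"
        with purge_path.open("w") as fh:
            fh.write(
                "record_id\tpassed_structural\tpassed_dibasic\tpassed_convertase"
                "\tsignal_span\tsites\tpeptides\n"
            )
            for rec in records:
                ann = structural_screen(rec)
                ann.passed_dibasic = dibasic_screen(rec, ann)
                ann.passed_convertase = convertase_screen(rec, ann)
                sites = ";".join(
                    f"{s.pos}:{s.motif}:{s.convertase_score:g}" for s in ann.sites
                )
                peps = ";".join(
                    f"{p.span[0]}-{p.span[1]}:{p.seq}:{int(p.amidated)}"
                    for p in ann.peptides
                )
                span = (
                    f"{ann.signal_span[0]}-{ann.signal_span[1]}"
                    if ann.signal_span
                    else ""
                )
                fh.write(
                    f"{rec.record_id}\t{int(ann.passed_structural)}"
                    f"\t{int(ann.passed_dibasic)}\t{int(ann.passed_convertase)}"
                    f"\t{span}\t{sites}\t{peps}\n"
                )
        artifacts.append(purge_path)
        counts_path = out / "counts.json"
        _write_json(counts_path, summarize_pipeline(counts))
        artifacts.append(counts_path)

    with stage("classify"):
        cls_path = out / "classification.tsv"
        with cls_path.open("w") as fh:
            fh.write("record_id\tcopy_index\tpeptide\tamidated\tfamily\tgnrh_lineage\n")
            for ann in retained:
                for pep in ann.peptides:
                    call = classify_family(pep.seq, pep.amidated)
                    gn = (
                        classify_gnrh_lineage(pep.seq)
                        if call.family == "GnRH"
                        else ""
                    )
                    fh.write(
                        f"{ann.record_id}\t{pep.copy_index}\t{pep.seq}"
                        f"\t{int(pep.amidated)}\t{call.family}\t{gn}\n"
                    )
        artifacts.append(cls_path)

    with stage("align-and-trees"):
        ids_retained = {a.record_id for a in retained}
        align_records = [r for r in records if r.record_id in ids_retained]
        align_records = sorted(align_records, key=lambda r: r.record_id)[
            : config.max_align
        ]
        trees = {}
        if len(align_records) >= 4:
            for preset in config.presets:
                aln = progressive_align(align_records, PRESETS[preset])
                aln_path = out / f"alignment_{preset}.fasta"
                with aln_path.open("w") as fh:
                    for sid, row in zip(aln.ids, aln.rows):
                        fh.write(f">{sid}\n{row}\n")
                artifacts.append(aln_path)
                D, labels = p_distance_matrix(aln)
                tree = nj_tree(D, labels)
                tree_path = out / f"tree_{preset}.nwk"
                tree_path.write_text(tree.to_newick() + "\n")
                artifacts.append(tree_path)
                trees[preset] = tree

    with stage("compare"):
        report = {
            "n_input": counts.n_input,
            "n_retained": len(retained),
            "retention_pct": retention_rate(counts.n_convertase, counts.n_input)
            if counts.n_input
            else None,
        }
        if len(trees) == 2:
            a, b = (trees[p] for p in config.presets)
            report["rf"] = robinson_foulds(a, b)
            report["rf_normalized"] = normalized_rf(a, b)
        rf_path = out / "rf_report.json"
        _write_json(rf_path, report)
        artifacts.append(rf_path)

    with stage("manifest"):
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "presets": list(config.presets),
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        }
        _write_json(out / "manifest.json", manifest)

    return out
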