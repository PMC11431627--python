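"""YAML pipeline configuration and the multi-stage runner.

A pipeline config is a mapping of known stage blocks; unknown keys are
rejected by name.  ``run_pipeline`` executes the requested stages in
dependency order into a run directory, writes a manifest (inputs,
parameters, seed, output checksums) plus a resolved copy of the config,
and reruns byte-identically under the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

_STAGES = ("simulate", "reconstruct", "annotate", "motifs")

_KNOWN_KEYS = {
    "seed": int,
    "outdir": str,
    "stages": list,
    "simulate": {"length", "gc_target", "variant", "n_pairs", "read_length",
                 "error_rate", "motif_blacklist"},
    "reconstruct": {"target_gene", "closure_min", "max_rounds", "min_support",
                    "min_anchor", "reference_divergence"},
    "annotate": {"min_aa", "allow_ctg"},
    "motifs": {"motifs", "threshold", "min_expected"},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    stages: list = field(default_factory=lambda: list(_STAGES))
    simulate: dict = field(default_factory=dict)
    reconstruct: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_KNOWN_KEYS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for stage, allowed in _KNOWN_KEYS.items():
            if isinstance(allowed, set) and stage in raw:
                extra = set(raw[stage]) - allowed
                if extra:
                    raise ValueError(f"unknown keys in '{stage}' block: {sorted(extra)}")
        bad = [s for s in raw.get("stages", []) if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "outdir": self.outdir, "stages": list(self.stages),
            "simulate": dict(self.simulate), "reconstruct": dict(self.reconstruct),
            "annotate": dict(self.annotate), "motifs": dict(self.motifs),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir=None) -> Path:
    """Execute the configured stages; returns the run directory.

    A failing stage halts the run, leaves partial outputs in place, and
    drops a FAILED marker naming the stage and cause.
    """
    from . import experiments
    from .annotate import find_orfs, module_structure_report
    from .circular import CircularSequence
    from .io import write_fasta, write_gff3, write_tsv
    from .motifs import motif_report
    from .reconstruct import ReconstructionConfig, reconstruct
    from .simulate import PlasmidSpec, ReadSimParams, simulate_paired_reads, simulate_plasmid

    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))
    manifest = {"seed": config.seed, "stages": [], "outputs": {}}
    state: dict = {}
    try:
        for stage in config.stages:
            params = getattr(config, stage)
            manifest["stages"].append({"name": stage, "params": params})
            if stage == "simulate":
                spec = PlasmidSpec(seed=config.seed,
                                   **{k: v for k, v in params.items()
                                      if k in {"length", "gc_target", "variant"}})
                if "motif_blacklist" in params:
                    spec.motif_blacklist = tuple(params["motif_blacklist"])
                plasmid, annotations = simulate_plasmid(spec)
                rp = ReadSimParams(seed=config.seed + 1,
                                   **{k: v for k, v in params.items()
                                      if k in {"n_pairs", "read_length", "error_rate"}})
                pairs = simulate_paired_reads(plasmid, rp)
                write_fasta(out / "truth.fasta", [plasmid])
                write_gff3(out / "truth.gff3", plasmid, annotations)
                state.update(plasmid=plasmid, annotations=annotations, pairs=pairs)
            elif stage == "reconstruct":
                divergence = params.get("reference_divergence", 0.25)
                ref = CircularSequence(
                    experiments.mutate_sequence(state["plasmid"].seq, divergence,
                                                config.seed + 2),
                    "reference",
                )
                refann = [
                    GeneAnnotationCopy(a, "reference") for a in state["annotations"]
                ]
                cfg = ReconstructionConfig(
                    **{k: v for k, v in params.items() if k != "reference_divergence"}
                )
                result = reconstruct(state["pairs"], [(ref, refann)], cfg,
                                     reference_for_rotation=ref)
                if not result.closed:
                    raise RuntimeError("reconstruction did not reach ring closure")
                write_fasta(out / "reconstructed.fasta", [result.monomer])
                write_tsv(out / "rounds.tsv",
                          [r for r in result.log if r.get("stage") == "extend"])
                state["monomer"] = result.monomer
            elif stage == "annotate":
                target = state.get("monomer", state["plasmid"])
                orfs = find_orfs(target, **params)
                rows = [
                    {"start": o.start + 1, "end": o.end, "strand": o.strand,
                     "aa": len(o.protein)}
                    for o in orfs
                ]
                write_tsv(out / "orfs.tsv", rows)
                structure = module_structure_report(state["annotations"], state["plasmid"])
                (out / "structure.json").write_text(json.dumps(structure, indent=1))
            elif stage == "motifs":
                target = state.get("monomer", state["plasmid"])
                reports = motif_report(target, **params)
                write_tsv(out / "motifs.tsv", [
                    {"motif": r.motif, "observed": r.observed,
                     "expected": None if r.expected is None else round(r.expected, 3),
                     "ratio": None if r.ratio is None else round(r.ratio, 3),
                     "classification": r.classification}
                    for r in reports
                ])
    except Exception as exc:  # halt with stage name and cause
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in {"manifest.json"}:
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def GeneAnnotationCopy(a, seqid):
    from .circular import GeneAnnotation

    return GeneAnnotation(seqid, a.label, a.start, a.end, a.strand, a.feature_type,
                          dict(a.attributes))
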