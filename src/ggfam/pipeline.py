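"""Config-driven orchestration of the full analysis sequence.

Stages run in dependency order: motif scan -> homology screen -> rooting and
event labeling -> expression clustering -> ancestral states + permutation
test.  A YAML config supplies per-stage parameters; every omitted parameter
falls back to the study defaults (homology threshold 130 Dayhoff units,
detection floor 2.5 log2, dendrogram cut 0.35, 10,000 permutations).  Each
run writes a manifest recording the config snapshot, per-stage input/output
checksums and seeds, so a rerun with the same config reproduces identical
outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version

from ggfam import expression as xp
from ggfam import homology as hm
from ggfam import motifs as mt
from ggfam import parsimony as ps
from ggfam.events import label_events, root_by_parsimony
from ggfam.trees import SpeciesMap, parse_newick, write_newick

#: stage -> {key: (default, type, validator)}
_SCHEMA: dict[str, dict[str, tuple]] = {
    "scan": {
        "enabled": (False, bool, None),
        "fasta": (None, str, None),
        "out": ("architectures.tsv", str, None),
        "hydrophobic": ("AVLIMFWP", str, None),
    },
    "homologs": {
        "enabled": (False, bool, None),
        "queries": (None, str, None),
        "candidates": (None, str, None),
        "threshold": (130.0, float, lambda v: v >= 0 or "threshold must be >= 0"),
        "inclusive": (False, bool, None),
        "matrix": (None, str, None),
        "out": ("homologs.tsv", str, None),
    },
    "root": {
        "enabled": (False, bool, None),
        "tree": (None, str, None),
        "species_map": (None, str, None),
        "species_tree": (None, str, None),
        "out": ("rooted.nwk", str, None),
        "audit": ("rooting_audit.tsv", str, None),
    },
    "cluster": {
        "enabled": (False, bool, None),
        "expr": (None, str, None),
        "height": (0.35, float, lambda v: v >= 0 or "height must be >= 0"),
        "detect": (2.5, float, None),
        "linkage": (
            "complete",
            str,
            lambda v: v in ("complete", "average", "single")
            or "linkage must be complete/average/single",
        ),
        "merge": (None, str, None),
        "out": ("clusters.tsv", str, None),
    },
    "asr": {
        "enabled": (False, bool, None),
        "tree": (None, str, None),
        "states": (None, str, None),
        "permutations": (10000, int, lambda v: v >= 1 or "permutations must be >= 1"),
        "seed": (17, int, None),
        "out": ("asr.json", str, None),
    },
}


@dataclass
class PipelineConfig:
    stages: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, stage: str) -> dict:
        return self.stages[stage]

    @classmethod
    def defaults(cls) -> "PipelineConfig":
        return cls(
            stages={
                st: {k: v[0] for k, v in keys.items()} for st, keys in _SCHEMA.items()
            }
        )


def validate_config(path: str | Path | None, overrides: dict | None = None) -> PipelineConfig:
    """Load, default-fill and type-check a pipeline config.

    Unknown stages/keys are rejected with a closest-match suggestion; all
    problems are reported at once.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        raw = yaml.safe_load(p.read_text()) or {}
    if overrides:
        for stage, kv in overrides.items():
            raw.setdefault(stage, {}).update(kv)

    problems: list[str] = []
    cfg = PipelineConfig.defaults()
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of stage sections")
    for stage, section in raw.items():
        if stage not in _SCHEMA:
            hint = difflib.get_close_matches(stage, _SCHEMA, n=1)
            problems.append(
                f"unknown stage {stage!r}"
                + (f" (did you mean {hint[0]!r}?)" if hint else "")
            )
            continue
        if section is None:
            continue
        for key, value in section.items():
            if key not in _SCHEMA[stage]:
                hint = difflib.get_close_matches(key, _SCHEMA[stage], n=1)
                problems.append(
                    f"{stage}: unknown key {key!r}"
                    + (f" (did you mean {hint[0]!r}?)" if hint else "")
                )
                continue
            default, typ, check = _SCHEMA[stage][key]
            if value is None:
                cfg.stages[stage][key] = None
                continue
            try:
                if typ is bool and not isinstance(value, bool):
                    raise ValueError
                value = typ(value)
            except (TypeError, ValueError):
                problems.append(f"{stage}.{key}: cannot coerce {value!r} to {typ.__name__}")
                continue
            if check is not None:
                msg = check(value)
                if msg is not True and isinstance(msg, str):
                    problems.append(f"{stage}.{key}: {msg}")
                    continue
            cfg.stages[stage][key] = value
    # dependency check happens before execution
    if cfg["asr"]["enabled"] and not cfg["cluster"]["enabled"] and not cfg["asr"]["states"]:
        problems.append("asr: needs a states file when the cluster stage is disabled")
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2,
        )


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, log=print) -> RunManifest:
    """Run every enabled stage in dependency order; write outputs + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        ver = _pkg_version("ggfam")
    except Exception:
        ver = "0"
    manifest = RunManifest(version=ver, config=cfg.stages)

    def record(stage: str, inputs: list[Path], outputs: list[Path], **extra):
        manifest.stages.append(
            {
                "stage": stage,
                "inputs": {str(p): _sha256(p) for p in inputs},
                "outputs": {str(p): _sha256(p) for p in outputs},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                **extra,
            }
        )

    def out_path(stage: str, key: str) -> Path:
        return outdir / cfg[stage][key]

    if cfg["scan"]["enabled"]:
        log("BEGIN scan")
        src = Path(cfg["scan"]["fasta"])
        archs = mt.scan_fasta(src, frozenset(cfg["scan"]["hydrophobic"]))
        dest = out_path("scan", "out")
        mt.architecture_table(archs).to_csv(dest, sep="\t", index=False)
        record("scan", [src], [dest], n_sequences=len(archs))
        log(f"END scan ({len(archs)} sequences)")

    if cfg["homologs"]["enabled"]:
        log("BEGIN homologs")
        q = Path(cfg["homologs"]["queries"])
        c = Path(cfg["homologs"]["candidates"])
        matrix = (
            hm.load_matrix(cfg["homologs"]["matrix"])
            if cfg["homologs"]["matrix"]
            else hm.load_matrix()
        )
        sels = hm.screen_homologs(
            mt.read_fasta(q),
            mt.read_fasta(c),
            matrix,
            threshold=cfg["homologs"]["threshold"],
            inclusive=cfg["homologs"]["inclusive"],
        )
        dest = out_path("homologs", "out")
        hm.selection_table(sels, cfg["homologs"]["inclusive"]).to_csv(
            dest, sep="\t", index=False
        )
        record("homologs", [q, c], [dest], n_passed=sum(
            s.passed(cfg["homologs"]["inclusive"]) for s in sels
        ))
        log(f"END homologs ({len(sels)} candidates)")

    if cfg["root"]["enabled"]:
        log("BEGIN root")
        tree_path = Path(cfg["root"]["tree"])
        tree = parse_newick(tree_path)
        smap = (
            SpeciesMap.from_tsv(cfg["root"]["species_map"])
            if cfg["root"]["species_map"]
            else SpeciesMap()
        )
        sp_tree = (
            parse_newick(Path(cfg["root"]["species_tree"]))
            if cfg["root"]["species_tree"]
            else None
        )
        rooted, audit = root_by_parsimony(tree, smap, sp_tree)
        label_events(rooted)
        dest = out_path("root", "out")
        dest.write_text(write_newick(rooted, include_events=True) + "\n")
        audit_dest = out_path("root", "audit")
        pd.DataFrame(
            [
                {
                    "edge_id": a.edge_id,
                    "dup_count": a.dup_count,
                    "loss_count": a.loss_count,
                    "total": a.total,
                    "chosen": a.chosen,
                }
                for a in audit
            ]
        ).to_csv(audit_dest, sep="\t", index=False)
        record(
            "root",
            [tree_path],
            [dest, audit_dest],
            loss_model="lca-reconciliation" if sp_tree else "duplications-only",
        )
        log("END root")

    states_path = Path(cfg["asr"]["states"]) if cfg["asr"]["states"] else None

    if cfg["cluster"]["enabled"]:
        log("BEGIN cluster")
        expr_path = Path(cfg["cluster"]["expr"])
        m = xp.load_expression(expr_path, detection_threshold=cfg["cluster"]["detect"])
        if cfg["cluster"]["merge"]:
            merge_df = pd.read_csv(cfg["cluster"]["merge"], sep="\t")
            m = xp.merge_probesets(
                m, dict(zip(merge_df.iloc[:, 0], merge_df.iloc[:, 1]))
            )
        assign = xp.cluster_profiles(
            xp.pearson_distance(m),
            linkage=xp.Linkage(cfg["cluster"]["linkage"]),
            cut_height=cfg["cluster"]["height"],
        )
        dest = out_path("cluster", "out")
        xp.cluster_table(assign).to_csv(dest, sep="\t", index=False)
        record("cluster", [expr_path], [dest], n_clusters=assign.n_clusters)
        log(f"END cluster ({assign.n_clusters} clusters)")
        if states_path is None:
            states_path = dest

    if cfg["asr"]["enabled"]:
        log("BEGIN asr")
        tree_path = Path(cfg["asr"]["tree"])
        tree = parse_newick(tree_path)
        if states_path is None:
            raise ValueError("asr: no states file available")
        if states_path.suffix == ".tsv" and "cluster_id" in states_path.read_text().splitlines()[0]:
            df = pd.read_csv(states_path, sep="\t")
            states = dict(zip(df["gene_id"], df["state"].astype(int)))
        else:
            states = ps.read_states(states_path)
        result = ps.fitch_parsimony(tree, states)
        perm = ps.permutation_test(
            tree, states, n=cfg["asr"]["permutations"], seed=cfg["asr"]["seed"]
        )
        dest = out_path("asr", "out")
        dest.write_text(json.dumps(perm.to_dict(), indent=2) + "\n")
        nodes_dest = outdir / "ancestral_states.tsv"
        ps.ancestral_report(tree, result).to_csv(nodes_dest, sep="\t", index=False)
        record("asr", [tree_path, states_path], [dest, nodes_dest], observed=result.score)
        log(f"END asr (score {result.score}, p {perm.p:.4g})")

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
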