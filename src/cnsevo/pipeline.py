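"""Configuration-driven orchestration of the full analysis.

A single YAML config drives simulate -> align -> calibrate -> detect ->
phylo -> annotate -> profiles on a simulated clade. Every source of
randomness flows from the global seed through per-stage derived seeds, so
a rerun with the same config is reproducible; a JSON manifest records each
artifact with its SHA-256 digest and the stage parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import annotate, calibrate, detect, phylo, profiles
from .align import local_align, write_hits
from .seqio import write_bed
from .simulate import SimConfig, LossEvent, RelocationEvent, simulate_clade, emit_ortholog_cds

logger = logging.getLogger(__name__)

STAGES = ("simulate", "align", "calibrate", "detect", "phylo", "annotate",
          "profiles")


@dataclass
class RunConfig:
    """Validated run configuration; see ``RunConfig.from_yaml``."""

    seed: int
    reference: str
    members: list[str]
    outgroups: list[str]
    stages: list[str]
    sim: SimConfig
    evalue_max: float = 1e-5
    engine: str = "auto"
    min_length: int = 100
    bootstrap_reps: int = 100

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        order = {s: i for i, s in enumerate(STAGES)}
        if sorted(self.stages, key=order.get) != self.stages:
            raise ValueError("stages must appear in pipeline order")
        roles = [self.reference] + self.members + self.outgroups
        if len(set(roles)) != len(roles):
            raise ValueError("every species may appear in exactly one role")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim_raw = dict(raw.get("simulate", {}))
        sim_raw.setdefault("seed", raw["seed"])
        sim_raw.setdefault("reference", raw["species"]["reference"])
        sim_raw["loss_events"] = [
            LossEvent(**ev) for ev in sim_raw.get("loss_events", [])]
        sim_raw["relocation_events"] = [
            RelocationEvent(**ev) for ev in sim_raw.get("relocation_events", [])]
        return cls(
            seed=raw["seed"],
            reference=raw["species"]["reference"],
            members=list(raw["species"].get("members", [])),
            outgroups=list(raw["species"].get("outgroups", [])),
            stages=list(raw.get("stages", list(STAGES))),
            sim=SimConfig(**sim_raw),
            evalue_max=float(raw.get("evalue_max", 1e-5)),
            engine=raw.get("engine", "auto"),
            min_length=int(raw.get("min_length", 100)),
            bootstrap_reps=int(raw.get("bootstrap_reps", 100)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    state: dict = {}

    for stage in config.stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            state["sim"] = simulate_clade(config.sim)
            artifacts.update(state["sim"].write(outdir / "sim"))
        elif stage == "align":
            sim = state["sim"]
            ref = {"chr1": sim.genomes[config.reference]}
            state["hits"] = {}
            for sp in config.members + config.outgroups:
                hits = local_align(ref, {"chr1": sim.genomes[sp]},
                                   evalue_max=config.evalue_max,
                                   engine=config.engine)
                state["hits"][sp] = hits
                p = outdir / f"hits_{sp}.tsv"
                write_hits(hits, p)
                artifacts[f"hits_{sp}"] = p
        elif stage == "calibrate":
            sim = state["sim"]
            most_diverged = config.members[-1] if config.members else \
                config.outgroups[0]
            pairs = emit_ortholog_cds(sim, (config.reference, most_diverged))
            spec = calibrate.whole_coding_threshold(pairs, lineage="lineage")
            state["threshold"] = spec
            p = outdir / "thresholds.yaml"
            with open(p, "w") as fh:
                yaml.safe_dump({
                    "lineage": spec.lineage,
                    "whole_coding_divergence": spec.whole_coding_divergence,
                    "whole_coding_sd": spec.whole_coding_sd,
                    "skip3_divergence": spec.skip3_divergence,
                    "n_genes": spec.n_genes,
                    "min_length": spec.min_length,
                }, fh)
            artifacts["thresholds"] = p
        elif stage == "detect":
            sim = state["sim"]
            thr = state["threshold"].whole_coding_divergence
            member_hits = {sp: state["hits"][sp] for sp in config.members}
            tracks = {sp: detect.conserved_track(h, thr, config.min_length)
                      for sp, h in member_hits.items()}
            common = detect.group_common(
                tracks, sim.exclusion_track(config.reference),
                config.min_length, member_hits)
            out_tracks = {sp: detect.conserved_track(
                state["hits"][sp], thr, config.min_length)
                for sp in config.outgroups}
            unique = detect.group_unique(common, out_tracks, config.min_length)
            state["common"], state["unique"] = common, unique
            p = outdir / "cns_common.bed"
            write_bed([r.interval for r in common], p)
            artifacts["cns_common"] = p
            p = outdir / "cns_unique.bed"
            write_bed([r.interval for r in unique], p)
            artifacts["cns_unique"] = p
        elif stage == "phylo":
            sim = state["sim"]
            leaves = sim.leaves()
            alns = []
            for _, row in sim.truth.iterrows():
                if any(row[f"{lf}_start"] < 0 for lf in leaves):
                    continue
                aln = {}
                for lf in leaves:
                    s, e = int(row[f"{lf}_start"]), int(row[f"{lf}_end"])
                    aln[lf] = sim.genomes[lf][s:e].upper()
                if len({len(v) for v in aln.values()}) == 1:
                    alns.append(aln)
            concat = phylo.concat_alignment(alns, leaves)
            if len(concat) >= 3 and len(next(iter(concat.values()))) > 0:
                njres = phylo.nj_tree(concat, bootstrap_reps=config.bootstrap_reps,
                                      seed=config.seed + 1)
                p = outdir / "cns_nj.nwk"
                p.write_text(njres.newick() + "\n")
                artifacts["nj_tree"] = p
                state["nj"] = njres
            losses = _loss_table(sim, state, config)
            if losses is not None:
                p = outdir / "losses.tsv"
                losses.to_csv(p, sep="\t")
                artifacts["losses"] = p
        elif stage == "annotate":
            sim = state["sim"]
            genes = sim.genes[config.reference]
            calls = [annotate.classify_location(r.interval, genes, cns_id=r.cns_id)
                     for r in state.get("common", [])]
            p = outdir / "locations.tsv"
            import pandas as pd
            pd.DataFrame([c.__dict__ for c in calls]).to_csv(p, sep="\t",
                                                             index=False)
            artifacts["locations"] = p
        elif stage == "profiles":
            sim = state["sim"]
            member = config.members[0]
            ivs = [r.interval for r in state.get("common", [])]
            hits = state["hits"][member]
            prof = profiles.conservation_profile(
                ivs, [hits] * len(ivs)) if ivs else None
            if prof is not None and len(prof):
                p = outdir / "conservation_profile.tsv"
                prof.to_csv(p, sep="\t", index=False)
                artifacts["conservation_profile"] = p
            gc = profiles.gc_profile(ivs, {"chr1": sim.genomes[config.reference]})
            if len(gc):
                p = outdir / "gc_profile.tsv"
                gc.to_csv(p, sep="\t", index=False)
                artifacts["gc_profile"] = p
        else:  # pragma: no cover
            raise AssertionError(stage)

    manifest = {
        "seed": config.seed,
        "stages": config.stages,
        "parameters": {
            "evalue_max": config.evalue_max,
            "min_length": config.min_length,
            "engine": config.engine,
        },
        "artifacts": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _loss_table(sim, state, config):
    """Per-branch Dollo loss counts from truth-table presence patterns."""
    import pandas as pd

    leaves = sim.leaves()
    rows = []
    ids = []
    for _, row in sim.truth.iterrows():
        rows.append({lf: row[f"{lf}_start"] >= 0 for lf in leaves})
        ids.append(f"elem{int(row.element_id)}")
    if not rows:
        return None
    presence = pd.DataFrame(rows, index=ids)
    presence = presence[presence.any(axis=1)]
    matrix = phylo.PresenceMatrix(rows=[], presence=presence)
    assignment = phylo.assign_losses(matrix, sim.tree)
    return pd.Series(assignment.per_branch, name="losses").sort_index()
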