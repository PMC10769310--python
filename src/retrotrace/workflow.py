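"""Pipeline stages with config, manifests, and reproducible outputs.

The pipeline runs a two-species HTT world end to end: ``simulate`` plants a
known TE history (one horizontal transfer, one recombinant clade) and emits
genomes, reads, and alignments; ``coverage`` profiles LTR/internal copy
number and calls presence; ``annotate`` classifies copies in the assemblies
and extracts FLE internal regions; ``consensus`` builds strain-specific
consensus sequences with the depth/breadth retention rule; ``divergence``
maps the recombinant's breakpoints; ``phylo`` builds bootstrapped NJ trees
(whole and per-segment); ``htt`` runs the presence/absence parsimony and
the TE-vs-host distance ratio test.  Every stage writes a JSON manifest
(inputs, outputs, parameters, seed, version) into its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import annotate as ann
from . import consensus as cns
from . import coverage as cov
from .divergence import SeqAlignment, detect_breakpoints, partition_alignment, sliding_divergence
from .io import read_fasta, read_te_library, write_fasta, write_te_library
from .phylo import (
    DistanceMatrix,
    bootstrap_support,
    distance_matrix,
    dollo_events,
    htt_signal,
    midpoint_root,
    nj_tree,
    rf_distance,
)
from .scenarios import htt_recombination_truth
from .sequencing import emit_alignments, emit_genomes, simulate_reads

STAGES = ("simulate", "coverage", "annotate", "consensus", "divergence", "phylo", "htt", "all")


class StageError(RuntimeError):
    """A stage cannot run (missing inputs or invalid parameters)."""


@dataclass
class PipelineConfig:
    """All stage parameters, with the published thresholds as defaults."""

    outdir: str = "runs/pipeline"
    seed: int = 1
    # simulation world
    n_per_species: int = 12
    bg_length: int = 40_000
    coverage: float = 50.0
    read_length: int = 100
    error_rate: float = 0.01
    # coverage profiling
    downsample_target: float = 100.0
    tau_ltr: float = 1.0
    tau_int: float = 0.5
    min_mapq_depth: int = 0
    min_genome_depth: float = 10.0
    # consensus
    min_mapq: int = 20
    min_baseq: int = 20
    delta_min: float = 0.75
    beta_min: float = 0.9
    # annotation
    min_identity: float = 80.0
    theta_fle: float = 0.9
    d_join: int = 500
    ltr: dict = field(default_factory=lambda: dataclasses.asdict(ann.LTRParams()))
    # divergence / recombination
    window: int = 50
    step: int = 10
    min_run: int = 5
    # phylogenetics
    bootstrap: int = 100
    well_supported: float = 70.0
    ratio_threshold: float = 0.5

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise StageError(f"config error: unknown keys {sorted(bad)}")
        return cls(**data)

    def to_toml(self, path) -> None:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            return f'"{v}"'

        lines = []
        table = None
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, dict):
                table = (f.name, v)
                continue
            lines.append(f"{f.name} = {fmt(v)}")
        if table:
            lines.append(f"\n[{table[0]}]")
            for k, v in table[1].items():
                lines.append(f"{k} = {fmt(v)}")
        Path(path).write_text("\n".join(lines) + "\n")

    def ltr_params(self) -> ann.LTRParams:
        return ann.LTRParams(**self.ltr)


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _manifest(stage_dir: Path, stage: str, cfg: PipelineConfig, inputs, outputs, extra=None) -> dict:
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    path = stage_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise StageError(f"missing input {path}; run the {hint} stage first")
    return path


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Run one pipeline stage (or ``all``); returns the stage manifest."""
    if stage not in STAGES:
        raise StageError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_toml(outdir / "resolved_config.toml")
    if stage == "all":
        manifest = {}
        for s in STAGES[:-1]:
            manifest[s] = run_stage(s, cfg)
        return manifest
    return globals()[f"_stage_{stage}"](cfg, outdir)


# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "simulate"
    (d / "genomes").mkdir(parents=True, exist_ok=True)
    (d / "reads").mkdir(exist_ok=True)
    (d / "aln").mkdir(exist_ok=True)
    _log(f"simulate: two-species world, {cfg.n_per_species} strains/species, seed {cfg.seed}")
    scen = htt_recombination_truth(n_per_species=cfg.n_per_species, seed=cfg.seed)
    truth = scen.truth
    truth.tree.write(path=str(d / "host_tree.nwk"), schema="newick")
    write_te_library(scen.te_models, d / "te_library.fasta")
    genomes = emit_genomes(truth, bg_length=cfg.bg_length, seed=cfg.seed + 100)
    outputs = [d / "host_tree.nwk", d / "te_library.fasta"]
    for i, strain in enumerate(truth.strains):
        g = genomes[strain]
        fa = d / "genomes" / f"{strain}.fasta"
        bed = d / "genomes" / f"{strain}.truth.bed"
        g.write_fasta(fa)
        g.write_bed(bed)
        fq, _ = simulate_reads(
            g, cfg.coverage, cfg.read_length, cfg.error_rate,
            seed=cfg.seed + 200 + i, out_path=d / "reads" / f"{strain}.fastq",
        )
        bam = emit_alignments(fq, g, scen.te_models, d / "aln" / f"{strain}.bam")
        outputs += [fa, bed, fq, bam]
    with open(d / "events.tsv", "w") as fh:
        fh.write("branch\ttime\tkind\telement\tdetail\n")
        for ev in truth.events:
            fh.write(f"{ev.branch}\t{ev.time:.5f}\t{ev.kind}\t{ev.eid or '.'}\t{json.dumps(ev.detail)}\n")
    rows = []
    for sub in scen.te_models:
        pres = truth.presence(sub)
        internal = truth.internal_presence(sub)
        for strain in truth.strains:
            rows.append(
                {"strain": strain, "subfamily": sub,
                 "present": pres[strain], "internal_present": internal[strain]}
            )
    pd.DataFrame(rows).to_csv(d / "presence_truth.tsv", sep="\t", index=False)
    scenario_meta = {
        "species_of": scen.species_of,
        "donor_species": scen.donor_species,
        "recipient_species": scen.recipient_species,
        "recipient_clade": sorted(scen.recipient_clade),
        "recomb_strains": sorted(scen.recomb_strains),
        "breakpoints": scen.breakpoints,
        "species_divergence": scen.species_divergence,
        "strains": truth.strains,
    }
    (d / "scenario.json").write_text(json.dumps(scenario_meta, indent=2) + "\n")
    outputs += [d / "events.tsv", d / "presence_truth.tsv", d / "scenario.json"]
    return _manifest(d, "simulate", cfg, [], outputs)


def _scenario_meta(outdir: Path) -> dict:
    path = _require(outdir / "simulate" / "scenario.json", "simulate")
    return json.loads(path.read_text())


def _stage_coverage(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "coverage"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    sim = outdir / "simulate"
    te_models = read_te_library(_require(sim / "te_library.fasta", "simulate"))
    rows = []
    flagged = []
    for strain in meta["strains"]:
        fq = _require(sim / "reads" / f"{strain}.fastq", "simulate")
        fa = _require(sim / "genomes" / f"{strain}.fasta", "simulate")
        bam = _require(sim / "aln" / f"{strain}.bam", "simulate")
        genome_length = sum(len(s) for s in read_fasta(fa).values())
        depth = cov.genome_depth_from_fastq(fq, genome_length)
        if cov.is_low_depth(depth, cfg.min_genome_depth):
            flagged.append(strain)
            continue
        # sequencing above the target depth would be thinned here; the
        # simulated worlds sit at or below it, so this records a no-op
        for sub, te in te_models.items():
            ests = {}
            for region, query in (("LTR", te.ltr_query), ("internal", te.internal_query)):
                profile = cov.compute_depth_profile(bam, query, min_mapq=cfg.min_mapq_depth)
                est = cov.estimate_copy_number(profile, genome_depth=depth)
                ests[region] = est
                rows.append(
                    {"strain": strain, "subfamily": sub, "region": region,
                     "cn": est.cn, "breadth": est.breadth, "genome_depth": depth}
                )
            call = cov.call_presence(ests["LTR"], ests["internal"], cfg.tau_ltr, cfg.tau_int)
            rows.append(
                {"strain": strain, "subfamily": sub, "region": "call",
                 "cn": float(call.ltr_present), "breadth": float(call.internal_present),
                 "genome_depth": depth}
            )
    df = pd.DataFrame(rows)
    df.to_csv(d / "copy_number.tsv", sep="\t", index=False)
    calls = df[df.region == "call"].copy()
    calls = calls.rename(columns={"cn": "ltr_present", "breadth": "internal_present"})
    calls[["strain", "subfamily", "ltr_present", "internal_present"]].to_csv(
        d / "presence_calls.tsv", sep="\t", index=False
    )
    _log(f"coverage: {len(meta['strains'])} strains profiled, {len(flagged)} below "
         f"{cfg.min_genome_depth}x excluded")
    return _manifest(
        d, "coverage", cfg,
        [sim / "aln", sim / "reads"],
        [d / "copy_number.tsv", d / "presence_calls.tsv"],
        {"low_depth_flagged": flagged},
    )


def _stage_annotate(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "annotate"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    sim = outdir / "simulate"
    te_models = read_te_library(_require(sim / "te_library.fasta", "simulate"))
    library = list(te_models.values())
    all_rows = []
    fle_records: dict[str, str] = {}
    cand_rows = []
    outputs = []
    for strain in meta["strains"]:
        genome = read_fasta(_require(sim / "genomes" / f"{strain}.fasta", "simulate"))
        hits = ann.find_repeat_hits(genome, library, min_identity=cfg.min_identity)
        chains = ann.defragment_hits(hits, te_models)
        calls = ann.classify_elements(chains, te_models, theta_fle=cfg.theta_fle, d_join=cfg.d_join)
        if len(library) > 1:
            calls = ann.select_best_calls(calls)
        ann.write_gff3(calls, d / f"{strain}.gff3")
        ann.write_bed(calls, d / f"{strain}.bed")
        outputs += [d / f"{strain}.gff3", d / f"{strain}.bed"]
        fle_records.update(ann.extract_fle_internal(calls, genome, te_models))
        for c in calls:
            all_rows.append(
                {"strain": strain, "contig": c.contig, "start": c.start, "end": c.end,
                 "strand": c.strand, "class": c.clazz, "subfamily": c.subfamily,
                 "fraction_of_canonical": round(c.fraction_of_canonical, 4),
                 "nested": c.nested_flag}
            )
        for cand in ann.detect_ltr_candidates(genome, cfg.ltr_params()):
            cand_rows.append(
                {"strain": strain, "contig": cand.contig,
                 "ltr5_start": cand.ltr5[0], "ltr5_end": cand.ltr5[1],
                 "ltr3_start": cand.ltr3[0], "ltr3_end": cand.ltr3[1],
                 "distance": cand.distance, "similarity": round(cand.similarity, 2),
                 "tsd": cand.tsd[0]}
            )
    pd.DataFrame(all_rows).to_csv(d / "elements.tsv", sep="\t", index=False)
    pd.DataFrame(cand_rows).to_csv(d / "ltr_candidates.tsv", sep="\t", index=False)
    write_fasta(fle_records, d / "fle_internal.fasta")
    n_fle = sum(r["class"] == "FLE" for r in all_rows)
    _log(f"annotate: {len(all_rows)} element calls ({n_fle} FLEs) across "
         f"{len(meta['strains'])} strains; {len(cand_rows)} structural LTR candidates")
    outputs += [d / "elements.tsv", d / "ltr_candidates.tsv", d / "fle_internal.fasta"]
    return _manifest(d, "annotate", cfg, [sim / "genomes"], outputs)


def _stage_consensus(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "consensus"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    sim = outdir / "simulate"
    te_models = read_te_library(_require(sim / "te_library.fasta", "simulate"))
    cn_path = _require(outdir / "coverage" / "copy_number.tsv", "coverage")
    cn = pd.read_csv(cn_path, sep="\t")
    # consensus targets the horizontally mobile subfamily (Tsu4 analog)
    sub = "Tsu4" if "Tsu4" in te_models else sorted(te_models)[0]
    te = te_models[sub]
    records = {}
    rows = []
    for strain in meta["strains"]:
        bam = _require(sim / "aln" / f"{strain}.bam", "simulate")
        pileup = cns.build_pileup(bam, te.internal_query, cfg.min_mapq, cfg.min_baseq)
        consensus = cns.call_consensus(pileup, te.internal_seq)
        sel = cn[(cn.strain == strain) & (cn.subfamily == sub) & (cn.region == "internal")]
        consensus.normalized_depth = float(sel.cn.iloc[0]) if len(sel) else 0.0
        retained = cns.filter_consensus(consensus, cfg.delta_min, cfg.beta_min)
        rows.append(
            {"strain": strain, "subfamily": sub,
             "normalized_depth": round(consensus.normalized_depth, 4),
             "breadth": round(consensus.breadth, 4), "retained": retained}
        )
        if retained:
            records[strain] = consensus.sequence
    write_fasta(records, d / "consensus.fasta")
    pd.DataFrame(rows).to_csv(d / "consensus_stats.tsv", sep="\t", index=False)
    _log(f"consensus: {len(records)}/{len(rows)} strains retained at "
         f"depth>={cfg.delta_min}, breadth>={cfg.beta_min}")
    return _manifest(
        d, "consensus", cfg, [sim / "aln", cn_path],
        [d / "consensus.fasta", d / "consensus_stats.tsv"],
    )


def _truth_subfamily_map(outdir: Path, meta: dict) -> dict[str, str]:
    """Map extracted FLE ids to their true source subfamily via the truth BED."""
    sim = outdir / "simulate"
    fle = read_fasta(_require(outdir / "annotate" / "fle_internal.fasta", "annotate"))
    out = {}
    for rid in fle:
        contig, span = rid.split(":")
        lo, hi = map(int, span.split("-"))
        bed = sim / "genomes" / f"{contig}.truth.bed"
        for line in bed.read_text().splitlines():
            f = line.split("\t")
            if int(f[1]) <= lo and hi <= int(f[2]):
                out[rid] = f[7]
                break
    return out


def _stage_divergence(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "divergence"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    fle = read_fasta(_require(outdir / "annotate" / "fle_internal.fasta", "annotate"))
    truth_sub = _truth_subfamily_map(outdir, meta)
    recomb = [r for r, s in truth_sub.items() if "x" in s]
    pure_ty = [r for r, s in truth_sub.items() if s == "Ty4"]
    pure_tsu = [r for r, s in truth_sub.items() if s == "Tsu4"]
    if not recomb or not pure_ty or not pure_tsu:
        raise StageError("divergence stage needs a recombinant plus pure references in the FLE set")
    query = recomb[0]

    # parental proxies: the pure element nearest to the query on each side,
    # which maximizes the in-segment divergence contrast
    def nearest(candidates: list[str]) -> str:
        from .divergence import k2p_distance

        return min(candidates, key=lambda r: k2p_distance(fle[query], fle[r]).d)

    ref_a, ref_b = nearest(pure_ty), nearest(pure_tsu)
    aln = SeqAlignment({k: fle[k] for k in (query, ref_a, ref_b)})
    track = sliding_divergence(aln, query, [ref_a, ref_b], window=cfg.window, step=cfg.step)
    track.to_frame().to_csv(d / "divergence_track.tsv", sep="\t", index=False)
    bps = detect_breakpoints(track, ref_a, ref_b, min_run=cfg.min_run)
    with open(d / "breakpoints.tsv", "w") as fh:
        fh.write("query\tref_ty4\tref_tsu4\tbreakpoints\tsegments\n")
        segs = ";".join(f"{s.start:.0f}-{s.end:.0f}:{'Ty4' if s.parent == ref_a else 'Tsu4'}"
                        for s in bps.segments)
        fh.write(f"{query}\t{ref_a}\t{ref_b}\t"
                 f"{','.join(f'{b:.0f}' for b in bps.breakpoints)}\t{segs}\n")
    _log(f"divergence: recombinant {query}: breakpoints at "
         f"{[round(b) for b in bps.breakpoints]} (planted {meta['breakpoints']})")
    return _manifest(
        d, "divergence", cfg, [outdir / "annotate" / "fle_internal.fasta"],
        [d / "divergence_track.tsv", d / "breakpoints.tsv"],
        {"query": query, "breakpoints": bps.breakpoints},
    )


def _representatives(truth_sub: dict[str, str], per_group: int = 3) -> list[str]:
    groups: dict[tuple, list[str]] = {}
    for rid, sub in sorted(truth_sub.items()):
        strain = rid.split(":")[0]
        groups.setdefault((strain[0], sub), []).append(rid)
    reps = []
    for key in sorted(groups):
        reps.extend(groups[key][:per_group])
    return reps


def _stage_phylo(cfg: PipelineConfig, outdir: Path) -> dict:
    d = outdir / "phylo"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    fle = read_fasta(_require(outdir / "annotate" / "fle_internal.fasta", "annotate"))
    truth_sub = _truth_subfamily_map(outdir, meta)
    reps = _representatives(truth_sub)
    aln = SeqAlignment({r: fle[r] for r in reps})
    tree, supports = bootstrap_support(aln, n_reps=cfg.bootstrap, seed=cfg.seed + 900)
    rooted = midpoint_root(tree)
    tree.write(path=str(d / "fle_tree.nwk"), schema="newick")
    rooted.write(path=str(d / "fle_tree_rooted.nwk"), schema="newick")
    # per-segment trees at the inferred breakpoints
    bp_manifest = json.loads(_require(outdir / "divergence" / "manifest.json", "divergence").read_text())
    breakpoints = bp_manifest.get("breakpoints", [])
    parts = partition_alignment(aln, breakpoints)
    seg_trees = []
    for i, part in enumerate(parts):
        t = nj_tree(distance_matrix(part, saturation="cap"))
        t.write(path=str(d / f"segment_{i}.nwk"), schema="newick")
        seg_trees.append(t)
    rf_rows = []
    for i in range(len(seg_trees)):
        for j in range(i + 1, len(seg_trees)):
            rf_rows.append({"segment_a": i, "segment_b": j,
                            "rf": rf_distance(seg_trees[i], seg_trees[j])})
    pd.DataFrame(rf_rows).to_csv(d / "segment_rf.tsv", sep="\t", index=False)
    n_strong = sum(v >= cfg.well_supported for v in supports.values())
    _log(f"phylo: {len(reps)} FLE representatives; {n_strong}/{len(supports)} splits "
         f"with bootstrap >= {cfg.well_supported:.0f}")
    return _manifest(
        d, "phylo", cfg, [outdir / "annotate" / "fle_internal.fasta"],
        sorted(d.glob("*.nwk")) + [d / "segment_rf.tsv"],
        {"n_representatives": len(reps)},
    )


def _stage_htt(cfg: PipelineConfig, outdir: Path) -> dict:
    import dendropy

    d = outdir / "htt"
    d.mkdir(parents=True, exist_ok=True)
    meta = _scenario_meta(outdir)
    sim = outdir / "simulate"
    host = dendropy.Tree.get(path=str(_require(sim / "host_tree.nwk", "simulate")),
                             schema="newick", rooting="force-rooted")
    calls = pd.read_csv(_require(outdir / "coverage" / "presence_calls.tsv", "coverage"), sep="\t")
    fle = read_fasta(_require(outdir / "annotate" / "fle_internal.fasta", "annotate"))
    species_of = meta["species_of"]

    # Dollo/Fitch parsimony per subfamily within the recipient species
    rows = []
    for sub in sorted(calls.subfamily.unique()):
        sel = calls[calls.subfamily == sub]
        presence = dict(zip(sel.strain, sel.ltr_present.astype(bool)))
        for species in sorted(set(species_of.values())):
            leaves = [s for s in presence if species_of[s] == species]
            subtree = host.extract_tree_with_taxa_labels(leaves)
            inf = dollo_events(subtree, {s: presence[s] for s in leaves})
            rows.append(
                {"subfamily": sub, "species": species, "gains": inf.n_gains,
                 "losses": inf.n_losses, "fitch_changes": inf.fitch_changes,
                 "gain_clade": ",".join(sorted(inf.gain_clade or [])) or "."}
            )
    pd.DataFrame(rows).to_csv(d / "dollo_events.tsv", sep="\t", index=False)

    # ratio test on extracted FLE internal sequences
    te_aln = SeqAlignment(fle)
    te_dm = distance_matrix(te_aln, saturation="cap")
    seq_species = {rid: species_of[rid.split(":")[0]] for rid in fle}
    species = sorted(set(seq_species.values()))
    host_pdm = host.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in host.taxon_namespace}
    mat = np.zeros((len(species), len(species)))
    for i, s1 in enumerate(species):
        for j, s2 in enumerate(species):
            if i >= j:
                continue
            ds = [
                host_pdm.patristic_distance(taxa[a], taxa[b])
                for a in meta["strains"] if species_of[a] == s1
                for b in meta["strains"] if species_of[b] == s2
            ]
            mat[i, j] = mat[j, i] = float(np.mean(ds))
    host_dm = DistanceMatrix(labels=species, matrix=mat)
    flags = htt_signal(te_dm, host_dm, seq_species, ratio_threshold=cfg.ratio_threshold)
    with open(d / "htt_flags.tsv", "w") as fh:
        fh.write("species_a\tspecies_b\tratio\tte_distance\thost_distance\tte_pair\n")
        for f in flags:
            fh.write(f"{f.species_pair[0]}\t{f.species_pair[1]}\t{f.ratio:.4f}\t"
                     f"{f.te_distance:.4f}\t{f.host_distance:.4f}\t{f.te_pair[0]}|{f.te_pair[1]}\n")
    _log(f"htt: {len(flags)} species pair(s) flagged as HTT-consistent "
         f"(threshold ratio < {cfg.ratio_threshold})")
    return _manifest(
        d, "htt", cfg,
        [sim / "host_tree.nwk", outdir / "coverage" / "presence_calls.tsv"],
        [d / "dollo_events.tsv", d / "htt_flags.tsv"],
        {"flagged_pairs": [f.species_pair for f in flags]},
    )
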