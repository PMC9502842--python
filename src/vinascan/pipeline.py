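"""End-to-end orchestration: simulate (or load), screen, annotate, infer hosts,
assign clades, compute the core and tally abundance — plus a truth-comparison
report when ground truth is available.

Stages communicate through plain files plus an in-memory result bundle; a JSON
run manifest records the config, seed and a checksum per output so a run can
be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .abundance import build_index, classify_reads
from .core_genome import build_matrix, core_genes, lysin_host_table
from .core_model import (
    GffFeature,
    write_fasta,
    write_fastq,
    write_genome_map,
)
from .gene_calling import find_orfs, genes_to_features
from .host_inference import (
    crispr_host_assignments,
    detect_crispr,
    flank_best_hits,
    match_spacers,
    vote_host,
)
from .mcp_screen import assignments_table, screen_contigs, summarize_groups
from .phylo import assign_clade
from .prophage_annotation import annotate_and_classify
from .synthetic_data import (
    SimulationConfig,
    decoy_profiles,
    default_clade_model,
    default_reference_db,
    default_taxonomy,
    generate_metagenome,
    marker_gene_sets,
    mcp_group_profiles,
    family_profiles,
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds default to the study's printed values; overrides are logged."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    evalue: float = 0.05
    cluster_id: float = 0.5
    derep_id: float = 0.8
    spacer_id: float = 95.0
    spacer_evalue: float = 1e-15
    window: int = 15_000
    spacer_window: int = 8_000
    core_fraction: float = 0.5
    core_min_clades: int = 3
    block_identity: float = 0.90
    min_len_aa: int = 30
    abundance_k: int = 31
    # stage toggles
    do_screen: bool = True
    do_prophage: bool = True
    do_host: bool = True
    do_clades: bool = True
    do_core: bool = True
    do_abundance: bool = True

    def validate(self):
        deps = {
            "do_prophage": "do_screen",
            "do_host": "do_screen",
            "do_clades": "do_screen",
            "do_core": "do_prophage",
        }
        for stage, needs in deps.items():
            if getattr(self, stage) and not getattr(self, needs):
                raise PipelineError(f"stage {stage} requires {needs}")
        if self.do_core and not self.do_clades:
            raise PipelineError("stage do_core requires do_clades")


@dataclass
class PipelineResult:
    contigs: list
    reads: list
    manifest: dict
    assignments: list = field(default_factory=list)
    group_summary: Optional[pd.DataFrame] = None
    annotations: dict = field(default_factory=dict)  # contig_id -> ProphageAnnotation
    clades: dict = field(default_factory=dict)  # contig_id -> (clade, hgv, dist)
    host_flank: dict = field(default_factory=dict)  # contig_id -> HostAssignment
    host_crispr: dict = field(default_factory=dict)
    crispr_arrays: list = field(default_factory=list)
    core: set = field(default_factory=set)
    pa_matrix: Optional[object] = None
    lysin_table: Optional[pd.DataFrame] = None
    abundance_counts: Optional[pd.DataFrame] = None
    truth_report: dict = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _overlap(a0, a1, b0, b1) -> bool:
    return a0 < b1 and b0 < a1


def run(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all enabled stages; deterministic given the simulation seed."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def emit(name, writer):
        if out is None:
            return
        path = out / name
        writer(path)
        written[name] = _sha256(path)

    contigs, reads, manifest = generate_metagenome(config.simulation)
    res = PipelineResult(contigs, reads, manifest)
    emit("contigs.fasta", lambda p: write_fasta(contigs, p))
    if reads:
        emit("reads.fastq", lambda p: write_fastq(reads, p))
    emit("truth.json", lambda p: p.write_text(json.dumps(manifest, indent=1)))
    truth_feats = [
        GffFeature(cid, s, e, st, "CDS", fam)
        for cid, info in manifest["contigs"].items()
        for fam, s, e, st in info["planted_genes"]
    ]
    emit(
        "truth.gff3",
        lambda p: write_genome_map(truth_feats, p, {c.id: len(c) for c in contigs}),
    )

    gene_calls = {c.id: find_orfs(c, config.min_len_aa) for c in contigs}
    all_feats = [f for c in contigs for f in genes_to_features(gene_calls[c.id])]
    emit(
        "genes.gff3",
        lambda p: write_genome_map(all_feats, p, {c.id: len(c) for c in contigs}),
    )

    fam_profiles = family_profiles()
    if config.do_screen:
        res.assignments = screen_contigs(
            contigs,
            list(mcp_group_profiles().values()),
            evalue_cutoff=config.evalue,
            gene_calls=gene_calls,
            decoy_profiles=decoy_profiles(),
        )
        res.group_summary = summarize_groups(res.assignments)
        emit("mcp_hits.tsv", lambda p: assignments_table(res.assignments).to_csv(p, sep="\t", index=False))
        emit("group_summary.tsv", lambda p: res.group_summary.to_csv(p, sep="\t"))

    by_id = {c.id: c for c in contigs}
    vina = [a for a in res.assignments if a.group == "Vinavirales"]
    # one annotation per contig, around its best (lowest-E) MCP
    best_per_contig: dict[str, object] = {}
    for a in vina:
        cur = best_per_contig.get(a.contig_id)
        if cur is None or a.hit.evalue < cur.hit.evalue:
            best_per_contig[a.contig_id] = a

    if config.do_prophage:
        rows = []
        for cid, a in sorted(best_per_contig.items()):
            ann = annotate_and_classify(
                by_id[cid],
                a.locus,
                list(fam_profiles.values()),
                gene_calls=gene_calls[cid],
                window=config.window,
                evalue_cutoff=config.evalue,
            )
            res.annotations[cid] = ann
            rows.append(
                {
                    "contig_id": cid,
                    "classification": ann.classification,
                    "completeness": ann.completeness,
                    "boundaries": json.dumps(ann.boundaries),
                    "flags": ",".join(ann.flags),
                }
            )
        emit(
            "prophages.tsv",
            lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
        )

    if config.do_clades:
        model, anchor_seqs = default_clade_model()
        for cid, a in sorted(best_per_contig.items()):
            gene = next(g for g in gene_calls[cid] if g.id == a.protein_id)
            res.clades[cid] = assign_clade(gene.aa_seq, model, anchor_seqs)
        emit(
            "clades.tsv",
            lambda p: pd.DataFrame(
                [
                    {"contig_id": cid, "clade": c, "hgv_group": h or "", "distance": d}
                    for cid, (c, h, d) in sorted(res.clades.items())
                ]
            ).to_csv(p, sep="\t", index=False),
        )

    if config.do_host:
        taxonomy = default_taxonomy()
        ref_db = default_reference_db()
        for cid in sorted(best_per_contig):
            ann = res.annotations.get(cid)
            genes = gene_calls[cid]
            if ann is not None and ann.boundaries:
                coords = [v[:2] for v in ann.boundaries.values()]
                s0, s1 = min(c[0] for c in coords), max(c[1] for c in coords)
                voters = [g for g in genes if g.end <= s0 or g.start >= s1]
            else:
                voters = genes
            if not voters:
                continue
            hits = flank_best_hits(voters, ref_db)
            assignment = vote_host(hits, taxonomy, contig_id=cid)
            if assignment is not None:
                res.host_flank[cid] = assignment
        # CRISPR route
        spacers = []
        spacer_hosts = {}
        for c in contigs:
            if c.id in best_per_contig:
                continue
            for k, arr in enumerate(detect_crispr(c)):
                res.crispr_arrays.append(arr)
                for si, (sp, _) in enumerate(arr.spacers):
                    sid = f"{c.id}|arr{k}|sp{si}"
                    spacers.append((sid, sp))
                    if c.truth is not None and c.truth.host_taxon:
                        spacer_hosts[sid] = c.truth.host_taxon
                    elif c.id in res.host_flank:
                        spacer_hosts[sid] = res.host_flank[c.id].taxon_id
        regions = []
        for cid, a in sorted(best_per_contig.items()):
            c = by_id[cid]
            r0 = max(0, a.locus[0] - config.spacer_window)
            r1 = min(len(c), a.locus[1] + config.spacer_window)
            regions.append((cid, c.seq[r0:r1]))
        matches = match_spacers(
            spacers,
            regions,
            identity_threshold=config.spacer_id,
            evalue_threshold=config.spacer_evalue,
        )
        for ha in crispr_host_assignments(matches, spacer_hosts):
            res.host_crispr[ha.contig_id] = ha
        host_rows = []
        for cid in sorted(set(res.host_flank) | set(res.host_crispr)):
            fv = res.host_flank.get(cid)
            cr = res.host_crispr.get(cid)
            agree = ""
            if fv and cr:
                agree = str(
                    taxonomy.lca([fv.taxon_id, cr.taxon_id])
                    in (fv.taxon_id, cr.taxon_id)
                )
            host_rows.append(
                {
                    "contig_id": cid,
                    "flank_taxon": fv.taxon_id if fv else "",
                    "flank_support": fv.support if fv else "",
                    "crispr_taxon": cr.taxon_id if cr else "",
                    "crispr_spacers": cr.support if cr else "",
                    "methods_agree": agree,
                }
            )
        emit(
            "hosts.tsv",
            lambda p: pd.DataFrame(host_rows).to_csv(p, sep="\t", index=False),
        )

    if config.do_core and res.annotations:
        clade_labels = {
            cid: res.clades[cid][0]
            for cid in res.annotations
            if cid in res.clades and res.clades[cid][0] in "ABCDE"
        }
        usable = [res.annotations[cid] for cid in sorted(clade_labels)]
        excluded = {
            cid
            for cid in clade_labels
            if by_id[cid].truth is not None and by_id[cid].truth.extra.get("degenerate")
        }
        if usable:
            res.pa_matrix = build_matrix(usable, clade_labels, exclusions=excluded)
            res.core = core_genes(
                res.pa_matrix, config.core_fraction, config.core_min_clades
            )
            taxonomy = default_taxonomy()
            host_classes = {
                cid: taxonomy.ancestor_at_rank(ha.taxon_id, "class") or ha.taxon_id
                for cid, ha in res.host_flank.items()
            }
            res.lysin_table = lysin_host_table(usable, host_classes)
            emit(
                "presence_absence.tsv",
                lambda p: res.pa_matrix.table.to_csv(p, sep="\t"),
            )
            emit(
                "core_genes.tsv",
                lambda p: p.write_text("\n".join(sorted(res.core)) + "\n"),
            )
            if res.lysin_table is not None and not res.lysin_table.empty:
                emit(
                    "lysin_host.tsv",
                    lambda p: res.lysin_table.to_csv(p, sep="\t"),
                )

    if config.do_abundance and reads:
        index = build_index(marker_gene_sets(), k=config.abundance_k)
        report = classify_reads(reads, index)
        res.abundance_counts = report.counts
        emit("abundance.tsv", lambda p: report.counts.to_csv(p, sep="\t"))

    res.truth_report = compare_to_truth(res)
    emit(
        "truth_report.json",
        lambda p: p.write_text(json.dumps(res.truth_report, indent=1)),
    )
    res.run_log = {
        "version": __version__,
        "seed": config.simulation.seed,
        "config": _config_dict(config),
        "outputs": written,
    }
    emit("run_manifest.json", lambda p: p.write_text(json.dumps(res.run_log, indent=1)))
    return res


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


# -------------------------------------------------------------- truth comparison


def compare_to_truth(res: PipelineResult) -> dict:
    """Per-stage recovery rates against the simulation's truth manifest."""
    manifest = res.manifest
    truth_mcps = []  # (cid, start, end)
    for cid, info in manifest["contigs"].items():
        if "mcp_interval" in info:
            truth_mcps.append((cid, *info["mcp_interval"][:2]))
    detected = {(a.contig_id, a.locus) for a in res.assignments}
    tp = sum(
        1
        for cid, s, e in truth_mcps
        if any(c == cid and _overlap(s, e, l0, l1) for c, (l0, l1) in detected)
    )
    report: dict = {
        "n_contigs": len(res.contigs),
        "n_truth_mcps": len(truth_mcps),
        "n_detected_mcps": len(res.assignments),
        "mcp_sensitivity": tp / len(truth_mcps) if truth_mcps else None,
        "mcp_precision": (
            sum(
                1
                for c, (l0, l1) in detected
                if any(cid == c and _overlap(s, e, l0, l1) for cid, s, e in truth_mcps)
            )
            / len(detected)
            if detected
            else None
        ),
    }
    # prophage vs phage labels on non-degenerate cassette-bearing contigs
    lab_total = lab_ok = 0
    bnd_total = bnd_ok = 0
    for cid, info in manifest["contigs"].items():
        if info.get("group") != "Vinavirales" or info.get("degenerate"):
            continue
        truth_label = "prophage" if info["kind"] == "prophage" else "phage"
        ann = res.annotations.get(cid)
        if ann is None:
            continue
        lab_total += 1
        lab_ok += ann.classification == truth_label
        planted = info["planted_genes"]
        for side, fams in (("p16", ("P16",)), ("p15", ("P15", "TR_Z1"))):
            truth_b = [g for g in planted if g[0] in fams]
            if not truth_b:
                continue
            bnd_total += 1
            pred = ann.boundaries.get(side)
            if pred is None:
                continue
            ti = next(i for i, g in enumerate(planted) if g[0] in fams)
            near = planted[max(0, ti - 1) : ti + 2]
            if any(_overlap(pred[0], pred[1], g[1], g[2]) for g in near):
                bnd_ok += 1
    report["prophage_label_accuracy"] = lab_ok / lab_total if lab_total else None
    report["boundary_recovery_within_1_gene"] = bnd_ok / bnd_total if bnd_total else None
    # hosts: genus-level accuracy of flank voting
    taxonomy = default_taxonomy()
    h_total = h_ok = 0
    for cid, ha in res.host_flank.items():
        info = manifest["contigs"].get(cid, {})
        truth_taxon = info.get("host_taxon")
        if not truth_taxon:
            continue
        h_total += 1
        tg = taxonomy.ancestor_at_rank(truth_taxon, "genus")
        pg = taxonomy.ancestor_at_rank(ha.taxon_id, "genus")
        h_ok += pg is not None and pg == tg
    report["host_genus_accuracy_flank"] = h_ok / h_total if h_total else None
    c_total = c_ok = 0
    for cid, ha in res.host_crispr.items():
        # truth: the spacer-donor relationship recorded on array contigs
        donors = [
            info
            for info in manifest["contigs"].values()
            if any(
                o["source_contig"] == cid
                for o in info.get("crispr", {}).get("spacer_origins", [])
            )
        ]
        if not donors:
            continue
        c_total += 1
        c_ok += any(d.get("host_taxon") == ha.taxon_id for d in donors)
    report["crispr_host_accuracy"] = c_ok / c_total if c_total else None
    # clades
    cl_total = cl_ok = 0
    for cid, (clade, hgv, _) in res.clades.items():
        info = manifest["contigs"].get(cid, {})
        if info.get("clade"):
            cl_total += 1
            cl_ok += clade == info["clade"]
    report["clade_accuracy"] = cl_ok / cl_total if cl_total else None
    # core recovery: expected = families >50% prevalent in >=3 clades by truth
    if res.core is not None and res.pa_matrix is not None and len(res.pa_matrix.table):
        from .prophage_annotation import FAMILY_MERGE_MAP

        clade_fams: dict[str, list] = {}
        for cid, info in manifest["contigs"].items():
            if cid not in res.pa_matrix.table.index or not info.get("clade"):
                continue
            fams = {
                FAMILY_MERGE_MAP.get(g[0], g[0])
                for g in info["planted_genes"]
                if not g[0].startswith(("host:", "filler:"))
            }
            clade_fams.setdefault(info["clade"], []).append(fams)
        all_f = sorted({f for rows in clade_fams.values() for fams in rows for f in fams})
        expected = set()
        for f in all_f:
            n_clades = sum(
                1
                for rows in clade_fams.values()
                if sum(f in fams for fams in rows) / len(rows) > 0.5
            )
            if n_clades >= 3:
                expected.add(f)
        report["expected_core"] = sorted(expected)
        report["detected_core"] = sorted(res.core)
        report["core_exact_match"] = expected == res.core
    # abundance: classified read fraction per truth gene-set origin
    if res.abundance_counts is not None and manifest.get("reads"):
        report["n_reads"] = int(res.abundance_counts.to_numpy().sum())
    return report
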