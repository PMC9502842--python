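"""Truth-labeled synthetic metagenomes for end-to-end pipeline testing.

The generator emulates the input universe of a gut-metagenome (pro)phage
census: bacterial host contigs carrying taxonomically informative proteins,
integrated tailless-phage cassettes with the canonical conserved gene order,
clade-structured major capsid proteins (MCPs), CRISPR arrays whose spacers
point back at phage regions, and short reads drawn from the contigs. Every
planted feature is recorded in a truth manifest so recovery can be scored.

Determinism: all reference material (family consensus proteins, clade
consensi, taxonomy, host protein database, profile seed alignments) derives
from fixed per-name seeds and is identical across runs; per-simulation
randomness flows from ``SimulationConfig.seed`` alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from ._align import AA_ALPHABET, b62
from .core_model import Contig, Read, TaxNode, TaxonomyTree, TruthLabel, revcomp
from .host_inference import RefProtein
from .profile_search import ProteinProfile, build_profile, calibrate_evalue
from .prophage_annotation import CASSETTE_ORDER, GENE_FAMILIES

# palindromic 12-mer with stop codons in all six reading frames; placed around
# every planted gene so the ORF caller recovers planted intervals exactly
INSULATOR = "TTAATTAATTAA"

VARIDNAVIRUS_GROUPS = ("Vinavirales", "NCLDV", "virophage", "polintovirus", "tectivirus_Bam35")
CLADES = ("A", "B", "C", "D", "E")
HGV_GROUPS = ("HGV-1", "HGV-2", "HGV-3")

# clade -> (host class, lysin family, right-boundary regulator family)
CLADE_BIOLOGY = {
    "A": ("c__Alphaproteobacteria", "CWH_SleB", "TR_Z1"),
    "B": ("c__Gammaproteobacteria", "P5_lysin", "P15"),
    "C": ("c__Gammaproteobacteria", "P5_lysin", "P15"),
    "D": ("c__Betaproteobacteria", "T4lyz", "P15"),
    "E": ("c__Gammaproteobacteria", "P5_lysin", "P15"),
}

# sequence-space layout: divergence of clade consensi from the base MCP, and of
# the human-gut (HGV) group consensi from the clade A consensus
CLADE_RADIATION = 0.25
HGV_RADIATION = 0.10

_CALIBRATION_SEED = 987_654  # fixed: profiles are reference material


def _name_seed(name: str) -> int:
    return zlib.crc32(name.encode()) & 0x7FFFFFFF


def _rng(name: str) -> np.random.Generator:
    return np.random.default_rng(_name_seed(name))


# ------------------------------------------------------------------ protein evolution

_AA = np.array(list(AA_ALPHABET))


@lru_cache(maxsize=1)
def _exchange_matrix() -> np.ndarray:
    """Row-stochastic replacement kernel weighted by BLOSUM62 exchangeability."""
    m = np.exp(b62()[:20, :20] / 2.0)
    np.fill_diagonal(m, 0.0)
    return m / m.sum(axis=1, keepdims=True)


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site (except the initiator Met) with prob ``divergence``,
    drawing replacements from the BLOSUM62-weighted kernel."""
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    if divergence == 0:
        return seq
    ex = _exchange_matrix()
    idx = {a: i for i, a in enumerate(AA_ALPHABET)}
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        if i == 0:
            continue
        a = idx.get(seq[i])
        if a is None:
            continue
        out[i] = _AA[rng.choice(20, p=ex[a])]
    return "".join(out)


def random_protein(name: str, length: int) -> str:
    rng = _rng("prot:" + name)
    return "M" + "".join(rng.choice(_AA, size=length - 1))


# ------------------------------------------------------------------ back-translation

_T11 = CodonTable.unambiguous_dna_by_id[11]


@lru_cache(maxsize=1)
def _codons_by_aa() -> dict:
    by_aa: dict[str, list] = {}
    for codon, aa in _T11.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa


def back_translate(aa_seq: str, rng: np.random.Generator) -> str:
    """Uniform-codon back-translation: ATG start, TAA stop."""
    table = _codons_by_aa()
    codons = ["ATG"]
    for aa in aa_seq[1:]:
        opts = table[aa]
        codons.append(opts[rng.integers(len(opts))])
    codons.append("TAA")
    return "".join(codons)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


# ------------------------------------------------------------------ reference material


@lru_cache(maxsize=None)
def family_consensus(family: str) -> str:
    """Deterministic consensus protein for a conserved gene family."""
    lo, hi, _ = GENE_FAMILIES[family]
    return random_protein("family:" + family, (lo + hi) // 2)


@lru_cache(maxsize=None)
def group_mcp_consensus(group: str) -> str:
    """MCP consensus for one of the five varidnavirus groups."""
    if group == "Vinavirales":
        return family_consensus("MCP")
    lo, hi, _ = GENE_FAMILIES["MCP"]
    return random_protein("group_mcp:" + group, (lo + hi) // 2)


@lru_cache(maxsize=None)
def clade_consensus(clade: str) -> str:
    """Clade-level MCP consensus, radiated from the base consensus."""
    if clade not in CLADES:
        raise ValueError(f"unknown clade {clade}")
    return mutate_protein(family_consensus("MCP"), CLADE_RADIATION, _rng("clade:" + clade))


@lru_cache(maxsize=None)
def hgv_consensus(group: str) -> str:
    if group not in HGV_GROUPS:
        raise ValueError(f"unknown HGV group {group}")
    return mutate_protein(clade_consensus("A"), HGV_RADIATION, _rng("hgv:" + group))


def seed_msa(name: str, consensus: str, n_variants: int = 4, divergence: float = 0.1) -> list:
    """Seed alignment for a profile: the consensus plus jittered variants.

    Substitution-only evolution keeps rows aligned without gaps.
    """
    rows = [(f"{name}|consensus", consensus)]
    for v in range(n_variants):
        rng = _rng(f"msa:{name}:{v}")
        rows.append((f"{name}|v{v}", mutate_protein(consensus, divergence, rng)))
    return rows


def _mcp_vinavirales_msa() -> list:
    """The curated-style seed alignment for the tailless-phage MCP profile:
    all five clade consensi plus the human-gut group consensi."""
    rows = [("MCP|base", family_consensus("MCP"))]
    rows += [(f"MCP|clade_{c}", clade_consensus(c)) for c in CLADES]
    rows += [(f"MCP|{g}", hgv_consensus(g)) for g in HGV_GROUPS]
    return rows


@lru_cache(maxsize=None)
def family_profiles(calibrated: bool = True) -> dict:
    """One calibrated profile per conserved gene family (profile name = family)."""
    out = {}
    for fam in GENE_FAMILIES:
        msa = _mcp_vinavirales_msa() if fam == "MCP" else seed_msa(fam, family_consensus(fam))
        prof = build_profile(msa, name=fam, group=fam, source_msa_id=f"seed:{fam}")
        if calibrated:
            calibrate_evalue(prof, seed=_name_seed("cal:" + fam) % (2**31))
        out[fam] = prof
    return out


@lru_cache(maxsize=None)
def mcp_group_profiles(calibrated: bool = True) -> dict:
    """MCP profiles for the five varidnavirus groups (profile name = group)."""
    out = {}
    for grp in VARIDNAVIRUS_GROUPS:
        msa = (
            _mcp_vinavirales_msa()
            if grp == "Vinavirales"
            else seed_msa(grp, group_mcp_consensus(grp))
        )
        prof = build_profile(msa, name=grp, group=grp, source_msa_id=f"seed:{grp}")
        if calibrated:
            calibrate_evalue(prof, seed=_name_seed("cal:" + grp) % (2**31))
        out[grp] = prof
    return out


def decoy_profiles() -> list[ProteinProfile]:
    """Non-MCP family profiles, used to reject proteins whose best match is a
    different conserved domain."""
    return [p for f, p in family_profiles().items() if f != "MCP"]


# ------------------------------------------------------------------ taxonomy & host DB


@lru_cache(maxsize=1)
def default_taxonomy() -> TaxonomyTree:
    """A ~40-node reference taxonomy covering the host groups of the census."""
    nodes = [TaxNode("d__Bacteria", None, "domain", "Bacteria")]

    def add(tid, parent, rank, name):
        nodes.append(TaxNode(tid, parent, rank, name))

    add("p__Proteobacteria", "d__Bacteria", "phylum", "Proteobacteria")
    add("p__Verrucomicrobia", "d__Bacteria", "phylum", "Verrucomicrobia")
    layout = {
        "c__Alphaproteobacteria": (
            "p__Proteobacteria", "o__Rhodospirillales", "f__Rhodospirillaceae",
            [("g__Azospirillum", ["brasilense", "lipoferum"]),
             ("g__Paremcibacter", ["congregatus", "aestuarii"])],
        ),
        "c__Betaproteobacteria": (
            "p__Proteobacteria", "o__Burkholderiales", "f__Burkholderiaceae",
            [("g__Burkholderia", ["cepacia", "gladioli"]),
             ("g__Ralstonia", ["pickettii", "insidiosa"])],
        ),
        "c__Gammaproteobacteria": (
            "p__Proteobacteria", "o__Enterobacterales", "f__Enterobacteriaceae",
            [("g__Escherichia", ["coli", "fergusonii"]),
             ("g__Klebsiella", ["pneumoniae", "oxytoca"])],
        ),
        "c__Verrucomicrobiae": (
            "p__Verrucomicrobia", "o__Verrucomicrobiales", "f__Akkermansiaceae",
            [("g__Akkermansia", ["muciniphila", "glycaniphila"]),
             ("g__Luteolibacter", ["pohnpeiensis", "algae"])],
        ),
    }
    for cls, (phylum, order, fam, genera) in layout.items():
        add(cls, phylum, "class", cls[3:])
        add(order, cls, "order", order[3:])
        add(fam, order, "family", fam[3:])
        for genus, species in genera:
            add(genus, fam, "genus", genus[3:])
            for sp in species:
                sid = f"s__{genus[3:]}_{sp}"
                add(sid, genus, "species", f"{genus[3:]} {sp}")
    return TaxonomyTree(nodes)


def species_in_class(taxonomy: TaxonomyTree, cls: str) -> list:
    return sorted(
        t for t in taxonomy.descendants(cls) if taxonomy.nodes[t].rank == "species"
    )


N_REF_PROTEINS_PER_SPECIES = 6
SPECIES_DIVERGENCE = 0.03  # within-genus protein divergence between species


@lru_cache(maxsize=1)
def default_reference_db() -> list[RefProtein]:
    """Taxon-labeled host protein database: per genus a set of base proteins,
    radiated slightly into each species so best hits are species-informative."""
    tax = default_taxonomy()
    db = []
    for genus in sorted(t for t in tax.nodes if tax.nodes[t].rank == "genus"):
        bases = []
        for i in range(N_REF_PROTEINS_PER_SPECIES):
            rng = _rng(f"refbase:{genus}:{i}")
            length = int(rng.integers(150, 251))
            bases.append(random_protein(f"refprot:{genus}:{i}", length))
        for sp in sorted(tax.children(genus)):
            for i, base in enumerate(bases):
                seq = mutate_protein(base, SPECIES_DIVERGENCE, _rng(f"refsp:{sp}:{i}"))
                db.append(RefProtein(f"{sp}|p{i}", seq, sp))
    return db


# ------------------------------------------------------------------ anchors / clade model


def clade_anchor_seqs() -> dict:
    anchors = {f"anchor_{c}": clade_consensus(c) for c in CLADES}
    anchors.update({f"anchor_{g}": hgv_consensus(g) for g in HGV_GROUPS})
    return anchors


def default_clade_model():
    """Anchored clade framework built from the reference consensi."""
    from .phylo import CladeModel, build_tree, progressive_align

    seqs = clade_anchor_seqs()
    msa = progressive_align(sorted(seqs.items()))
    newick, supports = build_tree(msa, n_bootstrap=50, seed=_name_seed("clade_tree"))
    anchors = {f"anchor_{c}": c for c in CLADES}
    anchors.update({f"anchor_{g}": "A" for g in HGV_GROUPS})
    hgv = {f"anchor_{g}": g for g in HGV_GROUPS}
    return CladeModel(newick, anchors, hgv, supports), seqs


# ------------------------------------------------------------------ specs & config


@dataclass
class CassetteSpec:
    """Gene order and composition of one integrated phage cassette."""

    clade: str = "B"
    hgv_group: Optional[str] = None
    lysin: Optional[str] = None  # default: clade biology
    tail_tr: Optional[str] = None  # P15 or TR_Z1; default: clade biology
    degenerate: bool = False  # Verrucomicrobia-style: no lysin, no P15/P16/TR_Z1

    def gene_order(self) -> list[str]:
        _, lysin, tail = CLADE_BIOLOGY[self.clade]
        lysin = self.lysin or lysin
        tail = self.tail_tr or tail
        if self.clade == "A" and self.tail_tr is None:
            tail = "TR_Z1"
        if tail == "TR_Z1" and self.clade != "A":
            raise ValueError("TR_Z1 occupies the P15 locus only in clade A")
        order = [g for g in CASSETTE_ORDER]
        order[order.index("<lysin>")] = lysin
        order[order.index("<tail_TR>")] = tail
        if self.degenerate:
            order = [g for g in order if g not in ("P16", "P15", "TR_Z1", lysin)]
        if self.hgv_group == "HGV-2":
            order.append("IS630_transposase")
        return order


@dataclass
class SimulationConfig:
    seed: int = 0
    n_host_contigs: int = 50
    prophage_probability: float = 0.5
    free_phage_fraction: float = 0.1  # of viral contigs: cassette with no host flanks
    divergence: float = 0.1  # aa substitutions/site of planted genes vs consensus
    flank_divergence: float = 0.05
    n_flank_genes: int = 4  # per side of a prophage
    host_taxa: Optional[list] = None  # [(species_id, weight)]; default clade biology
    group_weights: dict = field(
        default_factory=lambda: {
            "Vinavirales": 0.8, "NCLDV": 0.1, "virophage": 0.05,
            "polintovirus": 0.03, "tectivirus_Bam35": 0.02,
        }
    )
    clade_weights: dict = field(default_factory=lambda: {c: 0.2 for c in CLADES})
    verrucomicrobia_fraction: float = 0.0  # of clade-A cassettes: degenerate prophages
    crispr_probability: float = 0.3  # per host-only contig
    crispr_mismatches: int = 0
    intergenic_gap: tuple = (5, 30)
    read_count: int = 0
    read_length: int = 100
    error_rate: float = 0.0

    def __post_init__(self):
        for p in (self.prophage_probability, self.free_phage_fraction,
                  self.crispr_probability, self.error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")
        if not 0 <= self.divergence < 0.75:
            raise ValueError("divergence must be < 0.75")


# ------------------------------------------------------------------ contig assembly


class _ContigBuilder:
    def __init__(self, rng, gap_range):
        self.rng = rng
        self.gap_range = gap_range
        self.parts: list[str] = []
        self.length = 0
        self.genes: list[tuple] = []  # (family, start, end, strand, aa)

    def gap(self, lo=None, hi=None):
        lo = self.gap_range[0] if lo is None else lo
        hi = self.gap_range[1] if hi is None else hi
        g = random_dna(int(self.rng.integers(lo, hi + 1)), self.rng)
        self.parts.append(g)
        self.length += len(g)

    def raw(self, seq: str):
        self.parts.append(seq)
        self.length += len(seq)

    def gene(self, family: str, aa: str, strand: str):
        nt = back_translate(aa, self.rng)
        block = INSULATOR + nt + INSULATOR
        if strand == "-":
            block = revcomp(block)
        start = self.length + len(INSULATOR)
        self.genes.append((family, start, start + len(nt), strand, aa))
        self.raw(block)

    def build(self, cid, source="sim", truth=None) -> Contig:
        return Contig(cid, "".join(self.parts), source, truth)


def _sample_weighted(rng, items: dict):
    keys = sorted(items)
    w = np.array([items[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _planted_mcp(spec: CassetteSpec, divergence, rng) -> str:
    if spec.hgv_group:
        base = hgv_consensus(spec.hgv_group)
    else:
        base = clade_consensus(spec.clade)
    return mutate_protein(base, divergence, rng)


def _build_cassette(builder, spec: CassetteSpec, divergence, rng):
    """Append the cassette's genes; returns (interval, gene records)."""
    strand = "+" if rng.random() < 0.5 else "-"
    order = spec.gene_order()
    if strand == "-":
        order = order[::-1]
    first_gene = len(builder.genes)
    for fam in order:
        if fam == "MCP":
            aa = _planted_mcp(spec, divergence, rng)
        else:
            aa = mutate_protein(family_consensus(fam), divergence, rng)
        builder.gene(fam, aa, strand)
        builder.gap()
    recs = builder.genes[first_gene:]
    interval = (
        min(r[1] for r in recs) - len(INSULATOR),
        max(r[2] for r in recs) + len(INSULATOR),
    )
    return interval, recs


def _host_flank(builder, species, n_genes, flank_divergence, rng, ref_by_species):
    for _ in range(n_genes):
        pid, base = ref_by_species[species][rng.integers(len(ref_by_species[species]))]
        aa = mutate_protein(base, flank_divergence, rng)
        builder.gene(f"host:{pid}", aa, "+" if rng.random() < 0.5 else "-")
        builder.gap()


# ------------------------------------------------------------------ main generator


def generate_metagenome(
    config: SimulationConfig,
    seed_profiles: Optional[dict] = None,
) -> tuple[list[Contig], list[Read], dict]:
    """Generate contigs, reads and a truth manifest under one seed.

    Every prophage contig has host genes on both flanks; the manifest records
    every planted gene interval, host taxon, prophage interval, cassette clade
    and CRISPR spacer origin. Identical config (seed included) reproduces
    byte-identical sequences.
    """
    rng = np.random.default_rng(config.seed)
    tax = default_taxonomy()
    ref = default_reference_db()
    ref_by_species: dict[str, list] = {}
    for r in ref:
        ref_by_species.setdefault(r.taxon_id, []).append((r.id, r.seq))
    manifest: dict = {"config_seed": config.seed, "contigs": {}, "warnings": [], "reads": {}}
    if config.divergence >= 0.5:
        manifest["warnings"].append(
            f"divergence {config.divergence} may push planted MCPs below the "
            "decoy-calibrated detection threshold"
        )
    contigs: list[Contig] = []
    prophage_pool: list[tuple[str, tuple, tuple]] = []  # (cid, mcp iv, cassette iv)
    host_only: list[str] = []

    def pick_host(clade=None) -> str:
        if config.host_taxa:
            return _sample_weighted(rng, dict(config.host_taxa))
        cls = CLADE_BIOLOGY[clade][0] if clade else "c__Gammaproteobacteria"
        species = species_in_class(tax, cls)
        return species[rng.integers(len(species))]

    for i in range(config.n_host_contigs):
        cid = f"ctg_{i:04d}"
        builder = _ContigBuilder(rng, config.intergenic_gap)
        builder.gap()
        viral = rng.random() < config.prophage_probability
        if viral:
            group = _sample_weighted(rng, config.group_weights)
            if group != "Vinavirales":
                # contaminant-style contig: a bare group MCP among anonymous genes
                aa = mutate_protein(group_mcp_consensus(group), config.divergence, rng)
                builder.gene(f"filler:{cid}:0", random_protein(f"filler:{cid}:0", 150), "+")
                builder.gap()
                builder.gene("MCP", aa, "+" if rng.random() < 0.5 else "-")
                builder.gap()
                mcp = next(g for g in builder.genes if g[0] == "MCP")
                truth = TruthLabel(
                    "free_phage",
                    planted_genes=[g[:4] for g in builder.genes],
                    extra={"group": group},
                )
                contigs.append(builder.build(cid, truth=truth))
                manifest["contigs"][cid] = {
                    "kind": "free_phage", "group": group,
                    "mcp_interval": list(mcp[1:4]), "clade": None,
                    "planted_genes": [list(g[:4]) for g in builder.genes],
                }
                continue
            clade = _sample_weighted(rng, config.clade_weights)
            hgv = (
                HGV_GROUPS[rng.integers(3)] if clade == "A" else None
            )
            degenerate = (
                clade == "A" and rng.random() < config.verrucomicrobia_fraction
            )
            spec = CassetteSpec(clade=clade, hgv_group=hgv, degenerate=degenerate)
            free = rng.random() < config.free_phage_fraction
            if degenerate:
                host = species_in_class(tax, "c__Verrucomicrobiae")[rng.integers(2)]
            else:
                host = pick_host(clade)
            if not free:
                _host_flank(builder, host, config.n_flank_genes,
                            config.flank_divergence, rng, ref_by_species)
            cass_iv, recs = _build_cassette(builder, spec, config.divergence, rng)
            if not free:
                _host_flank(builder, host, config.n_flank_genes,
                            config.flank_divergence, rng, ref_by_species)
            builder.gap()
            mcp = next(g for g in recs if g[0] == "MCP")
            kind = "free_phage" if free else "prophage"
            lysin = next(
                (f for f in spec.gene_order()
                 if f in ("P5_lysin", "CWH_SleB", "MltE", "T4lyz")),
                None,
            )
            truth = TruthLabel(
                kind,
                prophage_interval=cass_iv if kind == "prophage" else None,
                host_taxon=None if free else host,
                planted_genes=[g[:4] for g in builder.genes],
                clade=clade,
                extra={"group": "Vinavirales", "hgv_group": hgv,
                       "degenerate": degenerate, "lysin": lysin},
            )
            contigs.append(builder.build(cid, truth=truth))
            manifest["contigs"][cid] = {
                "kind": kind, "group": "Vinavirales", "clade": clade,
                "hgv_group": hgv, "degenerate": degenerate,
                "host_taxon": truth.host_taxon,
                "cassette_interval": list(cass_iv),
                "mcp_interval": list(mcp[1:4]),
                "planted_genes": [list(g[:4]) for g in builder.genes],
            }
            prophage_pool.append((cid, tuple(mcp[1:3]), cass_iv))
        else:
            host = pick_host(None) if config.host_taxa else _sample_weighted(
                rng,
                {s: 1.0 for c in ("c__Alphaproteobacteria", "c__Betaproteobacteria",
                                  "c__Gammaproteobacteria")
                 for s in species_in_class(tax, c)},
            )
            n_genes = 12
            _host_flank(builder, host, n_genes, config.flank_divergence, rng, ref_by_species)
            # pad past the CRISPR caller's contig-length floor
            while builder.length < 10_600:
                builder.raw(INSULATOR)
                builder.raw(random_dna(400, rng))
            truth = TruthLabel("host_only", host_taxon=host,
                               planted_genes=[g[:4] for g in builder.genes])
            contigs.append(builder.build(cid, truth=truth))
            manifest["contigs"][cid] = {
                "kind": "host_only", "host_taxon": host,
                "planted_genes": [list(g[:4]) for g in builder.genes],
            }
            host_only.append(cid)

    # ---- CRISPR arrays on host-only contigs, spacers lifted from phage regions
    by_id = {c.id: c for c in contigs}
    index_of = {c.id: k for k, c in enumerate(contigs)}
    for cid in host_only:
        if not prophage_pool or rng.random() >= config.crispr_probability:
            continue
        src_cid, mcp_iv, _ = prophage_pool[rng.integers(len(prophage_pool))]
        src = by_id[src_cid]
        w0 = max(0, mcp_iv[0] - 8000)
        w1 = min(len(src), mcp_iv[1] + 8000)
        n_spacers = int(rng.integers(2, 5))
        protos = []
        for _ in range(n_spacers):
            ln = int(rng.integers(28, 41))
            p0 = int(rng.integers(w0, w1 - ln))
            protos.append((src.seq[p0 : p0 + ln], p0))
        repeat = random_dna(int(rng.integers(28, 37)), rng)
        new_contig, info = plant_crispr_array(
            by_id[cid], [p for p, _ in protos], repeat,
            seed=int(rng.integers(2**31)), mismatches=config.crispr_mismatches,
        )
        by_id[cid] = new_contig
        contigs[index_of[cid]] = new_contig
        info["spacer_origins"] = [
            {"source_contig": src_cid, "interval": [p0, p0 + len(p)]}
            for p, p0 in protos
        ]
        manifest["contigs"][cid]["crispr"] = info

    # ---- reads
    reads: list[Read] = []
    if config.read_count > 0:
        reads = simulate_reads(
            contigs, config.read_count, config.read_length, config.error_rate,
            seed=int(rng.integers(2**31)), manifest=manifest,
        )
    return contigs, reads, manifest


def plant_crispr_array(
    host_contig: Contig,
    protospacers: Sequence[str],
    repeat: str,
    seed: int,
    mismatches: int = 0,
    position: Optional[int] = None,
) -> tuple[Contig, dict]:
    """Append/insert a repeat-spacer array built from protospacer copies.

    The array is repeat-(spacer-repeat)xN, so N protospacers always yield
    N+1 >= 3 repeat copies. Each spacer carries ``mismatches`` substitutions
    relative to its protospacer. Returns (new contig, placement record).
    """
    if not 23 <= len(repeat) <= 47:
        raise ValueError(f"repeat length {len(repeat)} outside [23,47]")
    for p in protospacers:
        if not 26 <= len(p) <= 50:
            raise ValueError(f"spacer length {len(p)} outside [26,50]")
    rng = np.random.default_rng(seed)
    spacers = []
    for p in protospacers:
        s = list(p)
        if mismatches:
            sites = rng.choice(len(s), size=mismatches, replace=False)
            for i in sites:
                s[i] = "ACGT"[(("ACGT".index(s[i])) + 1 + rng.integers(3)) % 4]
        spacers.append("".join(s))
    array = repeat + "".join(s + repeat for s in spacers)
    pos = len(host_contig.seq) if position is None else position
    new_seq = host_contig.seq[:pos] + INSULATOR + array + INSULATOR + host_contig.seq[pos:]
    truth = host_contig.truth
    if truth is not None:
        shift = len(INSULATOR) * 2 + len(array)
        truth = TruthLabel(
            truth.kind,
            truth.prophage_interval,
            truth.host_taxon,
            [
                (f, s if s < pos else s + shift, e if s < pos else e + shift, st)
                for f, s, e, st in truth.planted_genes
            ],
            truth.clade,
            dict(truth.extra),
        )
    info = {
        "array_interval": [pos + len(INSULATOR), pos + len(INSULATOR) + len(array)],
        "repeat": repeat,
        "spacers": spacers,
        "mismatches": mismatches,
    }
    return Contig(host_contig.id, new_seq, host_contig.source, truth), info


def simulate_reads(
    contigs: Sequence[Contig],
    n: int,
    length: int,
    error_rate: float,
    seed: int,
    manifest: Optional[dict] = None,
) -> list[Read]:
    """Uniform short-read simulation with per-base substitution errors.

    Start positions are uniform over all valid positions across contigs, so a
    contig's expected read share equals its share of valid positions
    (~ its length share).
    """
    if n == 0:
        return []
    if length > min(len(c) for c in contigs):
        raise ValueError("read length exceeds the shortest contig")
    rng = np.random.default_rng(seed)
    weights = np.array([len(c) - length + 1 for c in contigs], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(contigs), size=n, p=weights)
    reads = []
    for ri, ci in enumerate(picks):
        c = contigs[ci]
        start = int(rng.integers(0, len(c) - length + 1))
        seq = c.seq[start : start + length]
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        if error_rate > 0:
            s = list(seq)
            errs = np.nonzero(rng.random(length) < error_rate)[0]
            for i in errs:
                if s[i] in "ACGT":
                    s[i] = "ACGT"[("ACGT".index(s[i]) + 1 + rng.integers(3)) % 4]
            seq = "".join(s)
        rid = f"read_{ri:06d}"
        reads.append(Read(rid, seq, dataset_id=c.source or "sim"))
        if manifest is not None:
            manifest["reads"][rid] = {
                "contig": c.id, "start": start, "end": start + length, "strand": strand,
            }
    return reads


# ------------------------------------------------------------------ abundance fixtures


@lru_cache(maxsize=1)
def marker_gene_sets() -> dict:
    """Nucleotide marker-gene sets for the read classifier: an HK97-fold MCP
    set (the tailed-phage contrast marker) and per-group DJR MCP sets."""
    sets: dict[str, list] = {}
    rng = _rng("hk97")
    sets["HK97"] = [
        back_translate(random_protein(f"hk97:{i}", 380), rng) for i in range(4)
    ]
    for grp in VARIDNAVIRUS_GROUPS:
        rng = _rng("djr_nt:" + grp)
        if grp == "Vinavirales":
            seqs = [back_translate(clade_consensus(c), rng) for c in CLADES]
        else:
            seqs = [back_translate(group_mcp_consensus(grp), rng)]
        sets[f"DJR:{grp}"] = seqs
    return sets
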