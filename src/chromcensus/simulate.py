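"""Synthetic proteomes, search outputs and AUC tables with planted truth.

The generator emulates the census study design — two species groups
(Aspergilli and outgroup), per-family gene losses and duplications, search
output that the retention filters must clean up (fragmented HSPs, decoys),
and a subset of true genes withheld from annotation-based search but planted
in genomic contigs so only the rescue stage can recover them. Everything is
deterministic per seed, so parameter-recovery tests can compare pipeline
output against the planted ground truth exactly.

Domain "motifs" are fixed arbitrary 60-residue blocks per Pfam accession
(derived from the accession, independent of the run seed); search output is
simulated rather than produced by real search tools, keeping tests tool-free.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .census import ArchitectureRule, DEFAULT_RULES
from .io import (
    ASPERGILLI,
    OUTGROUP,
    AucObservation,
    BlastTabRecord,
    DomtblRecord,
    ProteinRecord,
    SpeciesCatalog,
    SpeciesEntry,
    write_auc_table,
    write_blast_tab,
    write_domtblout,
    write_fasta,
)

MOTIF_LEN = 60
_AA = "ACDEFGHIKLMNPQSTVWY"  # no R: cleavage/linker control stays explicit

#: one codon per amino acid for reverse translation of planted rescue genes
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def domain_motif(accession: str) -> str:
    """The fixed 60-residue block standing in for one Pfam domain."""
    rng = np.random.default_rng(zlib.crc32(accession.encode()) % (2**31))
    return "".join(rng.choice(list(_AA), size=MOTIF_LEN))


@dataclass(frozen=True)
class CensusSimConfig:
    """Conditions of a simulated census run.

    Defaults mirror the study design: 94 Aspergilli plus 15 outgroup species
    screened for the default family set, with moderate loss/duplication
    rates, up to three-way HSP fragmentation and a couple of decoy hits per
    species.
    """

    n_aspergilli: int = 94
    n_outgroup: int = 15
    families: tuple[ArchitectureRule, ...] = DEFAULT_RULES
    loss_prob: float = 0.2
    dup_prob: float = 0.1
    fragmentation: int = 3
    decoy_rate: float = 2.0
    n_background_proteins: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.loss_prob <= 1.0 and 0.0 <= self.dup_prob <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        if self.n_aspergilli + self.n_outgroup < 2:
            raise ValueError("need at least two species")
        if self.fragmentation < 1:
            raise ValueError("fragmentation must be >= 1")


@dataclass(frozen=True)
class PlantedProtein:
    protein_id: str
    species_id: str
    family: str
    architecture: tuple[tuple[str, int, int], ...]  # (accession, start, end)
    length: int


@dataclass
class GroundTruth:
    """Planted truth of one simulated census run."""

    presence: dict[tuple[str, str], int]  # (species, family) -> copy number
    proteins: dict[str, PlantedProtein]
    species: SpeciesCatalog
    families: tuple[str, ...]
    seed: int

    def present_pairs(self) -> set[tuple[str, str]]:
        return {k for k, n in self.presence.items() if n > 0}

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "families": list(self.families),
                "presence": {f"{s}:{f}": n for (s, f), n in sorted(self.presence.items())},
                "proteins": {
                    pid: {
                        "species": p.species_id,
                        "family": p.family,
                        "architecture": [list(a) for a in p.architecture],
                        "length": p.length,
                    }
                    for pid, p in sorted(self.proteins.items())
                },
            },
            indent=1,
        )


def _ladder_newick(species_ids: Sequence[str]) -> str:
    """A ladder (caterpillar) tree over the species, in the given leaf order."""
    if len(species_ids) == 1:
        return f"{species_ids[0]};"
    tree = species_ids[-1]
    for sp in reversed(species_ids[:-1]):
        tree = f"({sp},{tree})"
    return tree + ";"


def _family_sequence(rule: ArchitectureRule) -> tuple[str, tuple[tuple[str, int, int], ...]]:
    """Protein sequence realizing a family architecture, with domain spans."""
    accs = sorted(rule.required_domains)
    seq = "M" + "G" * 19
    arch = []
    for acc in accs:
        start = len(seq) + 1
        seq += domain_motif(acc)
        arch.append((acc, start, len(seq)))
        seq += "G" * 15
    return seq, tuple(arch)


def simulate_census_truth(
    cfg: CensusSimConfig,
) -> tuple[GroundTruth, dict[str, list[ProteinRecord]], str]:
    """Realize gene content per species: Bernoulli loss and duplication per
    (species, family). Returns (truth, proteomes keyed by species, Newick)."""
    rng = np.random.default_rng(cfg.seed)
    asp = [f"asp{i:03d}" for i in range(1, cfg.n_aspergilli + 1)]
    out = [f"out{i:03d}" for i in range(1, cfg.n_outgroup + 1)]
    entries = []
    for i, sp in enumerate(out + asp):
        group = OUTGROUP if sp.startswith("out") else ASPERGILLI
        entries.append(SpeciesEntry(sp, group, "", i))
    catalog = SpeciesCatalog(tuple(entries))
    newick = _ladder_newick(out + asp)

    presence: dict[tuple[str, str], int] = {}
    proteins: dict[str, PlantedProtein] = {}
    proteomes: dict[str, list[ProteinRecord]] = {sp: [] for sp in out + asp}
    fam_names = tuple(r.family_name for r in cfg.families)

    for sp in out + asp:
        for rule in cfg.families:
            lost = rng.random() < cfg.loss_prob
            copies = 0 if lost else 1 + int(rng.random() < cfg.dup_prob)
            presence[(sp, rule.family_name)] = copies
            seq, arch = _family_sequence(rule)
            for k in range(copies):
                pid = f"{sp}|{rule.family_name}_{k + 1}"
                proteins[pid] = PlantedProtein(pid, sp, rule.family_name, arch, len(seq))
                proteomes[sp].append(ProteinRecord(pid, sp, seq))
        for b in range(cfg.n_background_proteins):
            pid = f"{sp}|bg_{b + 1}"
            bseq = "M" + "".join(rng.choice(list(_AA), size=199))
            proteomes[sp].append(ProteinRecord(pid, sp, bseq))

    truth = GroundTruth(presence, proteins, catalog, fam_names, cfg.seed)
    return truth, proteomes, newick


def family_references(
    families: Sequence[ArchitectureRule],
) -> dict[str, ProteinRecord]:
    """Reference query protein per family (the search bait)."""
    refs = {}
    for rule in families:
        seq, _ = _family_sequence(rule)
        refs[rule.family_name] = ProteinRecord(f"REF|{rule.family_name}", "REF", seq)
    return refs


def _split_span(rng, start: int, end: int, max_parts: int) -> list[tuple[int, int]]:
    """Split a span into 1..max_parts contiguous pieces whose union is exact."""
    length = end - start + 1
    parts = int(rng.integers(1, max_parts + 1))
    parts = min(parts, length)
    if parts == 1:
        return [(start, end)]
    cuts = sorted(rng.choice(np.arange(1, length), size=parts - 1, replace=False))
    bounds = [0] + [int(c) for c in cuts] + [length]
    return [(start + bounds[i], start + bounds[i + 1] - 1) for i in range(parts)]


def _overlapping_split(rng, start: int, end: int, max_parts: int) -> list[tuple[int, int]]:
    """Split a span into 1..max_parts overlapping pieces whose union is the
    full span and each of which covers more than half of it.

    Domain-scan rows are coverage-filtered one row at a time (there is no
    HSP-merging step for profile hits), so a fragmented but genuine domain
    occurrence survives the filter only if each reported fragment clears the
    per-row cutoff; the pairwise-search rows use the contiguous split
    instead, because those are merged before filtering.
    """
    length = end - start + 1
    parts = int(rng.integers(1, max_parts + 1))
    if parts == 1 or length < 4:
        return [(start, end)]
    frag_len = max(int(np.ceil(0.6 * length)), 2)
    pieces = []
    for i in range(parts):
        offset = round(i * (length - frag_len) / (parts - 1)) if parts > 1 else 0
        pieces.append((start + offset, start + offset + frag_len - 1))
    return pieces


def emit_search_outputs(
    truth: GroundTruth,
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    cfg: CensusSimConfig,
    outdir: str | Path,
    families: Sequence[ArchitectureRule] | None = None,
    withhold: set[tuple[str, str]] | None = None,
) -> dict[str, Path]:
    """Write the simulated search output files for a realized run.

    Every true domain occurrence becomes 1..``fragmentation`` domtblout rows
    whose interval union reconstructs the true span; true pairwise hits are
    emitted the same way against the family reference queries. Decoys carry
    e-values >= 1e-5 or coverage <= 0.5, so the retention filters must remove
    them. Pairs listed in ``withhold`` are omitted from domtblout/BLAST and
    instead planted as intact single-exon genes in genomic contigs with
    matching translated-search (TBLASTN-style) rows — recoverable only
    through the rescue stage.

    Returns the mapping of logical names to written paths. Each file records
    the seed in a comment line.
    """
    families = tuple(families) if families is not None else cfg.families
    rules = {r.family_name: r for r in families}
    withhold = withhold or set()
    unknown = withhold - set(truth.presence)
    if unknown:
        raise KeyError(f"withheld pairs not in truth: {sorted(unknown)[:3]}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "proteomes").mkdir(exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    refs = family_references(families)
    tag = f"seed={cfg.seed}"

    dom_rows: list[DomtblRecord] = []
    blast_rows: list[BlastTabRecord] = []
    tblastn_rows: list[BlastTabRecord] = []
    contigs: dict[str, str] = {}

    species_ids = truth.species.species_ids
    proteins_by_species: dict[str, list[PlantedProtein]] = {s: [] for s in species_ids}
    for p in truth.proteins.values():
        proteins_by_species[p.species_id].append(p)

    for sp in species_ids:
        for prot in sorted(proteins_by_species[sp], key=lambda p: p.protein_id):
            if (sp, prot.family) in withhold:
                continue
            # --- domain scan rows (fragmented; union == true span)
            for acc, dstart, dend in prot.architecture:
                for fs, fe in _overlapping_split(rng, dstart, dend, cfg.fragmentation):
                    # model coordinates proportional to the envelope fragment
                    h_from = fs - dstart + 1
                    h_to = fe - dstart + 1
                    dom_rows.append(
                        DomtblRecord(
                            target_id=prot.protein_id,
                            target_len=prot.length,
                            domain_id=acc,
                            hmm_len=MOTIF_LEN,
                            i_evalue=float(10.0 ** rng.uniform(-40, -10)),
                            hmm_from=h_from,
                            hmm_to=h_to,
                            env_from=fs,
                            env_to=fe,
                        )
                    )
            # --- pairwise search rows against the family reference
            ref = refs[prot.family]
            q_span = (5, ref.length - 4)  # > 0.5 query coverage after merging
            for fs, fe in _split_span(rng, *q_span, cfg.fragmentation):
                blast_rows.append(
                    BlastTabRecord(
                        qseqid=ref.protein_id,
                        sseqid=prot.protein_id,
                        pident=float(rng.uniform(60, 95)),
                        aln_len=fe - fs + 1,
                        mismatch=0,
                        gapopen=0,
                        qstart=fs,
                        qend=fe,
                        sstart=fs,
                        send=fe,
                        evalue=float(10.0 ** rng.uniform(-40, -10)),
                        bitscore=float(rng.uniform(100, 400)),
                    )
                )
        # --- decoys: must fall to the filters (bad coverage or weak e-value).
        # Strong-e-value decoys always report the same short query segment, so
        # merging several of them never pushes the union past 50 % coverage.
        n_decoys = int(rng.poisson(cfg.decoy_rate))
        for _ in range(n_decoys):
            fam = families[int(rng.integers(len(families)))]
            ref = refs[fam.family_name]
            target = f"{sp}|bg_{int(rng.integers(1, cfg.n_background_proteins + 1))}"
            weak_evalue = bool(rng.random() < 0.5)
            qlen = ref.length
            span_len = max(4, int(min(qlen, 200) * 0.3))
            if weak_evalue:
                evalue = float(10.0 ** rng.uniform(-4, -1))
                q0 = int(rng.integers(1, qlen - span_len))
            else:
                evalue = float(10.0 ** rng.uniform(-30, -10))
                q0 = 1
            blast_rows.append(
                BlastTabRecord(
                    qseqid=ref.protein_id, sseqid=target,
                    pident=float(rng.uniform(25, 40)), aln_len=span_len,
                    mismatch=span_len // 2, gapopen=1,
                    qstart=q0, qend=q0 + span_len - 1,
                    sstart=10, send=10 + span_len - 1,
                    evalue=evalue, bitscore=float(rng.uniform(30, 60)),
                )
            )
            # domain-scan decoy: low coverage on both axes
            dom_rows.append(
                DomtblRecord(
                    target_id=target, target_len=200,
                    domain_id=sorted(fam.required_domains)[0], hmm_len=MOTIF_LEN,
                    i_evalue=float(10.0 ** rng.uniform(-8, -3)),
                    hmm_from=1, hmm_to=int(MOTIF_LEN * 0.3),
                    env_from=20, env_to=20 + int(MOTIF_LEN * 0.3) - 1,
                )
            )

    # --- withheld genes: planted in contigs, visible only to rescue
    for sp, fam in sorted(withhold):
        rule = rules[fam]
        seq, _ = _family_sequence(rule)
        cds = "".join(_CODON[aa] for aa in seq) + "TAA"
        contig_id = f"{sp}|contig_{fam}"
        rng_bg = np.random.default_rng((zlib.crc32(contig_id.encode()) + cfg.seed) % (2**31))
        pad5 = "".join(rng_bg.choice(list("ACGT"), size=2000))
        pad3 = "".join(rng_bg.choice(list("ACGT"), size=2000))
        # avoid spurious upstream ATGs creating overlapping long ORFs: pad with
        # in-frame stops right before the gene
        contig = pad5 + "TAATAATAA" + cds + pad3
        contigs[contig_id] = contig
        gene_start = len(pad5) + 9 + 1
        hit_s = gene_start + 30
        hit_e = gene_start + 330
        tblastn_rows.append(
            BlastTabRecord(
                qseqid=f"REF|{fam}", sseqid=contig_id,
                pident=70.0, aln_len=100, mismatch=30, gapopen=0,
                qstart=11, qend=110, sstart=hit_s, send=hit_e,
                evalue=float(10.0 ** rng.uniform(-30, -10)), bitscore=200.0,
            )
        )

    paths: dict[str, Path] = {}
    paths["domtblout"] = outdir / "scan.domtbl"
    write_domtblout(dom_rows, paths["domtblout"], comment=tag)
    paths["blastp"] = outdir / "blastp.tsv"
    write_blast_tab(blast_rows, paths["blastp"], comment=tag)
    paths["tblastn"] = outdir / "tblastn.tsv"
    write_blast_tab(tblastn_rows, paths["tblastn"], comment=tag)
    paths["contigs"] = outdir / "contigs.fasta"
    with open(paths["contigs"], "w") as fh:
        for cid, cseq in sorted(contigs.items()):
            fh.write(f">{cid} {tag}\n{cseq}\n")
    paths["refs"] = outdir / "family_refs.fasta"
    write_fasta(refs.values(), paths["refs"])
    paths["tree"] = outdir / "species.nwk"
    truth_species = truth.species.species_ids
    paths["tree"].write_text(f"[{tag}]" + _ladder_newick(truth_species) + "\n")
    paths["groups"] = outdir / "groups.tsv"
    with open(paths["groups"], "w") as fh:
        fh.write(f"# {tag}\n")
        for e in truth.species.entries:
            fh.write(f"{e.species_id}\t{e.group}\n")
    # annotated proteomes: withheld genes are missing (that is the point of
    # the rescue stage); background proteins are included so subject lengths
    # resolve for decoy hits
    for sp in truth_species:
        recs = [
            r for r in proteomes[sp]
            if "|bg_" in r.protein_id
            or (sp, truth.proteins[r.protein_id].family) not in withhold
        ]
        write_fasta(recs, outdir / "proteomes" / f"{sp}.fasta")
    paths["proteomes"] = outdir / "proteomes"
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# MS simulation

@dataclass(frozen=True)
class MsSimConfig:
    """Conditions of a simulated histone quantification run.

    ``proportions`` maps each observed span (start, end) to the true %RA
    design (fractions summing to 1 over canonical form labels). AUCs are the
    span total times the true proportion times multiplicative lognormal
    noise of the given coefficient of variation.
    """

    histone_id: str
    sequence: str
    proportions: tuple[tuple[tuple[int, int], tuple[tuple[str, float], ...]], ...]
    auc_total: float = 1e6
    noise_cv: float = 0.05
    n_below_threshold: int = 0
    seed: int = 0

    def __post_init__(self):
        for span, forms in self.proportions:
            total = sum(p for _, p in forms)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"proportions for span {span} sum to {total}, expected 1"
                )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def default_ms_design(histone_id: str = "H3") -> MsSimConfig:
    """A realistic design over the H3 tail: the K9/K14 peptide observed in
    all 25 forms plus the K4 and K18/K23 peptides in common states."""
    from .histone import DEFAULT_HISTONES, KState

    seq = DEFAULT_HISTONES[histone_id]
    # span 9-17 (KSTGGKAPR): all 25 two-lysine forms, geometric-ish weights
    labels_9_17 = []
    for s9 in KState:
        for s14 in KState:
            labels_9_17.append(f"K9{s9.value}+K14{s14.value}")
    w = np.array([2.0 ** -(i % 7) for i in range(len(labels_9_17))])
    w = w / w.sum()
    forms_9_17 = tuple(zip(labels_9_17, (float(x) for x in w)))
    forms_3_8 = (("K4pr", 0.55), ("K4me1", 0.2), ("K4me2", 0.15), ("K4me3", 0.1))
    forms_18_26 = (
        ("K18pr+K23pr", 0.6), ("K18ac+K23pr", 0.15),
        ("K18pr+K23ac", 0.15), ("K18ac+K23ac", 0.1),
    )
    return MsSimConfig(
        histone_id=histone_id,
        sequence=seq,
        proportions=(
            ((3, 8), forms_3_8),
            ((9, 17), forms_9_17),
            ((18, 26), forms_18_26),
        ),
    )


def simulate_ms_aucs(
    cfg: MsSimConfig, out_csv: str | Path | None = None
) -> tuple[list[AucObservation], dict[tuple[int, int], dict[str, float]]]:
    """Draw an AUC table from the design; returns (observations, truth %RA).

    True forms receive scores/probabilities above the identification
    thresholds; ``n_below_threshold`` planted false forms per span receive
    sub-threshold scores so identification filtering is exercised.
    """
    from .histone import digest_argc, parse_form_label

    rng = np.random.default_rng(cfg.seed)
    protein = ProteinRecord(cfg.histone_id, cfg.histone_id, cfg.sequence)
    spans = {(s.start, s.end): s for s in digest_argc(protein)}
    obs: list[AucObservation] = []
    truth: dict[tuple[int, int], dict[str, float]] = {}
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    for (start, end), forms in cfg.proportions:
        if (start, end) not in spans:
            raise ValueError(
                f"span {start}-{end} is not an Arg-C peptide of {cfg.histone_id}"
            )
        truth[(start, end)] = {}
        for label, prop in forms:
            parse_form_label(label, span=(start, end))
            truth[(start, end)][label] = 100.0 * prop
            noise = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            obs.append(
                AucObservation(
                    histone_id=cfg.histone_id,
                    span_start=start, span_end=end,
                    form_label=label,
                    auc=cfg.auc_total * prop * noise,
                    andromeda_score=float(rng.uniform(80, 160)),
                    localization_prob=float(rng.uniform(0.9, 1.0)),
                )
            )
        used = {label for label, _ in forms}
        planted = 0
        k_positions = spans[(start, end)].k_positions
        if k_positions:
            from .histone import KState as _KS

            for state in _KS:
                if planted >= cfg.n_below_threshold:
                    break
                label = "+".join(
                    f"K{pos}{state.value}" for pos in k_positions
                )
                if label in used:
                    continue
                planted += 1
                low_score = bool(rng.random() < 0.5)
                obs.append(
                    AucObservation(
                        histone_id=cfg.histone_id,
                        span_start=start, span_end=end,
                        form_label=label,
                        auc=cfg.auc_total * 0.5,
                        andromeda_score=float(rng.uniform(5, 50)) if low_score
                        else float(rng.uniform(80, 160)),
                        localization_prob=float(rng.uniform(0.9, 1.0)) if low_score
                        else float(rng.uniform(0.0, 0.75)),
                    )
                )
    if out_csv is not None:
        write_auc_table(obs, out_csv, comment=f"seed={cfg.seed}")
    return obs, truth


# ---------------------------------------------------------------------------
# synthetic subunit panel (stand-in for the published complex catalog)

#: (complex, subunit, planted category) — a synthetic reconstruction of the
#: published 15-complex / 83-subunit catalog with the reported conservation
#: design: 44 conserved everywhere, 10 patchy in both groups, 9 specific to
#: S. cerevisiae, 8 absent in Aspergilli with patchy outgroup, 9 present in
#: all Aspergilli with patchy outgroup, 3 present in all outgroup species
#: with patchy Aspergilli. Subunit names follow the complexes discussed in
#: the fungal literature; the matrix realization is synthetic.
_C, _PB, _SC, _OPA, _OPAL, _OAP = (
    "conserved_all", "pap_both", "species_specific",
    "outgroup_pap_asp_absent", "outgroup_pap_asp_all", "outgroup_all_asp_pap",
)

SYNTHETIC_PANEL_DESIGN: tuple[tuple[str, str, str], ...] = (
    # COMPASS (H3K4 methylation)
    ("COMPASS", "SET1", _C), ("COMPASS", "CclA", _C), ("COMPASS", "Swd1", _C),
    ("COMPASS", "Swd2", _C), ("COMPASS", "Swd3", _C),
    ("COMPASS", "Spp1", _OPA), ("COMPASS", "Sdc1", _PB),
    # DCDC (H3K9 methylation)
    ("DCDC", "Dim-5", _C), ("DCDC", "Dim-7", _PB), ("DCDC", "Dim-9", _PB),
    ("DCDC", "Cul4", _C), ("DCDC", "Dim-8", _OAP),
    # SET2 complex (H3K36 methylation)
    ("SET2C", "SET2", _OAP), ("SET2C", "Spt6", _C),
    # PRC2 (H3K27 methylation; catalytic subunit SET7/KMT6)
    ("PRC2", "SET7", _OPA), ("PRC2", "EED", _OPA),
    ("PRC2", "SUZ12", _OPA), ("PRC2", "NPF", _OPA),
    # Dot1 (H3K79 methylation)
    ("DOT1", "Dot1", _C),
    # GNAT acetyltransferase complexes
    ("HAT-A2", "Gcn5", _C), ("HAT-A2", "Ada2", _C), ("HAT-A2", "Ada3", _C),
    ("ADA", "Ahc1", _SC), ("ADA", "Ahc2", _SC),
    ("SAGA", "Spt3", _C), ("SAGA", "Spt7", _C), ("SAGA", "Spt8", _OPAL),
    ("SAGA", "Spt20", _C), ("SAGA", "Ada1", _C), ("SAGA", "Taf5", _C),
    ("SAGA", "Taf6", _C), ("SAGA", "Taf9", _C), ("SAGA", "Taf10", _C),
    ("SAGA", "Taf12", _C), ("SAGA", "Tra1", _C), ("SAGA", "Chd1", _OPAL),
    ("SAGA", "Ubp8", _C), ("SAGA", "Sgf73", _OPA),
    ("SAGA", "Sgf11", _SC), ("SAGA", "Sus1", _OPA),
    ("ELONGATOR", "Elp1", _C), ("ELONGATOR", "Elp2", _C),
    ("ELONGATOR", "Elp3", _C), ("ELONGATOR", "Elp4", _C),
    ("ELONGATOR", "Elp5", _OPAL), ("ELONGATOR", "Elp6", _SC),
    ("ELONGATOR", "Hpa2", _PB), ("ELONGATOR", "Hpa3", _PB),
    # MYST acetyltransferase complexes
    ("SAS", "Sas2", _PB), ("SAS", "Sas4", _SC), ("SAS", "Sas5", _SC),
    ("SAS", "Cac1", _OPAL), ("SAS", "Cac2", _C),
    ("NuA4", "Esa1", _C), ("NuA4", "Eaf1", _C), ("NuA4", "Eaf5", _SC),
    ("NuA4", "Eaf6", _C), ("NuA4", "Eaf7", _PB), ("NuA4", "Epl1", _C),
    ("NuA4", "Yng2", _C), ("NuA4", "Arp4", _C), ("NuA4", "Swc4", _C),
    ("NuA4", "Yaf9", _OPAL),
    ("NuA3", "Sas3", _C), ("NuA3", "Taf14", _C), ("NuA3", "Nto1", _PB),
    ("NuA3", "Pdp3", _PB), ("NuA3", "Yng1", _SC), ("NuA3", "Scp1", _OPAL),
    ("NuB4", "Hat1", _C), ("NuB4", "Hat2", _C), ("NuB4", "Hif1", _OPAL),
    # histone deacetylase complexes
    ("Sin3-Rpd3", "RpdA", _C), ("Sin3-Rpd3", "Sin3", _C),
    ("Sin3-Rpd3", "Sds3", _C), ("Sin3-Rpd3", "Ume1", _SC),
    ("Sin3-Rpd3", "Pho23", _PB), ("Sin3-Rpd3", "Rxt2", _OPAL),
    ("Sin3-Rpd3", "Cti6", _OPA),
    ("HCHC", "HdaA", _C), ("HCHC", "Cdp2", _C),
    ("HCHC", "Chp2", _OAP), ("HCHC", "Hif2", _OPAL),
)

#: species panel behind the synthetic matrix: 93 Aspergilli + 14 outgroup
#: species (the study's 109 minus the two taxa excluded from the panel)
_OUTGROUP_NAMES = (
    "Saccharomyces_cerevisiae", "Schizosaccharomyces_pombe",
    "Neurospora_crassa", "Fusarium_graminearum", "Botrytis_cinerea",
    "Zymoseptoria_tritici", "Penicillium_chrysogenum", "Cladonia_grayi",
    "Plectania_melastoma", "Tuber_melanosporum", "Xylona_heveae",
    "Trichoderma_reesei", "Coprinopsis_cinerea", "Dendrothele_bispora",
)


def synthetic_panel_species(n_aspergilli: int = 93) -> SpeciesCatalog:
    entries = []
    for i, sp in enumerate(_OUTGROUP_NAMES):
        entries.append(SpeciesEntry(sp, OUTGROUP, "", i))
    for j in range(n_aspergilli):
        entries.append(
            SpeciesEntry(f"Aspergillus_sp{j + 1:03d}", ASPERGILLI, "",
                         len(_OUTGROUP_NAMES) + j)
        )
    return SpeciesCatalog(tuple(entries))


def synthetic_subunit_panel(seed: int = 0):
    """Synthetic subunit catalog + presence matrix realizing the panel design.

    Returns (SubunitCatalog, PapMatrix, SpeciesCatalog). The matrix is a
    synthetic stand-in for the published supplementary presence/absence
    table: every row is drawn to realize its planted conservation category
    (patchy rows sampled per seed), and a few patchy present cells are marked
    as rescued to mimic the translated-search corrections.
    """
    from .pap import CellState, PapMatrix, SubunitCatalog

    species = synthetic_panel_species()
    asp = species.in_group(ASPERGILLI)
    out = species.in_group(OUTGROUP)
    rng = np.random.default_rng(seed)

    complexes: dict[str, list[str]] = {}
    for cplx, sub, _ in SYNTHETIC_PANEL_DESIGN:
        complexes.setdefault(cplx, []).append(sub)
    catalog = SubunitCatalog(
        tuple((name, tuple(subs)) for name, subs in complexes.items())
    )

    def mixed(pool: list[str]) -> set[str]:
        # a strict subset with at least one present and one absent
        k = int(rng.integers(1, len(pool)))
        return set(rng.choice(pool, size=k, replace=False))

    cells: dict[tuple[str, str], CellState] = {}
    for cplx, sub, cat in SYNTHETIC_PANEL_DESIGN:
        if cat == _C:
            present = set(asp) | set(out)
        elif cat == _SC:
            present = {"Saccharomyces_cerevisiae"}
        elif cat == _OPA:
            pool = [s for s in out]
            k = int(rng.integers(2, len(pool)))  # >=2 so the row is not single-species
            present = set(rng.choice(pool, size=k, replace=False))
        elif cat == _OPAL:
            present = set(asp) | mixed(out)
        elif cat == _OAP:
            present = set(out) | mixed(asp)
        elif cat == _PB:
            present = mixed(asp) | mixed(out)
        else:  # pragma: no cover
            raise AssertionError(cat)
        for sp in asp + out:
            state = CellState.PRESENT if sp in present else CellState.ABSENT
            cells[(sub, sp)] = state
        # mark one patchy presence as a rescue correction now and then
        if cat in (_PB, _OPAL, _OAP) and rng.random() < 0.5:
            candidates = sorted(present)
            pick = candidates[int(rng.integers(len(candidates)))]
            cells[(sub, pick)] = CellState.PRESENT_RESCUED

    matrix = PapMatrix(
        tuple(catalog.subunits), tuple(species.species_ids), cells
    )
    return catalog, matrix, species
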