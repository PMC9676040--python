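"""End-to-end orchestration of the census and MS quantification stages.

``run_census`` composes the stages in order: domain-scan filtering,
architecture classification, HSP merging and retention filtering,
escalation/joining, genomic rescue, presence calling, matrix assembly and
categorization. ``run_ms`` composes digestion, form enumeration, mass
computation, identification filtering, %RA and the PTM status report. Both
write a manifest (config, seed, input checksums) sufficient to reproduce
their outputs bit-for-bit, and log retained/removed record counts per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from . import census as cz
from . import histone as hz
from . import pap as pz
from .io import (
    ProteinRecord,
    SpeciesCatalog,
    read_auc_table,
    read_blast_tab,
    read_domtblout,
    read_fasta,
    read_newick_groups,
    write_pap_tsv,
)

log = logging.getLogger("chromcensus")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, config, inputs: Mapping[str, Path],
                    counts: Mapping[str, int]) -> None:
    cfg_dict = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in inputs.items()
            if Path(p).is_file()
        },
        "stage_counts": dict(counts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_groups_tsv(path: str | Path) -> dict[str, str]:
    groups = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sp, group = line.split("\t")[:2]
            groups[sp] = group.strip()
    return groups


def run_census(
    indir: str | Path,
    outdir: str | Path,
    cfg: cz.CensusConfig = cz.CensusConfig(),
    rules: Sequence[cz.ArchitectureRule] = cz.DEFAULT_RULES,
    enable_rescue: bool = True,
    exclude_species: Sequence[str] = (),
) -> dict:
    """Run the full census on a directory of search outputs.

    Expects the layout the synthetic generator writes: ``scan.domtbl``,
    ``blastp.tsv``, ``tblastn.tsv``, ``contigs.fasta``, ``family_refs.fasta``,
    ``species.nwk``, ``groups.tsv`` and ``proteomes/<species>.fasta``.
    Returns a summary dict and writes the per-protein architecture table,
    presence calls, presence/absence matrix and category report.
    """
    indir, outdir = Path(indir), Path(outdir)
    inputs = {
        "domtblout": indir / "scan.domtbl",
        "blastp": indir / "blastp.tsv",
        "tblastn": indir / "tblastn.tsv",
        "contigs": indir / "contigs.fasta",
        "refs": indir / "family_refs.fasta",
        "tree": indir / "species.nwk",
        "groups": indir / "groups.tsv",
    }
    missing = [str(p) for p in inputs.values() if not p.is_file()]
    if missing:
        raise FileNotFoundError(f"missing census inputs: {missing}")
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    group_map = read_groups_tsv(inputs["groups"])
    species_catalog = read_newick_groups(inputs["tree"], group_map)
    species_ids = [s for s in species_catalog.species_ids if s not in set(exclude_species)]

    proteins: dict[str, ProteinRecord] = {}
    for fasta in sorted((indir / "proteomes").glob("*.fasta")):
        for rec in read_fasta(fasta):
            proteins[rec.protein_id] = rec
    refs = {r.protein_id: r for r in read_fasta(inputs["refs"], species_id="REF")}
    family_of_query = {rid: rid.split("|", 1)[1] for rid in refs}

    # stage 1: domain scan filter
    dom_hits = read_domtblout(inputs["domtblout"])
    counts["domain_hits_raw"] = len(dom_hits)
    dom_kept = cz.filter_domain_hits(dom_hits, cfg)
    counts["domain_hits_kept"] = len(dom_kept)
    log.info("domain scan: kept %d / %d hits", len(dom_kept), len(dom_hits))

    # stage 2: architecture and family classification
    by_protein: dict[str, list] = {}
    for h in dom_kept:
        by_protein.setdefault(h.target_id, []).append(h)
    arch_rows = []
    domain_evidence: dict[tuple[str, str], list[str]] = {}
    for pid, hits in sorted(by_protein.items()):
        arch = cz.assemble_architecture(hits)
        family = cz.classify_family(arch, rules)
        sp = pid.split("|", 1)[0]
        arch_rows.append((pid, sp, ";".join(arch), family))
        if family in {r.family_name for r in rules} and sp in species_ids:
            domain_evidence.setdefault((sp, family), []).append(pid)
    counts["proteins_classified"] = len(arch_rows)
    with open(outdir / "architectures.tsv", "w") as fh:
        fh.write("protein\tspecies\tdomains\tfamily\n")
        for row in arch_rows:
            fh.write("\t".join(row) + "\n")

    # stage 3: HSP merging + retention filter
    blast = read_blast_tab(inputs["blastp"])
    counts["blastp_hsps"] = len(blast)
    qlens = {rid: r.length for rid, r in refs.items()}
    slens = {pid: p.length for pid, p in proteins.items()}
    merged = cz.merge_all_hsps(blast, qlens, slens, cfg)
    counts["merged_matches"] = len(merged)
    retained = cz.filter_matches(merged, cfg)
    counts["matches_retained"] = len(retained)
    log.info("pairwise search: %d HSPs -> %d merged -> %d retained",
             len(blast), len(merged), len(retained))

    # stage 4: escalation decisions (the escalated search itself is an
    # upstream tool; its output, when present, joins here)
    asp_set = set(
        s for s in species_ids if species_catalog.group_of(s) == "ASPERGILLI"
    )
    blastp_evidence: dict[tuple[str, str], list[str]] = {}
    escalations = []
    by_query: dict[str, list] = {}
    for m in retained:
        by_query.setdefault(m.query_id, []).append(m)
    for qid, matches in sorted(by_query.items()):
        family = family_of_query.get(qid, qid)
        plan = cz.escalation_decision(matches, asp_set, qid, cfg)
        escalations.append((qid, family, plan.escalate, plan.next_query_id))
        for m in matches:
            sp = m.subject_id.split("|", 1)[0]
            if sp in species_ids:
                blastp_evidence.setdefault((sp, family), []).append(m.subject_id)
    psiblast_path = indir / "psiblast.tsv"
    psiblast_evidence: dict[tuple[str, str], list[str]] = {}
    if psiblast_path.is_file():
        psi = read_blast_tab(psiblast_path)
        merged_psi = cz.merge_all_hsps(psi, qlens, slens, cfg)
        for m in cz.filter_matches(merged_psi, cfg):
            sp = m.subject_id.split("|", 1)[0]
            family = family_of_query.get(m.query_id, m.query_id)
            if sp in species_ids:
                psiblast_evidence.setdefault((sp, family), []).append(m.subject_id)
    with open(outdir / "escalation.tsv", "w") as fh:
        fh.write("query\tfamily\tescalate\tnext_query\n")
        for qid, family, esc, nxt in escalations:
            fh.write(f"{qid}\t{family}\t{int(esc)}\t{nxt}\n")
    counts["escalations_flagged"] = sum(1 for e in escalations if e[2])

    # stage 5: genomic rescue
    rescue_evidence: dict[tuple[str, str], list[str]] = {}
    if enable_rescue:
        tb = read_blast_tab(inputs["tblastn"])
        counts["tblastn_hits"] = len(tb)
        contigs = {r.id: str(r.seq).upper()
                   for r in SeqIO.parse(str(inputs["contigs"]), "fasta")}
        contig_lengths = {cid: len(s) for cid, s in contigs.items()}
        windows = cz.rescue_windows(tb, contig_lengths, cfg)
        counts["rescue_windows"] = len(windows)
        rescued_fasta = []
        for w in windows:
            cands = cz.single_exon_rescue(w, contigs[w.contig_id], cfg)
            if not cands:
                continue
            family = family_of_query.get(w.query_id, w.query_id)
            sp = w.contig_id.split("|", 1)[0]
            if sp in species_ids:
                rescue_evidence.setdefault((sp, family), []).append(
                    cands[0].protein_id
                )
                rescued_fasta.append(cands[0])
        counts["rescue_candidates"] = len(rescued_fasta)
        if rescued_fasta:
            from .io import write_fasta

            write_fasta(rescued_fasta, outdir / "rescued_candidates.fasta")

    # stage 6: presence calls
    families = [r.family_name for r in rules]
    calls = cz.call_presence(
        domain_scan=domain_evidence,
        blastp=blastp_evidence,
        psiblast=psiblast_evidence,
        rescue=rescue_evidence,
        grid=(species_ids, families),
    )
    counts["presence_calls"] = len(calls)
    counts["present_calls"] = sum(1 for c in calls if c.present)
    with open(outdir / "presence.tsv", "w") as fh:
        fh.write("species\ttarget\tpresent\tevidence\tsupporting_ids\n")
        for c in sorted(calls, key=lambda c: (c.family_or_subunit, c.species_id)):
            fh.write(
                f"{c.species_id}\t{c.family_or_subunit}\t{int(c.present)}\t"
                f"{c.evidence.name}\t{','.join(c.supporting_ids)}\n"
            )

    # stage 7: matrix + categorization (families as rows of a one-complex catalog)
    catalog = pz.SubunitCatalog((("census", tuple(families)),))
    reduced = SpeciesCatalog(
        tuple(
            dataclasses.replace(e, tree_order_index=i)
            for i, e in enumerate(
                e2 for e2 in sorted(species_catalog.entries,
                                    key=lambda e: e.tree_order_index)
                if e2.species_id in set(species_ids)
            )
        )
    )
    matrix = pz.build_pap_matrix(calls, catalog, reduced)
    write_pap_tsv(matrix, outdir / "pap.tsv")
    cats = pz.categorize_matrix(matrix, reduced)
    summary = pz.summarize_categories(matrix, reduced)
    with open(outdir / "categories.tsv", "w") as fh:
        fh.write("target\tcategory\tspecies\n")
        for row in matrix.rows:
            cat = cats[row]
            fh.write(f"{row}\t{cat.kind.value}\t{cat.species or ''}\n")

    _write_manifest(outdir, cfg, inputs, counts)
    return {
        "counts": counts,
        "calls": calls,
        "matrix": matrix,
        "categories": cats,
        "category_summary": dict(summary),
        "species": reduced,
    }


def run_ms(
    auc_csv: str | Path,
    outdir: str | Path,
    cfg: hz.MsConfig = hz.MsConfig(),
    histones: Mapping[str, str] = hz.DEFAULT_HISTONES,
    targets: Sequence[tuple[str, int, str]] = (),
) -> dict:
    """Run the MS quantification stage on an AUC table.

    Digest the histones, validate that every observed span is digestible,
    filter identifications, compute %RA per span, and classify the requested
    PTM targets. Writes the quantification table, the theoretical
    inclusion-list table and the PTM status report.
    """
    auc_csv, outdir = Path(auc_csv), Path(outdir)
    if not auc_csv.is_file():
        raise FileNotFoundError(str(auc_csv))
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    obs = read_auc_table(auc_csv)
    counts["observations"] = len(obs)

    digestible: dict[str, set[tuple[int, int]]] = {}
    for hid, seq in histones.items():
        prot = ProteinRecord(hid, hid, seq)
        digestible[hid] = {(s.start, s.end) for s in hz.digest_argc(prot, cfg)}
    for o in obs:
        if o.histone_id not in digestible:
            raise ValueError(f"unknown histone {o.histone_id!r} in AUC table")
        if (o.span_start, o.span_end) not in digestible[o.histone_id]:
            raise ValueError(
                f"span {o.histone_id} {o.span_start}-{o.span_end} is not an "
                f"Arg-C peptide of the histone sequence"
            )

    kept = hz.filter_identifications(obs, cfg)
    counts["observations_kept"] = len(kept)
    log.info("identification filter: kept %d / %d", len(kept), len(obs))
    quant = hz.relative_abundance(kept)
    counts["spans_quantified"] = len(quant.table)

    with open(outdir / "quant.csv", "w") as fh:
        fh.write("histone,span_start,span_end,form,percent_ra\n")
        for (hid, s, e) in quant.spans():
            for label, ra in sorted(quant.table[(hid, s, e)].items()):
                fh.write(f"{hid},{s},{e},{label},{ra:.6f}\n")

    with open(outdir / "theoretical_forms.csv", "w") as fh:
        fh.write("histone,span_start,span_end,form,mass,mz\n")
        for hid, seq in histones.items():
            prot = ProteinRecord(hid, hid, seq)
            for span, label, mass, mz in hz.theoretical_form_table(prot, cfg):
                fh.write(f"{hid},{span.start},{span.end},{label},"
                         f"{mass:.5f},{mz:.5f}\n")

    report = {}
    if targets:
        report = hz.detect_ptm_status(quant, targets, histones, cfg)
        with open(outdir / "ptm_status.tsv", "w") as fh:
            fh.write("histone\tposition\tmod_class\tstatus\n")
            for (hid, pos, mc), status in sorted(report.items()):
                fh.write(f"{hid}\t{pos}\t{mc}\t{status.value}\n")

    _write_manifest(outdir, cfg, {"auc": auc_csv}, counts)
    return {"counts": counts, "quant": quant, "ptm_status": report}
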