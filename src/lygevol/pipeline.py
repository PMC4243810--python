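"""End-to-end orchestration: align -> trim -> NJ + bootstrap -> root ->
reconcile -> functional scan -> synteny -> report.

Stages communicate through plain-text intermediate files (aligned FASTA,
Newick, TSV) written into the output directory, so each stage is
independently runnable and testable.  All randomness flows from the single
config seed through named substreams; two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import align as A
from . import function as F
from . import phylo as P
from . import reconcile as R
from . import synteny as S
from .trees import Tree

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("lygevol")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the published protocol where it
    states one (trim cutoff 0.93, 1000 bootstrap replications)."""

    sequences: str = ""
    species_tree: str = ""
    leaf_map: str = ""
    out_dir: str = "lygevol_out"
    loci: Optional[str] = None
    secretion_annotations: Optional[str] = None
    outgroup: list = field(default_factory=list)
    reference_id: str = ""
    mature_offset: int = 20
    trim_cutoff: float = 0.93
    bootstrap_reps: int = 1000
    confidence_perturbations: int = 20
    min_overlap: int = 20
    synteny_k: int = S.DEFAULT_K
    synteny_max_gap: int = S.DEFAULT_MAX_GAP
    family_prefix: str = "Lyg"
    seed: int = 1

    # -- round-trip through YAML ----------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        data = dataclasses.asdict(self)
        data.pop("out_dir")  # the destination does not affect the results
        payload = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Machine-readable diagnostics; empty list means consistent inputs."""
    findings: list[dict] = []

    def finding(kind: str, detail: str, **extra) -> None:
        findings.append({"kind": kind, "detail": detail, **extra})

    seqs = {}
    try:
        seqs = A.read_fasta(config.sequences)
    except Exception as exc:  # noqa: BLE001 - diagnostics, not exceptions
        finding("fasta", f"cannot read sequences: {exc}", path=config.sequences)
    stree = None
    try:
        stree = Tree.read(config.species_tree)
        stree.validate_species_tree()
    except Exception as exc:  # noqa: BLE001
        finding("newick", f"cannot read species tree: {exc}", path=config.species_tree)
    leaf_map = {}
    try:
        lm = pd.read_csv(config.leaf_map, sep="\t")
        leaf_map = dict(zip(lm.iloc[:, 0].astype(str), lm.iloc[:, 1].astype(str)))
    except Exception as exc:  # noqa: BLE001
        finding("tsv", f"cannot read leaf map: {exc}", path=config.leaf_map)

    if seqs and leaf_map:
        species = set(stree.leaf_names()) if stree is not None else set()
        for sid in seqs:
            if sid in config.outgroup:
                continue
            if sid not in leaf_map:
                finding("leaf_map", f"sequence {sid!r} has no species mapping", id=sid)
            elif species and leaf_map[sid] not in species:
                finding(
                    "leaf_map",
                    f"sequence {sid!r} maps to species {leaf_map[sid]!r} "
                    "absent from the species tree",
                    id=sid,
                )
    if config.reference_id and seqs and config.reference_id not in seqs:
        finding("reference", f"reference id {config.reference_id!r} not in sequences")
    for og in config.outgroup:
        if seqs and og not in seqs:
            finding("outgroup", f"outgroup id {og!r} not in sequences", id=og)
    if config.loci:
        try:
            df = S.read_loci(config.loci)
            for line, r in enumerate(df.itertuples(), start=2):
                if int(r.start) > int(r.end):
                    finding(
                        "loci",
                        f"start > end for {r.symbol}",
                        path=config.loci,
                        line=line,
                    )
                if str(r.strand) not in ("+", "-"):
                    finding(
                        "loci",
                        f"bad strand {r.strand!r} for {r.symbol}",
                        path=config.loci,
                        line=line,
                    )
        except Exception as exc:  # noqa: BLE001
            finding("loci", f"cannot read loci: {exc}", path=config.loci)
    return findings


def _stage(name: str, config: PipelineConfig, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s seed=%d config=%s %s", name, config.seed, config.digest(), extras)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, persist intermediate artifacts, return the report.

    Raises on any stage failure, naming the stage.  Outputs are byte-stable
    under a fixed config.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    findings = validate_inputs(config)
    errors = [f for f in findings if f["kind"] in ("fasta", "newick", "tsv")]
    if errors:
        raise RuntimeError(f"stage=validate: {errors}")
    for f in findings:
        log.warning("stage=validate finding=%s", f)

    sequences = A.read_fasta(config.sequences)
    stree = Tree.read(config.species_tree)
    lm = pd.read_csv(config.leaf_map, sep="\t")
    leaf_map = dict(zip(lm.iloc[:, 0].astype(str), lm.iloc[:, 1].astype(str)))
    _stage("load", config, sequences=len(sequences), species=len(stree.leaves()))

    # --- alignment + confidence + trim -------------------------------------
    scheme = A.ScoringScheme.blosum62()
    aln = A.align_with_confidence(
        sequences,
        scheme,
        n_perturb=config.confidence_perturbations,
        seed=config.seed,
    )
    aln.write_fasta(out("aligned.fasta"))
    pd.DataFrame(
        {
            "column": range(1, aln.width + 1),
            "confidence": [round(float(c), 6) for c in aln.confidence],
        }
    ).to_csv(out("confidence.tsv"), sep="\t", index=False)
    trimmed, removed = A.trim(aln, config.trim_cutoff)
    if trimmed.width == 0:
        log.warning(
            "stage=align trimming removed every column at cutoff %.2f; "
            "using the untrimmed alignment for tree building",
            config.trim_cutoff,
        )
        trimmed, removed = aln, []
    trimmed.write_fasta(out("trimmed.fasta"))
    pd.DataFrame({"removed_column": [c + 1 for c in removed]}).to_csv(
        out("removed_columns.tsv"), sep="\t", index=False
    )
    _stage("align", config, width=aln.width, removed=len(removed))

    # --- distances + NJ + bootstrap + rooting -------------------------------
    dm = P.distance_matrix(trimmed, min_sites=config.min_overlap)
    P.write_phylip(dm, out("distances.phy"))
    tree, skipped = P.bootstrap_support(
        trimmed,
        n_reps=config.bootstrap_reps,
        seed=config.seed,
        min_sites=config.min_overlap,
    )
    supports = {
        "|".join(sorted(key)): (node.support if node.support is not None else float("nan"))
        for key, node in tree.bipartitions().items()
    }
    pd.DataFrame(
        sorted(supports.items()), columns=["bipartition", "support"]
    ).to_csv(out("supports.tsv"), sep="\t", index=False)
    if config.outgroup:
        rooted = P.root_by_outgroup(tree, config.outgroup)
    else:
        rooted = P.midpoint_root(tree)
        log.info("stage=tree rooting=midpoint reason=no-outgroup-configured")
    rooted.write(out("gene_tree.nwk"))
    _stage("tree", config, bootstrap=config.bootstrap_reps, skipped=skipped)

    # --- reconciliation -----------------------------------------------------
    species_names = set(n.name for n in stree.leaves())
    drop = [
        leaf.name
        for leaf in rooted.leaves()
        if leaf_map.get(leaf.name) not in species_names
    ]
    ingroup_tree = _drop_leaves(rooted, drop) if drop else rooted
    for d in drop:
        log.info("stage=reconcile dropped=%s reason=species-not-in-tree", d)
    rec = R.lca_reconcile(ingroup_tree, stree, leaf_map)
    R.label_duplication_ages(rec)
    losses = R.count_losses_per_lineage(rec)
    naming = R.assign_names(rec, family_prefix=config.family_prefix)
    pd.DataFrame(
        [
            {
                "node": d.name or "",
                "type": "duplication",
                "species_branch": rec.age_labels.get(d, ""),
            }
            for d in rec.duplications
        ]
    ).to_csv(out("events.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(losses.items()), columns=["species_branch", "losses"]
    ).to_csv(out("losses.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(naming.names.items()), columns=["gene", "name"]
    ).to_csv(out("names.tsv"), sep="\t", index=False)
    _stage("reconcile", config, duplications=len(rec.duplications), losses=rec.losses_total)

    # --- functional scan ----------------------------------------------------
    annotations = None
    if config.secretion_annotations:
        adf = pd.read_csv(config.secretion_annotations, sep="\t")
        annotations = {
            str(r.id): {
                "signal_peptide": r.signal_peptide,
                "nonclassical_score": getattr(r, "nonclassical_score", None),
            }
            for r in adf.itertuples()
        }
    statuses: dict[str, F.FunctionalStatus] = {}
    refmap = None
    if config.reference_id:
        refmap = F.build_reference_map(aln, config.reference_id, config.mature_offset)
        for sid in aln.ids:
            if sid in config.outgroup or sid not in leaf_map:
                continue
            st = F.classify_catalytic(refmap.site_states(sid))
            ann = annotations.get(sid) if annotations else None
            st.secretion, provenance = F.classify_secretion(sequences[sid], ann)
            st.notes.append(f"secretion: {provenance}")
            statuses[sid] = st
        pd.DataFrame(
            [
                {
                    "gene": sid,
                    "name": naming.names.get(sid, ""),
                    "site73": statuses[sid].site73,
                    "site86": statuses[sid].site86,
                    "site97": statuses[sid].site97,
                    "muramidase": statuses[sid].muramidase,
                    "secretion": statuses[sid].secretion,
                    "notes": "; ".join(statuses[sid].notes),
                }
                for sid in sorted(statuses)
            ]
        ).to_csv(out("status.tsv"), sep="\t", index=False)
        table, summary, flags = F.compensation_table(statuses, leaf_map)
        table.to_csv(out("compensation.tsv"), sep="\t", index=False)
    else:
        table, summary, flags = pd.DataFrame(), {}, []
    _stage("scan", config, classified=len(statuses), flagged=len(flags))

    # --- synteny ------------------------------------------------------------
    synteny_report = {}
    if config.loci:
        loci = S.read_loci(config.loci)
        family = sorted(set(sequences) - set(config.outgroup))
        clusters = S.tandem_clusters(loci, family, max_gap=config.synteny_max_gap)
        pd.DataFrame(
            [
                {**c, "members": ";".join(c["members"])}
                for c in clusters
            ]
        ).to_csv(out("clusters.tsv"), sep="\t", index=False)
        # conservation of each family gene's neighborhood against every other
        hoods = []
        for sym in family:
            try:
                hoods.extend(
                    S.extract_neighborhood(
                        loci, sym, k=config.synteny_k, family_symbols=family
                    )
                )
            except S.SyntenyError:
                continue
        scores = []
        for i in range(len(hoods)):
            for j in range(i + 1, len(hoods)):
                sc, shared = S.conservation_score(hoods[i], hoods[j])
                scores.append(
                    {
                        "gene_a": hoods[i].focal.symbol,
                        "species_a": hoods[i].focal.species,
                        "gene_b": hoods[j].focal.symbol,
                        "species_b": hoods[j].focal.species,
                        "jaccard": round(sc, 6),
                        "shared": ";".join(shared),
                    }
                )
        pd.DataFrame(scores).to_csv(out("synteny.tsv"), sep="\t", index=False)
        synteny_report = {
            "clusters": len(clusters),
            "mean_jaccard": (
                round(sum(s["jaccard"] for s in scores) / len(scores), 6)
                if scores
                else None
            ),
        }
        _stage("synteny", config, clusters=len(clusters))

    # --- report -------------------------------------------------------------
    report = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_sequences": len(sequences),
        "alignment_width": aln.width,
        "trimmed_width": trimmed.width,
        "removed_columns": len(removed),
        "duplications": [
            {"node": d.name or "", "age_label": rec.age_labels.get(d, "")}
            for d in rec.duplications
        ],
        "losses_total": rec.losses_total,
        "losses_per_branch": dict(sorted(losses.items())),
        "copy_number": dict(sorted(rec.copy_number.items())),
        "paralog_names": dict(sorted(naming.names.items())),
        "functional_summary": summary,
        "uncompensated_species": flags,
        "synteny": synteny_report,
        "validation_findings": findings,
    }
    with open(out("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _stage("report", config)
    return report


def _drop_leaves(tree: Tree, names: list[str]) -> Tree:
    """Copy of ``tree`` without the named leaves (unary nodes spliced)."""
    drop = set(names)

    def rec(n):
        from .trees import Node

        if n.is_leaf:
            if n.name in drop:
                return None
            m = Node(n.name, n.length)
            m.support = n.support
            return m
        kept = [c for c in (rec(ch) for ch in n.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += n.length
            return kept[0]
        m = Node(n.name, n.length)
        m.support = n.support
        for c in kept:
            m.add_child(c)
        return m

    root = rec(tree.root)
    if root is None:
        raise ValueError("dropping leaves emptied the tree")
    root.length = 0.0
    return Tree(root)
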