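"""Ground-truthed synthetic gene families.

This module generates everything the downstream analysis consumes — species
trees, gene trees with a complete duplication/loss event history, amino-acid
sequences with conserved catalytic sites, post-duplication functional decay,
and clustered gene coordinates with conserved flanking genes — so that every
pipeline stage can be tested against known truth.

The model mirrors the biology of a vertebrate gene family such as goose-type
lysozyme: a single ancestral gene at the root of the species tree undergoes a
linear birth--death process (duplication rate ``dup_rate``, loss rate
``loss_rate``) along every species-tree branch; sequences evolve by an
independent-site 20-state substitution process with three strongly conserved
catalytic positions (the analogues of mature-goose E73/D86/D97) and an
N-terminal signal peptide; after a duplication, one daughter clade may lose
catalytic residues (E->Q, D->N) and/or its signal peptide while its sibling
stays intact, reproducing the within-species compensation pattern in which a
degraded copy always co-occurs with an intact paralog.

Randomness: every operation draws from its own named stream derived from the
user seed via ``numpy.random.SeedSequence(seed, spawn_key=(crc32(name),))``.
Adding a new operation therefore never perturbs the draws of an existing one.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import Node, Tree

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_SIGNAL_PEPTIDE",
    "DEFAULT_ROOT_SEQUENCE",
    "DEFAULT_CATALYTIC_MATURE_POSITIONS",
    "Event",
    "EventHistory",
    "SimulatedFamily",
    "stream_rng",
    "simulate_species_tree",
    "vertebrate_species_tree",
    "simulate_gene_family",
    "evolve_sequences",
    "inject_functional_decay",
    "assign_loci",
    "simulate_family",
    "write_fixture",
    "read_fixture",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for operation ``name`` under user ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Default root sequence: 20-residue hydrophobic signal peptide followed by a
# 185-residue mature region with catalytic glutamate at mature position 73 and
# aspartates at 86 and 97 (the goose-lysozyme coordinate system).
# ---------------------------------------------------------------------------

DEFAULT_SIGNAL_PEPTIDE = "MKVLSLLLLLALCSLAVLAQ"  # 20 residues, strongly hydrophobic
DEFAULT_CATALYTIC_MATURE_POSITIONS = (73, 86, 97)


def _default_mature(length: int = 185) -> str:
    rng = np.random.default_rng(np.random.SeedSequence(20140188))
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    seq[73 - 1] = "E"
    seq[86 - 1] = "D"
    seq[97 - 1] = "D"
    return "".join(seq)


DEFAULT_ROOT_SEQUENCE = DEFAULT_SIGNAL_PEPTIDE + _default_mature()
#: 0-based indices of the catalytic sites within DEFAULT_ROOT_SEQUENCE
DEFAULT_CATALYTIC_INDICES = tuple(
    len(DEFAULT_SIGNAL_PEPTIDE) + p - 1 for p in DEFAULT_CATALYTIC_MATURE_POSITIONS
)


# ---------------------------------------------------------------------------
# Event history
# ---------------------------------------------------------------------------


@dataclass
class Event:
    """One event of the gene-family process.

    ``branch`` names the species-tree node at the lower end of the branch on
    which the event occurred (speciations occur exactly at that node).
    ``time`` is measured from the top of that branch.  ``lineage`` is the id
    of the affected gene lineage; duplication events carry the ids of the two
    daughter lineages so that truth can be matched to gene-tree nodes.
    """

    kind: str  # duplication | loss | speciation
    branch: str
    time: float
    lineage: str
    daughters: tuple[str, str] | None = None


@dataclass
class EventHistory:
    events: list[Event] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    @property
    def n_duplications(self) -> int:
        return len(self.of_kind("duplication"))

    @property
    def n_losses(self) -> int:
        return len(self.of_kind("loss"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "branch": e.branch,
                    "time": e.time,
                    "lineage": e.lineage,
                    "daughters": ";".join(e.daughters) if e.daughters else "",
                }
                for e in self.events
            ],
            columns=["kind", "branch", "time", "lineage", "daughters"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventHistory":
        evs = []
        for _, r in df.iterrows():
            daughters = tuple(r["daughters"].split(";")) if r["daughters"] else None
            evs.append(Event(r["kind"], r["branch"], float(r["time"]), r["lineage"], daughters))
        return cls(evs)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def simulate_species_tree(n_species: int, birth_rate: float, seed: int) -> Tree:
    """Yule (pure-birth) ultrametric species tree with ``n_species`` leaves.

    Lineages split at rate ``birth_rate`` each; after the last split the tree
    is extended by one further exponential waiting time so that every cherry
    has a positive pendant branch.  Leaves are named ``sp1..spN`` in the order
    they appear; internal nodes are named ``anc1..`` in postorder.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = stream_rng(seed, "species_tree")

    root = Node()
    tips: list[Node] = [root.add_child(Node()), root.add_child(Node())]
    birth_times = {id(root): 0.0}
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        birth_times[id(node)] = t
        tips.insert(i, node.add_child(Node()))
        tips.insert(i + 1, node.add_child(Node()))
    t += rng.exponential(1.0 / (birth_rate * len(tips)))

    tree = Tree(root)
    # convert birth times into branch lengths; tips end at time t
    for node in tree.preorder():
        if node.parent is None:
            node.length = 0.0
            continue
        end = birth_times.get(id(node), t)
        node.length = end - birth_times[id(node.parent)]
    k_leaf, k_int = 0, 0
    for node in tree.postorder():
        if node.is_leaf:
            k_leaf += 1
            node.name = f"sp{k_leaf}"
        elif node.name is None:
            k_int += 1
            node.name = f"anc{k_int}"
    return tree


#: Fixed vertebrate-class topology with named ancestors, ultrametric in units
#: of 100 Myr (depths are round figures, not inferences).
_VERTEBRATE_NEWICK = (
    "((((((human:0.9,mouse:0.9)placental_ancestor:0.7,opossum:1.6)"
    "mammal_ancestor:1.5,((chicken:0.4,turkey:0.4)bird_ancestor:1.9,"
    "(alligator:2.0,turtle:2.0)reptile_ancestor:0.3)sauropsid_ancestor:0.8)"
    "amniote_ancestor:0.4,xenopus:3.5)tetrapod_ancestor:0.6,"
    "(coelacanth:3.9,(zebrafish:3.2,(medaka:1.8,tetraodon:1.8)"
    "acanthomorph_ancestor:1.4)teleost_ancestor:0.7)fish_split:0.2)"
    "jawed_vertebrate_ancestor:1.4,lamprey:5.5)vertebrate_ancestor;"
)


def vertebrate_species_tree() -> Tree:
    """The packaged vertebrate species tree (mammals/birds/reptiles = amniotes,
    amphibian, lobe-finned fish, teleosts, jawless fish outgroup)."""
    return Tree.from_newick(_VERTEBRATE_NEWICK)


# ---------------------------------------------------------------------------
# Birth--death gene family simulation
# ---------------------------------------------------------------------------


def simulate_gene_family(
    tree: Tree, dup_rate: float, loss_rate: float, seed: int
) -> tuple[Tree, EventHistory]:
    """Linear birth--death process along every species-tree branch.

    One gene is present at the species-tree root.  Duplications create a
    sister gene lineage at that time point; losses terminate a lineage;
    at each speciation node every surviving lineage is copied into both
    daughter branches.  The returned gene tree is pruned to lineages with
    extant descendants (unary nodes spliced out, root set to the MRCA of the
    extant copies) and carries time-unit branch lengths; the history keeps
    every event, including those in fully pruned clades.  Surviving
    duplication nodes keep their event id (``d<k>``) as the gene-tree
    internal node name, so truth can be matched to reconciliation output.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    tree.validate_species_tree()
    rng = stream_rng(seed, "gene_family")
    history = EventHistory()
    counter = {"lineage": 0, "dup": 0}
    sdepth = {id(n): n.depth() for n in tree.preorder()}
    times: dict[int, float] = {}

    def new_lineage() -> str:
        counter["lineage"] += 1
        return f"L{counter['lineage']}"

    groot = Node()
    times[id(groot)] = 0.0
    extant: list[Node] = []
    leaf_species: dict[int, str] = {}

    def along_branch(gnode: Node, lineage: str, snode: Node, t0: float) -> None:
        """Evolve ``lineage`` from branch-relative time ``t0`` to the end of
        the branch leading to species node ``snode``."""
        total = dup_rate + loss_rate
        top_abs = sdepth[id(snode)] - snode.length
        t = t0
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if t + wait >= snode.length:
                break
            t += wait
            if rng.random() < (dup_rate / total if total else 0.0):
                counter["dup"] += 1
                a, b = new_lineage(), new_lineage()
                history.events.append(
                    Event("duplication", snode.name, t, lineage, (a, b))
                )
                dup_node = Node(name=f"d{counter['dup']}")
                gnode.add_child(dup_node)
                times[id(dup_node)] = top_abs + t
                ca, cb = Node(), Node()
                dup_node.add_child(ca)
                dup_node.add_child(cb)
                times[id(ca)] = times[id(cb)] = top_abs + t
                along_branch(ca, a, snode, t)
                gnode, lineage = cb, b
                continue
            history.events.append(Event("loss", snode.name, t, lineage))
            gnode.name = f"lost_{lineage}"
            times[id(gnode)] = top_abs + t
            return
        at_node(gnode, lineage, snode)

    def at_node(gnode: Node, lineage: str, snode: Node) -> None:
        times[id(gnode)] = sdepth[id(snode)]
        if snode.is_leaf:
            leaf_species[id(gnode)] = snode.name
            extant.append(gnode)
            return
        history.events.append(Event("speciation", snode.name, snode.length, lineage))
        for child in snode.children:
            sub = new_lineage()
            cnode = Node()
            gnode.add_child(cnode)
            times[id(cnode)] = sdepth[id(snode)]
            along_branch(cnode, sub, child, 0.0)

    at_node(groot, "L0", tree.root)

    # branch lengths from absolute times
    for n in groot.preorder():
        n.length = 0.0 if n.parent is None else max(
            times[id(n)] - times[id(n.parent)], 0.0
        )

    # --- name extant leaves per species, stable in postorder ---------------
    extant_ids = {id(n) for n in extant}
    per_species_count: dict[str, int] = {}
    leaf_map: dict[str, str] = {}
    for n in groot.postorder():
        if id(n) in extant_ids:
            sp = leaf_species[id(n)]
            per_species_count[sp] = per_species_count.get(sp, 0) + 1
            n.name = f"{sp}_{per_species_count[sp]}"
            leaf_map[n.name] = sp

    # --- prune to lineages with extant descendants -------------------------
    def prune(n: Node) -> Optional[Node]:
        if n.is_leaf:
            return Node(n.name, n.length) if id(n) in extant_ids else None
        kept = [c for c in (prune(ch) for ch in n.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += n.length
            return kept[0]
        m = Node(n.name, n.length)
        for c in kept:
            m.add_child(c)
        return m

    pruned = prune(groot)
    if pruned is None:
        pruned = Node(name="empty")
    pruned.length = 0.0
    gene_tree = Tree(pruned)
    gene_tree.leaf_map = leaf_map  # type: ignore[attr-defined]
    return gene_tree, history


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequences(
    gene_tree: Tree,
    root_sequence: str,
    rate: float,
    conserved_sites: set[int] | tuple[int, ...] = (),
    conserved_rate_factor: float = 0.0,
    seed: int = 0,
    exchange_matrix: Optional[np.ndarray] = None,
) -> dict[str, str]:
    """Independent-site substitution along each gene-tree branch.

    Default model is uniform 20-state exchange: substitution events arrive as
    a Poisson process at ``rate`` per site per time unit (``rate *
    conserved_rate_factor`` at 0-based positions in ``conserved_sites``), and
    each event moves the site to one of the 19 other residues uniformly.  An
    alternative 20x20 row-stochastic jump matrix may be supplied.  Returns a
    leaf-name -> sequence dict; deterministic under a fixed seed.
    """
    if not root_sequence:
        raise ValueError("root_sequence must be non-empty")
    if not 0.0 <= conserved_rate_factor <= 1.0:
        raise ValueError("conserved_rate_factor must be in [0, 1]")
    L = len(root_sequence)
    conserved = sorted(set(int(i) for i in conserved_sites))
    if any(i < 0 or i >= L for i in conserved):
        raise ValueError("conserved site position out of sequence bounds")
    if exchange_matrix is not None:
        exchange_matrix = np.asarray(exchange_matrix, dtype=float)
        if exchange_matrix.shape != (20, 20):
            raise ValueError("exchange_matrix must be 20x20")

    rng = stream_rng(seed, "evolve_sequences")
    site_rates = np.full(L, float(rate))
    site_rates[conserved] = rate * conserved_rate_factor

    root = np.array([_AA_INDEX[a] for a in root_sequence], dtype=np.int64)
    out: dict[str, str] = {}

    def jump(states: np.ndarray, idx: np.ndarray) -> None:
        if exchange_matrix is None:
            shift = rng.integers(1, 20, size=idx.size)
            states[idx] = (states[idx] + shift) % 20
        else:
            for i in idx:
                states[i] = rng.choice(20, p=exchange_matrix[states[i]])

    def rec(node: Node, states: np.ndarray) -> None:
        if node.parent is not None and node.length > 0:
            n_events = rng.poisson(site_rates * node.length)
            m = int(n_events.max(initial=0))
            for _ in range(m):
                idx = np.flatnonzero(n_events > 0)
                jump(states, idx)
                n_events = n_events - 1
        if node.is_leaf:
            out[node.name] = "".join(AMINO_ACIDS[i] for i in states)
        for c in node.children:
            rec(c, states.copy())

    rec(gene_tree.root, root.copy())
    return out


# ---------------------------------------------------------------------------
# SimulatedFamily container and functional decay
# ---------------------------------------------------------------------------


@dataclass
class SimulatedFamily:
    """Ground-truth container for one simulated gene family."""

    species_tree: Tree
    gene_tree: Tree  # true tree, pruned to extant copies
    history: EventHistory
    leaf_map: dict[str, str]  # gene leaf -> species
    sequences: dict[str, str]
    signal_length: int = len(DEFAULT_SIGNAL_PEPTIDE)
    catalytic_indices: tuple[int, ...] = DEFAULT_CATALYTIC_INDICES
    # truth per copy: catalytic decay injected?, signal peptide present?
    catalytic_decayed: dict[str, bool] = field(default_factory=dict)
    signal_present: dict[str, bool] = field(default_factory=dict)
    loci: Optional[pd.DataFrame] = None

    def copies_of(self, species: str) -> list[str]:
        return [g for g, s in self.leaf_map.items() if s == species]

    def true_alignment_rows(self) -> dict[str, str]:
        """Gap-padded rows of the true alignment.

        The only indel the simulator produces is whole signal-peptide
        deletion, so the true alignment pads decayed prefixes with gaps.
        """
        rows = {}
        for g, seq in self.sequences.items():
            if self.signal_present.get(g, True):
                rows[g] = seq
            else:
                rows[g] = "-" * self.signal_length + seq
        return rows


def surviving_duplications(family_or_tree) -> list[str]:
    """Event ids of duplications with both daughter clades surviving (their
    nodes are internal nodes of the pruned true gene tree)."""
    tree = family_or_tree.gene_tree if hasattr(family_or_tree, "gene_tree") else family_or_tree
    return [
        n.name
        for n in tree.postorder()
        if not n.is_leaf and n.name and n.name.startswith("d") and n.name[1:].isdigit()
    ]


def inject_functional_decay(
    family: SimulatedFamily,
    post_dup_catalytic_loss_prob: float,
    post_dup_signal_loss_prob: float,
    seed: int,
) -> SimulatedFamily:
    """Degrade one daughter clade of surviving duplications, keeping the
    compensation invariant.

    For each surviving duplication (oldest first), one daughter clade is
    chosen at random; with the stated probabilities its extant copies receive
    catalytic substitutions (E->Q at the site-73 analogue, D->N at the 86/97
    analogues) and/or deletion of the signal-peptide prefix.  A candidate
    daughter is only degraded if afterwards every species carrying any
    degraded copy still carries an intact one; if neither daughter passes the
    check the duplication is skipped.  This makes the compensation pattern
    (degraded copy => intact within-species paralog) an exact construction
    invariant, not a statistical tendency.
    """
    for p in (post_dup_catalytic_loss_prob, post_dup_signal_loss_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if not family.catalytic_indices:
        raise ValueError("family has no designated catalytic sites")
    L = len(DEFAULT_ROOT_SEQUENCE)
    for i in family.catalytic_indices:
        if i < family.signal_length:
            raise ValueError("catalytic site falls inside the signal peptide")

    rng = stream_rng(seed, "functional_decay")
    for g in family.leaf_map:
        family.catalytic_decayed.setdefault(g, False)
        family.signal_present.setdefault(g, True)

    dup_nodes = [
        n
        for n in family.gene_tree.postorder()
        if not n.is_leaf and n.name and n.name.startswith("d") and n.name[1:].isdigit()
    ]
    # oldest first: smaller depth = closer to the root
    dup_nodes.sort(key=lambda n: (n.depth(), n.name))

    def compensated(cat_decay: dict[str, bool]) -> bool:
        by_species: dict[str, list[str]] = {}
        for g, sp in family.leaf_map.items():
            by_species.setdefault(sp, []).append(g)
        for sp, copies in by_species.items():
            if any(cat_decay[g] for g in copies) and not any(
                not cat_decay[g] for g in copies
            ):
                return False
        return True

    for node in dup_nodes:
        do_cat = rng.random() < post_dup_catalytic_loss_prob
        do_sig = rng.random() < post_dup_signal_loss_prob
        if not (do_cat or do_sig):
            continue
        first = int(rng.integers(2))
        chosen = None
        for k in (first, 1 - first):
            daughter = node.children[k]
            clade = daughter.leaf_names()
            if do_cat:
                trial = dict(family.catalytic_decayed)
                for g in clade:
                    trial[g] = True
                if not compensated(trial):
                    continue
            chosen = clade
            break
        if chosen is None:
            continue
        for g in chosen:
            if do_cat and not family.catalytic_decayed[g]:
                seq = list(family.sequences[g])
                off = 0 if family.signal_present[g] else family.signal_length
                i73, i86, i97 = (i - off for i in family.catalytic_indices)
                seq[i73] = "Q"
                seq[i86] = "N"
                seq[i97] = "N"
                family.sequences[g] = "".join(seq)
                family.catalytic_decayed[g] = True
            if do_sig and family.signal_present[g]:
                family.sequences[g] = family.sequences[g][family.signal_length:]
                family.signal_present[g] = False
    return family


# ---------------------------------------------------------------------------
# Gene coordinates
# ---------------------------------------------------------------------------

FLANK_UPSTREAM = ("E1F5B", "TXNDC9")
FLANK_DOWNSTREAM = ("MRPL30", "MITD1")


def assign_loci(
    family: SimulatedFamily,
    spacing: int = 30_000,
    gene_length: int = 5_000,
    flank_upstream: tuple[str, ...] = FLANK_UPSTREAM,
    flank_downstream: tuple[str, ...] = FLANK_DOWNSTREAM,
) -> pd.DataFrame:
    """Tandem-cluster coordinates per species with conserved flanking genes.

    Copies within a species sit on one scaffold, same strand, ``spacing`` bp
    apart (default 30 kb, the human LYGA1/LYGA2 separation), bracketed by the
    conserved marker genes on both sides.  Coordinates are 1-based inclusive.
    """
    rows = []
    by_species: dict[str, list[str]] = {}
    for g in sorted(family.leaf_map):
        by_species.setdefault(family.leaf_map[g], []).append(g)
    for sp, copies in sorted(by_species.items()):
        scaffold = "chr1"
        pos = 100_000
        for sym in flank_upstream:
            rows.append((sp, scaffold, pos, pos + gene_length - 1, "+", sym))
            pos += gene_length + spacing
        for g in copies:
            rows.append((sp, scaffold, pos, pos + gene_length - 1, "+", g))
            pos += gene_length + spacing
        for sym in flank_downstream:
            rows.append((sp, scaffold, pos, pos + gene_length - 1, "+", sym))
            pos += gene_length + spacing
    df = pd.DataFrame(rows, columns=["species", "scaffold", "start", "end", "strand", "symbol"])
    family.loci = df
    return df


# ---------------------------------------------------------------------------
# High-level convenience + fixture I/O
# ---------------------------------------------------------------------------


def simulate_family(
    seed: int,
    species_tree: Optional[Tree] = None,
    dup_rate: float = 0.2,
    loss_rate: float = 0.05,
    sub_rate: float = 0.08,
    root_sequence: str = DEFAULT_ROOT_SEQUENCE,
    conserved_rate_factor: float = 0.0,
    catalytic_loss_prob: float = 0.5,
    signal_loss_prob: float = 0.3,
) -> SimulatedFamily:
    """Simulate a complete family on the vertebrate tree (or a supplied one).

    Defaults give lineage-specific and ancient duplications at realistic
    family sizes (a handful of copies per species), near-invariant catalytic
    sites, and post-duplication decay at the rates the compensation analysis
    assumes.  ``sub_rate`` is per site per time unit (100 Myr on the packaged
    vertebrate tree); the default 0.08 yields roughly 50-60% divergence
    between the deepest tips, the regime in which distant family members
    remain alignable.
    """
    stree = species_tree if species_tree is not None else vertebrate_species_tree()
    gtree, history = simulate_gene_family(stree, dup_rate, loss_rate, seed)
    leaf_map = getattr(gtree, "leaf_map", {})
    if gtree.root.is_leaf and gtree.root.name == "empty":
        sequences = {}
    else:
        sequences = evolve_sequences(
            gtree,
            root_sequence,
            rate=sub_rate,
            conserved_sites=DEFAULT_CATALYTIC_INDICES,
            conserved_rate_factor=conserved_rate_factor,
            seed=seed,
        )
    fam = SimulatedFamily(
        species_tree=stree,
        gene_tree=gtree,
        history=history,
        leaf_map=dict(leaf_map),
        sequences=sequences,
    )
    inject_functional_decay(fam, catalytic_loss_prob, signal_loss_prob, seed)
    assign_loci(fam)
    return fam


def write_fixture(family: SimulatedFamily, out_dir) -> dict[str, str]:
    """Write a family as plain-text files that round-trip losslessly.

    Emits ``sequences.fasta``, ``gene_tree.nwk``, ``species_tree.nwk``,
    ``leaf_map.tsv``, ``events.tsv``, ``truth.tsv`` and ``loci.tsv``.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in {
        "sequences": "sequences.fasta",
        "gene_tree": "gene_tree.nwk",
        "species_tree": "species_tree.nwk",
        "leaf_map": "leaf_map.tsv",
        "events": "events.tsv",
        "truth": "truth.tsv",
        "loci": "loci.tsv",
    }.items()}
    records = [
        SeqRecord(Seq(seq), id=g, description="")
        for g, seq in sorted(family.sequences.items())
    ]
    SeqIO.write(records, paths["sequences"], "fasta")
    family.gene_tree.write(paths["gene_tree"], support_as_label=False)
    family.species_tree.write(paths["species_tree"], support_as_label=False)
    pd.DataFrame(
        sorted(family.leaf_map.items()), columns=["gene", "species"]
    ).to_csv(paths["leaf_map"], sep="\t", index=False)
    family.history.to_frame().to_csv(paths["events"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene": g,
                "catalytic_decayed": str(family.catalytic_decayed.get(g, False)),
                "signal_present": str(family.signal_present.get(g, True)),
            }
            for g in sorted(family.leaf_map)
        ]
    ).to_csv(paths["truth"], sep="\t", index=False)
    if family.loci is not None:
        family.loci.to_csv(paths["loci"], sep="\t", index=False)
    return paths


def read_fixture(out_dir) -> SimulatedFamily:
    """Read back a family written by :func:`write_fixture`."""
    p = lambda name: os.path.join(out_dir, name)  # noqa: E731
    sequences = {
        r.id: str(r.seq) for r in SeqIO.parse(p("sequences.fasta"), "fasta")
    }
    gene_tree = Tree.read(p("gene_tree.nwk"))
    species_tree = Tree.read(p("species_tree.nwk"))
    leaf_map = dict(
        pd.read_csv(p("leaf_map.tsv"), sep="\t").itertuples(index=False, name=None)
    )
    history = EventHistory.from_frame(
        pd.read_csv(p("events.tsv"), sep="\t", keep_default_na=False)
    )
    truth = pd.read_csv(p("truth.tsv"), sep="\t")
    fam = SimulatedFamily(
        species_tree=species_tree,
        gene_tree=gene_tree,
        history=history,
        leaf_map=leaf_map,
        sequences=sequences,
        catalytic_decayed={
            r.gene: str(r.catalytic_decayed) == "True" for r in truth.itertuples()
        },
        signal_present={
            r.gene: str(r.signal_present) == "True" for r in truth.itertuples()
        },
    )
    loci_path = p("loci.tsv")
    if os.path.exists(loci_path):
        fam.loci = pd.read_csv(loci_path, sep="\t")
    return fam
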