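"""Progressive multiple alignment with column-confidence trimming.

The stages mirror a standard protein-alignment protocol: global pairwise
Needleman--Wunsch with affine gaps, a k-mer/UPGMA guide tree, profile--profile
progressive alignment ("once a gap, always a gap"), a perturbation-based
per-column confidence score in the spirit of alignment-reliability tools, and
trimming at a confidence cutoff (default 0.93).

Conventions stated once and enforced throughout: the affine gap recurrence is
the three-state M/Ix/Iy dynamic programme; the first position of a gap costs
``gap_open + gap_extend`` and each further position ``gap_extend``; terminal
gaps are penalised identically to internal gaps; traceback ties prefer
match/mismatch over a gap in the second sequence over a gap in the first.
Internal coordinates are 0-based half-open; file coordinates 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .sim import AMINO_ACIDS, stream_rng
from .trees import Node, Tree

__all__ = [
    "AlignmentError",
    "ScoringScheme",
    "AlignedSet",
    "pairwise_align",
    "guide_tree",
    "progressive_align",
    "column_confidence",
    "align_with_confidence",
    "trim",
    "codon_backmap",
    "read_fasta",
]

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Symmetric amino-acid substitution scores with affine gap penalties.

    ``gap_open`` and ``gap_extend`` are non-positive by convention; opening a
    gap costs ``gap_open + gap_extend``.
    """

    matrix: dict
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")

    def score(self, a: str, b: str) -> float:
        return self.matrix[(a, b)]

    @classmethod
    def simple(
        cls, match: float = 1.0, mismatch: float = -1.0,
        gap_open: float = -2.0, gap_extend: float = -1.0,
    ) -> "ScoringScheme":
        m = {
            (a, b): (match if a == b else mismatch)
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        }
        return cls(m, gap_open, gap_extend)

    @classmethod
    def blosum62(cls, gap_open: float = -10.0, gap_extend: float = -1.0) -> "ScoringScheme":
        bl = substitution_matrices.load("BLOSUM62")
        m = {
            (a, b): float(bl[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        return cls(m, gap_open, gap_extend)


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise AlignmentError(f"empty sequence: {name}")
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise AlignmentError(
                f"illegal residue {ch!r} at position {i + 1} of {name}"
            )


@dataclass
class AlignedSet:
    """Fixed-width gapped sequence matrix with optional per-column confidence.

    ``original_columns`` maps each current column to its 0-based column index
    in the alignment the set was derived from (identity for fresh alignments);
    it lets site states be traced through trimming.
    """

    ids: list[str]
    rows: list[str]
    confidence: Optional[np.ndarray] = None
    original_columns: Optional[list[int]] = None

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentError("rows of unequal width")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        if self.confidence is not None and len(self.confidence) != self.width:
            raise AlignmentError("confidence vector length != width")
        if self.original_columns is None:
            self.original_columns = list(range(self.width))

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def positions(self, seq_id: str) -> list[Optional[int]]:
        """Per column: 1-based ungapped position in this row, or None at gaps."""
        out: list[Optional[int]] = []
        k = 0
        for ch in self.row(seq_id):
            if ch == GAP:
                out.append(None)
            else:
                k += 1
                out.append(k)
        return out

    # -- I/O -------------------------------------------------------------
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")

    @classmethod
    def read_fasta(cls, path) -> "AlignedSet":
        recs = list(SeqIO.parse(path, "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])


def read_fasta(path) -> dict[str, str]:
    """Ordered id -> sequence mapping; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise AlignmentError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


# ---------------------------------------------------------------------------
# Affine-gap global alignment (three-state DP, deterministic traceback)
# ---------------------------------------------------------------------------

_NEG = float("-inf")


def _affine_dp(
    n: int,
    m: int,
    score_at: Callable[[int, int], float],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[tuple[str, int, int]], float]:
    """Globally align positions 0..n-1 against 0..m-1.

    Returns the traceback path as a list of moves ("M" consume both, "X"
    consume left only / gap in right, "Y" consume right only) and the optimal
    score.  Tie preference on traceback: M > X > Y, applied at the final cell
    and within every recurrence.
    """
    go, ge = gap_open, gap_extend
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = score_at(i - 1, j - 1)
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + go + ge, Xp[j] + ge, Yp[j] + go + ge)
            Yi[j] = max(Mi[j - 1] + go + ge, Yi[j - 1] + ge, Xi[j - 1] + go + ge)

    # traceback
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i][j])
    # max() with a key keeps the first of equal candidates, giving M > X > Y
    path: list[str] = []
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    while i > 0 or j > 0:
        if state == "M":
            s = score_at(i - 1, j - 1)
            prev = M[i - 1][j - 1] + s
            if prev == M[i][j]:
                nxt = "M"
            elif X[i - 1][j - 1] + s == M[i][j]:
                nxt = "X"
            else:
                nxt = "Y"
            path.append("M")
            i, j = i - 1, j - 1
            state = nxt
        elif state == "X":
            if i >= 1 and j == 0:
                path.append("X")
                i -= 1
                continue
            if M[i - 1][j] + go + ge == X[i][j]:
                nxt = "M"
            elif X[i - 1][j] + ge == X[i][j]:
                nxt = "X"
            else:
                nxt = "Y"
            path.append("X")
            i -= 1
            state = nxt
        else:
            if j >= 1 and i == 0:
                path.append("Y")
                j -= 1
                continue
            if M[i][j - 1] + go + ge == Y[i][j]:
                nxt = "M"
            elif Y[i][j - 1] + ge == Y[i][j]:
                nxt = "Y"
            else:
                nxt = "X"
            path.append("Y")
            j -= 1
            state = nxt
    path.reverse()
    return path, score


def pairwise_align(
    a: str, b: str, scheme: Optional[ScoringScheme] = None
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences under an affine-gap scheme.

    Returns the two gapped strings and the optimal score.  Deterministic: on
    traceback ties, match/mismatch is preferred over a gap in ``b`` over a gap
    in ``a``.
    """
    scheme = scheme or ScoringScheme.blosum62()
    _check_sequence(a, "a")
    _check_sequence(b, "b")
    path, score = _affine_dp(
        len(a), len(b), lambda i, j: scheme.score(a[i], b[j]),
        scheme.gap_open, scheme.gap_extend,
    )
    ga, gb = [], []
    i = j = 0
    for move in path:
        if move == "M":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif move == "X":
            ga.append(a[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb), score


# ---------------------------------------------------------------------------
# Guide tree: 3-mer count vectors + UPGMA with lexicographic tie-breaking
# ---------------------------------------------------------------------------


def _kmer_vectors(sequences: dict[str, str], k: int = 3) -> tuple[list[str], np.ndarray]:
    kmers = sorted({s[i : i + k] for s in sequences.values() for i in range(len(s) - k + 1)})
    index = {km: i for i, km in enumerate(kmers)}
    mat = np.zeros((len(sequences), max(len(kmers), 1)))
    for r, s in enumerate(sequences.values()):
        for i in range(len(s) - k + 1):
            mat[r, index[s[i : i + k]]] += 1
    return list(sequences), mat


def _upgma(ids: list[str], dist: np.ndarray) -> Tree:
    """Average-linkage clustering; ties broken lexicographically on the
    smallest member id of each cluster (written in-house because the tie rule
    must be explicit for reproducibility)."""
    n = len(ids)
    if n < 2:
        raise AlignmentError("guide tree needs >= 2 sequences")
    clusters: dict[int, tuple[Node, int, str, float]] = {}
    for i, name in enumerate(ids):
        clusters[i] = (Node(name), 1, name, 0.0)  # node, size, rep id, height
    d = {frozenset((i, j)): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(clusters) > 1:
        best = None
        for key, val in d.items():
            i, j = sorted(key, key=lambda c: clusters[c][2])
            cand = (val, clusters[i][2], clusters[j][2])
            if best is None or cand < best[0]:
                best = (cand, i, j)
        _, i, j = best
        ni, nj = clusters[i], clusters[j]
        h = d[frozenset((i, j))] / 2.0
        parent = Node()
        for child_info in (ni, nj):
            child = child_info[0]
            child.length = max(h - child_info[3], 0.0)
            parent.add_child(child)
        new = (parent, ni[1] + nj[1], min(ni[2], nj[2]), h)
        del clusters[i], clusters[j]
        for k2 in list(clusters):
            dk = (
                ni[1] * d.pop(frozenset((i, k2)))
                + nj[1] * d.pop(frozenset((j, k2)))
            ) / (ni[1] + nj[1])
            d[frozenset((nxt, k2))] = dk
        del d[frozenset((i, j))]
        clusters[nxt] = new
        nxt += 1
    (root, _, _, _) = next(iter(clusters.values()))
    return Tree(root)


def guide_tree(sequences: dict[str, str], k: int = 3) -> Tree:
    """Rooted binary merge order from Euclidean distances between k-mer
    count vectors, clustered by UPGMA; deterministic with lexicographic
    tie-breaking on sequence ids."""
    if len(sequences) != len(set(sequences)):
        raise AlignmentError("duplicate sequence ids")
    if len(sequences) < 2:
        raise AlignmentError("guide tree needs >= 2 sequences")
    ids, mat = _kmer_vectors(sequences, k=k)
    diff = mat[:, None, :] - mat[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return _upgma(ids, dist)


# ---------------------------------------------------------------------------
# Progressive profile--profile alignment
# ---------------------------------------------------------------------------


def _profile_score(scheme: ScoringScheme):
    def score(col_a: Sequence[str], col_b: Sequence[str]) -> float:
        total = 0.0
        for x in col_a:
            if x == GAP:
                continue
            for y in col_b:
                if y != GAP:
                    total += scheme.score(x, y)
        return total / (len(col_a) * len(col_b))

    return score


def _merge_profiles(
    ids_a: list[str], rows_a: list[str], ids_b: list[str], rows_b: list[str],
    scheme: ScoringScheme,
) -> tuple[list[str], list[str]]:
    cols_a = ["".join(r[j] for r in rows_a) for j in range(len(rows_a[0]))]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(len(rows_b[0]))]
    colscore = _profile_score(scheme)
    path, _ = _affine_dp(
        len(cols_a), len(cols_b),
        lambda i, j: colscore(cols_a[i], cols_b[j]),
        scheme.gap_open, scheme.gap_extend,
    )
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for move in path:
        if move == "M":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            i += 1; j += 1
        elif move == "X":
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            for r in range(len(rows_b)):
                out_b[r].append(GAP)
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append(GAP)
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
    return ids_a + ids_b, ["".join(x) for x in out_a] + ["".join(x) for x in out_b]


def progressive_align(
    sequences: dict[str, str],
    guide: Optional[Tree] = None,
    scheme: Optional[ScoringScheme] = None,
) -> AlignedSet:
    """Profile--profile alignment up the guide tree ("once a gap, always a
    gap").  Output rows are in the input order of ``sequences``."""
    scheme = scheme or ScoringScheme.blosum62()
    for sid, s in sequences.items():
        _check_sequence(s, sid)
    if len(sequences) == 1:
        [(sid, s)] = sequences.items()
        return AlignedSet([sid], [s])
    guide = guide if guide is not None else guide_tree(sequences)
    if set(guide.leaf_names()) != set(sequences):
        raise AlignmentError("guide tree leaves do not match sequence ids")

    def rec(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [sequences[node.name]]
        parts = [rec(c) for c in node.children]
        ids, rows = parts[0]
        for ids_b, rows_b in parts[1:]:
            ids, rows = _merge_profiles(ids, rows, ids_b, rows_b, scheme)
        return ids, rows

    ids, rows = rec(guide.root)
    order = {sid: i for i, sid in enumerate(sequences)}
    pairs = sorted(zip(ids, rows), key=lambda p: order[p[0]])
    return AlignedSet([p[0] for p in pairs], [p[1] for p in pairs])


# ---------------------------------------------------------------------------
# Column confidence (perturbed-guide-tree agreement) and trimming
# ---------------------------------------------------------------------------


def _residue_pairs(aln: AlignedSet) -> list[set]:
    """Per column: the set of aligned residue pairs
    ``(row_i, pos_i, row_j, pos_j)`` with ungapped 1-based positions."""
    pos = [aln.positions(sid) for sid in aln.ids]
    out = []
    for c in range(aln.width):
        pairs = set()
        present = [(r, pos[r][c]) for r in range(len(aln.ids)) if pos[r][c] is not None]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                ri, pi = present[x]
                rj, pj = present[y]
                pairs.add((ri, pi, rj, pj))
        out.append(pairs)
    return out


def column_confidence(
    sequences: dict[str, str],
    scheme: Optional[ScoringScheme] = None,
    n_perturb: int = 20,
    seed: int = 0,
    base: Optional[AlignedSet] = None,
) -> np.ndarray:
    """Per-column reliability of the progressive alignment, in [0, 1].

    The guide-tree k-mer count vectors are bootstrap-resampled along the
    k-mer dimension ``n_perturb`` times; each perturbed guide tree yields a
    realignment, and a base column's score is the mean fraction of its aligned
    residue pairs that co-occur in the perturbed alignments.  Columns with no
    residue pair (fewer than two residues) score 1.0 vacuously.
    """
    if n_perturb < 1:
        raise ValueError("n_perturb must be >= 1")
    scheme = scheme or ScoringScheme.blosum62()
    if base is None:
        base = progressive_align(sequences, guide_tree(sequences), scheme)
    rng = stream_rng(seed, "column_confidence")
    ids, mat = _kmer_vectors(sequences)
    base_pairs = _residue_pairs(base)
    # row index correspondence between base and perturbed alignments
    scores = np.zeros(base.width)
    for _ in range(n_perturb):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        pm = mat[:, cols]
        diff = pm[:, None, :] - pm[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        ptree = _upgma(ids, dist)
        paln = progressive_align(sequences, ptree, scheme)
        ppairs = set().union(*_residue_pairs(paln)) if paln.width else set()
        # base and perturbed alignments share row order (input order)
        for c, pairs in enumerate(base_pairs):
            if not pairs:
                scores[c] += 1.0
            else:
                scores[c] += len(pairs & ppairs) / len(pairs)
    return scores / n_perturb


def align_with_confidence(
    sequences: dict[str, str],
    scheme: Optional[ScoringScheme] = None,
    n_perturb: int = 20,
    seed: int = 0,
) -> AlignedSet:
    """Progressive alignment with its confidence vector attached."""
    scheme = scheme or ScoringScheme.blosum62()
    aln = progressive_align(sequences, guide_tree(sequences), scheme)
    aln.confidence = column_confidence(
        sequences, scheme, n_perturb=n_perturb, seed=seed, base=aln
    )
    return aln


def trim(aln: AlignedSet, cutoff: float = 0.93) -> tuple[AlignedSet, list[int]]:
    """Retain columns with confidence >= cutoff (boundary kept so that a
    perfect-confidence alignment survives cutoff 1.0).

    Returns the trimmed set and the list of removed 0-based column indices
    (relative to ``aln``).  An empty result is flagged with a warning.
    """
    if aln.confidence is None:
        raise AlignmentError("confidence not computed; run column_confidence first")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    keep = [j for j in range(aln.width) if aln.confidence[j] >= cutoff]
    removed = [j for j in range(aln.width) if aln.confidence[j] < cutoff]
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    if not keep:
        warnings.warn("trim removed every column; empty alignment")
    out = AlignedSet(
        list(aln.ids),
        rows,
        confidence=np.asarray([aln.confidence[j] for j in keep]),
        original_columns=[aln.original_columns[j] for j in keep],
    )
    return out, removed


# ---------------------------------------------------------------------------
# Codon back-mapping
# ---------------------------------------------------------------------------


def codon_backmap(protein_aln: AlignedSet, cds: dict[str, str]) -> AlignedSet:
    """Expand each protein column to its codon triplet (gap columns to '---').

    Every CDS must translate (standard code) to its protein row, optionally
    with a terminal stop codon.
    """
    rows = []
    for sid in protein_aln.ids:
        if sid not in cds:
            raise AlignmentError(f"no CDS supplied for {sid}")
        nt = cds[sid].upper()
        prot = protein_aln.degapped(sid)
        if len(nt) not in (3 * len(prot), 3 * len(prot) + 3):
            raise AlignmentError(
                f"CDS length for {sid} is {len(nt)}, expected "
                f"{3 * len(prot)} (+3 for a stop)"
            )
        translated = str(Seq(nt[: 3 * len(prot)]).translate())
        for k, (x, y) in enumerate(zip(translated, prot)):
            if x != y:
                raise AlignmentError(
                    f"CDS for {sid} translates to {x!r} at residue {k + 1}, "
                    f"protein has {y!r}"
                )
        codons = [nt[3 * k : 3 * k + 3] for k in range(len(prot))]
        it = iter(codons)
        rows.append(
            "".join(next(it) if ch != GAP else "---" for ch in protein_aln.row(sid))
        )
    return AlignedSet(list(protein_aln.ids), rows)
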