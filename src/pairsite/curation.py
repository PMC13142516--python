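"""Dataset curation: record filtering, identity clustering, leakage-free splits.

Receptor–peptide pair records (BioLiP-style annotations) are filtered for
sequence integrity, focal proteins are clustered so no two share more than
25% pairwise identity, and whole clusters are assigned to train/validation/
blind subsets (or to grouped cross-validation folds) so a focal protein never
appears on both sides of a split.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ComplexRecord",
    "SplitAssignment",
    "filter_records",
    "pairwise_identity",
    "cluster_by_identity",
    "grouped_split",
    "grouped_kfold",
    "classify_disorder",
    "read_complex_records",
    "write_split_manifest",
    "MAX_PEPTIDE_LENGTH",
    "IDENTITY_CLUSTER_THRESHOLD",
]

MAX_PEPTIDE_LENGTH = 30          # residues; admission criterion for peptide ligands
IDENTITY_CLUSTER_THRESHOLD = 25.0  # percent pairwise identity
MIN_PARENT_IDENTITY = 90.0       # percent identity to the parent entry
DEFAULT_SPLIT_RATIOS = (0.60, 0.10, 0.30)
SUBSET_NAMES = ("train", "val", "blind")


@dataclass
class ComplexRecord:
    pdb_id: str
    receptor_chain: str
    peptide_chain: str
    receptor_parent_id: str
    peptide_parent_id: str
    peptide_length: int
    identity_to_parent: float          # for the focal chain, percent
    parent_id_count: int = 1
    is_antibody_complex: bool = False
    receptor_parent_sequence: str = ""
    peptide_parent_sequence: str = ""


@dataclass(frozen=True)
class SplitAssignment:
    focal_parent_id: str
    subset: str                         # train | val | blind
    fold: int | None = None


def filter_records(
    records: list[ComplexRecord],
) -> tuple[list[ComplexRecord], list[tuple[ComplexRecord, str]]]:
    """Apply the curation filters; every rejection carries exactly one rule tag.

    Rules, in order of precedence: missing parent reference, mapping to
    multiple parent identifiers, <90% identity to the parent entry, antibody
    complex, peptide longer than 30 residues.
    """
    kept, rejected = [], []
    for rec in records:
        if not rec.receptor_parent_id or not rec.peptide_parent_id:
            rejected.append((rec, "no-uniprot"))
        elif rec.parent_id_count != 1:
            rejected.append((rec, "multi-uniprot"))
        elif rec.identity_to_parent < MIN_PARENT_IDENTITY:
            rejected.append((rec, "identity<90"))
        elif rec.is_antibody_complex:
            rejected.append((rec, "antibody"))
        elif rec.peptide_length > MAX_PEPTIDE_LENGTH:
            rejected.append((rec, "peptide>30"))
        else:
            kept.append(rec)
    return kept, rejected


_ALIGNER: Align.PairwiseAligner | None = None


def _local_aligner() -> Align.PairwiseAligner:
    # Smith–Waterman, BLOSUM62, gap open 11 / extend 1: inclusive toward
    # locally similar regions, no coverage constraint.
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two sequences, CD-HIT convention.

    Identities are counted on the best local (Smith–Waterman) alignment and
    normalised by the shorter sequence length.  Normalising by alignment
    length instead would degenerate: any two proteins sharing one
    high-scoring residue pair (e.g. W–W under BLOSUM62) align over a single
    column at 100% identity, merging unrelated sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aln = _local_aligner().align(seq_a, seq_b)
    if len(aln) == 0 or aln.score <= 0:
        return 0.0
    identities = aln[0].counts().identities
    return 100.0 * identities / min(len(seq_a), len(seq_b))


def cluster_by_identity(
    sequences: dict[str, str], threshold: float = IDENTITY_CLUSTER_THRESHOLD
) -> dict[str, str]:
    """Greedy longest-first clustering (CD-HIT style) at >threshold% identity.

    Sequences are visited longest first; each joins the first existing
    cluster whose representative exceeds the threshold, otherwise founds a
    new cluster named after itself.  Returns id -> cluster-representative id.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    representatives: list[str] = []
    assignment: dict[str, str] = {}
    for sid in order:
        placed = False
        for rep in representatives:
            if pairwise_identity(sequences[rep], sequences[sid]) > threshold:
                assignment[sid] = rep
                placed = True
                break
        if not placed:
            representatives.append(sid)
            assignment[sid] = sid
    return assignment


def _cluster_groups(clusters: dict[str, str]) -> list[list[str]]:
    groups: dict[str, list[str]] = {}
    for sid, rep in clusters.items():
        groups.setdefault(rep, []).append(sid)
    return [sorted(groups[rep]) for rep in sorted(groups)]


def _apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder rounding of n units into len(ratios) bins."""
    raw = [n * r for r in ratios]
    base = [int(np.floor(x)) for x in raw]
    remainder = n - sum(base)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(remainder):
        base[order[i]] += 1
    return base


def grouped_split(
    clusters: dict[str, str],
    ratios: tuple[float, float, float] = DEFAULT_SPLIT_RATIOS,
    seed: int = 0,
) -> list[SplitAssignment]:
    """Assign whole clusters to train/val/blind at the requested ratios.

    The unit of assignment is the cluster, so all pairs of a focal protein
    (and all its >25%-identity relatives) land in one subset.  Deterministic
    for a fixed seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    groups = _cluster_groups(clusters)
    if len(groups) < len(ratios):
        raise ValueError(f"need at least {len(ratios)} clusters, got {len(groups)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    sizes = _apportion(len(groups), ratios)
    out: list[SplitAssignment] = []
    cursor = 0
    for subset, size in zip(SUBSET_NAMES, sizes):
        for gi in order[cursor : cursor + size]:
            for sid in groups[gi]:
                out.append(SplitAssignment(focal_parent_id=sid, subset=subset))
        cursor += size
    return out


def grouped_kfold(
    clusters: dict[str, str],
    k: int = 5,
    inner_ratios: tuple[float, float] = (0.70, 0.10),
    seed: int = 0,
) -> list[list[SplitAssignment]]:
    """k disjoint blind folds (~1/k of clusters each); within each fold the
    remaining clusters split train/val at inner_ratios renormalised — the
    default gives an overall 70:10:20 partition per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    groups = _cluster_groups(clusters)
    if len(groups) < k:
        raise ValueError(f"need at least k={k} clusters, got {len(groups)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for pos, gi in enumerate(order):
        fold_members[pos % k].append(gi)

    inner_total = sum(inner_ratios)
    folds: list[list[SplitAssignment]] = []
    for fold_idx in range(k):
        blind = fold_members[fold_idx]
        rest = [gi for f in range(k) if f != fold_idx for gi in fold_members[f]]
        n_train, n_val = _apportion(
            len(rest), tuple(r / inner_total for r in inner_ratios)
        )
        assignments: list[SplitAssignment] = []
        for gi in blind:
            for sid in groups[gi]:
                assignments.append(SplitAssignment(sid, "blind", fold=fold_idx + 1))
        for pos, gi in enumerate(rest):
            subset = "train" if pos < n_train else "val"
            for sid in groups[gi]:
                assignments.append(SplitAssignment(sid, subset, fold=fold_idx + 1))
        folds.append(assignments)
    return folds


def classify_disorder(secondary_structure: str, threshold_pct: float = 75.0) -> bool:
    """Disordered iff the coil fraction of a 3-state (H/E/C) string is
    >= threshold (inclusive)."""
    if not secondary_structure:
        raise ValueError("empty secondary-structure string")
    ss = secondary_structure.upper()
    bad = set(ss) - set("HEC")
    if bad:
        raise ValueError(f"illegal secondary-structure characters: {sorted(bad)}")
    coil_fraction = 100.0 * ss.count("C") / len(ss)
    return coil_fraction >= threshold_pct


def read_complex_records(path: str | Path) -> list[ComplexRecord]:
    """Read BioLiP-style annotation TSV.

    Columns: pdb_id, receptor_chain, peptide_chain, receptor_parent,
    peptide_parent, peptide_length, identity_pct, parent_id_count,
    is_antibody (0/1); extra columns ignored.
    """
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ComplexRecord(
                        pdb_id=row["pdb_id"],
                        receptor_chain=row["receptor_chain"],
                        peptide_chain=row["peptide_chain"],
                        receptor_parent_id=row["receptor_parent"],
                        peptide_parent_id=row["peptide_parent"],
                        peptide_length=int(row["peptide_length"]),
                        identity_to_parent=float(row["identity_pct"]),
                        parent_id_count=int(row.get("parent_id_count", 1) or 1),
                        is_antibody_complex=bool(int(row.get("is_antibody", 0) or 0)),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed record at line {lineno}: {exc}") from exc
    return records


def write_split_manifest(assignments: list[SplitAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["focal_id", "subset", "fold"])
        for a in assignments:
            writer.writerow([a.focal_parent_id, a.subset, a.fold if a.fold else ""])
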