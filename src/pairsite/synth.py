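"""Synthetic fixtures: planted partner-conditioned motifs and toy complexes.

Real peptide interfaces are often mediated by short linear motifs (SLiMs):
a few contiguous query residues that bind only when the partner presents a
complementary surface.  The generator emulates this with coupled k-mer
pairs: a query residue is a true interface residue iff it lies inside a
planted query motif AND the coupled partner motif occurs somewhere in the
partner sequence.  Labels are therefore partner-conditioned by construction
and recomputable by plain string matching, and scrambling the partner
destroys them.  Class imbalance defaults to the few-percent range typical
of residue-level interface data.

Toy two-chain coordinate sets give the ΔRSA labeler a fixture with an exact
expected answer: chain B atoms occlude precisely the requested chain A
positions and sit far outside occlusion range of all others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labeling import ChainStructure

__all__ = ["PlantedRule", "PairRecord", "generate_pair_dataset", "planted_labels",
           "generate_toy_complex", "DEFAULT_POSITIVE_RATE"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_POSITIVE_RATE = 0.03  # realized residue-level positive fraction target


@dataclass(frozen=True)
class PlantedRule:
    """Coupled (query-motif, partner-motif) k-mer pairs defining ground truth."""

    motif_pairs: tuple[tuple[str, str], ...] = (("CWH", "MYF"),)
    background_positive_rate: float = 0.0
    label_noise: float = 0.0

    def __post_init__(self) -> None:
        if len(set(self.motif_pairs)) != len(self.motif_pairs) or not self.motif_pairs:
            raise ValueError("motif pairs must be non-empty and distinct")
        if any(len(q) < 1 or len(p) < 1 for q, p in self.motif_pairs):
            raise ValueError("motifs must be non-empty")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")

    @property
    def k(self) -> int:
        return max(len(q) for q, _ in self.motif_pairs)


@dataclass
class PairRecord:
    query_id: str
    partner_id: str
    query_seq: str
    partner_seq: str
    labels: np.ndarray  # int8, per query residue


def planted_labels(query_seq: str, partner_seq: str, rule: PlantedRule) -> np.ndarray:
    """Ground-truth oracle: pure string matching of the motif couples.

    Every residue of every query-motif occurrence is positive iff the
    coupled partner motif occurs anywhere in the partner.
    """
    labels = np.zeros(len(query_seq), dtype=np.int8)
    for qm, pm in rule.motif_pairs:
        if pm not in partner_seq:
            continue
        start = query_seq.find(qm)
        while start != -1:
            labels[start : start + len(qm)] = 1
            start = query_seq.find(qm, start + 1)
    return labels


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _plant(seq: list[str], motif: str, rng: np.random.Generator) -> None:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    seq[pos : pos + len(motif)] = list(motif)


def generate_pair_dataset(
    n_pairs: int,
    query_len_range: tuple[int, int] = (40, 60),
    partner_len_range: tuple[int, int] = (20, 40),
    rule: PlantedRule = PlantedRule(),
    positive_rate_target: float = DEFAULT_POSITIVE_RATE,
    seed: int = 0,
    query_motif_rate: float = 1.0,
    max_retries: int = 20,
) -> list[PairRecord]:
    """Generate paired sequences with planted partner-conditioned labels.

    Each pair receives a query-motif occurrence with probability
    ``query_motif_rate`` (default 1: every query carries its motif, so the
    query side is marginally uninformative and the label information lives
    entirely in whether the partner presents the coupled motif — the design
    that makes the scrambled-partner control meaningful).  The partner-motif
    planting probability is derived so the expected residue-level positive
    fraction equals ``positive_rate_target``; a dataset whose realized
    fraction falls outside +/-30% relative of the target is redrawn
    (bounded retries).
    """
    if not (0.0 < positive_rate_target < 0.2):
        raise ValueError("positive_rate_target must lie in (0, 0.2)")
    if query_len_range[0] > query_len_range[1] or partner_len_range[0] > partner_len_range[1]:
        raise ValueError("invalid length ranges")
    k = rule.k
    if query_len_range[0] < k or partner_len_range[0] < max(len(p) for _, p in rule.motif_pairs):
        raise ValueError("sequences too short to host the motifs")

    if not (0.0 < query_motif_rate <= 1.0):
        raise ValueError("query_motif_rate must lie in (0, 1]")
    mean_lq = 0.5 * (query_len_range[0] + query_len_range[1])
    p_partner = positive_rate_target * mean_lq / (k * query_motif_rate)
    if p_partner > 0.95:
        raise ValueError("positive_rate_target unreachable at these lengths")

    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        records: list[PairRecord] = []
        n_pos = n_res = 0
        for i in range(n_pairs):
            lq = int(rng.integers(query_len_range[0], query_len_range[1] + 1))
            lp = int(rng.integers(partner_len_range[0], partner_len_range[1] + 1))
            q, p = _random_seq(rng, lq), _random_seq(rng, lp)
            qm, pm = rule.motif_pairs[int(rng.integers(len(rule.motif_pairs)))]
            if rng.random() < query_motif_rate:
                _plant(q, qm, rng)
            if rng.random() < p_partner:
                _plant(p, pm, rng)
            qs, ps = "".join(q), "".join(p)
            labels = planted_labels(qs, ps, rule)
            if rule.background_positive_rate > 0.0:
                labels |= (rng.random(lq) < rule.background_positive_rate).astype(np.int8)
            if rule.label_noise > 0.0:
                flips = rng.random(lq) < rule.label_noise
                labels = np.where(flips, 1 - labels, labels).astype(np.int8)
            records.append(
                PairRecord(
                    query_id=f"Q{i:04d}", partner_id=f"P{i:04d}",
                    query_seq=qs, partner_seq=ps, labels=labels,
                )
            )
            n_pos += int(labels.sum())
            n_res += lq
        realized = n_pos / n_res
        if abs(realized - positive_rate_target) <= 0.30 * positive_rate_target:
            return records
    raise RuntimeError(
        f"could not realize positive rate {positive_rate_target} within "
        f"{max_retries} attempts (last realized {realized:.4f})"
    )


def generate_toy_complex(
    n_residues_a: int,
    n_residues_b: int,
    contact_positions: set[int],
    seed: int = 0,
    spacing: float = 10.0,
    contact_distance: float = 4.0,
    far_offset: float = 500.0,
) -> tuple[ChainStructure, ChainStructure]:
    """Two toy chains with exactly controlled occlusion.

    Chain A: one carbon sphere per residue on a line, ``spacing`` Å apart
    (far beyond mutual occlusion range).  Chain B: one atom placed
    ``contact_distance`` Å from each requested A position — inside the
    occlusion radius 2*(r_vdw + r_probe) = 6.2 Å — and any remaining B atoms
    ``far_offset`` Å away, outside occlusion range of everything.
    Positions are 0-based indices into chain A.
    """
    if any(p < 0 or p >= n_residues_a for p in contact_positions):
        raise ValueError("contact position outside chain A")
    if len(contact_positions) > n_residues_b:
        raise ValueError(f"need >= {len(contact_positions)} B residues for the contacts")
    if n_residues_b < 1:
        raise ValueError("chain B must have at least one residue")

    coords_a = np.array([[spacing * i, 0.0, 0.0] for i in range(n_residues_a)])
    chain_a = ChainStructure(
        chain_id="A",
        residue_names=["ALA"] * n_residues_a,
        residue_numbers=list(range(1, n_residues_a + 1)),
        atom_elements=["C"] * n_residues_a,
        atom_residue_index=np.arange(n_residues_a),
        atom_coords=coords_a,
    )
    coords_b = []
    for p in sorted(contact_positions):
        coords_b.append([spacing * p, contact_distance, 0.0])
    for j in range(n_residues_b - len(contact_positions)):
        coords_b.append([spacing * j, far_offset, 0.0])
    chain_b = ChainStructure(
        chain_id="B",
        residue_names=["ALA"] * n_residues_b,
        residue_numbers=list(range(1, n_residues_b + 1)),
        atom_elements=["C"] * n_residues_b,
        atom_residue_index=np.arange(n_residues_b),
        atom_coords=np.array(coords_b),
    )
    return chain_a, chain_b
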