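"""Seeded generators for every input the pipeline consumes.

These emulate, at desk scale, the statistical features the method relies
on: low-complexity disorder-like sequence composition with planted
two-residue motifs, piecewise disorder-score tracks, toy ligand libraries
built from known base substructures, peptide–ligand coordinate sets with
a clear contact/no-contact margin around the 4.0 Å rule, and interaction
records generated by a learnable residue-context site rule.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import IdrSegment, InteractionRecord, ScoreTrack
from .protogroups import MolecularGraph
from .sequences import ALPHABET, MAX_SEP, Sequence

#: Disorder-promoting default composition: enriched in P, E, S, K, G and
#: depleted in the order-promoting aromatics and Cys.  Weights are a design
#: default of the generator, not measured data.
DISORDER_COMPOSITION: dict[str, float] = {
    "P": 0.12, "E": 0.12, "S": 0.12, "K": 0.11, "G": 0.11,
    "A": 0.07, "Q": 0.06, "D": 0.06, "R": 0.05, "T": 0.05,
    "N": 0.04, "L": 0.03, "V": 0.02, "I": 0.01, "M": 0.01,
    "H": 0.01, "F": 0.003, "Y": 0.003, "W": 0.002, "C": 0.002,
}


@dataclass(frozen=True)
class FamilySpec:
    """A compositional sequence family with one planted dipeptide motif."""

    family_id: str
    composition: dict[str, float] = field(default_factory=lambda: dict(DISORDER_COMPOSITION))
    motif: tuple[str, str, int] = ("Y", "G", 3)  # (first aa, second aa, separation k)
    motif_density: float = 0.1  # planted motifs per residue
    length_mean: float = 80.0
    length_min: int = 40

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"composition weights sum to {total}, not 1")
        a, b, k = self.motif
        if not (1 <= k <= MAX_SEP):
            raise ValueError(f"motif separation {k} outside 1..{MAX_SEP}")
        if a not in ALPHABET or b not in ALPHABET:
            raise ValueError(f"motif residues {a}, {b} must be standard amino acids")


@dataclass(frozen=True)
class PlantedSiteRule:
    """Interaction-site ground truth: a residue letter in a fixed context.

    A position is a site iff it holds *target* and the residue at
    ``position + context_offset`` is *context_residue*.  Records generated
    under the rule link their sites to *protogroup_index*.
    """

    target: str = "Y"
    context_residue: str = "G"
    context_offset: int = 3
    protogroup_index: int = 1

    def __post_init__(self) -> None:
        if abs(self.context_offset) > MAX_SEP:
            raise ValueError(f"context offset {self.context_offset} outside ±{MAX_SEP}")

    def sites(self, residues: str) -> set[int]:
        """1-based positions matching the rule."""
        out = set()
        for i, aa in enumerate(residues):
            j = i + self.context_offset
            if aa == self.target and 0 <= j < len(residues) and residues[j] == self.context_residue:
                out.add(i + 1)
        return out


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng([abs(int(seed)) % (2**31), *keys])


def gen_idr_sequences(spec: FamilySpec, n: int, seed: int) -> list[Sequence]:
    """Draw *n* sequences from the family composition with planted motifs.

    Motifs are planted by overwriting ``round(density * L)`` positions
    (and their offset partners) with the motif residues at the family's
    separation; infeasible densities (no room for the motif) raise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _spawn(seed, 1)
    letters = np.array(list(spec.composition))
    weights = np.array([spec.composition[aa] for aa in letters])
    weights = weights / weights.sum()
    a, b, k = spec.motif
    sequences = []
    for i in range(n):
        length = max(spec.length_min, int(rng.poisson(spec.length_mean)))
        if length <= k:
            raise ValueError("sequence too short to hold the planted motif")
        residues = rng.choice(letters, size=length, p=weights)
        n_motifs = int(round(spec.motif_density * length))
        if n_motifs > 0:
            if length - k < 1:
                raise ValueError("motif density infeasible for sequence length")
            starts = rng.integers(0, length - k, size=n_motifs)
            for s in starts:
                residues[s] = a
                residues[s + k] = b
        sequences.append(Sequence(id=f"{spec.family_id}_{i}", residues="".join(residues)))
    return sequences


def gen_score_tracks(
    segments: list[tuple[int, float, float]],
    seed: int,
    sequence_id: str = "synthetic_track",
    composition: dict[str, float] | None = None,
) -> ScoreTrack:
    """Piecewise-constant disorder track with clipped Gaussian noise.

    *segments* is a list of (length, level, noise_sd) pieces; residues are
    drawn from *composition* (disorder default).
    """
    rng = _spawn(seed, 2)
    comp = composition or DISORDER_COMPOSITION
    letters = np.array(list(comp))
    weights = np.array([comp[aa] for aa in letters])
    weights = weights / weights.sum()
    scores: list[np.ndarray] = []
    for length, level, noise_sd in segments:
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"disorder level {level} outside [0, 1]")
        piece = np.full(length, level)
        if noise_sd > 0:
            piece = piece + rng.normal(0.0, noise_sd, size=length)
        scores.append(np.clip(piece, 0.0, 1.0))
    all_scores = np.concatenate(scores) if scores else np.empty(0)
    residues = "".join(rng.choice(letters, size=len(all_scores), p=weights))
    return ScoreTrack(sequence_id=sequence_id, residues=residues, scores=all_scores)


# ---------------------------------------------------------------------------
# Toy ligand library

#: Base substructure motifs the library is assembled from.  Mining should
#: rediscover the >= 4-atom members of this list near the top ranks.
BASE_MOTIFS: dict[str, MolecularGraph] = {
    "ring6": MolecularGraph(
        "ring6", ("C",) * 6, tuple((i, (i + 1) % 6) for i in range(6))
    ),
    "chain4": MolecularGraph("chain4", ("C",) * 4, ((0, 1), (1, 2), (2, 3))),
    "branch4": MolecularGraph("branch4", ("C", "C", "C", "N"), ((0, 1), (0, 2), (0, 3))),
    "chain3o": MolecularGraph("chain3o", ("C", "C", "O"), ((0, 1), (1, 2))),
    "chain5": MolecularGraph("chain5", ("C",) * 5, tuple((i, i + 1) for i in range(4))),
}

_DECORATIONS = ("C", "N", "O", "S")


def gen_toy_ligands(
    n: int,
    decoration_rate: float = 0.5,
    seed: int = 0,
    base_motifs: dict[str, MolecularGraph] | None = None,
) -> tuple[list[MolecularGraph], dict[str, str]]:
    """Toy ligand library assembled from base motifs with random decorations.

    Each ligand starts as a copy of a base motif; with probability
    *decoration_rate* per existing atom (capped at 3 additions) a decoration
    atom is attached.  Returns (ligands, membership) where membership maps
    ligand id -> originating base motif id.
    """
    rng = _spawn(seed, 3)
    motifs = base_motifs or BASE_MOTIFS
    motif_ids = sorted(motifs)
    ligands: list[MolecularGraph] = []
    membership: dict[str, str] = {}
    for i in range(n):
        base = motifs[motif_ids[int(rng.integers(len(motif_ids)))]]
        atoms = list(base.atoms)
        bonds = list(base.bonds)
        additions = 0
        for anchor in range(len(base.atoms)):
            if additions >= 3:
                break
            if rng.random() < decoration_rate:
                atoms.append(str(rng.choice(_DECORATIONS)))
                bonds.append((anchor, len(atoms) - 1))
                additions += 1
        lig_id = f"lig{i:03d}"
        ligands.append(MolecularGraph(component_id=lig_id, atoms=tuple(atoms), bonds=tuple(bonds)))
        membership[lig_id] = base.component_id
    return ligands, membership


# ---------------------------------------------------------------------------
# Synthetic peptide–ligand complexes

_BACKBONE_SPACING = 3.8  # Å between consecutive pseudo-residues
_CONTACT_HEIGHT = 3.4    # Å: < 3.5 to the site, > 5.0 to its neighbours


def gen_synthetic_complex(
    seq_len: int, site_positions: set[int], seed: int = 0
) -> tuple[list[tuple[int, np.ndarray]], np.ndarray]:
    """Linear pseudo-atom peptide plus ligand atoms planted at site residues.

    One pseudo-atom per residue on a straight 3.8 Å-spaced backbone; one
    ligand atom 3.4 Å above each site residue, which puts it within the
    4.0 Å contact cutoff of that residue and beyond 5 Å of every other
    (sqrt(3.8² + 3.4²) ≈ 5.10).  The tiny jitter keeps coordinates unique
    without eroding that margin.
    """
    bad = [p for p in site_positions if not 1 <= p <= seq_len]
    if bad:
        raise ValueError(f"site positions {bad} outside 1..{seq_len}")
    rng = _spawn(seed, 4)
    residue_atoms = [
        (i + 1, np.array([[i * _BACKBONE_SPACING, 0.0, 0.0]])) for i in range(seq_len)
    ]
    ligand = np.array(
        [
            [(p - 1) * _BACKBONE_SPACING + rng.uniform(-0.01, 0.01), _CONTACT_HEIGHT, 0.0]
            for p in sorted(site_positions)
        ]
    ).reshape(-1, 3)
    return residue_atoms, ligand


# ---------------------------------------------------------------------------
# End-to-end planted-site dataset


def gen_planted_site_dataset(
    rules: PlantedSiteRule | list[PlantedSiteRule],
    families: FamilySpec | list[FamilySpec],
    n: int,
    seed: int,
) -> list[InteractionRecord]:
    """Interaction records whose sites follow a planted residue-context rule.

    *rules* and *families* are matched element-wise (a single rule is
    broadcast); *n* records are generated, balanced across families.
    Sequences with no rule match are redrawn (up to a retry cap), so every
    record has at least one site; a family whose rule can never match its
    alphabet raises.
    """
    family_list = families if isinstance(families, list) else [families]
    rule_list = rules if isinstance(rules, list) else [rules] * len(family_list)
    if len(rule_list) != len(family_list):
        raise ValueError("need one site rule per family")
    records: list[InteractionRecord] = []
    per_family = [n // len(family_list)] * len(family_list)
    for i in range(n % len(family_list)):
        per_family[i] += 1
    for f, (family, rule) in enumerate(zip(family_list, rule_list)):
        made = 0
        attempt = 0
        while made < per_family[f]:
            attempt += 1
            if attempt > 50 * per_family[f]:
                raise ValueError(
                    f"site rule for family {family.family_id!r} matched nothing "
                    f"after {attempt} draws"
                )
            (seq,) = gen_idr_sequences(family, 1, seed=int(_spawn(seed, 5, f, attempt).integers(2**31)))
            sites = rule.sites(seq.residues)
            if not sites:
                continue
            segment = IdrSegment(
                parent_id=f"{family.family_id}_r{made}",
                start=1,
                end=len(seq.residues),
                residues=seq.residues,
                mean_disorder_score=0.95,
            )
            records.append(
                InteractionRecord(
                    segment=segment,
                    site_positions=frozenset(sites),
                    protogroup_ids=frozenset({rule.protogroup_index}),
                )
            )
            made += 1
    return records
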