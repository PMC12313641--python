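"""Training- and validation-set construction from disorder tracks and structures.

The pipeline classifies a region as disordered when at least 30 consecutive
residues have a disorder score above 0.9, chops ligand-bearing chains into
segments whose lengths mimic the disordered-segment length distribution,
labels residues with any atom within 4.0 Å of a ligand atom as interacting
sites, and assembles training sets biased toward high mean disorder plus a
low-disorder (0.0–0.3) negative set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence as TypingSequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

IDR_SCORE_THRESHOLD = 0.9
IDR_MIN_LENGTH = 30
CONTACT_CUTOFF = 4.0
TRAIN_KEEP_ABOVE = 0.5
NEGATIVE_SCORE_RANGE = (0.0, 0.3)


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue disorder scores for one sequence (1-based, contiguous)."""

    sequence_id: str
    residues: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.float64)
        if len(scores) != len(self.residues):
            raise ValueError("residues and scores lengths differ")
        if ((scores < 0) | (scores > 1)).any():
            raise ValueError("disorder scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IdrSegment:
    """A contiguous subsequence [start, end] (1-based, inclusive) of a parent chain."""

    parent_id: str
    start: int
    end: int
    residues: str
    mean_disorder_score: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.residues):
            raise ValueError(
                f"segment span {self.start}-{self.end} does not match "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def segment_id(self) -> str:
        return f"{self.parent_id}/{self.start}-{self.end}"


@dataclass(frozen=True)
class InteractionRecord:
    """A segment plus its ligand-interaction annotation.

    ``site_positions`` are 1-based indices local to the segment;
    ``protogroup_ids`` index the substructure vocabulary.
    """

    segment: IdrSegment
    site_positions: frozenset[int] = frozenset()
    protogroup_ids: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_positions", frozenset(self.site_positions))
        object.__setattr__(self, "protogroup_ids", frozenset(self.protogroup_ids))
        n = len(self.segment)
        bad = [p for p in self.site_positions if not 1 <= p <= n]
        if bad:
            raise ValueError(f"site positions {bad} outside segment of length {n}")
        if self.site_positions and not self.protogroup_ids:
            raise ValueError("records with sites must name at least one protogroup")


def read_score_track(path: str | Path, sequence_id: str | None = None) -> ScoreTrack:
    """Parse a disorder-track TSV (``# comments``; columns POS, RES, SCORE)."""
    path = Path(path)
    rows = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["pos", "res", "score"], usecols=[0, 1, 2],
    )
    positions = rows["pos"].to_numpy()
    if len(positions) == 0:
        raise ValueError(f"no score rows in {path}")
    if not (positions == np.arange(1, len(positions) + 1)).all():
        raise ValueError(f"positions in {path} are not contiguous from 1")
    return ScoreTrack(
        sequence_id=sequence_id or path.stem,
        residues="".join(rows["res"].astype(str)),
        scores=rows["score"].to_numpy(dtype=float),
    )


def extract_idr_segments(
    track: ScoreTrack,
    threshold: float = IDR_SCORE_THRESHOLD,
    min_len: int = IDR_MIN_LENGTH,
) -> list[IdrSegment]:
    """Maximal runs of score > threshold with length >= min_len, in order."""
    segments: list[IdrSegment] = []
    above = track.scores > threshold
    i = 0
    n = len(track)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= min_len:
            segments.append(
                IdrSegment(
                    parent_id=track.sequence_id,
                    start=i + 1,
                    end=j,
                    residues=track.residues[i:j],
                    mean_disorder_score=float(track.scores[i:j].mean()),
                )
            )
        i = j
    return segments


def segment_chain(
    parent_id: str,
    residues: str,
    length_sampler: Callable[[np.random.Generator], int],
    rng_seed: int,
    scores: np.ndarray | None = None,
) -> list[IdrSegment]:
    """Split a chain into contiguous segments with sampled lengths.

    Lengths are drawn from *length_sampler* (a callable receiving the
    seeded generator and returning a positive int); the final segment is
    truncated at the chain end.  When per-residue *scores* are supplied
    each segment carries its mean score, else 0.
    """
    rng = np.random.default_rng(rng_seed)
    out: list[IdrSegment] = []
    pos = 0
    n = len(residues)
    while pos < n:
        length = int(length_sampler(rng))
        if length < 1:
            raise ValueError("length sampler must yield positive integers")
        end = min(pos + length, n)
        mean_score = float(np.mean(scores[pos:end])) if scores is not None else 0.0
        out.append(
            IdrSegment(
                parent_id=parent_id,
                start=pos + 1,
                end=end,
                residues=residues[pos:end],
                mean_disorder_score=mean_score,
            )
        )
        pos = end
    return out


def extract_contacts(
    residue_atoms: TypingSequence[tuple[int, np.ndarray]],
    ligand_atoms: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
) -> set[int]:
    """Residue positions with any atom within *cutoff* Å of any ligand atom.

    *residue_atoms* maps each residue position to an (n_atoms, 3) coordinate
    array; residues with no coordinates are skipped with a warning.  The
    cutoff is inclusive.
    """
    ligand_atoms = np.asarray(ligand_atoms, dtype=np.float64).reshape(-1, 3)
    contacts: set[int] = set()
    for position, coords in residue_atoms:
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if coords.size == 0:
            logger.warning("residue %d has no coordinates; skipped", position)
            continue
        d2 = ((coords[:, None, :] - ligand_atoms[None, :, :]) ** 2).sum(axis=2)
        if (d2 <= cutoff * cutoff).any():
            contacts.add(position)
    return contacts


def contact_pairs(
    residue_atoms: TypingSequence[tuple[int, np.ndarray]],
    ligand_atoms: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
) -> dict[int, set[int]]:
    """Map residue position -> indices of ligand atoms within the cutoff."""
    ligand_atoms = np.asarray(ligand_atoms, dtype=np.float64).reshape(-1, 3)
    pairs: dict[int, set[int]] = {}
    for position, coords in residue_atoms:
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        if coords.size == 0:
            continue
        d2 = ((coords[:, None, :] - ligand_atoms[None, :, :]) ** 2).sum(axis=2)
        hit = np.nonzero((d2 <= cutoff * cutoff).any(axis=0))[0]
        if hit.size:
            pairs[position] = set(int(a) for a in hit)
    return pairs


def load_structure_atoms(
    path: str | Path, ligand_resnames: set[str]
) -> tuple[list[tuple[int, np.ndarray]], np.ndarray]:
    """Read a PDB/mmCIF file into (residue_atoms, ligand_atom_coords).

    Polymer residues are keyed by their sequence number; every residue whose
    name is in *ligand_resnames* contributes its atoms to the ligand pool.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    residue_atoms: list[tuple[int, np.ndarray]] = []
    ligand_coords: list[list[float]] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            coords = [[a.pos.x, a.pos.y, a.pos.z] for a in residue]
            if residue.name in ligand_resnames:
                ligand_coords.extend(coords)
            else:
                residue_atoms.append((residue.seqid.num, np.array(coords)))
    return residue_atoms, np.array(ligand_coords).reshape(-1, 3)


def default_acceptance_probability(score: float, keep_above: float = TRAIN_KEEP_ABOVE) -> float:
    """Decreasing acceptance curve for sub-threshold segments: (s / 0.5)^2."""
    return float(min(score, keep_above) / keep_above) ** 2


def select_training_segments(
    segments: Iterable[IdrSegment],
    keep_above: float = TRAIN_KEEP_ABOVE,
    prob_fn: Callable[[float], float] | None = None,
    rng_seed: int = 0,
) -> list[IdrSegment]:
    """High-disorder training selection.

    Segments with mean disorder score > *keep_above* are always kept;
    the rest are kept with probability ``prob_fn(score)`` (default the
    quadratic curve), drawn from a generator seeded with *rng_seed*.
    """
    if prob_fn is None:
        prob_fn = default_acceptance_probability
    rng = np.random.default_rng(rng_seed)
    kept: list[IdrSegment] = []
    for seg in segments:
        score = seg.mean_disorder_score
        if score > keep_above:
            kept.append(seg)
            continue
        p = float(prob_fn(score))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"acceptance probability {p} outside [0, 1] for score {score}")
        if rng.random() < p:
            kept.append(seg)
    return kept


def build_negative_set(
    segments: TypingSequence[IdrSegment],
    n: int,
    score_range: tuple[float, float] = NEGATIVE_SCORE_RANGE,
    rng_seed: int = 0,
) -> list[IdrSegment]:
    """Uniform sample of low-disorder segments (mean score within *score_range*)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    lo, hi = score_range
    eligible = [s for s in segments if lo <= s.mean_disorder_score <= hi]
    if n >= len(eligible):
        if n > len(eligible):
            warnings.warn(
                f"requested {n} negatives but only {len(eligible)} eligible segments",
                stacklevel=2,
            )
        return list(eligible)
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# Manifest I/O


def write_manifest(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Dataset manifest TSV: one row per record."""
    rows = []
    for rec in records:
        seg = rec.segment
        rows.append(
            {
                "segment_id": seg.segment_id,
                "parent_id": seg.parent_id,
                "start": seg.start,
                "end": seg.end,
                "mean_score": f"{seg.mean_disorder_score:.6f}",
                "residues": seg.residues,
                "sites": ",".join(str(p) for p in sorted(rec.site_positions)),
                "protogroups": ",".join(str(g) for g in sorted(rec.protogroup_ids)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sites": str, "protogroups": str}, keep_default_na=False)
    records = []
    for row in df.itertuples():
        seg = IdrSegment(
            parent_id=row.parent_id,
            start=int(row.start),
            end=int(row.end),
            residues=row.residues,
            mean_disorder_score=float(row.mean_score),
        )
        sites = frozenset(int(p) for p in str(row.sites).split(",") if p)
        groups = frozenset(int(g) for g in str(row.protogroups).split(",") if g)
        records.append(InteractionRecord(segment=seg, site_positions=sites, protogroup_ids=groups))
    return records
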