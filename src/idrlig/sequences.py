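"""Pair-separation featurization of protein sequences.

A sequence of length L is represented by a 20 x 20 x 20 tensor
``f(a_i, a_j, k)`` of amino-acid pair frequencies: for every ordered pair
of positions i < j with separation k = j - i <= 19, the count at
(a_i, a_j, k) is incremented, and layer k = 0 holds one count per residue
(a diagonal amino-acid frequency matrix).  Counts are normalized by their
global sum, the k = 0 layer is attenuated by a factor 20, and the tensor
is smoothed along the separation axis with 1/4^|k-l| weights over a
seven-layer window.

The inverse direction maps a (decoded) tensor back onto a sequence: the
per-residue interaction score s_i sums every tensor cell in which residue
i can participate, and sn_i = s_i / max_l s_l rescales to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Canonical ordering of the 20 standard amino acids along tensor axes.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Number of separation layers; k = 0..MAX_SEP.
MAX_SEP = 19
TENSOR_SHAPE = (20, 20, 20)

#: Attenuation divisor for the k = 0 amino-acid frequency layer.
DIAGONAL_ATTENUATION = 20.0

#: Half-width of the smoothing window along the separation axis.
SMOOTH_HALFWIDTH = 3


class SequenceError(ValueError):
    """Raised for sequences that cannot be featurized."""


@dataclass(frozen=True)
class Sequence:
    """A protein sequence with 1-based positional indexing.

    Non-standard residue codes (X, B, Z, U, ...) are retained so that
    positions stay aligned with external annotations, but they contribute
    no tensor counts and receive zero interaction scores.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def standard_mask(self) -> np.ndarray:
        return np.array([r in AA_INDEX for r in self.residues])

    def indices(self) -> np.ndarray:
        """Alphabet index per position; -1 for non-standard codes."""
        return np.array([AA_INDEX.get(r, -1) for r in self.residues])


@dataclass(frozen=True)
class PairTensor:
    """20 x 20 x 20 pair-separation tensor with processing-state flags."""

    values: np.ndarray
    normalized: bool = False
    smoothed: bool = False
    id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != TENSOR_SHAPE:
            raise ValueError(f"pair tensor must be {TENSOR_SHAPE}, got {values.shape}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ResidueScores:
    """Per-residue interaction-site scores s_i and normalized sn_i."""

    raw: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=np.float64))
        if self.normalized is not None:
            norm = np.asarray(self.normalized, dtype=np.float64)
            if norm.shape != self.raw.shape:
                raise ValueError("raw and normalized score lengths differ")
            object.__setattr__(self, "normalized", norm)


def encode_pair_tensor(seq: Sequence, site_positions: set[int] | None = None,
                       site_mode: str = "either") -> PairTensor:
    """Build the normalized, attenuated (not yet smoothed) pair tensor.

    Parameters
    ----------
    seq
        Input sequence; must contain at least one standard residue.
    site_positions
        Optional set of 1-based positions.  When given, only pairs touching
        a site are counted (``site_mode="either"``: at least one member is a
        site; ``"both"``: both members), and k = 0 counts are restricted to
        site residues.  This is how interaction-site target tensors are
        built; ``None`` counts everything.
    site_mode
        "either" or "both"; ignored when *site_positions* is None.

    Returns
    -------
    PairTensor
        Counts normalized by the global sum (including the k = 0 layer),
        then the k = 0 layer divided by 20.
    """
    if site_mode not in ("either", "both"):
        raise ValueError(f"site_mode must be 'either' or 'both', got {site_mode!r}")
    idx = seq.indices()
    length = len(idx)
    if not (idx >= 0).any():
        raise SequenceError(f"sequence {seq.id!r} has no standard residues")
    if site_positions is not None:
        bad = [p for p in site_positions if not 1 <= p <= length]
        if bad:
            raise ValueError(f"site positions {bad} outside sequence of length {length}")
        is_site = np.zeros(length, dtype=bool)
        for p in site_positions:
            is_site[p - 1] = True
    else:
        is_site = np.ones(length, dtype=bool)

    counts = np.zeros(TENSOR_SHAPE, dtype=np.float64)
    # k = 0: one count per (site-)residue position.
    for i in range(length):
        if idx[i] >= 0 and is_site[i]:
            counts[idx[i], idx[i], 0] += 1.0
    # k >= 1: ordered pairs (i < j), separation capped by the tensor depth.
    for i in range(length):
        if idx[i] < 0:
            continue
        for j in range(i + 1, min(i + MAX_SEP, length - 1) + 1):
            if idx[j] < 0:
                continue
            if site_positions is not None:
                if site_mode == "either" and not (is_site[i] or is_site[j]):
                    continue
                if site_mode == "both" and not (is_site[i] and is_site[j]):
                    continue
            counts[idx[i], idx[j], j - i] += 1.0

    total = counts.sum()
    if total > 0:
        counts /= total
    counts[:, :, 0] /= DIAGONAL_ATTENUATION
    return PairTensor(counts, normalized=True, smoothed=False, id=seq.id)


def smoothing_matrix() -> np.ndarray:
    """(20, 20) linear operator S with out = in @ S along the k axis.

    S[l, k] = 1/4^|k-l| for |k-l| <= 3 (window truncated at the axis
    boundaries), else 0.  Smoothing does not renormalize.
    """
    n = MAX_SEP + 1
    mat = np.zeros((n, n))
    for k in range(n):
        for l in range(max(0, k - SMOOTH_HALFWIDTH), min(n - 1, k + SMOOTH_HALFWIDTH) + 1):
            mat[l, k] = 0.25 ** abs(k - l)
    return mat


_SMOOTH = smoothing_matrix()


def smooth_tensor(t: PairTensor) -> PairTensor:
    """Smooth along the separation axis with weights 1/4^|k-l|, l in k±3."""
    if t.smoothed:
        raise ValueError(f"tensor {t.id!r} is already smoothed")
    return replace(t, values=t.values @ _SMOOTH, smoothed=True)


def featurize(seq: Sequence) -> PairTensor:
    """Full input featurization: encode, attenuate, smooth."""
    return smooth_tensor(encode_pair_tensor(seq))


def residue_scores(decoded: PairTensor | np.ndarray, seq: Sequence) -> ResidueScores:
    """Convert a decoded tensor fd into per-residue scores.

    s_i = sum_{l <= i, i-l <= K} fd(a_l, a_i, i-l)
        + sum_{l > i, l-i <= K} fd(a_i, a_l, l-i)

    with K = 19, the deepest separation layer the tensor holds.  The l = i
    self term fd(a_i, a_i, 0) is included exactly once.  Non-standard
    residues contribute and receive nothing.
    """
    fd = decoded.values if isinstance(decoded, PairTensor) else np.asarray(decoded, dtype=np.float64)
    if fd.shape != TENSOR_SHAPE:
        raise ValueError(f"decoded tensor must be {TENSOR_SHAPE}, got {fd.shape}")
    idx = seq.indices()
    length = len(idx)
    if not (idx >= 0).all():
        logger.warning("sequence %r has non-standard residues; they score 0", seq.id)
    s = np.zeros(length)
    for i in range(length):
        ai = idx[i]
        if ai < 0:
            continue
        for l in range(max(0, i - MAX_SEP), i + 1):
            if idx[l] >= 0:
                s[i] += fd[idx[l], ai, i - l]
        for l in range(i + 1, min(length - 1, i + MAX_SEP) + 1):
            if idx[l] >= 0:
                s[i] += fd[ai, idx[l], l - i]
    return ResidueScores(raw=s)


def normalize_scores(r: ResidueScores) -> ResidueScores:
    """sn_i = s_i / max_l s_l; an all-zero (or non-positive) profile maps to zeros."""
    top = r.raw.max(initial=0.0)
    if top <= 0:
        return ResidueScores(raw=r.raw, normalized=np.zeros_like(r.raw))
    return ResidueScores(raw=r.raw, normalized=r.raw / top)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a (multi-record, line-wrapped) FASTA file."""
    records = [
        Sequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def save_tensor(t: PairTensor, path: str | Path) -> None:
    """Write a tensor archive (HDF5: dataset 'tensor' + state attributes)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("tensor", data=t.values)
        ds.attrs["id"] = t.id
        ds.attrs["normalized"] = t.normalized
        ds.attrs["smoothed"] = t.smoothed


def load_tensor(path: str | Path) -> PairTensor:
    with h5py.File(path, "r") as fh:
        ds = fh["tensor"]
        return PairTensor(
            values=ds[()],
            normalized=bool(ds.attrs["normalized"]),
            smoothed=bool(ds.attrs["smoothed"]),
            id=str(ds.attrs["id"]),
        )
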