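"""Shared fixtures: synthetic study conditions and a session-scoped trained
pipeline (steps 1-3 at the reduced profile) reused by training-dependent
tests so the expensive runs happen once."""

from __future__ import annotations

import numpy as np
import pytest

from idrlig.network import (
    NetworkConfig,
    build_network,
    build_site_target,
    make_predictor_examples,
    train_autoencoder,
    train_protogroup_predictor,
    train_site_decoder,
)
from idrlig.network import decoder_forward, encoder_forward
from idrlig.sequences import Sequence, featurize, normalize_scores, residue_scores
from idrlig.synth import (
    FamilySpec,
    PlantedSiteRule,
    gen_idr_sequences,
    gen_planted_site_dataset,
)

PIPELINE_SEED = 7

#: Three compositional families with distinct planted dipeptide motifs and
#: matching site rules (motif family i <-> protogroup i).
FAMILIES = [
    FamilySpec("famA", motif=("Y", "G", 3)),
    FamilySpec("famB", motif=("L", "P", 5)),
    FamilySpec("famC", motif=("R", "E", 2)),
]
RULES = [
    PlantedSiteRule("Y", "G", 3, protogroup_index=1),
    PlantedSiteRule("L", "P", 5, protogroup_index=2),
    PlantedSiteRule("R", "E", 2, protogroup_index=3),
]


def site_scores_for(bundle, seq: Sequence) -> np.ndarray:
    """Decoded per-residue sn scores for one sequence."""
    encoding, _ = encoder_forward(featurize(seq).values[None], bundle)
    fd, _ = decoder_forward(encoding, bundle)
    return normalize_scores(residue_scores(fd.reshape(20, 20, 20), seq)).normalized


def pooled_site_scores(bundle, records) -> tuple[np.ndarray, np.ndarray]:
    """Scores and binary site labels pooled over a record set."""
    scores, labels = [], []
    for rec in records:
        seq = Sequence(rec.segment.parent_id, rec.segment.residues)
        scores.extend(site_scores_for(bundle, seq))
        labels.extend(
            1 if p + 1 in rec.site_positions else 0 for p in range(len(seq))
        )
    return np.asarray(scores), np.asarray(labels)


@pytest.fixture(scope="session")
def study_sequences():
    return [s for fam in FAMILIES for s in gen_idr_sequences(fam, 60, seed=11)]


@pytest.fixture(scope="session")
def study_tensors(study_sequences):
    return [featurize(s) for s in study_sequences]


@pytest.fixture(scope="session")
def site_records():
    return gen_planted_site_dataset(RULES, FAMILIES, 300, seed=1000 + PIPELINE_SEED)


@pytest.fixture(scope="session")
def heldout_records():
    return gen_planted_site_dataset(RULES, FAMILIES, 60, seed=5000 + PIPELINE_SEED)


@pytest.fixture(scope="session")
def trained_pipeline(study_tensors, site_records):
    """Steps 1-3 on the synthetic study conditions, with freeze witnesses.

    Returns a dict holding the final bundle, the three histories, and the
    SHA-256 checksums of each frozen part taken immediately before and
    after the step that froze it.
    """
    cfg = NetworkConfig.reduced(output_classes=3)
    bundle, history1 = train_autoencoder(study_tensors, cfg, rng_seed=PIPELINE_SEED)

    pairs = []
    for rec in site_records:
        seq = Sequence(rec.segment.parent_id, rec.segment.residues)
        pairs.append((featurize(seq), build_site_target(seq, set(rec.site_positions))))
    encoder_before_2 = bundle.checksum("encoder")
    bundle, history2 = train_site_decoder(bundle, pairs, cfg, rng_seed=PIPELINE_SEED)
    encoder_after_2 = bundle.checksum("encoder")

    examples = make_predictor_examples(site_records, vocab_size=3)
    frozen_before_3 = {p: bundle.checksum(p) for p in ("encoder", "decoder")}
    bundle, history3 = train_protogroup_predictor(
        bundle, examples, cfg, rng_seed=PIPELINE_SEED
    )
    frozen_after_3 = {p: bundle.checksum(p) for p in ("encoder", "decoder")}
    return {
        "cfg": cfg,
        "bundle": bundle,
        "history1": history1,
        "history2": history2,
        "history3": history3,
        "encoder_checksums_step2": (encoder_before_2, encoder_after_2),
        "frozen_checksums_step3": (frozen_before_3, frozen_after_3),
    }
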