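"""Shared fixtures: tiny hand-built challenges and independent metric oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import priobench as pb

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def vk(s: str) -> pb.VariantKey:
    return pb.normalize_variant(s)


@pytest.fixture
def two_proband_key() -> pb.AnswerKey:
    """Two solved probands, one causal SNV each."""
    return pb.AnswerKey(
        [
            pb.AnswerKeyEntry("A", True, pb.MatchMode.ALL_OF, frozenset({vk("1:100:A:G")})),
            pb.AnswerKeyEntry("B", True, pb.MatchMode.ALL_OF, frozenset({vk("2:200:C:T")})),
        ]
    )


@pytest.fixture
def worked_example(two_proband_key) -> tuple[pb.ModelSubmission, pb.AnswerKey]:
    """A: causal@0.9 then decoy@0.8; B: decoy@0.7 then causal@0.6."""
    recs = {
        "A": [
            pb.PredictionRecord("A", frozenset({vk("1:100:A:G")}), 0.9, 1),
            pb.PredictionRecord("A", frozenset({vk("3:1:A:C")}), 0.8, 2),
        ],
        "B": [
            pb.PredictionRecord("B", frozenset({vk("4:1:G:T")}), 0.7, 1),
            pb.PredictionRecord("B", frozenset({vk("2:200:C:T")}), 0.6, 2),
        ],
    }
    return pb.ModelSubmission("t", "m", recs), two_proband_key


def random_small_submission(
    rng: np.random.Generator, n_probands: int = 4, max_records: int = 8
) -> tuple[pb.ModelSubmission, pb.AnswerKey]:
    """Random single-variant challenge: each solved proband has one causal SNV
    that the model may or may not list; EPCRs are multiples of 1e-3 so a 1e-4
    grid resolves every step of the F curve."""
    entries, predictions = [], {}
    for p in range(n_probands):
        pid = f"P{p}"
        causal = pb.VariantKey("1", 1000 + p, "A", "G")
        entries.append(
            pb.AnswerKeyEntry(pid, True, pb.MatchMode.ALL_OF, frozenset({causal}))
        )
        n_rec = int(rng.integers(0, max_records + 1))
        include_causal = rng.random() < 0.7
        variants: list[frozenset] = []
        if include_causal and n_rec > 0:
            variants.append(frozenset({causal}))
        while len(variants) < n_rec:
            v = pb.VariantKey("2", int(rng.integers(1, 10_000_000)), "C", "T")
            fs = frozenset({v})
            if fs not in variants:
                variants.append(fs)
        order = rng.permutation(len(variants))
        recs = []
        for rank, j in enumerate(order, start=1):
            epcr = round(float(rng.integers(0, 1001)) / 1000.0, 3)
            recs.append(pb.PredictionRecord(pid, variants[j], epcr, rank))
        if recs:
            predictions[pid] = recs
    return pb.ModelSubmission("t", "m", predictions), pb.AnswerKey(entries)


def brute_force_fmax(sub: pb.ModelSubmission, key: pb.AnswerKey, n_grid: int = 10_000) -> float:
    """Dense-grid F maximum, computed from raw records by direct enumeration.

    Independent of the sweep implementation; valid for single-variant ALL_OF
    answers where at most one record per proband can match.
    """
    best = 0.0
    n_solved = key.n_solved
    for t in np.linspace(0.0, 1.0, n_grid):
        calls = 0
        tp = 0
        for entry in key.solved_entries:
            for rec in sub.records_for(entry.proband_id):
                if rec.epcr >= t:
                    calls += 1
                    if rec.variants == entry.required_set:
                        tp += 1
        if calls == 0:
            continue
        precision = tp / calls
        recall = tp / n_solved
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best
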