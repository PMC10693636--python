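"""Shared fixtures.

The expensive fixture is ``recovery_run``: one desk-scale training on the
restricted-alphabet synthetic benchmark, shared (session-scoped) by the
acceptance tests for held-out accuracy and the peak-retention property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from tcnovo import encoding, evaluation, model, pipeline, simulator, training


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_peptides(rng, n, lengths=(5, 12), alphabet=None):
    from tcnovo import chem
    alphabet = alphabet or chem.RESIDUES
    out = []
    for _ in range(n):
        k = int(rng.integers(lengths[0], lengths[1] + 1))
        out.append("".join(
            alphabet[i] for i in rng.integers(0, len(alphabet), size=k)))
    return out


@dataclass
class RecoveryRun:
    """Artifacts of one desk-scale training on the synthetic benchmark."""

    sim_config: simulator.SimulatorConfig
    enc_config: encoding.EncodingConfig
    net: model.SpectrumTCN
    history: list
    test_spectra: list
    test_peptides: list
    results: list          # SequencingResults on the held-out set
    positional_accuracy: float          # prefix-mass matching convention
    positional_accuracy_by_index: float  # plain index matching
    peptide_accuracy: float


@pytest.fixture(scope="session")
def recovery_run() -> RecoveryRun:
    """Train the scale-0.1 model on 5,000 simulated training spectra
    (8-residue alphabet, lengths 6-10, mild noise) and sequence the
    peptide-disjoint held-out split."""
    scfg = simulator.SimulatorConfig.recovery_benchmark()
    records = simulator.generate_dataset(scfg, 5800, seed=2024)
    peptides = [r.peptide for r in records]
    ecfg = encoding.EncodingConfig.desk_scale()
    data = training.TrainingData.from_records(
        [r.spectrum for r in records], peptides, ecfg)
    tr, va, te = training.split_by_peptide(
        peptides, (5000 / 5800, 300 / 5800, 500 / 5800), seed=2024)
    net = model.build_model(model.ModelConfig.desk_scale(), seed=2024)
    tcfg = training.TrainingConfig.desk_scale(seed=2024)
    result = training.train(net, data.subset(tr), data.subset(va), tcfg)
    test_spectra = [records[i].spectrum for i in te]
    test_peptides = [records[i].peptide for i in te]
    results = pipeline.sequence_spectra(net, test_spectra, ecfg)
    preds = [r.peptide for r in results]
    by_index = sum(
        evaluation.positional_matches(p, t, by_index=True)
        for p, t in zip(preds, test_peptides)
    ) / sum(len(t) for t in test_peptides)
    return RecoveryRun(
        sim_config=scfg, enc_config=ecfg, net=net, history=result.history,
        test_spectra=test_spectra, test_peptides=test_peptides,
        results=results,
        positional_accuracy=evaluation.positional_accuracy(preds, test_peptides),
        positional_accuracy_by_index=by_index,
        peptide_accuracy=evaluation.peptide_accuracy(preds, test_peptides))
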