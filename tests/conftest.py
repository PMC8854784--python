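"""Shared fixtures: toy HMMs and an exhaustive path-enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from anchorscreen.topology_hmm import (
    AA20,
    AA_INDEX,
    GROUP_HELIX,
    GROUP_INSIDE,
    GROUP_OUTSIDE,
    LABEL_IN,
    LABEL_MEM,
    LABEL_OUT,
    TopologyModel,
)


def _emission_row(weights: dict[str, float]) -> np.ndarray:
    row = np.full(len(AA20), 0.01)
    for aa, w in weights.items():
        row[AA_INDEX[aa]] = w
    return row / row.sum()


@pytest.fixture(scope="session")
def toy3_model() -> TopologyModel:
    """A 3-state inside/membrane/outside toy obeying the loop-helix grammar.

    Probabilities are deliberately irregular so no two path scores tie.
    """
    T = np.array([
        [0.61, 0.39, 0.00],
        [0.23, 0.44, 0.33],
        [0.00, 0.27, 0.73],
    ])
    E = np.stack([
        _emission_row({"K": 5.0, "D": 2.0, "A": 1.0}),
        _emission_row({"L": 6.0, "A": 3.0}),
        _emission_row({"D": 4.0, "A": 2.0, "S": 1.5}),
    ])
    model = TopologyModel(
        states=["in", "mem", "out"],
        labels=[LABEL_IN, LABEL_MEM, LABEL_OUT],
        groups=[GROUP_INSIDE, GROUP_HELIX, GROUP_OUTSIDE],
        transitions=T,
        emissions=E,
        initial=np.array([0.58, 0.0, 0.42]),
        helix_min_len=5,
        helix_max_len=25,
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def toy2_model() -> TopologyModel:
    """A 2-state inside/membrane toy for closed-form checks."""
    T = np.array([[0.7, 0.3], [0.4, 0.6]])
    E = np.stack([
        _emission_row({"K": 4.0, "A": 1.0}),
        _emission_row({"L": 4.0, "A": 1.0}),
    ])
    model = TopologyModel(
        states=["in", "mem"],
        labels=[LABEL_IN, LABEL_MEM],
        groups=[GROUP_INSIDE, GROUP_HELIX],
        transitions=T,
        emissions=E,
        initial=np.array([0.65, 0.35]),
        helix_min_len=5,
        helix_max_len=25,
    )
    model.validate()
    return model


def enumerate_paths(model: TopologyModel, sequence: str):
    """Brute-force path enumeration, independent of the recursions.

    Returns (total probability, per-residue label posteriors dict,
    best path state indices).
    """
    L = len(sequence)
    S = model.n_states
    cols = [model.emission_column(c) for c in sequence]
    total = 0.0
    label_mass = {lab: np.zeros(L) for lab in (LABEL_IN, LABEL_MEM, LABEL_OUT)}
    best_p, best_path = -1.0, None
    for path in itertools.product(range(S), repeat=L):
        p = model.initial[path[0]] * cols[0][path[0]]
        for t in range(1, L):
            p *= model.transitions[path[t - 1], path[t]] * cols[t][path[t]]
        total += p
        for t, s in enumerate(path):
            label_mass[model.labels[s]][t] += p
        if p > best_p:
            best_p, best_path = p, path
    posteriors = {lab: mass / total for lab, mass in label_mass.items()}
    return total, posteriors, best_path


def segments_to_labels(segments, length: int) -> list[str]:
    labels = [None] * length
    for lab, start, end in segments:
        for i in range(start - 1, end):
            labels[i] = lab
    return labels
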