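"""Membrane-topology prediction with a compact cyclic hidden Markov model.

The model follows the classic grammar of transmembrane-topology HMMs:
cytoplasmic (inside) loops and extracytoplasmic (outside) loops are
connected exclusively through membrane-helix state chains, so the decoded
path can never jump across the membrane without passing through a helix.
Helix length is enforced structurally — 15 mandatory core states followed
by up to 10 optional ones — rather than by explicit duration modelling.
Two residues of "cap" states flank each helix chain on either side; for
reporting, caps are folded into the membrane label.

Emissions are tied by state group (inside loop, cap, helix core, outside
loop, outside globular).  Helix emissions follow a hydropathy-derived
membrane propensity (background-weighted exponential transform); inside
loops up-weight lysine and arginine, implementing the positive-inside
rule, which is what lets the decoder orient a protein whose N-terminal
flank is basic.

All posterior computation uses per-position rescaling (no underflow for
arbitrarily long sequences); Viterbi decoding runs in log space with ties
broken by fixed state index order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# Amino-acid alphabet and shared composition/propensity tables
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}
#: ambiguity / rare codes accepted in input; they emit the background
#: average (i.e. they carry no topology information)
EXTENDED_AA = "XBZU"
ALLOWED_AA = set(AA20) | set(EXTENDED_AA)

#: Kyte–Doolittle hydropathy (used by the export-signal heuristics too)
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

#: membrane-helix propensity: Kyte–Doolittle with the interfacial
#: aromatics (W, Y) shifted up, reflecting their enrichment in helices
MEMBRANE_PROPENSITY = dict(KYTE_DOOLITTLE, W=1.9, Y=0.5)

#: approximate average bacterial cytoplasmic amino-acid frequencies;
#: the synthetic generator draws background residues from this table
CYTOPLASMIC_COMPOSITION = {
    "A": 0.089, "R": 0.055, "N": 0.040, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.022, "I": 0.059,
    "L": 0.099, "K": 0.064, "M": 0.028, "F": 0.038, "P": 0.042,
    "S": 0.057, "T": 0.054, "W": 0.011, "Y": 0.030, "V": 0.072,
}

LABEL_IN = "inside"
LABEL_MEM = "membrane"
LABEL_OUT = "outside"

GROUP_INSIDE = "inside-loop"
GROUP_CAP = "cap"
GROUP_HELIX = "helix"
GROUP_OUTSIDE = "outside-loop"
GROUP_GLOBULAR = "outside-globular"

GROUPS = (GROUP_INSIDE, GROUP_CAP, GROUP_HELIX, GROUP_OUTSIDE, GROUP_GLOBULAR)

_GROUP_LABEL = {
    GROUP_INSIDE: LABEL_IN,
    GROUP_CAP: LABEL_MEM,
    GROUP_HELIX: LABEL_MEM,
    GROUP_OUTSIDE: LABEL_OUT,
    GROUP_GLOBULAR: LABEL_OUT,
}


def _normalized(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    total = vec.sum()
    if total <= 0:
        raise ValueError("cannot normalize a non-positive vector")
    return vec / total


def composition_vector(table: dict[str, float]) -> np.ndarray:
    """Return a composition table as a normalized vector in AA20 order."""
    return _normalized(np.array([table[a] for a in AA20]))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


class TopologyError(ValueError):
    """Raised for invalid model structure or decoding arguments."""


@dataclass
class TopologyModel:
    """A cyclic topology HMM.

    states        -- state names (fixed order; Viterbi ties resolve to the
                     lowest index)
    labels        -- coarse per-state label: inside / membrane / outside
    groups        -- per-state emission-tying group (see GROUPS)
    transitions   -- (S, S) row-stochastic matrix
    emissions     -- (S, 20) per-state emission probabilities over AA20
    initial       -- (S,) distribution over states for residue 1
    """

    states: list[str]
    labels: list[str]
    groups: list[str]
    transitions: np.ndarray
    emissions: np.ndarray
    initial: np.ndarray
    helix_min_len: int = 15
    helix_max_len: int = 25

    @property
    def n_states(self) -> int:
        return len(self.states)

    def validate(self, atol: float = 1e-9) -> None:
        """Check stochasticity and the inside/outside grammar."""
        if self.helix_min_len < 5:
            raise TopologyError("helix_min_len must be >= 5")
        if self.helix_max_len < self.helix_min_len:
            raise TopologyError("helix_max_len must be >= helix_min_len")
        S = self.n_states
        if self.transitions.shape != (S, S):
            raise TopologyError("transition matrix shape mismatch")
        if self.emissions.shape != (S, len(AA20)):
            raise TopologyError("emission matrix shape mismatch")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=atol):
            raise TopologyError("transition rows must sum to 1")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=atol):
            raise TopologyError("emission rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=atol):
            raise TopologyError("initial distribution must sum to 1")
        # grammar: no inside<->outside transition that bypasses a membrane state
        for i in range(S):
            for j in range(S):
                if self.transitions[i, j] <= 0:
                    continue
                a, b = self.labels[i], self.labels[j]
                if {a, b} == {LABEL_IN, LABEL_OUT}:
                    raise TopologyError(
                        f"illegal direct {a}->{b} transition "
                        f"({self.states[i]} -> {self.states[j]})"
                    )

    # -- symbol handling ----------------------------------------------------

    def emission_column(self, residue: str) -> np.ndarray:
        """Per-state emission likelihood of one residue.

        X/B/Z/U emit the state's background average (the row mean), i.e.
        they are uninformative about topology.
        """
        idx = AA_INDEX.get(residue)
        if idx is not None:
            return self.emissions[:, idx]
        if residue in ALLOWED_AA:
            return self.emissions.mean(axis=1)
        raise TopologyError(f"unknown residue {residue!r}")

    def emission_matrix_for(self, sequence: str) -> np.ndarray:
        """(L, S) emission likelihoods for a whole sequence."""
        return np.stack([self.emission_column(c) for c in sequence])

    def label_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == label])


@dataclass
class ResiduePosterior:
    """Per-residue posterior probability of the three topology labels."""

    p_in: np.ndarray
    p_mem: np.ndarray
    p_out: np.ndarray

    def __len__(self) -> int:
        return len(self.p_in)


@dataclass
class TopologySummary:
    """Window statistics consumed by the anchor-screening rubric.

    prob_n_in         -- posterior probability that residue 1 is inside
    out_first_w       -- mean p_out over residues 1..window
    out_last_w        -- mean p_out over the last `window` residues
    n_helices         -- membrane segments on the best path
    segments          -- (label, start, end) 1-based inclusive, tiling 1..L
    n_helix_mem_mass  -- mean membrane posterior over the first helix
                         segment when that segment overlaps residues 1..40,
                         else 0 (the "retention" evidence used for the
                         N-anchored possibility score)
    """

    n_helices: int
    prob_n_in: float
    out_first_w: float
    out_last_w: float
    window: int
    segments: list[tuple[str, int, int]]
    n_helix_mem_mass: float = 0.0


# ---------------------------------------------------------------------------
# Default model
# ---------------------------------------------------------------------------

HELIX_BETA = 0.5           # steepness of the hydropathy->emission transform
INSIDE_KR_BOOST = 3.5      # positive-inside up-weighting of K and R
LOOP_UNIFORM_MIX = 0.15    # uniform-leaning mixing weight for loop states
CAP_HELIX_MIX = 0.25       # helix fraction in cap emissions (caps tolerate
                           # basic residues snorkeling at the interface)


def _group_emissions() -> dict[str, np.ndarray]:
    bg = composition_vector(CYTOPLASMIC_COMPOSITION)
    uniform = np.full(len(AA20), 1.0 / len(AA20))
    loop_bg = (1 - LOOP_UNIFORM_MIX) * bg + LOOP_UNIFORM_MIX * uniform

    prop = np.array([MEMBRANE_PROPENSITY[a] for a in AA20])
    helix = _normalized(loop_bg * np.exp(HELIX_BETA * prop))

    inside = loop_bg.copy()
    for aa in "KR":
        inside[AA_INDEX[aa]] *= INSIDE_KR_BOOST
    inside = _normalized(inside)

    outside = loop_bg.copy()
    globular = _normalized(0.6 * loop_bg + 0.4 * uniform)
    cap = _normalized(CAP_HELIX_MIX * helix + (1 - CAP_HELIX_MIX) * loop_bg)
    return {
        GROUP_INSIDE: inside,
        GROUP_CAP: cap,
        GROUP_HELIX: helix,
        GROUP_OUTSIDE: outside,
        GROUP_GLOBULAR: globular,
    }


#: probability of leaving a loop into a helix entry cap per residue
P_CROSS_IN = 0.04
P_CROSS_OUT = 0.04
#: per-residue probability of visiting the outside-globular state
P_GLOBULAR = 0.01
P_GLOBULAR_EXIT = 0.03
#: initial probability that residue 1 is cytoplasmic (proteins are born
#: in the cytoplasm, so an inside start is a priori more likely)
P_INIT_IN = 0.7


def build_model(
    group_emissions: dict[str, np.ndarray] | None = None,
    helix_min_len: int = 15,
    helix_max_len: int = 25,
    p_cross_in: float = P_CROSS_IN,
    p_cross_out: float = P_CROSS_OUT,
    p_init_in: float = P_INIT_IN,
) -> TopologyModel:
    """Assemble the cyclic topology model from group emission rows.

    Two helix chains are laid out, one per crossing direction
    (inside->outside and outside->inside), each with two entry caps and
    two exit caps.
    """
    if group_emissions is None:
        group_emissions = _group_emissions()
    n_core = helix_max_len
    n_opt = helix_max_len - helix_min_len

    states: list[str] = []
    groups: list[str] = []

    def add(name: str, group: str) -> int:
        states.append(name)
        groups.append(group)
        return len(states) - 1

    s_in = add("in", GROUP_INSIDE)
    s_out = add("out", GROUP_OUTSIDE)
    s_glob = add("out-glob", GROUP_GLOBULAR)

    def helix_chain(tag: str) -> tuple[list[int], list[int], list[int]]:
        caps_entry = [add(f"cap-{tag}-e{k}", GROUP_CAP) for k in (1, 2)]
        core = [add(f"helix-{tag}-{k}", GROUP_HELIX) for k in range(1, n_core + 1)]
        caps_exit = [add(f"cap-{tag}-x{k}", GROUP_CAP) for k in (1, 2)]
        return caps_entry, core, caps_exit

    io_entry, io_core, io_exit = helix_chain("io")
    oi_entry, oi_core, oi_exit = helix_chain("oi")

    S = len(states)
    T = np.zeros((S, S))

    # loops
    T[s_in, s_in] = 1.0 - p_cross_in
    T[s_in, io_entry[0]] = p_cross_in
    T[s_out, s_out] = 1.0 - P_GLOBULAR - p_cross_out
    T[s_out, s_glob] = P_GLOBULAR
    T[s_out, oi_entry[0]] = p_cross_out
    T[s_glob, s_glob] = 1.0 - P_GLOBULAR_EXIT
    T[s_glob, s_out] = P_GLOBULAR_EXIT

    def wire_chain(entry, core, exit_, dest):
        T[entry[0], entry[1]] = 1.0
        T[entry[1], core[0]] = 1.0
        for k in range(n_core - 1):
            if k + 1 < helix_min_len:
                T[core[k], core[k + 1]] = 1.0          # mandatory run
            else:
                T[core[k], core[k + 1]] = 0.5          # optional extension
                T[core[k], exit_[0]] = 0.5
        T[core[-1], exit_[0]] = 1.0
        T[exit_[0], exit_[1]] = 1.0
        T[exit_[1], dest] = 1.0

    wire_chain(io_entry, io_core, io_exit, s_out)
    wire_chain(oi_entry, oi_core, oi_exit, s_in)

    if n_opt == 0:  # no optional states: last mandatory core exits with prob 1
        pass

    emis = np.stack([group_emissions[g] for g in groups])
    labels = [_GROUP_LABEL[g] for g in groups]
    initial = np.zeros(S)
    initial[s_in] = p_init_in
    initial[s_out] = 1.0 - p_init_in

    model = TopologyModel(
        states=states,
        labels=labels,
        groups=groups,
        transitions=T,
        emissions=emis,
        initial=initial,
        helix_min_len=helix_min_len,
        helix_max_len=helix_max_len,
    )
    model.validate()
    return model


_DEFAULT_MODEL: TopologyModel | None = None


def default_model() -> TopologyModel:
    """The shipped hydropathy-derived topology model (cached)."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = build_model()
    return _DEFAULT_MODEL


# ---------------------------------------------------------------------------
# Forward / backward / posterior / Viterbi
# ---------------------------------------------------------------------------


def _forward_scaled(model: TopologyModel, emis: np.ndarray):
    """Scaled forward pass.  Returns (alpha, scales); log L = sum(log scales)."""
    L = emis.shape[0]
    alpha = np.zeros_like(emis)
    scales = np.zeros(L)
    a = model.initial * emis[0]
    scales[0] = a.sum()
    if scales[0] <= 0:
        raise TopologyError("sequence has zero probability under the model")
    alpha[0] = a / scales[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ model.transitions) * emis[t]
        scales[t] = a.sum()
        if scales[t] <= 0:
            raise TopologyError("sequence has zero probability under the model")
        alpha[t] = a / scales[t]
    return alpha, scales


def _backward_scaled(model: TopologyModel, emis: np.ndarray, scales: np.ndarray):
    L = emis.shape[0]
    beta = np.zeros_like(emis)
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (model.transitions @ (emis[t + 1] * beta[t + 1])) / scales[t + 1]
    return beta


def sequence_likelihood(model: TopologyModel, sequence: str) -> float:
    """Log probability of the sequence under the model (forward algorithm)."""
    if not sequence:
        raise TopologyError("empty sequence")
    emis = model.emission_matrix_for(sequence)
    _, scales = _forward_scaled(model, emis)
    return float(np.log(scales).sum())


def sequence_likelihood_backward(model: TopologyModel, sequence: str) -> float:
    """Log probability computed from the backward recursion (cross-check)."""
    if not sequence:
        raise TopologyError("empty sequence")
    emis = model.emission_matrix_for(sequence)
    L = emis.shape[0]
    # unscaled backward in log space via iterative rescaling
    beta = np.ones(model.n_states)
    log_c = 0.0
    for t in range(L - 1, 0, -1):
        beta = model.transitions @ (emis[t] * beta)
        s = beta.sum()
        beta /= s
        log_c += math.log(s)
    total = float(model.initial @ (emis[0] * beta))
    return math.log(total) + log_c


def posterior_decode(model: TopologyModel, sequence: str) -> ResiduePosterior:
    """Forward–backward posteriors aggregated to inside/membrane/outside."""
    if not sequence:
        raise TopologyError("empty sequence")
    emis = model.emission_matrix_for(sequence)
    alpha, scales = _forward_scaled(model, emis)
    beta = _backward_scaled(model, emis, scales)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    out = {}
    for label in (LABEL_IN, LABEL_MEM, LABEL_OUT):
        idx = model.label_indices(label)
        out[label] = gamma[:, idx].sum(axis=1) if len(idx) else np.zeros(len(sequence))
    return ResiduePosterior(out[LABEL_IN], out[LABEL_MEM], out[LABEL_OUT])


def viterbi_topology(model: TopologyModel, sequence: str) -> list[tuple[str, int, int]]:
    """Best-path segments as (label, start, end), 1-based inclusive."""
    if not sequence:
        raise TopologyError("empty sequence")
    emis = model.emission_matrix_for(sequence)
    with np.errstate(divide="ignore"):
        log_t = np.log(model.transitions)
        log_e = np.log(np.maximum(emis, 1e-300))
        log_init = np.log(np.maximum(model.initial, 1e-300))
    L, S = emis.shape
    delta = log_init + log_e[0]
    back = np.zeros((L, S), dtype=np.int32)
    for t in range(1, L):
        cand = delta[:, None] + log_t
        back[t] = np.argmax(cand, axis=0)  # first index wins ties
        delta = cand[back[t], np.arange(S)] + log_e[t]
    path = np.zeros(L, dtype=np.int32)
    path[-1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    labels = [model.labels[s] for s in path]
    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, L + 1):
        if i == L or labels[i] != labels[start]:
            segments.append((labels[start], start + 1, i))
            start = i
    return segments


def summarize_topology(
    posterior: ResiduePosterior,
    segments: list[tuple[str, int, int]],
    window: int = 20,
    agg: str = "mean",
    n_anchor_span: int = 40,
) -> TopologySummary:
    """Derive the window statistics the screening rubric consumes.

    `agg` selects the window aggregate (arithmetic mean by default; "max"
    is available).  For sequences shorter than `window` the statistic is
    computed over all residues.
    """
    if window < 1:
        raise TopologyError("window must be >= 1")
    if agg not in ("mean", "max"):
        raise TopologyError("agg must be 'mean' or 'max'")
    L = len(posterior)
    w = min(window, L)
    fn = np.mean if agg == "mean" else np.max
    out_first = float(fn(posterior.p_out[:w]))
    out_last = float(fn(posterior.p_out[-w:]))
    helices = [s for s in segments if s[0] == LABEL_MEM]
    mem_mass = 0.0
    if helices:
        lbl, start, end = helices[0]
        if start <= n_anchor_span:
            mem_mass = float(np.mean(posterior.p_mem[start - 1:end]))
    return TopologySummary(
        n_helices=len(helices),
        prob_n_in=float(posterior.p_in[0]),
        out_first_w=out_first,
        out_last_w=out_last,
        window=window,
        segments=list(segments),
        n_helix_mem_mass=mem_mass,
    )


def predict_topology(
    model: TopologyModel, sequence: str, window: int = 20, agg: str = "mean"
) -> tuple[ResiduePosterior, TopologySummary]:
    """Posterior decoding + Viterbi segmentation + window summary."""
    post = posterior_decode(model, sequence)
    segs = viterbi_topology(model, sequence)
    return post, summarize_topology(post, segs, window=window, agg=agg)


# ---------------------------------------------------------------------------
# Sampling and supervised re-estimation
# ---------------------------------------------------------------------------


def sample_sequence(
    model: TopologyModel, length: int, rng: np.random.Generator
) -> tuple[str, list[str]]:
    """Draw (sequence, per-residue group labels) from the model."""
    if length < 1:
        raise TopologyError("length must be >= 1")
    seq = []
    groups = []
    state = int(rng.choice(model.n_states, p=model.initial))
    for _ in range(length):
        seq.append(AA20[int(rng.choice(len(AA20), p=model.emissions[state]))])
        groups.append(model.groups[state])
        state = int(rng.choice(model.n_states, p=model.transitions[state]))
    return "".join(seq), groups


def train_emissions(
    model: TopologyModel,
    labelled: list[tuple[str, list[str]]],
) -> TopologyModel:
    """Re-estimate group emission rows from labelled residues.

    Counts are accumulated per emission-tying group with add-one
    smoothing; transitions are left untouched.  Labels must come from the
    model's group alphabet.
    """
    if not labelled:
        raise TopologyError("need at least one labelled sequence")
    valid = set(model.groups)
    counts = {g: np.ones(len(AA20)) for g in valid}  # add-one smoothing
    for seq, labs in labelled:
        if len(seq) != len(labs):
            raise TopologyError("sequence/label length mismatch")
        for aa, g in zip(seq, labs):
            if g not in valid:
                raise TopologyError(f"label {g!r} not in model label alphabet")
            idx = AA_INDEX.get(aa)
            if idx is not None:
                counts[g][idx] += 1
    rows = {g: _normalized(c) for g, c in counts.items()}
    emis = np.stack([rows[g] for g in model.groups])
    new = replace(model, emissions=emis)
    new.validate()
    return new


def expected_group_emissions(model: TopologyModel) -> dict[str, np.ndarray]:
    """The emission row of each tying group (rows are tied, so the first
    state of each group is representative)."""
    out = {}
    for g, row in zip(model.groups, model.emissions):
        out.setdefault(g, row)
    return out


# ---------------------------------------------------------------------------
# Plain-text model serialization
# ---------------------------------------------------------------------------


def model_to_text(model: TopologyModel) -> str:
    """Serialize a model to a key/value text document."""
    lines = [
        f"helix_min_len\t{model.helix_min_len}",
        f"helix_max_len\t{model.helix_max_len}",
        "alphabet\t" + AA20,
    ]
    for i, name in enumerate(model.states):
        lines.append(
            "state\t" + "\t".join(
                [name, model.labels[i], model.groups[i],
                 repr(float(model.initial[i]))]
            )
        )
        lines.append("emit\t" + "\t".join(repr(float(x)) for x in model.emissions[i]))
    for i in range(model.n_states):
        for j in range(model.n_states):
            if model.transitions[i, j] > 0:
                lines.append(
                    f"trans\t{model.states[i]}\t{model.states[j]}\t"
                    f"{float(model.transitions[i, j])!r}"
                )
    return "\n".join(lines) + "\n"


def model_from_text(text: str) -> TopologyModel:
    """Parse a model serialized with :func:`model_to_text`."""
    states: list[str] = []
    labels: list[str] = []
    groups: list[str] = []
    initial: list[float] = []
    emis_rows: list[list[float]] = []
    trans: list[tuple[str, str, float]] = []
    helix_min, helix_max = 15, 25
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "helix_min_len":
            helix_min = int(parts[1])
        elif key == "helix_max_len":
            helix_max = int(parts[1])
        elif key == "alphabet":
            if parts[1] != AA20:
                raise TopologyError("unexpected alphabet in model file")
        elif key == "state":
            states.append(parts[1])
            labels.append(parts[2])
            groups.append(parts[3])
            initial.append(float(parts[4]))
        elif key == "emit":
            emis_rows.append([float(x) for x in parts[1:]])
        elif key == "trans":
            trans.append((parts[1], parts[2], float(parts[3])))
        else:
            raise TopologyError(f"unknown model-file key {key!r}")
    idx = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for a, b, p in trans:
        T[idx[a], idx[b]] = p
    model = TopologyModel(
        states=states,
        labels=labels,
        groups=groups,
        transitions=T,
        emissions=np.array(emis_rows),
        initial=np.array(initial),
        helix_min_len=helix_min,
        helix_max_len=helix_max,
    )
    model.validate()
    return model
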