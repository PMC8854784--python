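"""Subcellular-localization classification for Gram-positive proteomes.

Topology evidence (helix segments, window posteriors) and export-signal
evidence (SPI/SPII/Tat/LPXTG) are combined into one of seven
subcellular-localization classes, a secretion-pathway label, and three
"possibility" scores:

* intracellular possibility, range -1..1 — exactly 1 when no export
  evidence of any kind exists, decreasing as signal-peptide confidence or
  predicted transmembrane helices accumulate;
* signal-peptide possibility, range -1..1 — a rescaled best
  signal-peptide confidence;
* N-anchored possibility, integer range -2..7 with threshold 0 — high
  when an uncleaved N-terminal helix retains the protein on the membrane,
  negative when a cleaved signal with no retained helix releases it.

The class decision is a first-match decision tree that puts the most
specific evidence first (LPXTG, then lipobox).  Helices that lie inside a
cleaved signal peptide are not counted as anchors: the mature chain is
what remains after processing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .export_signals import (
    NO_CLEAVAGE,
    SignalAnnotation,
    selected_cleavage_pos,
)
from .topology_hmm import LABEL_MEM, TopologySummary

# the seven localization classes, written as the field prints them
SCL_INTRACELLULAR = "@Intracellular"
SCL_MULTI_TM = "@Multi-transmembrane"
SCL_N_ANCHORED = "@N-terminally anchored (no CS)"
SCL_C_ANCHORED = "@C-terminally anchored (with CS)"
SCL_LIPID = "@Lipid-anchored"
SCL_MULTI_TM_LIPID = "@Multi-transmembrane (lipid-modified N-termini)"
SCL_LPXTG = "@LPXTG cell-wall anchored"
SCL_SECRETORY = "@Secretory (released) (with CS)"

SCL_CLASSES = (
    SCL_INTRACELLULAR,
    SCL_MULTI_TM,
    SCL_N_ANCHORED,
    SCL_C_ANCHORED,
    SCL_LIPID,
    SCL_MULTI_TM_LIPID,
    SCL_LPXTG,
    SCL_SECRETORY,
)

#: the six classes eligible for anchor screening (the rubric's default
#: allow-list; intracellular and LPXTG-anchored proteins are outside it)
TABLE2_CLASSES = (
    SCL_C_ANCHORED,
    SCL_MULTI_TM_LIPID,
    SCL_LIPID,
    SCL_MULTI_TM,
    SCL_N_ANCHORED,
    SCL_SECRETORY,
)

PATHWAY_SEC_SPI = "Sec-(SPI)"
PATHWAY_SEC_SPII = "Sec-(SPII)"
PATHWAY_TAT_SPII = "Possibly Tat/Sec-(SPII)"
PATHWAY_TAT_SPI = "Tat-(SPI)"
PATHWAY_NONE = "No pathway"

#: an N-terminal anchor helix must overlap this initial span (residues)
N_ANCHOR_SPAN = 40
#: a C-terminal anchor helix must lie within this final span (residues)
C_ANCHOR_SPAN = 40


@dataclass(frozen=True)
class SCLPrediction:
    scl_class: str
    pathway: str
    intracellular_possibility: float
    signal_possibility: float
    n_anchored_possibility: float
    cleavage_window: str


def _mature_helices(
    annotation: SignalAnnotation, segments
) -> list[tuple[str, int, int]]:
    """Membrane segments of the mature chain.

    With a selected cleavage event, helices contained in the cleaved
    signal region do not count as anchors.
    """
    helices = [s for s in segments if s[0] == LABEL_MEM]
    cpos = selected_cleavage_pos(annotation)
    if cpos is None:
        return helices
    return [h for h in helices if h[1] > cpos]


def classify_scl(
    annotation: SignalAnnotation,
    summary: TopologySummary,
    length: int,
    require_spi_for_c_anchor: bool = True,
    n_anchor_span: int = N_ANCHOR_SPAN,
) -> SCLPrediction:
    """Assign the localization class, pathway, and possibility scores.

    The decision tree is total: every (annotation, summary) pair yields
    exactly one class, first match wins.
    """
    helices = _mature_helices(annotation, summary.segments)
    nh = len(helices)
    cleaved = annotation.selected is not None
    spi, spii, tat = annotation.spi, annotation.spii, annotation.tat

    if annotation.lpxtg.present:
        scl = SCL_LPXTG
    elif spii.present and nh >= 2:
        scl = SCL_MULTI_TM_LIPID
    elif spii.present:
        scl = SCL_LIPID
    elif nh >= 2:
        scl = SCL_MULTI_TM
    elif nh == 1 and helices[0][1] <= n_anchor_span and not cleaved:
        scl = SCL_N_ANCHORED
    elif nh == 1 and helices[0][2] >= length - C_ANCHOR_SPAN + 1:
        if spi.present or not require_spi_for_c_anchor:
            scl = SCL_C_ANCHORED
        else:
            # an uncleaved single C-terminal helix: membrane-anchored
            # without a cleavage site
            scl = SCL_N_ANCHORED
    elif spi.present and nh == 0:
        scl = SCL_SECRETORY
    else:
        scl = SCL_INTRACELLULAR

    raw_nh = sum(1 for s in summary.segments if s[0] == LABEL_MEM)
    if spii.present:
        pathway = PATHWAY_TAT_SPII if tat.present else PATHWAY_SEC_SPII
    elif tat.present and spi.present:
        pathway = PATHWAY_TAT_SPI
    elif spi.present or raw_nh >= 1:
        pathway = PATHWAY_SEC_SPI
    else:
        pathway = PATHWAY_NONE

    intr, sig, n_anch = score_possibilities(annotation, summary)
    window = annotation.cleavage_window

    if scl == SCL_INTRACELLULAR:
        # class-conditional consistency: an intracellular call means the
        # export evidence was discounted, so the score says so too
        pathway = PATHWAY_NONE
        window = NO_CLEAVAGE
        intr = 1.0

    return SCLPrediction(
        scl_class=scl,
        pathway=pathway,
        intracellular_possibility=intr,
        signal_possibility=sig,
        n_anchored_possibility=n_anch,
        cleavage_window=window,
    )


def score_possibilities(
    annotation: SignalAnnotation, summary: TopologySummary
) -> tuple[float, float, float]:
    """The three possibility scores.

    intracellular = 1 - 2E with E the strongest export evidence
    (signal-peptide confidence or a predicted helix), clamped to [0,1]:
    exactly 1 with no evidence, -1 at full evidence.

    signal = 2 * max(SPI, SPII confidence) - 1.

    n_anchored = round(7 r) - 2 c, where r is the retention score (mean
    membrane posterior of an uncleaved N-terminal helix) and c indicates
    a cleavage event with no retained helix; a perfect uncleaved
    N-terminal anchor scores 7, a cleaved and fully released protein -2.
    """
    sig_conf = max(annotation.spi.confidence, annotation.spii.confidence)
    nh = sum(1 for s in summary.segments if s[0] == LABEL_MEM)
    evidence = max(0.0, min(1.0, max(sig_conf, float(min(1, nh)))))
    intracellular = 1.0 - 2.0 * evidence
    signal = 2.0 * sig_conf - 1.0

    cleaved = annotation.selected is not None
    r = summary.n_helix_mem_mass if not cleaved else 0.0
    retained = bool(_mature_helices(annotation, summary.segments))
    c = 1 if cleaved and not retained else 0
    n_anchored = float(round(7.0 * r) - 2 * c)
    return intracellular, signal, n_anchored
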