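"""The anchor-protein screening rubric, ranking, and pipeline entry point.

Every protein flows through topology prediction, export-signal
annotation, and localization classification, then meets the screening
rubric:

hard rules (any failure excludes the protein)
  h1  length below the size cut-off (default 600 residues);
  h2  localization class on the allow-list (the six membrane/exported
      classes; intracellular and LPXTG-anchored are off it by default);
  h3  intracellular possibility at most 0.5;
  h4  terminal windows: the displayed terminus (the one fused to the
      passenger) must be extracytoplasmic (mean outside posterior of its
      20-residue window above 0.5) while the anchoring terminus must not
      be (below 0.5); when the displayed terminus is the N-terminus of a
      protein with a cleaved signal peptide, the window starts at the
      mature N-terminus, since that is the terminus that exists after
      processing;
  h5  for the N-terminally-anchored and secretory classes, the posterior
      probability that the N-terminus is cytoplasmic must exceed 0.8 (the
      mirror-image bound applies when such a protein anchors at C).

soft rules (ranking only, never exclusion)
  larger signal-peptide possibility, larger N-anchored possibility, and a
  more clearly outside display window, combined as a weighted score.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import export_signals, topology_hmm
from .io_formats import (
    ProteinRecord,
    ScreenCriteria,
    read_fasta,
    write_candidate_table,
)
from .scl_classifier import (
    SCL_C_ANCHORED,
    SCL_LIPID,
    SCL_LPXTG,
    SCL_MULTI_TM,
    SCL_MULTI_TM_LIPID,
    SCL_N_ANCHORED,
    SCL_SECRETORY,
    SCLPrediction,
    classify_scl,
)
from .topology_hmm import ResiduePosterior, TopologySummary

import math

import numpy as np

N_SITE = "N site"
C_SITE = "C site"


@dataclass
class CandidateRow:
    """One screened protein, shaped like a row of the candidate table."""

    protein_id: str
    locus_tag: str
    product: str
    prediction: SCLPrediction
    summary: TopologySummary | None
    length: int | None
    passed: bool
    fail_reasons: list[str]
    anchored_site: str
    rank_score: float
    display_outside: float = 0.0

    def as_record(self) -> dict:
        p = self.prediction
        return {
            "protein_id": self.protein_id,
            "locus_tag": self.locus_tag,
            "product": self.product,
            "pathway": p.pathway,
            "scl_class": p.scl_class,
            "intracellular_possibility": p.intracellular_possibility,
            "signal_possibility": p.signal_possibility,
            "n_anchored_possibility": p.n_anchored_possibility,
            "cleavage_window": p.cleavage_window,
            "anchored_site": self.anchored_site,
            "rank_score": self.rank_score,
            "pass": self.passed,
            "fail_reasons": list(self.fail_reasons),
        }


def assign_anchor_site(
    prediction: SCLPrediction, summary: TopologySummary | None = None
) -> str:
    """Which terminus anchors the protein (the passenger is fused to the
    other one).

    Class-determined for every class except multi-transmembrane, where
    the terminus whose window is less outside is the anchoring one.
    """
    scl = prediction.scl_class
    if scl == SCL_C_ANCHORED:
        return C_SITE
    if scl == SCL_MULTI_TM:
        if summary is None:
            return N_SITE
        return N_SITE if summary.out_last_w >= summary.out_first_w else C_SITE
    return N_SITE


def _window_mean_out(
    posterior: ResiduePosterior, start: int, window: int, agg: str
) -> float:
    """Aggregate p_out over `window` residues from 1-based `start`
    (truncated at the C-terminus; short sequences use what is there)."""
    seg = posterior.p_out[start - 1:start - 1 + window]
    if len(seg) == 0:
        seg = posterior.p_out
    return float(np.max(seg) if agg == "max" else np.mean(seg))


def terminal_windows(
    posterior: ResiduePosterior,
    anchored_site: str,
    criteria: ScreenCriteria,
    cleavage_pos: int | None = None,
) -> tuple[float, float]:
    """(display-window, anchor-window) mean outside posteriors.

    The display window sits at the terminus opposite the anchoring site.
    A display window at the N-terminus of a cleaved precursor starts at
    the mature N-terminus (cleavage_pos + 1).
    """
    w = criteria.terminal_window
    agg = criteria.window_agg
    L = len(posterior)
    first = _window_mean_out(posterior, 1, w, agg)
    last = _window_mean_out(posterior, max(1, L - w + 1), w, agg)
    if anchored_site == C_SITE:
        display = (
            _window_mean_out(posterior, cleavage_pos + 1, w, agg)
            if cleavage_pos
            else first
        )
        return display, last
    return last, first


def apply_rubric(
    prediction: SCLPrediction,
    summary: TopologySummary | None,
    length: int | None,
    criteria: ScreenCriteria,
    windows: tuple[float, float] | None = None,
) -> tuple[bool, list[str]]:
    """Evaluate the hard rules; returns (pass, fail_reasons).

    Rules whose inputs are unavailable (no length, no topology summary)
    are skipped, which is how the printed-fields-only fixture rows are
    evaluated.  `windows` carries the (display, anchor) outside means for
    h4; without them h4 falls back to the summary's raw terminal windows.
    """
    criteria.validate()
    reasons: list[str] = []
    if length is not None and not length < criteria.max_length:
        reasons.append("h1:length")
    if prediction.scl_class not in criteria.allowed_classes:
        reasons.append("h2:class")
    if not prediction.intracellular_possibility <= criteria.intracellular_max:
        reasons.append("h3:intracellular")
    if summary is not None and criteria.strict_windows:
        site = assign_anchor_site(prediction, summary)
        if windows is not None:
            display, anchor = windows
        elif site == C_SITE:
            display, anchor = summary.out_first_w, summary.out_last_w
        else:
            display, anchor = summary.out_last_w, summary.out_first_w
        if not (display > criteria.window_outside_min
                and anchor < criteria.opposite_window_outside_max):
            reasons.append("h4:windows")
        if prediction.scl_class in (SCL_N_ANCHORED, SCL_SECRETORY):
            if site == C_SITE:
                ok = summary.prob_n_in < 1.0 - criteria.n_in_min
            else:
                ok = summary.prob_n_in > criteria.n_in_min
            if not ok:
                reasons.append("h5:n_in")
    return (not reasons), reasons


def rank_candidates(
    rows: list[CandidateRow], criteria: ScreenCriteria
) -> list[CandidateRow]:
    """Score and order rows: passing rows by weighted soft score
    (descending, id ascending on ties), failing rows after, by id."""
    w = criteria.soft_weights
    for row in rows:
        p = row.prediction
        row.rank_score = (
            w.get("signal_possibility", 1.0) * p.signal_possibility
            + w.get("n_anchored_possibility", 1.0)
            * math.tanh(p.n_anchored_possibility / 7.0)
            + w.get("display_outside", 1.0) * row.display_outside
        )
    passing = sorted(
        (r for r in rows if r.passed),
        key=lambda r: (-r.rank_score, r.protein_id),
    )
    failing = sorted((r for r in rows if not r.passed), key=lambda r: r.protein_id)
    return passing + failing


def _locus_tag(record: ProteinRecord) -> str:
    """A locus-tag-looking token from the description, '-' when absent."""
    for token in record.description.split():
        if token[:1].isalpha() and any(c.isdigit() for c in token) and "_" not in token \
                and token[0].isupper() and len(token) >= 6:
            return token
    return "-"


def evaluate_record(
    record: ProteinRecord,
    criteria: ScreenCriteria,
    model: topology_hmm.TopologyModel | None = None,
) -> CandidateRow:
    """Run the full per-protein pipeline: topology, signals, class, rubric."""
    if model is None:
        model = topology_hmm.default_model()
    posterior, summary = topology_hmm.predict_topology(
        model, record.sequence, window=criteria.terminal_window,
        agg=criteria.window_agg,
    )
    annotation = export_signals.annotate(record.sequence)
    prediction = classify_scl(
        annotation, summary, record.length,
        require_spi_for_c_anchor=criteria.require_spi_for_c_anchor,
        n_anchor_span=criteria.n_anchor_span,
    )
    site = assign_anchor_site(prediction, summary)
    windows = terminal_windows(
        posterior, site, criteria,
        cleavage_pos=export_signals.selected_cleavage_pos(annotation),
    )
    passed, reasons = apply_rubric(
        prediction, summary, record.length, criteria, windows=windows
    )
    return CandidateRow(
        protein_id=record.id,
        locus_tag=_locus_tag(record),
        product=record.description or "-",
        prediction=prediction,
        summary=summary,
        length=record.length,
        passed=passed,
        fail_reasons=reasons,
        anchored_site=site,
        rank_score=0.0,
        display_outside=windows[0],
    )


def screen_records(
    records: list[ProteinRecord],
    criteria: ScreenCriteria | None = None,
    model: topology_hmm.TopologyModel | None = None,
) -> list[CandidateRow]:
    """Screen in-memory records; returns all rows (pass and fail), ranked."""
    if criteria is None:
        criteria = ScreenCriteria()
    criteria.validate()
    if model is None:
        model = topology_hmm.default_model()
    rows = [evaluate_record(rec, criteria, model) for rec in records]
    return rank_candidates(rows, criteria)


def screen_proteome(
    fasta_path,
    criteria: ScreenCriteria | None = None,
    out_path=None,
    pass_only: bool = False,
) -> list[CandidateRow]:
    """Screen a proteome FASTA end to end; optionally write the TSV."""
    records = read_fasta(fasta_path)
    rows = screen_records(records, criteria)
    selected = [r for r in rows if r.passed] if pass_only else rows
    if out_path is not None:
        crit = criteria if criteria is not None else ScreenCriteria()
        provenance = (
            f"anchorscreen candidate table; max_length={crit.max_length} "
            f"intracellular_max={crit.intracellular_max} n_in_min={crit.n_in_min} "
            f"strict_windows={crit.strict_windows}"
        )
        write_candidate_table([r.as_record() for r in selected], out_path,
                              provenance=provenance)
    return selected
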