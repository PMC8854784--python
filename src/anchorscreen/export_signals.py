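"""Detection of N-terminal export signals and C-terminal wall anchors.

Four sequence elements are recognized, all with plain, documented
heuristics (positions 1-based):

* Sec/SPI signal peptides — the classic tripartite architecture: a basic
  n-region (K/R within the first five residues), a hydrophobic h-region
  (best seven-residue hydropathy window inside positions 3..25), and a
  c-region ending in a small-residue -3/-1 site.  Hydrophobic stretches
  longer than `max_h_run` are rejected as membrane anchors rather than
  cleaved signal peptides.
* Sec/SPII lipoprotein signals — the lipobox [LVIF][ASTVIG][GAS]C with the
  cysteine inside positions 10..40, preceded by a hydrophobic h-region;
  the mature lipid-modified chain starts at the cysteine.
* Tat signals — the twin-arginine consensus [ST]RRx[FGAVML][LITMVF] near
  the N-terminus.
* LPXTG sortase motifs — LPxTG in the last 40 residues followed by a
  hydrophobic run and a positively charged tail.

When both an SPI site and a lipobox match, the lipobox wins as the
selected cleavage event (it is the more specific pattern).  Cleavage
windows are reported as an 8-mer for SPI (last four signal residues plus
first four mature residues) and a 7-mer for SPII (five residues before
the cysteine through one after).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .topology_hmm import KYTE_DOOLITTLE

logger = logging.getLogger("anchorscreen")

NO_CLEAVAGE = "No cleavage site"

# heuristic defaults (overridable via function arguments)
H_REGION_LEN = 7            # minimum hydrophobic-core window
H_REGION_MIN_KD = 1.6       # mean hydropathy threshold for an SPI h-region
H_REGION_SPAN = (3, 25)     # window must start within these positions
H_EXTEND_PROP = 1.0         # per-residue membrane propensity for run extension
MIN_H_CORE = 7              # hydrophobic core bounds for a cleavable signal:
MAX_H_CORE = 14             # longer cores are membrane anchors, not SPs
MATURE_MAX_PROP = 2.6       # residues after a true site are not membrane-like
SMALL_RESIDUES = set("AGSTV")   # allowed at the -3 and -1 cleavage positions
SP_MAX_CLEAVAGE = 45        # latest position considered for an SPI site
LIPOBOX_CYS_RANGE = (10, 40)
LIPOBOX_H_MIN_KD = 1.2
TAT_RE = re.compile(r"[ST]RR.[FGAVML][LITMVF]")
TAT_MAX_START = 33          # 0-based motif start; keeps the first R within 1..35
LPXTG_RE = re.compile(r"LP.TG")
LPXTG_TAIL_SPAN = 40
LPXTG_HYDROPHOBIC = set("AILMFWVCG")
LPXTG_MIN_RUN = 12
LPXTG_MIN_BASIC = 2


def _kd(residue: str) -> float:
    return KYTE_DOOLITTLE.get(residue, 0.0)


def _mean_kd(seq: str) -> float:
    return sum(_kd(c) for c in seq) / len(seq) if seq else 0.0


def _clamp(x: float) -> float:
    return max(0.0, min(1.0, x))


@dataclass(frozen=True)
class SpiResult:
    present: bool
    cleavage_pos: int | None = None  # 1-based position of the -1 residue
    confidence: float = 0.0


@dataclass(frozen=True)
class SpiiResult:
    present: bool
    cys_pos: int | None = None       # 1-based position of the lipobox Cys
    confidence: float = 0.0


@dataclass(frozen=True)
class TatResult:
    present: bool
    rr_pos: int | None = None        # 1-based position of the first R


@dataclass(frozen=True)
class LpxtgResult:
    present: bool
    motif_start: int | None = None   # 1-based position of the L


@dataclass(frozen=True)
class SignalAnnotation:
    spi: SpiResult
    spii: SpiiResult
    tat: TatResult
    lpxtg: LpxtgResult
    #: the cleavage event used downstream: "spii" beats "spi"; None if neither
    selected: str | None
    cleavage_window: str


def _best_h_window(seq: str) -> tuple[int, float]:
    """Best H_REGION_LEN-mer (1-based start, mean hydropathy) inside the
    allowed N-terminal span; (-1, -inf) if the sequence is too short."""
    lo, hi = H_REGION_SPAN
    best_start, best = -1, float("-inf")
    for start in range(lo, hi - H_REGION_LEN + 2):
        if start + H_REGION_LEN - 1 > len(seq):
            break
        mean = _mean_kd(seq[start - 1:start + H_REGION_LEN - 1])
        if mean > best:
            best_start, best = start, mean
    return best_start, best


def _prop(residue: str) -> float:
    from .topology_hmm import MEMBRANE_PROPENSITY
    return MEMBRANE_PROPENSITY.get(residue, 0.0)


def _hydrophobic_run(seq: str, h_start: int) -> tuple[int, int]:
    """1-based extent of the hydrophobic run containing the h-window."""
    start, end = h_start, h_start + H_REGION_LEN - 1
    while start > 1 and _prop(seq[start - 2]) >= H_EXTEND_PROP:
        start -= 1
    while end < len(seq) and _prop(seq[end]) >= H_EXTEND_PROP:
        end += 1
    return start, end


def detect_spi(sequence: str) -> SpiResult:
    """Tripartite Sec/SPI signal-peptide scan.

    A candidate -3/-1 small-residue site is accepted only when (a) it
    lies past the hydrophobic run (the c-region follows the h-region),
    (b) the five residues after it are clearly less membrane-like than
    the h-region itself (a site at the edge of a transmembrane helix is
    hydrophobic on both sides), and (c) the hydrophobic core strictly
    N-terminal of the c-region spans 7..14 residues — longer cores are
    uncleaved membrane anchors, the key discrimination between a signal
    peptide and a signal-anchor helix.
    """
    if len(sequence) < 15:
        return SpiResult(False)
    n_score = 1.0 if any(c in "KR" for c in sequence[:5]) else 0.0
    if n_score == 0.0:
        return SpiResult(False)
    h_start, h_mean = _best_h_window(sequence)
    if h_start < 0:
        return SpiResult(False)
    h_score = _clamp((h_mean - H_REGION_MIN_KD) / 1.0)
    if h_score == 0.0:
        return SpiResult(False)
    run_start, run_end = _hydrophobic_run(sequence, h_start)
    mature_cap = min(MATURE_MAX_PROP, h_mean - 1.0)
    last = min(SP_MAX_CLEAVAGE, len(sequence) - 1)
    for pos in range(max(3, run_end + 1), last + 1):
        if sequence[pos - 1] not in SMALL_RESIDUES or sequence[pos - 3] not in SMALL_RESIDUES:
            continue
        after = sequence[pos:pos + 5]
        if sum(_prop(c) for c in after) / max(1, len(after)) >= mature_cap:
            continue
        core_len = (pos - 3) - run_start + 1
        if core_len > MAX_H_CORE:
            return SpiResult(False)  # membrane anchor, not a signal peptide
        if core_len < MIN_H_CORE:
            continue
        return SpiResult(True, cleavage_pos=pos,
                         confidence=_clamp(n_score * h_score * 1.0))
    return SpiResult(False)


def detect_lipobox(sequence: str) -> SpiiResult:
    """Sec/SPII lipobox scan ([LVIF][ASTVIG][GAS]C, Cys in 10..40)."""
    if len(sequence) < 15:
        return SpiiResult(False)
    lo, hi = LIPOBOX_CYS_RANGE
    for cys in range(max(lo, 5), min(hi, len(sequence)) + 1):
        window = sequence[cys - 4:cys]  # the four lipobox residues
        if len(window) < 4 or window[3] != "C":
            continue
        if window[0] not in "LVIF" or window[1] not in "ASTVIG" or window[2] not in "GAS":
            continue
        h_seq = sequence[max(0, cys - 12):cys - 4]
        if not h_seq:
            continue
        h_score = _clamp((_mean_kd(h_seq) - LIPOBOX_H_MIN_KD) / 1.0)
        if h_score > 0.0:
            return SpiiResult(True, cys_pos=cys, confidence=h_score)
    return SpiiResult(False)


def detect_tat(sequence: str) -> TatResult:
    """Twin-arginine consensus scan near the N-terminus."""
    if len(sequence) < 15:
        return TatResult(False)
    m = TAT_RE.search(sequence[:TAT_MAX_START + 1 + len("SRRXFL")])
    if m and m.start() <= TAT_MAX_START:
        return TatResult(True, rr_pos=m.start() + 2)  # 1-based first R
    return TatResult(False)


def scan_lpxtg(sequence: str) -> LpxtgResult:
    """Sortase LPxTG motif scan in the C-terminal 40 residues."""
    L = len(sequence)
    if L < 50:
        return LpxtgResult(False)
    tail_from = max(0, L - LPXTG_TAIL_SPAN)  # 0-based
    for m in LPXTG_RE.finditer(sequence, tail_from):
        after = sequence[m.end():]
        run = best = 0
        for c in after:
            run = run + 1 if c in LPXTG_HYDROPHOBIC else 0
            best = max(best, run)
        basic = sum(1 for c in sequence[-10:] if c in "KR")
        if best >= LPXTG_MIN_RUN and basic >= LPXTG_MIN_BASIC:
            return LpxtgResult(True, motif_start=m.start() + 1)
    return LpxtgResult(False)


def cleavage_window(sequence: str, annotation: "SignalAnnotation") -> str:
    """The printed cleavage-site window for the selected event.

    SPI: 8-mer spanning cleavage_pos-3 .. cleavage_pos+4 (last four signal
    residues, first four mature residues).  SPII: 7-mer spanning
    cys_pos-5 .. cys_pos+1.  Windows running past a terminus are truncated
    (with a log note); no selected event gives the sentinel string.
    """
    if annotation.selected == "spii":
        cys = annotation.spii.cys_pos
        lo, hi = cys - 5, cys + 1
    elif annotation.selected == "spi":
        pos = annotation.spi.cleavage_pos
        lo, hi = pos - 3, pos + 4
    else:
        return NO_CLEAVAGE
    clipped_lo, clipped_hi = max(1, lo), min(len(sequence), hi)
    if (clipped_lo, clipped_hi) != (lo, hi):
        logger.info("cleavage window truncated to sequence bounds (%d..%d)",
                    clipped_lo, clipped_hi)
    return sequence[clipped_lo - 1:clipped_hi]


def annotate(sequence: str) -> SignalAnnotation:
    """Run all four detectors and select the cleavage event."""
    spi = detect_spi(sequence)
    spii = detect_lipobox(sequence)
    tat = detect_tat(sequence)
    lpxtg = scan_lpxtg(sequence)
    selected = "spii" if spii.present else ("spi" if spi.present else None)
    ann = SignalAnnotation(spi=spi, spii=spii, tat=tat, lpxtg=lpxtg,
                           selected=selected, cleavage_window="")
    window = cleavage_window(sequence, ann)
    return SignalAnnotation(spi=spi, spii=spii, tat=tat, lpxtg=lpxtg,
                            selected=selected, cleavage_window=window)


def selected_cleavage_pos(annotation: SignalAnnotation) -> int | None:
    """Last residue of the cleaved signal (None without a selected event).

    For SPII the signal ends at cys_pos - 1: the lipid-modified cysteine
    is residue +1 of the mature chain.
    """
    if annotation.selected == "spi":
        return annotation.spi.cleavage_pos
    if annotation.selected == "spii":
        return annotation.spii.cys_pos - 1
    return None
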