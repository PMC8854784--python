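"""Synthetic proteins with planted, labelled export signals and topologies.

The generator emits proteins whose background residues follow a fixed
average cytoplasmic composition and whose signal elements are planted at
recorded positions:

* SPI signal peptides: Met + two basic residues, a 12-residue hydrophobic
  h-region, and an A-x-A c-region;
* SPII lipoprotein signals: a 10-residue h-region followed by a lipobox
  ending in the +1 cysteine;
* Tat signals: the twin-arginine consensus spliced into the n-region;
* transmembrane helices: 16–22 hydrophobic residues, with lysines and
  arginines placed on the cytoplasmic flank (positive-inside rule), so the
  default topology model can orient them;
* LPXTG sortase tails: motif + hydrophobic run + basic C-terminal tail.

Every generated record carries a ground-truth label object, which is what
the detector-recovery and end-to-end screening tests measure against.

The module also embeds, verbatim, the two printed reference tables: the
five known endogenous anchor proteins of C. glutamicum and the 25
screened candidate proteins with their localization classes, possibility
scores, cleavage windows, and anchoring sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import ProteinRecord, write_fasta
from .scl_classifier import (
    SCL_C_ANCHORED,
    SCL_INTRACELLULAR,
    SCL_LIPID,
    SCL_LPXTG,
    SCL_MULTI_TM,
    SCL_MULTI_TM_LIPID,
    SCL_N_ANCHORED,
    SCL_SECRETORY,
    SCLPrediction,
)
from .topology_hmm import AA20, CYTOPLASMIC_COMPOSITION, composition_vector


class FixtureError(ValueError):
    """Raised for invalid generator specifications."""


# short generator keys for the eight plantable classes
CLASS_KEYS = {
    "intracellular": SCL_INTRACELLULAR,
    "secretory": SCL_SECRETORY,
    "lipid_anchored": SCL_LIPID,
    "n_anchored": SCL_N_ANCHORED,
    "c_anchored": SCL_C_ANCHORED,
    "multi_tm": SCL_MULTI_TM,
    "multi_tm_lipid": SCL_MULTI_TM_LIPID,
    "lpxtg": SCL_LPXTG,
}

#: default class proportions for a generated proteome: mostly cytoplasmic,
#: with the anchor-eligible classes sharing the exported minority
DEFAULT_CLASS_MIX = {
    "intracellular": 0.40,
    "secretory": 0.12,
    "lipid_anchored": 0.12,
    "n_anchored": 0.12,
    "c_anchored": 0.08,
    "multi_tm": 0.08,
    "multi_tm_lipid": 0.04,
    "lpxtg": 0.04,
}

_BG = composition_vector(CYTOPLASMIC_COMPOSITION)
_H_COMP = {"L": 0.35, "A": 0.20, "V": 0.20, "I": 0.15, "F": 0.10}
_TM_COMP = {"L": 0.28, "I": 0.18, "V": 0.15, "A": 0.12, "F": 0.12,
            "M": 0.05, "W": 0.04, "G": 0.03, "T": 0.03}


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: target class, length, seed, optional knobs."""

    target_class: str
    length: int = 250
    seed: int = 1
    n_helices: int | None = None
    tat: bool = False

    def validate(self) -> "PlantSpec":
        if self.target_class not in CLASS_KEYS:
            raise FixtureError(f"unknown class key {self.target_class!r}")
        if self.length < 60:
            raise FixtureError("length must be >= 60")
        if self.n_helices is not None:
            if self.n_helices < 0:
                raise FixtureError("n_helices must be >= 0")
            if self.target_class == "intracellular" and self.n_helices > 0:
                raise FixtureError("an intracellular protein cannot carry helices")
            if self.target_class in ("secretory", "lipid_anchored", "lpxtg") \
                    and self.n_helices > 0:
                raise FixtureError(
                    f"{self.target_class} proteins are generated without "
                    "transmembrane helices"
                )
        return self


@dataclass
class GroundTruth:
    """Recorded positions of every planted element (1-based)."""

    class_key: str
    target_class: str
    spi_cleavage_pos: int | None = None
    cys_pos: int | None = None
    rr_pos: int | None = None
    lpxtg_start: int | None = None
    helices: list[tuple[int, int]] = field(default_factory=list)


def _choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _bg(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    idx = rng.choice(len(AA20), size=n, p=_BG)
    return "".join(AA20[i] for i in idx)


def _basic(rng) -> str:
    return "KR"[int(rng.integers(2))]


def _sp_spi(rng, truth: GroundTruth, tat: bool = False) -> str:
    if tat:
        n_region = ("M" + "ST"[int(rng.integers(2))] + "RR" + _bg(rng, 1)
                    + "FGAVML"[int(rng.integers(6))]
                    + "LITMVF"[int(rng.integers(6))])
        truth.rr_pos = 3
    else:
        n_region = "M" + _basic(rng) + _basic(rng) + _bg(rng, 1)
    h = "".join(_choice(rng, _H_COMP) for _ in range(10))
    h += "".join("LIF"[int(rng.integers(3))] for _ in range(2))
    c_region = "A" + "SQ"[int(rng.integers(2))] + "A"
    sp = n_region + h + c_region
    truth.spi_cleavage_pos = len(sp)
    return sp


def _sp_spii(rng, truth: GroundTruth, tat: bool = False) -> str:
    if tat:
        n_region = ("M" + "ST"[int(rng.integers(2))] + "RR" + _bg(rng, 1)
                    + "FGAVML"[int(rng.integers(6))]
                    + "LITMVF"[int(rng.integers(6))])
        truth.rr_pos = 3
    else:
        n_region = "M" + _basic(rng) + _basic(rng)
    h = "".join(_choice(rng, _H_COMP) for _ in range(8))
    h += "".join("LIF"[int(rng.integers(3))] for _ in range(2))
    lipobox = ("LVF"[int(rng.integers(3))] + "AST"[int(rng.integers(3))]
               + "GAS"[int(rng.integers(3))] + "C")
    sp = n_region + h + lipobox
    truth.cys_pos = len(sp)
    return sp


def _helix(rng, truth: GroundTruth, offset: int) -> str:
    n = int(rng.integers(16, 23))  # 19 +/- 3 residues
    h = "".join(_choice(rng, _TM_COMP) for _ in range(n))
    truth.helices.append((offset + 1, offset + n))
    return h


def _inside_loop(rng, n: int, n_basic: int) -> str:
    body = [_basic(rng) for _ in range(min(n_basic, n))] + list(_bg(rng, n - min(n_basic, n)))
    order = rng.permutation(len(body))  # basic residues scattered through the loop
    return "".join(body[i] for i in order)


def generate_protein(spec: PlantSpec) -> tuple[ProteinRecord, GroundTruth]:
    """Generate one protein with planted elements and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    key = spec.target_class
    truth = GroundTruth(class_key=key, target_class=CLASS_KEYS[key])
    L = spec.length
    parts: list[str] = []

    def built() -> int:
        return sum(len(p) for p in parts)

    if key == "intracellular":
        parts.append(_bg(rng, L))

    elif key == "secretory":
        parts.append(_sp_spi(rng, truth, tat=spec.tat))
        parts.append(_bg(rng, L - built()))

    elif key == "lipid_anchored":
        parts.append(_sp_spii(rng, truth, tat=spec.tat))
        parts.append(_bg(rng, L - built()))

    elif key == "n_anchored":
        parts.append("M" + _inside_loop(rng, 4, 2))
        parts.append(_helix(rng, truth, built()))
        parts.append(_bg(rng, L - built()))

    elif key == "c_anchored":
        parts.append(_sp_spi(rng, truth, tat=spec.tat))
        tail = _inside_loop(rng, 3, 3) + _bg(rng, 3)
        helix_len_max = 22
        mid = L - built() - helix_len_max - len(tail)
        if mid < 5:
            raise FixtureError("length too small for a C-anchored construct")
        parts.append(_bg(rng, mid))
        parts.append(_helix(rng, truth, built()))
        parts.append(tail)

    elif key == "multi_tm":
        k = spec.n_helices if spec.n_helices is not None else 3
        if k < 2:
            raise FixtureError("multi_tm requires at least 2 helices")
        parts.append("M" + _inside_loop(rng, 5, 2))
        for i in range(k):
            parts.append(_helix(rng, truth, built()))
            if i < k - 1:
                inside = (i % 2 == 1)  # loop after an odd-numbered crossing
                parts.append(_inside_loop(rng, 12, 3) if inside else _bg(rng, 12))
        parts.append(_bg(rng, max(0, L - built())))

    elif key == "multi_tm_lipid":
        k = spec.n_helices if spec.n_helices is not None else 2
        if k < 2 or k % 2 != 0:
            raise FixtureError(
                "multi_tm_lipid plants an even helix count so the C-terminus "
                "ends extracytoplasmic"
            )
        parts.append(_sp_spii(rng, truth, tat=spec.tat))
        parts.append(_bg(rng, 10))
        for i in range(k):
            parts.append(_helix(rng, truth, built()))
            if i < k - 1:
                inside = (i % 2 == 0)
                parts.append(_inside_loop(rng, 10, 3) if inside else _bg(rng, 10))
        parts.append(_bg(rng, max(0, L - built())))

    elif key == "lpxtg":
        parts.append(_sp_spi(rng, truth, tat=spec.tat))
        tail = ("LP" + _bg(rng, 1) + "TG"
                + "".join(_choice(rng, {"L": .4, "I": .2, "V": .2, "F": .1, "A": .1})
                          for _ in range(15))
                + _bg(rng, 6) + "KRK" + _bg(rng, 1))
        mid = L - built() - len(tail)
        if mid < 5:
            raise FixtureError("length too small for an LPXTG construct")
        parts.append(_bg(rng, mid))
        truth.lpxtg_start = built() + 1
        parts.append(tail)

    seq = "".join(parts)
    if len(seq) < L:  # helix-length jitter can undershoot; pad background
        seq += _bg(rng, L - len(seq))
    record = ProteinRecord(
        id=f"{key}_s{spec.seed}",
        description=f"synthetic {CLASS_KEYS[key]} protein",
        sequence=seq,
    )
    return record, truth


def generate_proteome(
    n: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 1,
) -> tuple[list[ProteinRecord], list[GroundTruth]]:
    """Generate a labelled synthetic proteome.

    Classes are assigned by seeded sampling from `class_mix` (must sum to
    1 within 1e-6); lengths are drawn uniformly from 140..420 residues.
    Byte-identical output for identical (n, mix, seed).
    """
    if n <= 0:
        raise FixtureError("n must be >= 1")
    mix = dict(DEFAULT_CLASS_MIX if class_mix is None else class_mix)
    unknown = set(mix) - set(CLASS_KEYS)
    if unknown:
        raise FixtureError(f"unknown class keys in mix: {sorted(unknown)}")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise FixtureError(f"class mix must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    keys = sorted(mix)
    p = np.array([mix[k] for k in keys])
    records, truths = [], []
    for i in range(n):
        key = keys[int(rng.choice(len(keys), p=p))]
        length = int(rng.integers(140, 421))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec, truth = generate_protein(PlantSpec(key, length=length, seed=sub_seed))
        records.append(ProteinRecord(
            id=f"SYN{i + 1:04d}",
            description=rec.description,
            sequence=rec.sequence,
        ))
        truths.append(truth)
    return records, truths


def write_proteome(
    records: list[ProteinRecord],
    truths: list[GroundTruth],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write FASTA + ground-truth TSV for a generated proteome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "proteome.fasta"
    truth_tsv = out / "truth.tsv"
    write_fasta(records, fasta)
    with open(truth_tsv, "w") as fh:
        fh.write("protein_id\tclass_key\ttarget_class\tspi_cleavage_pos\t"
                 "cys_pos\trr_pos\tlpxtg_start\thelices\n")
        for rec, t in zip(records, truths):
            helices = ";".join(f"{s}-{e}" for s, e in t.helices)
            fh.write("\t".join([
                rec.id, t.class_key, t.target_class,
                str(t.spi_cleavage_pos or ""), str(t.cys_pos or ""),
                str(t.rr_pos or ""), str(t.lpxtg_start or ""), helices,
            ]) + "\n")
    return fasta, truth_tsv


# ---------------------------------------------------------------------------
# Embedded printed reference tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureRow:
    """One printed reference row (fields transcribed verbatim)."""

    protein_id: str
    locus_tag: str
    product: str
    pathway: str
    destination: str
    scl_class: str
    intracellular: float
    signal: float
    n_anchored: float
    cleavage_site: str
    anchored_site: str | None = None


_TABLE1 = [
    ("WP_003858702.1", "NCgl1337", "SGNH/GDSL hydrolase family protein",
     "Sec-(SPI)", "Extracellular", SCL_SECRETORY, 0.17, 1, -2, "PATAQSSG"),
    ("WP_011014245.1", "NCgl1221", "Mechanosensitive ion channel",
     "Sec-(SPI)", "Membrane", SCL_MULTI_TM, 0.17, -1, 1, "No cleavage site"),
    ("WP_003856752.1", "NCgl0933", "PorB",
     "Sec-(SPI)", "Extracellular", SCL_SECRETORY, -0.17, 1, -1, "FAAPASAS"),
    ("WP_003856749.1", "NCgl0932", "PorC",
     "Sec-(SPI)", "Extracellular", SCL_SECRETORY, -0.17, 1, -1, "PSASAQDF"),
    ("WP_011265995.1", "PorH", "PorH",
     "No pathway", "Cytoplasmic", SCL_INTRACELLULAR, 1, -1, -1,
     "No cleavage Site"),
]

_TABLE3 = [
    ("WP_011013799.1", "NCgl0550", "hypothetical protein", "Sec-(SPI)",
     "Membrane", SCL_C_ANCHORED, 0, 1, -2, "PTASAATL", "C site"),
    ("WP_011013739.1", "NCgl0633",
     "type VII secretion-associated serine protease mycosin", "Sec-(SPI)",
     "Membrane", SCL_C_ANCHORED, 0, 1, -2, "TRAQEVEA", "C site"),
    ("WP_011014951.1", "NCgl2115", "cytochrome c oxidase subunit II",
     "Sec-(SPII)", "Membrane", SCL_MULTI_TM_LIPID, 0, 1, 1, "LAMAGCE",
     "N site"),
    ("WP_011265759.1", "NCgl1460",
     "gi| 62390400| ref| YP_225802.1| hypothetical protein cg1712",
     "Sec-(SPII)", "Extracellular", SCL_LIPID, 0.17, 1, 1, "LLLSACT",
     "N site"),
    ("WP_011014306.1", "NCgl1307", "hypothetical protein", "Sec-(SPII)",
     "Extracellular", SCL_LIPID, -0.33, 1, 1, "FVLSGCG", "N site"),
    ("WP_011014779.1", "NCgl1876",
     "glutamate ABC transporter substrate-binding protein", "Sec-(SPII)",
     "Extracellular", SCL_LIPID, -0.33, 1, 1, "VTLTACG", "N site"),
    ("WP_011265985.1", "NCgl2562",
     "twin-arginine translocation signal domain-containing protein",
     "Possibly Tat/Sec-(SPII)", "Extracellular", SCL_LIPID, -0.33, 1, 1,
     "ATLAACA", "N site"),
    ("WP_011013364.1", "NCgl0067", "sensor histidine kinase", "Sec-(SPI)",
     "Membrane", SCL_MULTI_TM, 0.17, -1, 2, "No Cleavage Site", "N site"),
    ("WP_004567665.1", "NCgl2291",
     "MULTISPECIES: DUF4233 domain-containing protein", "Sec-(SPI)",
     "Membrane", SCL_MULTI_TM, 0.17, -1, 1, "No cleavage site", "C site"),
    ("WP_01101483.1", "NCgl1147", "family transporter", "Sec-(SPI)",
     "Membrane", SCL_MULTI_TM, 0.17, -1, 1, "No cleavage site", "N site"),
    ("WP_011014865.1", "NCgl1998", "ABC transporter ATP-binding protein",
     "Sec-(SPI)", "Membrane", SCL_MULTI_TM, 0.17, -0.5, 1,
     "No cleavage site", "N site"),
    ("WP_003859459.1", "NCgl2206", "MULTISPECIES: HlyC/CorC family transporter",
     "Sec-(SPI)", "Membrane", SCL_MULTI_TM, 0.17, 0, 0, "No cleavage site",
     "N site"),
    ("WP_003863539.1", "NCgl0743", "MULTISPECIES: potassium channel family protein",
     "Sec-(SPI)", "Membrane", SCL_MULTI_TM, 0.17, -1, -1, "No cleavage site",
     "N site"),
    ("WP_011013342.1", "NCgl0042", "penicillin-binding protein 2", "Sec-(SPI)",
     "Membrane", SCL_N_ANCHORED, 0.17, 1, 7, "No cleavage site", "N site"),
    ("WP_011013540.1", "NCgl0289", "TlpA family protein disulfide reductase",
     "Sec-(SPI)", "Membrane", SCL_N_ANCHORED, 0.17, 1, 7, "No cleavage site",
     "N site"),
    ("WP_011014270.1", "NCgl1250", "SRPBCC family protein", "Sec-(SPI)",
     "Membrane", SCL_N_ANCHORED, 0.17, 1, 7, "No cleavage site", "N site"),
    ("WP_011015453.1", "NCgl2775", "cutinase family protein", "Sec-(SPI)",
     "Membrane", SCL_N_ANCHORED, 0.17, 1, 7, "No cleavage site", "N site"),
    ("WP_003853779.1", "NCgl2610", "MULTISPECIES: DUF4247 domain-containing protein",
     "Sec-(SPI)", "Membrane", SCL_N_ANCHORED, 0.17, 1, 5, "No cleavage site",
     "N site"),
    ("WP_011013420.1", "NCgl0136", "hypothetical protein", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "IAATPATA", "N site"),
    ("WP_011013818.1", "NCgl0661", "CAP domain-containing protein", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "PSAHAFTA", "N site"),
    ("WP_011013866.1", "NCgl0717", "hypothetical protein", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "DIATSTTT", "N site"),
    ("WP_011014348.1", "NCgl1361", "copper transporter", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "GIAFGTYV", "N site"),
    ("WP_011014599.1", "NCgl1682",
     "LysM peptidoglycan-binding domain-containing protein", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "GGSGVTFL", "N site"),
    ("WP_042383306.1", "NCgl2577", "hypothetical protein", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -1, "VVALRGGS", "N site"),
    ("WP_003858490.1", "NCgl0872", "resuscitation-promoting factor", "Sec-(SPI)",
     "Extracellular", SCL_SECRETORY, 0.17, 1, -2, "VTAAATKK", "N site"),
]


def table_fixtures() -> tuple[list[FixtureRow], list[FixtureRow]]:
    """The embedded printed reference rows (5 known anchors, 25 candidates)."""
    t1 = [FixtureRow(*row) for row in _TABLE1]
    t3 = [FixtureRow(*row) for row in _TABLE3]
    return t1, t3


def prediction_from_fixture(row: FixtureRow) -> SCLPrediction:
    """Build an SCLPrediction carrying a fixture row's printed fields,
    for evaluating the rubric rules computable from printed values."""
    return SCLPrediction(
        scl_class=row.scl_class,
        pathway=row.pathway,
        intracellular_possibility=row.intracellular,
        signal_possibility=row.signal,
        n_anchored_possibility=row.n_anchored,
        cleavage_window=row.cleavage_site,
    )
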