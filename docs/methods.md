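# Methods

## Overview

`anchorscreen` operationalizes a published-style anchor-protein mining
workflow as one reproducible pipeline: membrane-topology prediction,
export-signal detection, seven-class subcellular-localization (SCL)
assignment, and a hard/soft screening rubric that emits a ranked
candidate table. The predictors are deliberately compact and fully
documented; they are this package's own parameterizations, not
re-implementations of any published tool's trained weights, and the
supported contract is the rubric's threshold comparisons (> 0.5, > 0.8,
≤ 0.5), not absolute probability values.

## Topology model

The topology HMM follows the classic loop–helix grammar. States:

* `in` — cytoplasmic loop; `out` — extracytoplasmic loop; `out-glob` —
  an outside globular-domain state with a flatter emission profile;
* two helix chains, one per crossing direction (in→out and out→in),
  each consisting of 2 entry caps, 25 core states, and 2 exit caps.

Helix length is enforced structurally: 15 mandatory core states, then 10
optional ones each with probability 0.5 of early exit, giving core runs
of 15–25 residues (19–29 counting caps, which are folded into the
membrane label for reporting). There is no direct inside↔outside
transition, so decoded paths can never cross the membrane without a
helix — the grammar is checked by `TopologyModel.validate()` and by
tests.

Emissions are tied by state group:

* **helix core** — background-weighted exponential transform of a
  membrane propensity scale (Kyte–Doolittle with the interfacial
  aromatics W and Y shifted up to 1.9 and 0.5), steepness β = 0.5:
  `e(a) ∝ bg(a)·exp(β·prop(a))`;
* **inside loop** — the loop background with lysine and arginine
  up-weighted ×3.5 (positive-inside rule). This is what lets the decoder
  orient a protein whose N-terminal flank is basic;
* **outside loop** — the loop background (fixed average cytoplasmic
  composition mixed with 15% uniform);
* **caps** — 25% helix + 75% loop background, so interface positions
  tolerate snorkeling basic residues;
* **outside globular** — 60% background + 40% uniform.

Transitions: loop self-transitions 0.96/0.95, loop→helix 0.04, and a
0.01 per-residue excursion into the globular state. Residue 1 starts
inside with probability 0.7 (proteins are born in the cytoplasm).
Ambiguity codes X/B/Z/U emit each state's row mean, i.e. they carry no
topology information.

These constants were chosen so that the default model decodes the
canonical architectures the synthetic generator plants — a 12-residue
signal-peptide h-region plus its c-region is exactly crossable (15 core
states), a 16–22-residue planted helix crosses decisively, and basic
N-terminal flanks pin the N-terminus inside. Absolute posteriors will
differ from any externally trained predictor; threshold behaviour is the
contract.

Decoding uses scaled forward–backward (no underflow at any length;
2000-residue sequences are tested) and log-space Viterbi with ties
broken by fixed state order. Posterior, Viterbi and likelihood are
verified against exhaustive path enumeration on all sequences of length
≤ 6 under a 3-state toy model at 1e-9.

`train_emissions` re-estimates the five tied emission rows from labelled
residues with add-one smoothing (transitions untouched); on 200
sequences sampled from the model it recovers every emission probability
within ±0.05.

### Window statistics

The rubric consumes: `prob_n_in` = posterior that residue 1 is inside;
`out_first_20` / `out_last_20` = arithmetic mean of the outside
posterior over the terminal 20-residue windows (mean is the default
aggregate; `max` is available via `window_agg`); sequences shorter than
the window use every residue. `n_helices` counts membrane segments on
the Viterbi path.

## Export-signal detectors

All detectors are deterministic pattern heuristics with documented
defaults; positions are 1-based.

* **Sec/SPI** — tripartite scan: K/R within residues 1–5; best 7-mer
  hydropathy window starting in 3..25 with mean Kyte–Doolittle > 1.6;
  then a c-region search for small residues ({A,G,S,T,V}) at −3/−1. A
  candidate site must lie past the hydrophobic run, its following five
  residues must be clearly less membrane-like than the h-region
  (mean propensity < min(2.6, h-mean − 1)), and the hydrophobic core
  strictly N-terminal of the c-region must span 7–14 residues. Cores
  longer than 14 are treated as uncleaved membrane anchors — this is the
  signal-peptide vs. signal-anchor discrimination.
* **Sec/SPII** — lipobox `[LVIF][ASTVIG][GAS]C` with the cysteine at
  10..40, preceded by a hydrophobic h-region (mean hydropathy of the
  eight residues before the motif > 1.2). The lipid-modified cysteine is
  residue +1 of the mature chain. When both SPI and SPII match, SPII is
  the selected cleavage event (the more specific pattern).
* **Tat** — `[ST]RR x [FGAVML][LITMVF]` with the first arginine at ≤ 35.
* **LPXTG** — `LP x TG` in the last 40 residues, followed by a ≥ 12
  hydrophobic run and ≥ 2 K/R in the final 10 residues.

Cleavage windows mirror the printed table conventions: SPI reports the
8-mer from −3 to +4 around the site (last four signal residues, first
four mature residues); SPII reports the 7-mer from cys−5 to cys+1;
windows crossing a terminus are truncated with a log note; otherwise the
sentinel "No cleavage site" is reported. The SPI-8/SPII-7 widths
reproduce the printed window widths but are an inferred convention, not
a published definition.

## Classification

A first-match decision tree, most specific evidence first:
LPXTG → lipobox + ≥2 mature helices → lipobox → ≥2 mature helices →
single uncleaved helix overlapping residues 1–40 (N-anchored) → single
mature helix in the last 40 residues (C-anchored when an SPI site
exists; `require_spi_for_c_anchor` exposes the alternative) → SPI with
no mature helix (secretory) → intracellular. "Mature helices" excludes
helices contained in a cleaved signal region: the anchor is what remains
after processing, and without this rule a cleaved precursor whose signal
peptide decodes as a helix would be mis-typed as polytopic.

Pathway label: lipobox → Sec-(SPII) (plus Tat → "Possibly
Tat/Sec-(SPII)"); Tat + SPI → Tat-(SPI); SPI or any uncleaved membrane
helix → Sec-(SPI); otherwise "No pathway".

Possibility scores:

* `intracellular = 1 − 2E`, E = max(signal confidence, min(1, helix
  count)) clamped to [0, 1] — exactly 1 with no export evidence, −1 at
  full evidence. Proteins classified @Intracellular always report 1
  (class-conditional consistency: the tree has discounted whatever weak
  evidence existed).
* `signal = 2·max(SPI, SPII confidence) − 1`.
* `n_anchored = round(7r) − 2c`, r = mean membrane posterior of an
  uncleaved N-terminal helix (0 without one), c = 1 when a cleavage
  event with no retained helix was selected. The extremes match the
  printed conventions: a perfect uncleaved N-anchor scores 7, a cleaved
  and released protein −2. Mid-range printed values are not reproduction
  targets — the underlying scoring of the original SCL predictor is
  unpublished, and these formulas are this package's own.

## Screening rubric

Hard rules (any failure excludes; identifiers appear in `fail_reasons`):
h1 length < 600; h2 class ∈ allow-list (the six exported/membrane
classes; @Intracellular and @LPXTG excluded by default, the latter
enabled via config); h3 intracellular ≤ 0.5; h4 terminal windows —
display-terminus mean outside posterior > 0.5 AND anchoring-terminus
< 0.5; h5 N-in > 0.8 for the N-anchored and secretory classes (mirrored
when such a protein anchors at C). Soft criteria never exclude; they
rank: `rank = w1·signal + w2·tanh(n_anchored/7) + w3·display_window`,
default weights 1.

Two deliberate interpretations, both configurable:

* The source screening table asks for "outside probability of the first
  20 AA > 0.5" while the accompanying text says the *inside* probability
  of the same window should be > 0.5. Resolved by intent: the terminus
  fused to the passenger must be extracytoplasmic, the anchoring
  terminus must not be. `strict_windows: false` drops h4/h5 entirely
  (screening by class and scores only).
* When the displayed terminus is the N-terminus of a cleaved precursor
  (the C-anchored class), its window starts at the mature N-terminus
  (cleavage position + 1): that is the terminus that exists after
  processing. Without this, no C-site candidate could ever pass on
  precursor windows, contradicting the printed candidate list.

Anchoring site: class-determined for every class except
@Multi-transmembrane (N site for N-anchored/lipid/secretory classes,
C site for C-anchored), and window-determined for polytopic proteins
(the terminus with the lower outside window anchors).

## Synthetic data

The generator emits proteins over a fixed average cytoplasmic
composition with planted elements at recorded positions: SPI signals
(M + two basic residues + 12 hydrophobic + A-x-A), SPII signals (10
hydrophobic + lipobox, Cys ≈ 17), Tat n-regions (consensus at residues
2–7), helices of 16–22 residues from a membrane composition, inside
loops enriched in K/R (so the positive-inside signal is decodable), and
LPXTG tails (motif + 15 hydrophobics + basic tail). Default proteome
mix: 40% intracellular, 12% each secretory/lipoprotein/N-anchored, 8%
each C-anchored/polytopic, 4% each lipid-modified-polytopic/LPXTG;
lengths uniform in 140–420. These defaults were fixed when the generator
was written and define the study conditions of the test suite.

What the generator does *not* emulate: real signal peptides with proline
or glycine-broken h-regions, genome-scale composition biases, homologous
families, or disordered regions. Passing tests therefore demonstrate
internal consistency of the pipeline under idealized-but-noisy
sequences, not field accuracy on real proteomes.

Measured operating point at the documented conditions (n = 200, seed 1):
≈ 95% sensitivity and ≈ 100% specificity for planted anchor-class
proteins end to end; ≥ 96% recovery (position ± 1) for each planted
signal element. Residual misses are honest prediction errors — weakly
hydrophobic sampled h-regions that leave the crossing posterior
ambiguous, or spurious background helices that flip terminal-window
parity.

## Numerical and design notes

* All coordinates in outputs are 1-based inclusive; TSV output is
  byte-deterministic (floats at two decimals, provenance only in `#`
  comments, pass rows sorted by rank then id, failing rows after).
* Viterbi ties break by fixed state order; toy-model tests use
  irregular probabilities so no ties arise in oracle comparisons.
* Degenerate inputs: empty sequences are hard errors; sequences shorter
  than a window use all residues; truncated cleavage windows are
  logged, not errors; an empty FASTA yields an empty (header-only)
  table.
* The h2/h3 rubric rules can be evaluated from printed fields alone
  (summary/length omitted), which is how the embedded candidate-table
  fixture is checked.

## Known limitations

* The topology model is hand-parameterized, not trained; its absolute
  posteriors are not calibrated probabilities.
* Signal-peptide confidence is a product of clamped sub-scores — a
  monotone ranking device, not a calibrated probability.
* Single mid-sequence uncleaved helices fall through the class tree to
  @Intracellular (the taxonomy has no "internally anchored" class);
  they are reported with intracellular possibility 1 by the consistency
  rule and are never screening candidates.
* Tat-specific cleavage sites are not modelled separately from SPI.
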