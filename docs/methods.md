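# Methods

## The problem

Selenoproteins carry selenocysteine (Sec, `U`), inserted at in-frame UGA
codons by the SECIS/SECISBP2 machinery. Sec peptides are so rare in public
spectral data that fragment-intensity, retention-time and ion-mobility
predictors cannot be trained on them directly, which blocks the in-silico
spectral libraries that DIA search engines such as DIA-NN need. `secproxy`
implements the proxy-training strategy: cysteine (Cys, `C`) is chemically
near-identical to Sec (thiol vs selenol), so an abundant library of
labeled Cys peptides is rewritten into a *pseudo-Sec* library by a pure
mass transformation, the predictors are trained on it, and the trained
models then generate a DIA-ready library for every tryptic selenopeptide
of a UGA-readthrough protein database.

## Mass chemistry

All masses are monoisotopic (library search operates on monoisotopic
species; no average masses anywhere). Element and residue masses come
from pyteomics' NIST tables; Sec is defined as Cys − S + Se so that the
proxy shift is exact by construction:

    Δ(Se−S) = 79.9165213 − 31.9720707 = 47.944451 Da

Built-in modifications (delta recomputed from elemental composition at
registry build time, so the two can never drift apart):

| name        | targets | composition      | Δm (Da)     |
|-------------|---------|------------------|-------------|
| CAM         | C, U    | C2H3NO           | +57.021464  |
| IodoAPB-CAM | C, U    | C18H30N4O5S      | +414.193691 |
| deSe        | U       | −H2Se            | −81.932170  |
| Oxidation   | M       | O                | +15.994915  |
| Acetyl      | N-term  | C2H2O            | +42.010565  |

IodoAPB-CAM is the adduct of the Sec-selective biotinylated probe
(EZ-Link Iodoacetyl-PEG2-Biotin); the vendor does not publish the adduct
formula, and C18H30N4O5S was adopted because it reproduces the reference
delta to < 1e-5 Da. Modification sites are 1-based on the stripped
sequence, 0 meaning the N-terminus — this makes fragment assignment
unambiguous: a modification belongs to exactly the b/y fragments that
span its residue.

Only b/y fragments at charge 1–2 are modeled. The model output layout
reserves modloss channels (see below) but they are emitted as zero: no
registered modification produces a dominant neutral loss.

## Sequence databases and digestion

`translate_readthrough` applies the standard genetic code except that
every TGA emits `U` and translation continues; TAA/TAG terminate. ORF
discovery is out of scope — the caller supplies the frame. Digestion is
fully tryptic (cleave after K/R, never before P, matching the MSFragger
default; `U` is never a cleavage site), ≤ 2 missed cleavages, length
7–50, mass 500–5000 Da. The mass window is evaluated on the *labeled*
peptide (fixed CAM on C, IodoAPB-CAM on U) because the searched species
carries the labels; `mass_on_modified=False` switches to stripped mass.
Precursors are enumerated at charges 1–4, one per (peptide, charge).

SCoSS filtering keeps only proteins whose accession appears in a
user-supplied SECISBP2-binder list (version suffixes normalized by
default); an empty binder list is an error so a bad file cannot silently
empty a library.

## The proxy transform

`cys_to_sec` substitutes C→U at eligible sites, keeping the site's
modification (both CAM and IodoAPB-CAM target C and U). The precursor
m/z shifts by k·Δ(Se−S)/z for k substituted sites and each fragment by
(sites it spans)·Δ(Se−S)/z_frag. Intensities, RT and ion mobility are
carried over bit-for-bit: the proxy assumption is that these properties
coincide between a peptide and its Sec twin, and no empirical correction
is applied. By default only IodoAPB-CAM-labeled Cys are substituted
("all_labeled") — in real SecMS data that label marks the Sec position
while bystander Cys are CAM-alkylated, so the pseudo-library mirrors the
composition of real selenopeptides; `mode="all"` substitutes every Cys.
Duplicate post-transform keys keep the higher-total-intensity entry and
are logged.

## Models

Because no deep-learning framework is assumed, the predictors run on a
small in-repo reverse-mode autodiff engine over numpy (vectorized
tensors, fused LSTM/conv kernels with hand-written backward passes,
verified against finite differences in float64). Architectures follow
the reference design:

* **MS2**: residue-token embedding + PTM elemental-composition projection
  (+ charge/NCE/instrument meta projection), sinusoidal positions,
  transformer encoder stack (default 4 layers, hidden 256, 4 heads,
  feed-forward 4×, pre-norm — attention details not fixed by the
  reference are standard defaults and recorded in `ModelConfig`), then
  per cleavage site the concatenated flanking states pass through FC
  128 → 8 sigmoid outputs: {b,y} × {z1,z2} × {regular, modloss}.
* **RT/CCS**: one-hot residues + PTM composition counts → 1-D conv
  (128 channels) → 2 LSTM layers (dim 128) → mean pooling (CCS also
  concatenates a charge one-hot) → FC 64 → 1. Targets are standardized;
  CCS predictions pass through a softplus so they are strictly positive.

`U` is a first-class token with its own embedding row / one-hot column.
`warm_start_sec_from_cys()` copies the C representation onto U — the
proxy hypothesis expressed in weight space — and is applied between
pretraining on Cys-only data and fine-tuning on pseudo-Sec data. With
identical modifications, a warm-started untrained model scores a peptide
and its Sec twin identically (tested).

**Training.** The fine-tuning recipe is fixed by `ModelConfig`: L1 loss,
20 epochs, 5 warm-up epochs then cosine decay, peak learning rate 1e-5,
dropout 0.1, mini-batch 256, Adam. Since no external pretrained weights
are shipped, `pretrain` first fits the network from scratch on the
(synthetic or experimental) Cys library with its own schedule (default
peak LR 2e-3, 50–60 epochs, same warm-up/cosine shape) — the offline
counterpart of loading pretrained generic weights — after which the
reference fine-tune runs verbatim on the pseudo-Sec library. A learning
rate of 1e-5 over 20 epochs moves a randomly initialized network only
marginally, which is exactly why the pretrain stage exists. Batches
group peptides of equal length, so no padding or masking is needed;
training is deterministic given a seed (single CPU).

`ModelConfig.desk_scale()` shrinks dimensions (MS2: 2 layers × 64; conv
48 / LSTM 48) for single-CPU runs while leaving the recipe untouched.
The parameter counts of the full-size reference models are not a test
target: they depend on embedding internals that are not specified.

**CCS ↔ ion mobility.** Mason–Schamp proportionality
1/K0 = CCS·√μ/(k·z) with μ the ion–N2 reduced mass (N2 = 28.013 Da) and
k = 1059.62245, placing tryptic 2+ peptides in the usual 0.6–1.6
Vs cm⁻² timsTOF window; the inverse is exact (round trip < 1e-9
relative).

## Library assembly

Predicted entries keep fragments with relative intensity ≥ 0.01 inside a
100–1700 m/z scan range and require ≥ 4 surviving fragments (the
minimum-matched-fragments convention of the upstream DDA search).
Buffering peptides — high-intensity experimental Cys precursors that
stabilize DIA scoring when most library entries are hypothetical — are
added at a Cys:Sec ratio interpreted over *precursor counts* (the
searchable unit): the top ⌈r·#Sec⌉ by summed fragment intensity ×
precursor intensity (when reported), ties broken by ascending m/z then
sequence. Decoys are never generated (DIA-NN builds its own). The TSV
dialect is long-format, one row per fragment, with bracketed-delta
modification notation (`U[+414.1937]`, 4 decimals) and a fixed 13-column
header; numeric fields survive a round trip to 1e-4.

## Evaluation

Fragment vectors are paired by annotation key (ion type, series number,
fragment charge), which is invariant under the proxy mass shift, so a
Cys entry can be compared directly with its Sec twin; m/z-tolerance
pairing (15 ppm, the upstream fragment tolerance) exists for
annotation-free spectra. Unmatched fragments are zero-filled by default
(library search penalizes missing peaks; both zero-fill and drop-
unmatched are implemented because the convention used upstream is not
fixed). Spectrum similarity is the Pearson correlation; the headline
statistic is the *median* PCC over precursors. RT/IM agreement is OLS
R² with a two-tailed p-value for slope ≠ 0. `normalize_irt` maps run
RTs onto a 120-min-gradient indexed scale either by a least-squares
linear fit to shared reference peptides (a lowess span of zero
degenerates to linear) or by pure gradient scaling.

## Synthetic data

The generator stands in for the experimental SecMS libraries so every
stage is testable offline, and keeps its noiseless truth for recovery
tests. It emulates: tryptic-looking random sequences (length 7–30, K/R
C-terminus, ≥ 1 Cys, all Cys IodoAPB-CAM-labeled, charges 2–3),
RT = intercept + Σ residue coefficients (a fixed hydrophobicity-like
scale shipped in-repo) + N(0, σ_rt = 3 iRT units), CCS = a_z·(m/z)^0.5 +
N(0, σ_ccs = 5 Å²), and MS2 intensities from a smooth deterministic
function of cleavage position, flanking-residue basicity and precursor
charge (including a proline y-boost), with multiplicative noise
(1 + N(0, σ_ms2 = 0.10)). Both the RT coefficients and basicity table map
`U` to the `C` value, embedding the proxy assumption; `generate_sec_holdout`
emits Sec twins with *fresh* noise draws around the same truth. The noise
levels are the generator's fixed study conditions: roughly 2–3 % of signal
range in each channel, about what well-calibrated replicate libraries show.

It does **not** emulate: missing/spurious peaks, interference,
co-elution, charge-state crosstalk, instrument drift, modified-Met
variants, or any systematic Sec/Cys property difference. Passing the
recovery tests therefore shows the machinery (transform, encodings,
training, prediction, metrics) is correct and that learnable structure
is recovered to the noise limit — not that real-data accuracies are
reproduced, which would require the deposited raw data.

The MS2 generative function is deliberately smooth and low-order so that
a small transformer can learn it in a desk-scale schedule; a recovery
failure therefore indicates a code defect, not task hardness.

**Noise ceilings.** Against observations y = t + N(0, σ²), the best
attainable R² is Var(t)/(Var(t)+σ²); against y = t(1+ε) the best
attainable per-spectrum PCC is √(Var(t)/(Var(t)+σ²·E[t²])), and the
ceiling reported is the median over spectra. The recovery criterion is
metric ≥ ceiling − 0.03.

## Problem sizes and numerical choices

The recovery experiment uses 2,000 peptides, desk-scale model dims, and
per-task pretraining epochs {MS2: 50, RT: 60, CCS: 60}; it completes in a
few minutes on one CPU and the margins to the ceilings are typically
≤ 0.01. Tolerances: mass bookkeeping is asserted at 1e-8–1e-9 Da
(pure float rounding); printed reference deltas at 1e-5 Da or half an
ulp of their printed precision. Degenerate inputs: empty sequences,
empty binder lists, empty training sets, non-finite losses, constant-x
regressions and zero-variance spectra all raise or flag explicitly
rather than returning NaN.

## Known limitations

* No semi-tryptic peptides, no variable modifications in the predicted
  library beyond the fixed labels, no a/c/x/z ions, no isotope envelopes.
* Fragment charge > 2 and modloss intensities are not predicted.
* NCE/instrument metadata default to a fixed profile (timsTOF, NCE 30)
  when the source library lacks them; no IM-dependent collision-energy
  modeling.
* Real pretrained weights are not shipped; accuracy on real data depends
  on the experimental Cys library used for pretraining.
* Multi-Cys peptides are substituted at all labeled sites; excluding
  them is possible upstream but not a built-in mode.
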