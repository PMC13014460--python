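# Methods

## Model

`mvitoxnet` is a binary classifier for acute dermal toxicity (ADT) that
fuses five views of a molecule given as a SMILES string:

* **M_maccs** — 167-bit MACCS structural keys (bit 0 is a placeholder and is
  never set);
* **M_ecfp** — 2048-bit binary ECFP4 (Morgan circular fingerprint, radius 2,
  folded);
* **M_char / M_atom / M_bpe** — the SMILES as a character stream, as
  atom-level tokens (bracket expressions, `Cl`/`Br`, `%nn` ring escapes are
  single tokens), and as byte-pair-encoded subword tokens learned over
  atom-level base units.

The two fingerprints are concatenated, `M_fp = [M_maccs | M_ecfp]`, and
encoded by a two-layer fully connected network with a Swish
(`x * sigmoid(x)`) hidden activation:

    R_fp = FC(M_fp)

Each token view is embedded and encoded by its own two-layer 1-D CNN
(kernel 3) with Softplus (`log(1 + e^x)`) activations and global max
pooling over non-pad positions:

    R_view = MaxPool(CNN(M_view)),   view in {char, atom, bpe}

Representations are fused by weighted summation — atom-level tokens are the
primary sequence signal; the character and BPE streams and the fingerprints
enter as down-weighted auxiliaries:

    R_seq = R_atom + alpha * (R_char + R_bpe)
    R     = R_seq + beta * R_fp

A single linear layer plus sigmoid decodes `R` into a toxicity probability,
trained with binary cross-entropy and Adam.

**Weighted model averaging (WMA).** Training snapshots the parameters after
every epoch together with the validation AUPRC (the selection metric: the
datasets this method targets are small with a positive-minority class, so
threshold-free precision-recall behaviour is the relevant ranking
criterion). The top three checkpoints by validation AUPRC, `W1, W2, W3`,
are collapsed into one inference model

    W_final = (1 - 2*kappa) * W1 + kappa * (W2 + W3),    kappa in [0, 0.4]

so the weights are non-negative and sum to one; `kappa = 0` is plain
best-checkpoint selection. Averaging parameters elementwise is well defined
because the parameter schema is fixed by the model configuration and the
network contains no normalization layers. With fewer than three checkpoints
the same weight profile is renormalized to sum to one.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha`, `beta` | 0.1 | fusion weights of the auxiliary views; auxiliaries help but should not dominate the atom view |
| max lengths | 80 / 60 / 40 | encoded lengths for char / atom / BPE streams; BPE compresses hardest, so its budget is smallest |
| BPE target size | 498 | subword vocabulary budget; small corpora saturate far below it (merging stops when no pair repeats) |
| `embed_dim`, `conv_channels`, `repr_dim`, `fc_hidden` | 128 / 128 / 128 / 512 | free architectural choices; fusion by summation forces all encoder outputs to share `repr_dim` |
| `kernel_size` | 3 | two stacked kernels of 3 give a receptive field of 5 tokens |
| `learning_rate` | 1e-5 | Adam step size for the full-scale setting |
| `batch_size`, `epochs` | 64, 50 | one checkpoint per epoch feeds WMA |
| `kappa`, `top_k` | 0.2, 3 | WMA weight and ensemble size |
| decision threshold | 0.5 | probability at or above the threshold counts as toxic |

## Numerical and design choices

* **Pad handling.** The pad embedding row is pinned at zero (never trained)
  and the activations between the two convolutions are zeroed at pad
  positions, so zero `same` convolution padding is exactly equivalent to
  extending the sequence with pad tokens; max pooling is restricted to
  non-pad positions. Together these make representations invariant to
  appended padding. An all-pad sequence falls back to pooling over every
  position and yields a finite output rather than an error.
* **Activation placement.** Softplus after each of the two convolutions;
  Swish after the first fingerprint FC layer; final projections and the
  decoder input are linear. The decoder is one linear layer plus sigmoid
  (a probability is required by the BCE loss); deeper decoders are
  configurable but off by default.
* **No dropout, no batch/layer norm.** Keeps forward outputs independent of
  batch composition and keeps parameter averaging meaningful.
* **BPE determinism.** Merges pick the most frequent adjacent pair; ties
  break toward the lexicographically smallest (left, right) pair. Training
  stops at the vocabulary budget or when no pair occurs twice. Application
  replays merges in rank order exhaustively. Base units are atom-level
  tokens, which is what lets a single subword span a bracket atom plus
  branch punctuation (e.g. `[C@H](O)`).
* **Checkpoint selection tie-break.** Among checkpoints with equal
  validation AUPRC the *later* epoch wins. AUPRC is threshold-free, so on a
  small validation set many epochs can tie exactly (typically at 1.0 once
  the ranking is perfect); among equally-ranked checkpoints the later one
  has lower training loss and better-calibrated probabilities, whereas
  preferring the earliest would systematically select undertrained models
  whose outputs sit on one side of the decision threshold. An optional
  `subsequent_only` mode restricts the runner-ups to epochs after the best
  one.
* **Metrics.** BACC, recall, F1 and MCC are computed from confusion counts
  with explicit zero-denominator conventions (MCC -> 0; an empty-class BACC
  term contributes 0 with a warning). AUROC uses the rank (Mann-Whitney)
  form with ties counting one half, which equals trapezoidal ROC
  integration. AUPRC uses the average-precision step convention rather than
  trapezoidal PR interpolation, which is known to overestimate. Single-class
  inputs yield NaN with a warning for the ranking metrics. All six match
  scikit-learn's implementations to 1e-9 in the test suite but are
  implemented independently, so model selection is self-consistent.
* **Determinism.** All randomness flows from explicit seeds: dataset
  generation, splitting, parameter initialization and minibatch shuffling.
  Two runs with the same seeds produce bit-identical parameters.

## Synthetic data

The generator emulates the *structure* of small imbalanced ADT datasets —
roughly 1,300–1,700 molecules with 27–37% positives — without reproducing
their chemistry. Molecules are seeded concatenations of small valid
fragments (alkyl chains, branches, hydroxyl/carbonyl, benzene, chiral
bracket atoms); a molecule is positive exactly when it contains the
toxicophore substructure (default: a trichloromethyl group, which also
exercises two-letter `Cl` tokens), XOR an optional Bernoulli label-noise
flip. Positive counts are exact by construction at zero noise, every SMILES
is validated with RDKit, and records carry canonical SMILES.

`generate_similar_pairs` produces the hard case that motivates subword
tokenization: pairs differing by one or two inserted chain carbons with
discordant labels. Half the pairs are long plain carbon chains, whose
homologue members fold to *identical* MACCS+ECFP4 fingerprints while their
token streams still differ — so fingerprint-only models cannot separate
them but sequence views can. Pair members keep their generated string form
(not re-canonicalized) so the few-character edit structure is preserved
verbatim.

What passing tests on this generator do **not** show: performance on real
toxicity data. Real ADT labels are driven by pharmacokinetics and many
interacting substructures, not a single planted motif; real SMILES are
longer and more diverse; and real class boundaries are noisy. The synthetic
recovery experiment is a correctness check of the pipeline (featurization,
optimization, selection, averaging), not an estimate of real-world accuracy.

## Experiment scale

The scripted end-to-end experiment (`scripts/acceptance.py`, mirrored by the
test suite) uses 400 training / 100 validation / 100 test molecules at
prevalence 0.3 with zero label noise, 50 epochs, batch 64, WMA with
kappa = 0.2 — and a deliberately compact model (`embed_dim` 32,
`conv_channels` 32, `repr_dim` 32, `fc_hidden` 64) with Adam at 1e-3.
The widths and step size are the package's desk-scale profile: on a planted
single-motif task this capacity is ample, and a NumPy implementation trains
it in well under a minute on one CPU core. The 128-wide defaults and the
1e-5 step remain the configuration intended for real datasets at the
method's published scale.

## Limitations

* The network and optimizer are implemented in NumPy with hand-written
  gradients (verified against finite differences in the tests); there is no
  GPU path, and large-vocabulary / large-corpus BPE training (the published
  498-token vocabulary was trained on 100 million molecules) is supported by
  the API but not exercised at that scale.
* The pretrained 498-token BPE vocabulary is not bundled; the loader reads
  external merge files in the common space-separated format, and the worked
  subword segmentation example is reproduced with a small constructed merge
  table (see `tests/test_acceptance.py`).
* Labels are taken as given binary GHS classes; LD50 regression and
  multi-level potency are out of scope.
* `stratified_split` falls back to a plain shuffle split (with a warning)
  when a split side cannot hold every class.
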