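# tcnovo

De novo peptide sequencing from HCD tandem mass spectra with a fully
convolutional neural network.

In shotgun proteomics, a peptide selected for fragmentation yields an MS/MS
spectrum whose dominant peaks are the b- and y-ion ladders
(b_i = Σ_{k≤i} m_k + H⁺, y_j = Σ_{k>n−j} m_k + H₂O + H⁺). Database search
engines identify such spectra only when the peptide is in a reference
database; *de novo* sequencing reads the peptide directly from the ladder
structure. `tcnovo` implements a dilated temporal-convolution (TCN)
architecture for this task: the spectrum is binned to a 20,480-dimensional
vector (0.1 Th bins over 0–2000 Th), stacked with a scaled m/z channel and
the reversed copies of both into a 20,480 × 4 matrix, passed through five
TCN blocks with down-sampling (channels [192, 288, 384, 576, 768]; each
block's receptive field is 1 + 2(k−1)(2ⁿ−1) for kernel k and n dilation
levels), fused bottom-up into a 32-position feature tensor, and decoded by
a per-position softmax into a 32 × 23 probability matrix (30 residue
positions + end + padding over 20 amino acids + 3 special symbols). The
loss is `masked_ce + c·MAE` — cross-entropy on non-padding positions plus a
small differentiable penalty on the expected-vs-true peptide mass — with
five auxiliary tasks (tryptic flag, length, residue presence, composition,
adjacent pairs). Decoding is greedy per position with a quality score
(product of residue probabilities) and a precursor-mass rescue that tries
each position's runner-up residue when the decoded mass misses the
precursor by more than 10 ppm.

The network runs on a small numpy autodiff engine included in the package
(`tcnovo.nn`) — convolutions lower to im2col + GEMM and train at BLAS
speed on a single CPU at desk scale. A synthetic HCD simulator
(`tcnovo.simulator`) generates b/y ladders with realistic intensity
structure (weak y-ions, suppressed b1/b2, noise peaks, precursor ppm
jitter) so the entire pipeline — training included — is exercisable
without any data download. See `docs/methods.md` for the model,
conventions and the desk-scale configuration.

## Worked example

Simulate a benchmark, train the desk-scale model, sequence and evaluate
(one CPU core; the train step takes ~15–20 minutes):

```bash
tcnovo simulate --n 5800 --seed 7 --out-dir data/
tcnovo train --mgf data/synthetic.mgf --truth data/synthetic.tsv \
             --out model --seed 7 --log train_log.csv
tcnovo denovo --mgf data/synthetic.mgf --checkpoint model --out results.tsv
tcnovo evaluate --results results.tsv --truth data/synthetic.tsv \
                --out report.json --curve curve.csv
```

`results.tsv` carries one row per spectrum: peptide, quality score
(product of residue probabilities), theoretical mass, ppm to the
precursor, and the rescue/mass-filter flags; `curve.csv` is the
precision–coverage curve over quality-score thresholds.

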