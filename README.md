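# procdl — dictionary learning with group-wise Procrustes rotations

`procdl` learns overcomplete dictionaries for sparse linear signal
representation.  Given training signals Y ∈ ℝ^{n×L}, it seeks a dictionary
D ∈ ℝ^{n×m} (n < m, unit-ℓ2 atoms) and k-sparse coefficients X ∈ ℝ^{m×L}
minimizing

    ‖Y − D X‖_F²   subject to   ‖x_i‖₀ ≤ k,  i = 1, …, L,

by the classic alternating scheme: sparse-code X with Orthogonal Matching
Pursuit, then update D, and repeat.  The package's centerpiece is a
dictionary-update rule that splits the atoms into groups I ⊂ [m] (ordered
by ascending atom popularity, the ℓ0-count of each row of X) and rotates
each group jointly.  Writing E = Y − D_{I^c} X_{I^c} and H = D_I X_I, the
best orthogonal transformation of the group solves the Orthogonal
Procrustes problem

    min_{R ∈ O(n)} ‖E − R H‖_F²,      R̂ = U Vᵀ  for  E Hᵀ = U Σ Vᵀ,

and D_I ← R̂ D_I never increases the objective while keeping every atom at
unit norm — no renormalization step is needed.  The cross-product E Hᵀ is
assembled from cached products X Yᵀ and X Xᵀ in O(s·n·(n+m−s)) flops per
group, and its SVD may be truncated at rank s = |I|.

For benchmarking, the package also implements two standard baselines
behind the same interface — K-SVD (per-atom rank-1 SVD update with
coefficient re-encoding) and ILS-DLA (batch least-squares update with
column renormalization) — plus:

* a **synthetic benchmark**: ground-truth Gaussian dictionaries, exact-SNR
  noise injection, and sign/permutation-invariant atom matching
  (1 − |d_iᵀ d̃_j| < δ = 0.01, optimal assignment);
* an **ECG compression pipeline**: R-peak detection, mean-removed RR
  segments, OMP coding with coefficient quantization, and the bit-accounting
  compression rate CR = qN / (k·q̂·M + M·log₂C(m,k));
* batch OMP with a compiled (numba) per-column kernel and an equivalent
  vectorized NumPy engine.

Intended users: signal-processing and biomedical-engineering researchers
studying dictionary learning, and anyone needing a reproducible sparse
compression baseline for quasi-periodic biosignals.

## Worked example

```sh
python examples/learn_dictionary.py
```

prints (50×100 dictionary, 5-sparse codes, L = 2000, 30 dB noise, 60
iterations):

```
iteration   E_SNR (dB)
        1       6.04
       11      14.89
       21      17.84
       31      19.49
       41      19.97
       51      20.88
       60      20.07

recovered 93/100 ground-truth atoms (cosine distance < 0.01)
```

E_SNR = 20·log₁₀(‖Y‖_F/‖Y − DX‖_F) climbing toward the 30 dB noise floor
means the model explains everything except the injected noise, and 93/100
matched atoms means the generating dictionary was essentially identified
up to column permutation and sign.  The other examples compare the three
learners on paired instances (`compare_learners.py`), sweep noise levels
(`atom_recovery.py`), and trace an ECG rate-distortion curve
(`ecg_rate_distortion.py`).

A thin CLI wraps the same library calls:

```sh
procdl simulate --n 50 --m 100 --L 2000 --k 5 --snr 30 -o out/
procdl learn out/Y.csv --algo rsvd --m 100 --k 5 --iters 60 -o out/run/
procdl recover --n 50 --m 100 --L 2000 --k 5 --trials 5 --seed 1 -o rec.csv
```

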